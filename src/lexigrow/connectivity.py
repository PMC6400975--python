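"""Cortical architecture and synaptic link construction.

Twelve areas, four processing streams:

* perisylvian auditory:      A1 - AB - PB
* perisylvian articulatory:  PF_i - PM_i - M1_i
* extrasylvian ventral visual:    V1 - TO - AT
* extrasylvian dorsolateral motor: PF_L - PM_L - M1_L

Between-area bundles comprise the 8 next-neighbour links within streams, the
6 links fully interconnecting the multimodal hubs {PB, PF_i, AT, PF_L}, and 8
second-order "jumping" links that skip one area within a stream — 22
reciprocal bundles in total.  Within an area every excitatory cell projects
sparsely into a local neighbourhood; an inhibitory twin cell pools spikes from
the 5x5 square around its position.  Link existence is Bernoulli with a
Gaussian distance profile clipped to zero outside the neighbourhood square,
and initial weights are uniform on [0, 0.1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SimConfig

# Canonical area order; global cell index = area_index * N + row * G + col.
AREAS: tuple[str, ...] = (
    "A1", "AB", "PB", "PF_i", "PM_i", "M1_i",
    "V1", "TO", "AT", "PF_L", "PM_L", "M1_L",
)
AREA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AREAS)}

PRIMARY_AREAS: tuple[str, ...] = ("A1", "M1_i", "V1", "M1_L")
HUB_AREAS: tuple[str, ...] = ("PB", "PF_i", "AT", "PF_L")
PERISYLVIAN: tuple[str, ...] = ("A1", "AB", "PB", "PF_i", "PM_i", "M1_i")
EXTRASYLVIAN: tuple[str, ...] = ("V1", "TO", "AT", "PF_L", "PM_L", "M1_L")

_ADJACENT = (
    ("A1", "AB"), ("AB", "PB"),
    ("PF_i", "PM_i"), ("PM_i", "M1_i"),
    ("V1", "TO"), ("TO", "AT"),
    ("PF_L", "PM_L"), ("PM_L", "M1_L"),
)
_HUB = (
    ("PB", "PF_i"), ("PB", "AT"), ("PB", "PF_L"),
    ("PF_i", "AT"), ("PF_i", "PF_L"), ("AT", "PF_L"),
)
_JUMPING = (
    ("A1", "PB"), ("PB", "PM_i"), ("AB", "PF_i"), ("PF_i", "M1_i"),
    ("V1", "AT"), ("AT", "PM_L"), ("TO", "PF_L"), ("PF_L", "M1_L"),
)


@dataclass(frozen=True)
class Architecture:
    """The fixed 12-area graph with its 22 reciprocal between-area bundles."""

    areas: tuple[str, ...]
    bundles: frozenset[frozenset[str]]

    def neighbours(self, area: str) -> set[str]:
        if area not in AREA_INDEX:
            raise ValueError(f"unknown area {area!r}")
        return {next(iter(b - {area})) for b in self.bundles if area in b}

    def has_bundle(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.bundles

    def directed_pairs(self) -> list[tuple[str, str]]:
        """Both directions of every bundle, in canonical area order."""
        out = []
        for a in AREAS:
            for b in AREAS:
                if a != b and self.has_bundle(a, b):
                    out.append((a, b))
        return out


def build_architecture() -> Architecture:
    bundles = frozenset(frozenset(p) for p in _ADJACENT + _HUB + _JUMPING)
    assert len(bundles) == 22
    return Architecture(areas=AREAS, bundles=bundles)


# ---------------------------------------------------------------------------
# link populations
# ---------------------------------------------------------------------------

@dataclass
class SynapseSet:
    """Directed weighted e->e links, partitioned by (source area, target area).

    ``src``/``tgt`` are global excitatory cell indices; ``blocks`` maps an
    (source area, target area) label pair to the half-open slice of the link
    arrays that holds that projection.
    """

    src: np.ndarray                      # int32 global source cell ids
    tgt: np.ndarray                      # int32 global target cell ids
    w: np.ndarray                        # float64 weights
    blocks: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    @property
    def n_links(self) -> int:
        return self.src.size

    def projection(self, src_area: str, tgt_area: str) -> "SynapseSet":
        lo, hi = self.blocks[(src_area, tgt_area)]
        return SynapseSet(self.src[lo:hi], self.tgt[lo:hi], self.w[lo:hi],
                          {(src_area, tgt_area): (0, hi - lo)})

    def copy(self) -> "SynapseSet":
        return SynapseSet(self.src.copy(), self.tgt.copy(), self.w.copy(),
                          dict(self.blocks))

    @staticmethod
    def concatenate(parts: list["SynapseSet"]) -> "SynapseSet":
        blocks: dict[tuple[str, str], tuple[int, int]] = {}
        off = 0
        for p in parts:
            for key, (lo, hi) in p.blocks.items():
                blocks[key] = (off + lo, off + hi)
            off += p.n_links
        return SynapseSet(
            np.concatenate([p.src for p in parts]) if parts else np.empty(0, np.int32),
            np.concatenate([p.tgt for p in parts]) if parts else np.empty(0, np.int32),
            np.concatenate([p.w for p in parts]) if parts else np.empty(0, float),
            blocks,
        )

    # -- serialisation -------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            src=self.src, tgt=self.tgt, w=self.w)
        meta = {f"{a}->{b}": [int(lo), int(hi)]
                for (a, b), (lo, hi) in self.blocks.items()}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SynapseSet":
        path = Path(path)
        dat = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        blocks = {}
        for key, (lo, hi) in meta.items():
            a, b = key.split("->")
            blocks[(a, b)] = (lo, hi)
        return cls(dat["src"], dat["tgt"], dat["w"], blocks)


def _projection_rng(seed: int, src_idx: int, tgt_idx: int) -> np.random.Generator:
    # keyed independently of build order so identical seeds give identical links
    return np.random.default_rng(np.random.SeedSequence((int(seed), src_idx, tgt_idx)))


def _draw_projection(rng: np.random.Generator, cfg: SimConfig, p0: float,
                     src_area: str, tgt_area: str) -> SynapseSet:
    """Bernoulli links with Gaussian distance kernel, clipped to the square."""
    g = cfg.grid_size
    n = cfg.n_cells_per_area
    half = cfg.neighbourhood // 2
    within = src_area == tgt_area
    rows = np.repeat(np.arange(g), g)
    cols = np.tile(np.arange(g), g)

    srcs, tgts, ws = [], [], []
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            if within and dr == 0 and dc == 0:
                continue  # no self-link
            p = p0 * np.exp(-(dr * dr + dc * dc) / (2.0 * cfg.sigma ** 2))
            ok = ((rows + dr >= 0) & (rows + dr < g)
                  & (cols + dc >= 0) & (cols + dc < g))
            cand = np.nonzero(ok)[0]
            hit = cand[rng.random(cand.size) < p]
            if hit.size:
                srcs.append(hit)
                tgts.append(hit + dr * g + dc)
                ws.append(rng.uniform(0.0, cfg.w_init_max, hit.size))
    if srcs:
        src = np.concatenate(srcs).astype(np.int32)
        tgt = np.concatenate(tgts).astype(np.int32)
        w = np.concatenate(ws)
    else:
        src = np.empty(0, np.int32)
        tgt = np.empty(0, np.int32)
        w = np.empty(0, float)
    src = src + AREA_INDEX[src_area] * n
    tgt = tgt + AREA_INDEX[tgt_area] * n
    return SynapseSet(src, tgt, w, {(src_area, tgt_area): (0, src.size)})


def build_within_area_links(seed: int, cfg: SimConfig, area: str,
                            p0: float | None = None) -> SynapseSet:
    """Within-area patchy excitatory links for one area."""
    if area not in AREA_INDEX:
        raise ValueError(f"unknown area {area!r}")
    i = AREA_INDEX[area]
    p0 = cfg.p0_within if p0 is None else p0
    return _draw_projection(_projection_rng(seed, i, i), cfg, p0, area, area)


def build_between_area_links(seed: int, bundle: tuple[str, str],
                             cfg: SimConfig, arch: Architecture | None = None,
                             p0: float | None = None) -> SynapseSet:
    """Both directed link populations of one reciprocal bundle."""
    arch = arch or build_architecture()
    a, b = bundle
    if not arch.has_bundle(a, b):
        raise ValueError(f"areas {a!r} and {b!r} are not connected in the architecture")
    p0 = cfg.p0_between if p0 is None else p0
    parts = []
    for s, t in ((a, b), (b, a)):
        rng = _projection_rng(seed, AREA_INDEX[s], AREA_INDEX[t])
        parts.append(_draw_projection(rng, cfg, p0, s, t))
    return SynapseSet.concatenate(parts)


def build_synapses(seed: int, cfg: SimConfig,
                   arch: Architecture | None = None) -> SynapseSet:
    """All e->e links of a network instance: 12 within-area populations plus
    the 44 directed between-area populations, deterministic in ``seed``."""
    arch = arch or build_architecture()
    parts = [build_within_area_links(seed, cfg, a) for a in AREAS]
    for s, t in arch.directed_pairs():
        rng = _projection_rng(seed, AREA_INDEX[s], AREA_INDEX[t])
        parts.append(_draw_projection(rng, cfg, cfg.p0_between, s, t))
    return SynapseSet.concatenate(parts)


def inhibitory_pool_indices(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (indptr, members): for every cell position, the excitatory
    cells of the same area within the 5x5 (``inhib_neighbourhood``) square
    whose spikes the twin inhibitory cell pools."""
    g = cfg.grid_size
    n = cfg.n_cells_per_area
    half = cfg.inhib_neighbourhood // 2
    counts = []
    members = []
    for r in range(g):
        for c in range(g):
            rr0, rr1 = max(0, r - half), min(g, r + half + 1)
            cc0, cc1 = max(0, c - half), min(g, c + half + 1)
            blk = [rr * g + cc for rr in range(rr0, rr1) for cc in range(cc0, cc1)]
            counts.append(len(blk))
            members.extend(blk)
    indptr1 = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    members1 = np.asarray(members, np.int64)
    # replicate per area with the global offset
    n_areas = len(AREAS)
    indptr = np.concatenate(
        [[0]] + [indptr1[1:] + k * members1.size for k in range(n_areas)]
    ).astype(np.int64)
    members_all = np.concatenate([members1 + k * n for k in range(n_areas)])
    return indptr, members_all.astype(np.int64)
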