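"""Synthetic sensorimotor stimuli.

A "word" is a set of fixed binary patterns delivered to primary areas: a word
form (A1 + M1_i) plus a semantic grounding pattern (V1 for object words, M1_L
for action words).  Each pattern activates ``pattern_size`` cells (19 of 625,
about 3% of an area) chosen at random without replacement.  During sighted
training the non-relevant fourth primary area receives a fresh uncorrelated
pattern every trial; the congenitally blind regime delivers nothing to V1 —
neither correlated nor uncorrelated patterns.  Continuous cell-intrinsic white
noise plus "contextual" white noise on the primary areas complete the input
statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import SimConfig
from .connectivity import PRIMARY_AREAS

OBJECT, ACTION = "object", "action"

#: primary areas addressed by each word category (word form + semantic area)
CATEGORY_TARGETS = {
    OBJECT: ("A1", "M1_i", "V1"),
    ACTION: ("A1", "M1_i", "M1_L"),
}
#: the non-relevant fourth primary area fed uncorrelated input (sighted only)
CATEGORY_FOURTH = {OBJECT: "M1_L", ACTION: "V1"}


@dataclass(frozen=True)
class WordPattern:
    """One word's fixed sensorimotor input patterns.

    ``targets`` maps a primary-area label to the sorted local (0-based,
    row-major) indices of its active cells.
    """

    word_id: int
    category: str
    targets: dict[str, np.ndarray]

    def __post_init__(self):
        if self.category not in CATEGORY_TARGETS:
            raise ValueError(f"unknown category {self.category!r}")
        if set(self.targets) != set(CATEGORY_TARGETS[self.category]):
            raise ValueError(
                f"{self.category} word must target {CATEGORY_TARGETS[self.category]}")

    def dense(self, area: str, n_cells: int) -> np.ndarray:
        v = np.zeros(n_cells)
        v[self.targets[area]] = 1.0
        return v


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes: intrinsic k2 = sqrt(24/dt), contextual in raw units."""

    intrinsic_amplitude: float
    contextual_amplitude: float
    timestep_duration: float

    def __post_init__(self):
        if self.intrinsic_amplitude < 0 or self.contextual_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        expect = math.sqrt(24.0 / self.timestep_duration)
        if not math.isclose(self.intrinsic_amplitude, expect, rel_tol=1e-12):
            raise ValueError("intrinsic amplitude inconsistent with sqrt(24/dt)")

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "NoiseSpec":
        return cls(cfg.k2, cfg.contextual_amplitude, cfg.dt)


def _draw_pattern(rng: np.random.Generator, n_cells: int, size: int,
                  shape: str = "compact") -> np.ndarray:
    """One binary input pattern: ``size`` distinct cells of an area.

    'compact' places a topographic blob around a uniformly random centre (the
    size nearest cells, random tie-break), mimicking the local feature maps
    of primary cortices; 'scattered' samples cells uniformly without
    replacement.
    """
    if size == 0:
        return np.empty(0, np.int64)
    if shape == "scattered":
        return np.sort(rng.choice(n_cells, size=size, replace=False)).astype(np.int64)
    g = int(round(math.sqrt(n_cells)))
    r0, c0 = rng.integers(0, g, size=2)
    rows, cols = np.divmod(np.arange(n_cells), g)
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    jitter = rng.random(n_cells)            # random tie-break among equidistant cells
    order = np.lexsort((jitter, d2))
    return np.sort(order[:size]).astype(np.int64)


def generate_word_patterns(seed: int, n_object: int, n_action: int,
                           pattern_size: int, cfg: SimConfig | None = None
                           ) -> list[WordPattern]:
    """Fixed word patterns for one network instance, deterministic in seed.

    The n_object + n_action word forms (the A1 and M1_i patterns) are pairwise
    distinct; patterns are drawn independently across areas.
    """
    cfg = cfg or SimConfig()
    n_cells = cfg.n_cells_per_area
    if pattern_size > n_cells:
        raise ValueError("pattern_size exceeds the number of cells per area")
    if n_object < 0 or n_action < 0:
        raise ValueError("word counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 7)))
    shape = cfg.pattern_shape
    words: list[WordPattern] = []
    seen_forms: set[tuple] = set()
    categories = [OBJECT] * n_object + [ACTION] * n_action
    for wid, cat in enumerate(categories, start=1):
        while True:
            form = {a: _draw_pattern(rng, n_cells, pattern_size, shape)
                    for a in ("A1", "M1_i")}
            key = (tuple(form["A1"]), tuple(form["M1_i"]))
            if pattern_size == 0 or key not in seen_forms:
                seen_forms.add(key)
                break
        sem_area = CATEGORY_TARGETS[cat][2]
        targets = dict(form)
        targets[sem_area] = _draw_pattern(rng, n_cells, pattern_size, shape)
        words.append(WordPattern(word_id=wid, category=cat, targets=targets))
    return words


def uncorrelated_pattern(rng: np.random.Generator, area: str, pattern_size: int,
                         cfg: SimConfig | None = None) -> np.ndarray:
    """A trial-unique random pattern for the non-relevant fourth primary area."""
    cfg = cfg or SimConfig()
    if area not in CATEGORY_FOURTH.values():
        raise ValueError(f"uncorrelated input goes to V1 or M1_L, not {area!r}")
    if pattern_size > cfg.n_cells_per_area:
        raise ValueError("pattern_size exceeds the number of cells per area")
    return _draw_pattern(rng, cfg.n_cells_per_area, pattern_size, cfg.pattern_shape)


def contextual_noise(rng: np.random.Generator, area: str,
                     cfg: SimConfig | None = None) -> np.ndarray:
    """One step of i.i.d. uniform contextual noise over an area's cells.

    Zero-mean, range [-a/2, a/2] with a = ``contextual_amplitude`` (raw input
    units); applied to primary areas only, superimposed on any stimulus, and
    present during both learning and retrieval.
    """
    cfg = cfg or SimConfig()
    if area not in PRIMARY_AREAS:
        raise ValueError(f"contextual noise is delivered to primary areas, not {area!r}")
    a = cfg.contextual_amplitude
    return rng.uniform(-a / 2.0, a / 2.0, size=cfg.n_cells_per_area)


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def patterns_to_json(words: list[WordPattern], path: str | Path | None = None) -> str:
    doc = [
        {"word_id": w.word_id, "category": w.category,
         "targets": {a: [int(i) for i in idx] for a, idx in w.targets.items()}}
        for w in words
    ]
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def patterns_from_json(source: str | Path) -> list[WordPattern]:
    text = Path(source).read_text() if isinstance(source, Path) else source
    doc = json.loads(text)
    return [
        WordPattern(word_id=d["word_id"], category=d["category"],
                    targets={a: np.asarray(v, np.int64)
                             for a, v in d["targets"].items()})
        for d in doc
    ]
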