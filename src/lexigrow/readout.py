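"""Cell-assembly identification and recognition time courses.

*Production* readout: after training (plasticity frozen) the word-form
patterns are presented to A1 and M1_i for 15 steps and every excitatory
cell's firing rate is estimated by the low-pass filter with the fast readout
time constant (tau = 5).  A cell belongs to the word's cell assembly (CA)
when its time-averaged response reaches the area- and word-specific threshold
theta_A(w) = gamma * (maximal single-cell response in that area), gamma = 0.5.

*Recognition* readout: only the auditory (A1) pattern is presented; the
per-step number of spiking CA members per area is recorded through
stimulation, ignition and reverberation.  The total active duration is the
last step at which at least ``active_fraction`` (10%) of the CA members spike,
counted from stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .connectivity import AREA_INDEX, AREAS
from .engine import Network, seed_kernel_rng
from .stimuli import WordPattern


@dataclass
class CellAssembly:
    """The set of above-threshold excitatory cells for one word."""

    word_id: int
    category: str
    members: dict[str, np.ndarray]        # area -> local cell indices
    thresholds: dict[str, float]          # area -> theta_A(w)
    responses: np.ndarray                 # per-cell time-averaged response (global)
    empty_areas: tuple[str, ...] = ()     # areas with an all-zero response map

    def member_mask(self, net: Network) -> np.ndarray:
        mask = np.zeros(net.n_cells, np.uint8)
        for area, idx in self.members.items():
            mask[net.cells_of(area, idx)] = 1
        return mask

    @property
    def size(self) -> int:
        return sum(v.size for v in self.members.values())

    def count(self, area: str) -> int:
        return int(self.members.get(area, np.empty(0)).size)


@dataclass
class TimeCourse:
    """Per-step spiking of a word's CA during simulated recognition."""

    word_id: int
    counts: np.ndarray          # (steps, n_areas) spiking CA members
    ca_size: int
    stimulus_steps: int
    active_duration: int        # steps from onset, last step with >=10% active
    censored: bool              # still active when the step cap was reached
    phases: dict[str, tuple[int, int]]

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def production_stimulus(net: Network, word: WordPattern) -> np.ndarray:
    stim = np.zeros(net.n_cells)
    for area in ("A1", "M1_i"):
        stim[net.cells_of(area, word.targets[area])] = net.cfg.stimulus_amplitude
    return stim


def simulate_production(net: Network, word: WordPattern,
                        reset: bool = True) -> np.ndarray:
    """Stimulate the word form (A1 + M1_i) for 15 steps, plasticity frozen;
    returns each excitatory cell's peak fast-filtered rate estimate.

    Responses keep being tracked for ``production_post_steps`` input-free
    steps after stimulus offset: ignition cascades across several areas take
    a few membrane time constants per hop, so the distant areas of a circuit
    reach their peak response shortly after the stimulation window.
    """
    cfg = net.cfg
    stim = production_stimulus(net, word)
    total = np.zeros(net.n_cells)
    repeats = max(1, cfg.production_repeats)
    for _ in range(repeats):
        if reset:
            net.reset_state()
            net.run_phase(None, 20, plastic=False)   # settle into baseline
        res = net.run_phase(stim, cfg.production_steps,
                            plastic=False, track_response=True)
        resp = res["responses"]
        if cfg.production_post_steps > 0:
            post = net.run_phase(None, cfg.production_post_steps,
                                 plastic=False, track_response=True)
            resp = np.maximum(resp, post["responses"])
        total += resp
    return total / repeats


def identify_ca(responses: np.ndarray, word: WordPattern,
                cfg: SimConfig, gamma: float | None = None) -> CellAssembly:
    """Threshold the per-cell responses area by area.

    An area whose maximal response is zero contributes no members (responses
    must be strictly positive) and is flagged in ``empty_areas``.
    """
    gamma = cfg.gamma if gamma is None else gamma
    n = cfg.n_cells_per_area
    members: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    empty = []
    for area in AREAS:
        lo = AREA_INDEX[area] * n
        resp = responses[lo:lo + n]
        peak = float(resp.max()) if resp.size else 0.0
        thr = gamma * peak
        thresholds[area] = thr
        if peak <= 0.0:
            members[area] = np.empty(0, np.int64)
            empty.append(area)
        else:
            members[area] = np.nonzero((resp >= thr) & (resp > 0.0))[0]
    return CellAssembly(word_id=word.word_id, category=word.category,
                        members=members, thresholds=thresholds,
                        responses=responses.copy(),
                        empty_areas=tuple(empty))


def identify_assemblies(net: Network, words: list[WordPattern],
                        seed: int | None = None) -> list[CellAssembly]:
    """Production readout for every word of a trained network."""
    if seed is not None:
        seed_kernel_rng(int(seed) % (2 ** 31))
    out = []
    for word in words:
        resp = simulate_production(net, word)
        out.append(identify_ca(resp, word, net.cfg))
    return out


def count_ca_per_area(assemblies: list[CellAssembly], network: int,
                      regime: str) -> pd.DataFrame:
    """Mean CA cell count per area, averaged over each word type's words."""
    rows = []
    for word_type in ("object", "action"):
        group = [a for a in assemblies if a.category == word_type]
        for area in AREAS:
            mean = float(np.mean([a.count(area) for a in group])) if group else 0.0
            rows.append({"network": network, "regime": regime,
                         "word_type": word_type, "area": area,
                         "mean_count": mean})
    return pd.DataFrame(rows)


def simulate_recognition(net: Network, word: WordPattern,
                         assembly: CellAssembly,
                         seed: int | None = None) -> TimeCourse:
    """Present only the word's auditory (A1) pattern and follow the CA."""
    cfg = net.cfg
    if word.word_id != assembly.word_id:
        raise ValueError("assembly does not belong to this word")
    if seed is not None:
        seed_kernel_rng(int(seed) % (2 ** 31))
    net.reset_state()
    stim = np.zeros(net.n_cells)
    stim[net.cells_of("A1", word.targets["A1"])] = cfg.stimulus_amplitude
    mask = assembly.member_mask(net)
    n_steps = cfg.recognition_max_steps
    counts = np.zeros((n_steps, net.n_areas), np.int64)
    res = net.run_phase(stim, cfg.stimulus_steps, plastic=False,
                        member_mask=mask,
                        member_counts=counts[:cfg.stimulus_steps])
    net.run_phase(None, n_steps - cfg.stimulus_steps, plastic=False,
                  member_mask=mask, member_counts=counts[cfg.stimulus_steps:])

    total = counts.sum(axis=1)
    size = max(assembly.size, 1)
    need = max(1, int(np.ceil(cfg.active_fraction * size)))
    active = np.nonzero(total >= need)[0]
    duration = int(active[-1]) + 1 if active.size else 0
    censored = bool(active.size and active[-1] == n_steps - 1)

    ignition_at = np.nonzero(total >= 0.5 * size)[0]
    phases = {"stimulation": (0, cfg.stimulus_steps)}
    if ignition_at.size:
        phases["ignition"] = (int(ignition_at[0]), int(ignition_at[-1]) + 1)
    if duration > cfg.stimulus_steps:
        phases["reverberation"] = (cfg.stimulus_steps, duration)
    return TimeCourse(word_id=word.word_id, counts=counts, ca_size=assembly.size,
                      stimulus_steps=cfg.stimulus_steps,
                      active_duration=duration, censored=censored,
                      phases=phases)


def timecourse_frame(tc: TimeCourse) -> pd.DataFrame:
    """Long-format (step, area, active_members) table for one time course."""
    steps, n_areas = tc.counts.shape
    return pd.DataFrame({
        "step": np.repeat(np.arange(steps), n_areas),
        "area": np.tile(np.asarray(AREAS), steps),
        "active_members": tc.counts.ravel(),
        "word_id": tc.word_id,
    })


def membership_mask_grid(assembly: CellAssembly, area: str, grid: int) -> np.ndarray:
    """25x25 (or scaled) 0/1 membership image for one area, mirroring the
    CA topography panels."""
    m = np.zeros(grid * grid)
    m[assembly.members.get(area, np.empty(0, np.int64))] = 1.0
    return m.reshape(grid, grid)
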