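"""The word-learning protocol.

A trial presents one word's sensorimotor patterns to the primary areas for 16
time-steps with plasticity on, then runs input-free (interstimulus interval)
until the global inhibition of both multimodal gateway areas PB and PF_i has
decayed below a threshold — a fixed fraction of the peak value reached during
stimulation — so one trial cannot leak into the next.  In the *sighted*
regime the non-relevant fourth primary area receives a trial-unique
uncorrelated pattern; in the congenitally *blind* regime V1 receives no
pattern input at all, correlated or uncorrelated.  Contextual noise rides on
all primary areas throughout, in both regimes.

Paired sighted/blind instances are built from the same seeds: identical
initial connectivity, word patterns and noise streams, so visual deprivation
is the only difference between the members of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .connectivity import AREA_INDEX, SynapseSet, build_synapses
from .engine import Network, seed_kernel_rng
from .stimuli import (CATEGORY_FOURTH, CATEGORY_TARGETS, WordPattern,
                      generate_word_patterns, uncorrelated_pattern)

SIGHTED, BLIND = "sighted", "blind"


class IsiDivergenceError(RuntimeError):
    """Raised when network activity fails to return to baseline within the guard."""


@dataclass(frozen=True)
class TrainingRegime:
    mode: str = SIGHTED
    presentations_per_pattern: int = 3000
    stimulus_steps: int = 16
    isi_threshold_fraction: float = 0.05
    stimulus_amplitude: float = 500.0
    isi_max_steps: int = 500

    def __post_init__(self):
        if self.mode not in (SIGHTED, BLIND):
            raise ValueError(f"unknown regime mode {self.mode!r}")
        if self.stimulus_steps < 1:
            raise ValueError("stimulus_steps must be >= 1")
        if self.isi_threshold_fraction <= 0:
            raise ValueError("isi threshold must be > 0")

    @classmethod
    def from_config(cls, cfg: SimConfig, mode: str) -> "TrainingRegime":
        return cls(mode=mode,
                   presentations_per_pattern=cfg.presentations_per_pattern,
                   stimulus_steps=cfg.stimulus_steps,
                   isi_threshold_fraction=cfg.isi_threshold_fraction,
                   stimulus_amplitude=cfg.stimulus_amplitude,
                   isi_max_steps=cfg.isi_max_steps)


@dataclass
class TrialLogs:
    """Arrays of per-trial telemetry (one entry per presented trial)."""

    word_id: list[int] = field(default_factory=list)
    trial_steps: list[int] = field(default_factory=list)
    isi_steps: list[int] = field(default_factory=list)
    area_spikes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.word_id)


def build_trial_stimulus(net: Network, pattern: WordPattern,
                         regime: TrainingRegime,
                         rng: np.random.Generator) -> np.ndarray:
    """The raw stimulus vector for one trial.

    The uncorrelated fourth-area pattern is always drawn from ``rng`` so that
    paired sighted/blind runs consume identical random streams; the blind
    regime then zeroes every V1 entry (the deprivation is exactly the removal
    of the V1 input channel).
    """
    cfg = net.cfg
    stim = np.zeros(net.n_cells)
    amp = regime.stimulus_amplitude
    for area in CATEGORY_TARGETS[pattern.category]:
        stim[net.cells_of(area, pattern.targets[area])] = amp
    fourth = CATEGORY_FOURTH[pattern.category]
    unc = uncorrelated_pattern(rng, fourth, cfg.pattern_size, cfg)
    stim[net.cells_of(fourth, unc)] = amp
    if regime.mode == BLIND:
        lo = AREA_INDEX["V1"] * cfg.n_cells_per_area
        stim[lo:lo + cfg.n_cells_per_area] = 0.0
    return stim


def estimate_gate_floor(net: Network, steps: int = 200, chunk: int = 10) -> float:
    """Spontaneous ceiling of omega_G in the gateway areas PB / PF_i.

    Networks with live baseline firing keep omega_G bouncing around a noise
    floor, so the ISI threshold (a fraction of the stimulation peak) must
    never be set below it.  Sampled from a noise-only run with plasticity off.
    """
    pb, pfi = AREA_INDEX["PB"], AREA_INDEX["PF_i"]
    peak = 0.0
    for _ in range(steps // chunk):
        net.run_phase(None, chunk, plastic=False)
        peak = max(peak, net.state.omega_G[pb], net.state.omega_G[pfi])
    return 1.5 * peak


def present_trial(net: Network, pattern: WordPattern, regime: TrainingRegime,
                  rng: np.random.Generator, logs: TrialLogs | None = None,
                  gate_floor: float = 0.0) -> dict:
    """One learning trial: 16 stimulation steps, then the gated ISI."""
    stim = build_trial_stimulus(net, pattern, regime, rng)
    res = net.run_phase(stim, regime.stimulus_steps, plastic=True)
    thr = max(regime.isi_threshold_fraction * res["gate_peak"], gate_floor)
    isi = net.run_phase(None, regime.isi_max_steps, plastic=True,
                        gate_threshold=thr)
    pb, pfi = AREA_INDEX["PB"], AREA_INDEX["PF_i"]
    gate_omega = float(max(net.state.omega_G[pb], net.state.omega_G[pfi]))
    timed_out = isi["steps"] >= regime.isi_max_steps and gate_omega > thr
    if timed_out and gate_omega > 0.5 * net.cfg.n_cells_per_area:
        # runaway: a large fraction of the area is firing persistently
        raise IsiDivergenceError(
            f"runaway activity, no return to baseline within "
            f"{regime.isi_max_steps} steps (word {pattern.word_id}; omega_G "
            f"PB={net.state.omega_G[pb]:.2f} PF_i={net.state.omega_G[pfi]:.2f}, "
            f"threshold {thr:.3f})")
    out = {
        "word_id": pattern.word_id,
        "trial_steps": regime.stimulus_steps + isi["steps"],
        "isi_steps": isi["steps"],
        "gate_timeout": timed_out,
        "gate_omega": gate_omega,
        "area_spikes": res["area_spikes"] + isi["area_spikes"],
    }
    if logs is not None:
        logs.word_id.append(out["word_id"])
        logs.trial_steps.append(out["trial_steps"])
        logs.isi_steps.append(out["isi_steps"])
        logs.area_spikes.append(out["area_spikes"])
    return out


def train_network(net: Network, words: list[WordPattern],
                  regime: TrainingRegime, seed: int) -> TrialLogs:
    """Run the full protocol: every word presented ``presentations_per_pattern``
    times, order randomised within blocks of all words; deterministic in seed."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    seed_kernel_rng(int(seed) % (2 ** 31))
    floor = estimate_gate_floor(net)
    logs = TrialLogs()
    n = len(words)
    for _ in range(regime.presentations_per_pattern):
        for wi in rng.permutation(n):
            out = present_trial(net, words[wi], regime, rng, logs,
                                gate_floor=floor)
            if out["gate_timeout"]:
                # learning raises the spontaneous omega_G baseline; ratchet
                # the gate floor up so the ISI ends once activity is back at
                # the (new) baseline rather than at the pre-training one
                floor = max(floor, 1.2 * out["gate_omega"])
    return logs


@dataclass
class TrainedPair:
    """A sighted and a blind network trained from identical seeds."""

    instance: int
    words: list[WordPattern]
    sighted: Network
    blind: Network
    logs: dict[str, TrialLogs]


def instance_seeds(master_seed: int, instance: int) -> dict[str, int]:
    ss = np.random.SeedSequence((int(master_seed), int(instance)))
    build, patt, train = ss.generate_state(3) >> np.uint32(1)  # keep < 2**31
    return {"build": int(build), "patterns": int(patt), "train": int(train)}


def make_instance(cfg: SimConfig, master_seed: int, instance: int
                  ) -> tuple[SynapseSet, list[WordPattern], dict[str, int]]:
    seeds = instance_seeds(master_seed, instance)
    syn = build_synapses(seeds["build"], cfg)
    words = generate_word_patterns(seeds["patterns"], cfg.n_object,
                                   cfg.n_action, cfg.pattern_size, cfg)
    return syn, words, seeds


def train_pair(cfg: SimConfig, master_seed: int, instance: int,
               modes: tuple[str, ...] = (SIGHTED, BLIND)) -> TrainedPair:
    """Train one sighted/blind pair sharing connectivity, words and noise."""
    syn, words, seeds = make_instance(cfg, master_seed, instance)
    nets: dict[str, Network] = {}
    logs: dict[str, TrialLogs] = {}
    for mode in modes:
        net = Network(cfg, syn.copy())
        regime = TrainingRegime.from_config(cfg, mode)
        logs[mode] = train_network(net, words, regime, seeds["train"])
        nets[mode] = net
    return TrainedPair(instance=instance, words=words,
                       sighted=nets.get(SIGHTED), blind=nets.get(BLIND),
                       logs=logs)


def run_experiment(master_seed: int, cfg: SimConfig | None = None,
                   n_instances: int | None = None) -> list[TrainedPair]:
    """Train ``n_instances`` paired sighted/blind networks (2 per instance)."""
    cfg = cfg or SimConfig()
    n_instances = cfg.n_instances if n_instances is None else n_instances
    return [train_pair(cfg, master_seed, i) for i in range(n_instances)]
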