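"""Simulation configuration.

All neuron, plasticity and protocol constants live in one dataclass so that a
run is fully specified by (config, master seed).  Defaults are the values used
throughout: membrane/adaptation time constants are expressed in simulation
time-steps, potentials and thresholds in dimensionless model units, and raw
synaptic input is rescaled by ``k1`` before it enters a membrane potential.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SimConfig:
    # -- geometry -----------------------------------------------------------
    grid_size: int = 25            # each area is grid_size x grid_size cells
    neighbourhood: int = 19        # side of the square clipping e->e kernels (odd)
    inhib_neighbourhood: int = 5   # side of the square pooled by an i-cell (odd)
    sigma: float = 8.0             # Gaussian kernel width, grid units
    p0_within: float = 0.90        # kernel peak connection probability, within-area
    p0_between: float = 0.80       # kernel peak connection probability, between-area
    w_init_max: float = 0.1       # initial weights ~ U[0, w_init_max]

    # -- membrane / spiking -------------------------------------------------
    tau_e: float = 2.5             # excitatory membrane time constant (steps)
    tau_i: float = 5.0             # inhibitory membrane time constant (steps)
    k1: float = 0.01               # total-input rescaling factor
    dt: float = 0.005              # model-time step used in the noise amplitude
    k_G: float = 0.60              # global-inhibition strength
    thresh: float = 0.18           # spiking threshold
    alpha: float = 7.0             # adaptation strength
    tau_adapt: float = 10.0        # adaptation time constant (steps)
    tau_favg: float = 30.0         # rate-estimate time constant during learning
    tau_favg_readout: float = 5.0  # rate-estimate time constant for CA readout
    tau_glob: float = 12.0         # global-inhibition time constant (steps)
    inhib_gain: float = 10.0       # weight of the i->e (twin) link, raw input units

    # -- Hebbian rule -------------------------------------------------------
    delta: float = 0.0008          # discrete weight step +/- delta
    theta_pre: float = 0.05        # presynaptic rate needed for an 'active' projection
    theta_plus: float = 0.15       # postsynaptic potential threshold for LTP
    theta_minus: float = 0.14      # lower postsynaptic threshold (homosynaptic LTD)
    w_max: float = 0.26            # saturation bound on e->e weights

    # -- stimulation protocol ----------------------------------------------
    pattern_size: int = 19                 # active cells per primary-area pattern
    pattern_shape: str = "scattered"       # 'scattered' cells or 'compact' blob
    n_object: int = 6
    n_action: int = 6
    presentations_per_pattern: int = 3000
    stimulus_steps: int = 16               # word-pattern presentation length
    production_steps: int = 15             # 'word production' readout stimulation
    production_post_steps: int = 25        # response tracking after offset
    production_repeats: int = 5            # independent repeats averaged per word
    stimulus_amplitude: float = 500.0      # raw input per active pattern cell
    contextual_amplitude: float = 50.0     # peak-to-peak contextual noise, raw units
    isi_threshold_fraction: float = 0.05   # gate: fraction of peak omega_G(PB/PF_i)
    isi_max_steps: int = 500               # guard against non-convergent ISIs

    # -- readout ------------------------------------------------------------
    gamma: float = 0.5                # CA membership: fraction of per-area max response
    active_fraction: float = 0.10     # CA counts 'on' while >=10% of members spike
    recognition_max_steps: int = 200  # cap on a recognition run

    # -- experiment ---------------------------------------------------------
    n_instances: int = 13

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0 or self.tau_adapt <= 0 \
                or self.tau_favg <= 0 or self.tau_favg_readout <= 0 or self.tau_glob <= 0:
            raise ValueError("all time constants must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.grid_size <= 0:
            raise ValueError("grid_size must be > 0")
        for name in ("neighbourhood", "inhib_neighbourhood"):
            n = getattr(self, name)
            if n % 2 == 0 or n < 1:
                raise ValueError(f"{name} must be odd and >= 1")
        if self.neighbourhood > 2 * self.grid_size - 1:
            raise ValueError("neighbourhood larger than the grid allows")
        if self.pattern_size < 0 or self.pattern_size > self.n_cells_per_area:
            raise ValueError("pattern_size must be within [0, cells per area]")
        if not (0 <= self.theta_minus < self.theta_plus):
            raise ValueError("need 0 <= theta_minus < theta_plus")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.w_max <= self.w_init_max:
            raise ValueError("w_max must exceed the initial weight range")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.contextual_amplitude < 0 or self.stimulus_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.isi_threshold_fraction <= 0:
            raise ValueError("isi_threshold_fraction must be > 0")
        if self.pattern_shape not in ("compact", "scattered"):
            raise ValueError("pattern_shape must be 'compact' or 'scattered'")

    # ------------------------------------------------------------------
    @property
    def k2(self) -> float:
        """Intrinsic noise amplitude, 1*sqrt(24/dt)."""
        return math.sqrt(24.0 / self.dt)

    @property
    def n_cells_per_area(self) -> int:
        return self.grid_size * self.grid_size

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------------
    @classmethod
    def full(cls) -> "SimConfig":
        """The full-scale study configuration (25x25 areas, 3000 presentations)."""
        return cls()

    @classmethod
    def scaled(cls) -> "SimConfig":
        """Desk-scale preset: 15x15 areas, 300 presentations per pattern, 5 pairs.

        Besides shrinking the geometry, the preset compensates for standing in
        225 cells for a whole cortical area: the learning quantum is scaled by
        the presentation ratio (3000/300) so total plastic change per link is
        preserved, global inhibition by the area-size ratio (625/225) so the
        firing set point thresh/(k1*k_G*N) is preserved, and the per-link
        saturation bound is raised so a cell's maximal fan-in can still reach
        the spiking threshold.  See docs/methods.md for the drive arithmetic.
        """
        return cls(
            grid_size=15,
            neighbourhood=11,
            pattern_size=19,
            presentations_per_pattern=300,
            n_instances=5,
            delta=0.02,
            k_G=2.5,
            w_max=6.0,
            contextual_amplitude=75.0,
        )

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance headers."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
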