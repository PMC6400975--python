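"""Per-time-step neuron and area dynamics.

Excitatory cells are leaky integrate-and-fire units with spike-frequency
adaptation; inhibitory twin cells are graded-response units pooling the
excitatory spikes of their 5x5 neighbourhood.  All differential forms are
integrated by explicit Euler with the simulation time-step as the unit:

    V   <- V + (1/tau) * (-V + k1 * (V_in + k2 * eta))          membrane
    phi  = 1  iff  V - alpha * omega > thresh                   spiking
    x   <- x + (1/tau_x) * (-x + drive)                         low-pass
           (adaptation omega, rate estimate omega_E, global inhibition omega_G)

The net input of an excitatory cell aggregates EPSPs, minus the graded output
of its twin inhibitory cell (local competition), minus k_G * omega_G of the
area (global competition).  Global inhibition and adaptation act on excitatory
cells only; the inhibitory twin integrates the raw pooled spike count and is
noise-free (k2 = 0 for inhibitory cells).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SimConfig

__all__ = [
    "membrane_update", "excitatory_output", "inhibitory_output",
    "adaptation_update", "AreaState", "area_step",
    "single_area_pool", "save_state", "load_state",
]


# ---------------------------------------------------------------------------
# scalar / vector primitives (each works elementwise on arrays too)
# ---------------------------------------------------------------------------

def membrane_update(V, V_in, noise, tau, k1, k2):
    """One Euler step of the membrane equation."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return V + (1.0 / tau) * (-V + k1 * (V_in + k2 * noise))


def excitatory_output(V, omega, alpha, thresh):
    """Spike (1) iff the membrane potential beats thresh by alpha*omega."""
    return (np.asarray(V) - alpha * np.asarray(omega) > thresh).astype(np.uint8)


def inhibitory_output(V):
    """Graded, rectified output of an inhibitory cell."""
    return np.maximum(np.asarray(V), 0.0)


def adaptation_update(x, drive, tau):
    """Euler step of the shared low-pass form (adaptation, rate, global)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return x + (1.0 / tau) * (-x + drive)


# ---------------------------------------------------------------------------
# area state
# ---------------------------------------------------------------------------

@dataclass
class AreaState:
    """State of one area's 2 x N cells plus its global-inhibition accumulator."""

    V_e: np.ndarray
    V_i: np.ndarray
    omega: np.ndarray      # adaptation, excitatory cells
    omega_E: np.ndarray    # low-passed firing-rate estimate, excitatory cells
    omega_G: float         # area-wide inhibition accumulator
    phi_e: np.ndarray      # binary spikes at the current step
    phi_i: np.ndarray      # graded inhibitory outputs

    @classmethod
    def zeros(cls, n_cells: int) -> "AreaState":
        z = lambda: np.zeros(n_cells)
        return cls(V_e=z(), V_i=z(), omega=z(), omega_E=z(), omega_G=0.0,
                   phi_e=np.zeros(n_cells, np.uint8), phi_i=z())

    def copy(self) -> "AreaState":
        return AreaState(self.V_e.copy(), self.V_i.copy(), self.omega.copy(),
                         self.omega_E.copy(), float(self.omega_G),
                         self.phi_e.copy(), self.phi_i.copy())


def single_area_pool(cfg: SimConfig) -> "np.ndarray":
    """Sparse (N x N) 0/1 matrix: row i pools the spikes the twin inhibitory
    cell at position i receives from its 5x5 neighbourhood."""
    from scipy import sparse

    from .connectivity import inhibitory_pool_indices

    indptr, members = inhibitory_pool_indices(cfg)
    n = cfg.n_cells_per_area
    indptr1 = indptr[: n + 1]
    members1 = members[: indptr1[-1]]
    data = np.ones(members1.size)
    return sparse.csr_matrix((data, members1, indptr1), shape=(n, n))


def area_step(state: AreaState, excitatory_input: np.ndarray, cfg: SimConfig,
              pool=None, noise: np.ndarray | None = None,
              tau_favg: float | None = None) -> AreaState:
    """One synchronous update of a single area.

    ``excitatory_input`` must already aggregate within-area, between-area and
    stimulus EPSPs per excitatory cell (raw input units, pre-``k1``);
    ``noise`` is the per-cell white-noise draw (uniform [-0.5, 0.5]), zeros if
    omitted.  Update order: pooled spikes -> inhibitory potentials ->
    excitatory potentials -> new spikes -> omega / omega_E / omega_G.
    """
    n = cfg.n_cells_per_area
    if excitatory_input.shape != (n,):
        raise ValueError("excitatory_input has the wrong shape")
    if noise is None:
        noise = np.zeros(n)
    if pool is None:
        pool = single_area_pool(cfg)
    tau_favg = cfg.tau_favg if tau_favg is None else tau_favg

    pooled = pool @ state.phi_e.astype(float)
    V_i = state.V_i + (1.0 / cfg.tau_i) * (-state.V_i + pooled)
    phi_i = inhibitory_output(V_i)

    net = excitatory_input - cfg.inhib_gain * phi_i - cfg.k_G * state.omega_G
    V_e = membrane_update(state.V_e, net, noise, cfg.tau_e, cfg.k1, cfg.k2)

    phi_e = excitatory_output(V_e, state.omega, cfg.alpha, cfg.thresh)
    omega = adaptation_update(state.omega, phi_e, cfg.tau_adapt)
    omega_E = adaptation_update(state.omega_E, phi_e, tau_favg)
    omega_G = adaptation_update(state.omega_G, float(phi_e.sum()), cfg.tau_glob)

    return AreaState(V_e=V_e, V_i=V_i, omega=omega, omega_E=omega_E,
                     omega_G=float(omega_G), phi_e=phi_e, phi_i=phi_i)


# ---------------------------------------------------------------------------
# snapshot serialisation
# ---------------------------------------------------------------------------

def save_state(path: str | Path, states: dict[str, AreaState],
               cfg: SimConfig, rng_state: dict | None = None) -> None:
    """Binary snapshot with named per-area datasets plus a JSON header."""
    path = Path(path)
    arrays = {}
    for label, st in states.items():
        for name in ("V_e", "V_i", "omega", "omega_E", "phi_e", "phi_i"):
            arrays[f"{label}/{name}"] = getattr(st, name)
        arrays[f"{label}/omega_G"] = np.asarray(st.omega_G)
    np.savez(path.with_suffix(".npz"), **arrays)
    header = {"config": cfg.to_dict(), "rng_state": rng_state,
              "areas": list(states)}
    path.with_suffix(".json").write_text(json.dumps(header))


def load_state(path: str | Path) -> tuple[dict[str, AreaState], SimConfig, dict | None]:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    cfg = SimConfig.from_dict(header["config"])
    dat = np.load(path.with_suffix(".npz"))
    states = {}
    for label in header["areas"]:
        states[label] = AreaState(
            V_e=dat[f"{label}/V_e"], V_i=dat[f"{label}/V_i"],
            omega=dat[f"{label}/omega"], omega_E=dat[f"{label}/omega_E"],
            omega_G=float(dat[f"{label}/omega_G"]),
            phi_e=dat[f"{label}/phi_e"].astype(np.uint8),
            phi_i=dat[f"{label}/phi_i"])
    return states, cfg, header.get("rng_state")
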