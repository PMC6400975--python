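"""Whole-network simulation engine.

The twelve areas are simulated as flat global arrays (excitatory cell index =
area_index * N + row * G + col) stepped by a single numba kernel.  The kernel
reproduces, cell for cell, the update order of :func:`network_core.area_step`:

1. gather EPSPs and 5x5 inhibitory pooling from the spikes at t
2. update inhibitory potentials
3. update excitatory potentials (stimulus + contextual noise + intrinsic noise,
   minus local and global inhibition)
4. threshold to the spikes at t+1
5. update adaptation, rate estimates and the per-area global inhibition
6. optionally apply the Hebbian rule to every e->e link, synchronously

Event-driven gathering (only spiking sources propagate) and activity-gated
plasticity (only links with an active presynaptic projection or a strongly
depolarised postsynaptic cell can change) keep the per-step cost proportional
to network activity rather than to the total link count.

Noise is drawn inside the kernel from numba's Mersenne-Twister state, which
matches the legacy ``numpy.random`` sequence for a given seed; draws happen
for every excitatory cell on every step in a fixed order, independent of the
stimulus, so paired runs that differ only in their stimulus share identical
noise histories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import sparse

from .config import SimConfig
from .connectivity import (AREA_INDEX, AREAS, PRIMARY_AREAS, Architecture,
                           SynapseSet, build_architecture, build_synapses,
                           inhibitory_pool_indices)
from .network_core import AreaState


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_phase(V_e, V_i, om, omE, omE2, omG, phi,
               w, src_indptr, src_tgt, tgt_indptr, tgt_src, tgt_map,
               pool_indptr, pool_members, area_of, ctx_flag,
               stim, n_steps,
               gate_mode, gate_thr, gate_a, gate_b,
               tau_e, tau_i, k1, k2, kG, thresh, alpha,
               tau_adapt, tau_favg, tau_favg2, tau_glob,
               inhib_gain, ctx_amp,
               plastic, delta, th_pre, th_plus, th_minus, w_max,
               track_resp, resp_max,
               track_members, member_mask, member_counts,
               area_spikes, gate_peak_out):
    E = V_e.size
    n_areas = omG.size
    inp = np.zeros(E)
    pool_in = np.zeros(E)
    new_phi = np.zeros(E, np.uint8)
    active = np.zeros(E, np.uint8)
    area_sums = np.zeros(n_areas)
    half_ctx = 0.5 * ctx_amp

    for t in range(n_steps):
        # (1) gather synaptic inputs and inhibitory pooling from spikes at t
        for e in range(E):
            inp[e] = 0.0
            pool_in[e] = 0.0
        for e in range(E):
            if phi[e] == 1:
                for l in range(src_indptr[e], src_indptr[e + 1]):
                    inp[src_tgt[l]] += w[l]
                for l in range(pool_indptr[e], pool_indptr[e + 1]):
                    pool_in[pool_members[l]] += 1.0
        # (2) inhibitory potentials and (3) excitatory potentials
        for e in range(E):
            V_i[e] = V_i[e] + (1.0 / tau_i) * (-V_i[e] + pool_in[e])
        for e in range(E):
            phi_i = V_i[e] if V_i[e] > 0.0 else 0.0
            net = (inp[e] + stim[e]) - inhib_gain * phi_i - kG * omG[area_of[e]]
            if ctx_flag[e] == 1:
                net = net + np.random.uniform(-half_ctx, half_ctx)
            eta = np.random.uniform(-0.5, 0.5)
            V_e[e] = V_e[e] + (1.0 / tau_e) * (-V_e[e] + k1 * (net + k2 * eta))
        # (4) spikes at t+1 and (5) low-pass filters
        for a in range(n_areas):
            area_sums[a] = 0.0
        for e in range(E):
            s = np.uint8(1) if V_e[e] - alpha * om[e] > thresh else np.uint8(0)
            new_phi[e] = s
            om[e] = om[e] + (1.0 / tau_adapt) * (-om[e] + s)
            omE[e] = omE[e] + (1.0 / tau_favg) * (-omE[e] + s)
            if track_resp:
                omE2[e] = omE2[e] + (1.0 / tau_favg2) * (-omE2[e] + s)
                if omE2[e] > resp_max[e]:
                    resp_max[e] = omE2[e]
            area_sums[area_of[e]] += s
        for a in range(n_areas):
            omG[a] = omG[a] + (1.0 / tau_glob) * (-omG[a] + area_sums[a])
            area_spikes[a] += area_sums[a]
        for e in range(E):
            phi[e] = new_phi[e]
        # (6) Hebbian rule on every e->e link, using the new V and omega_E
        if plastic:
            for i in range(E):
                active[i] = np.uint8(1) if omE[i] >= th_pre else np.uint8(0)
            for i in range(E):
                if active[i] == 1:
                    for l in range(src_indptr[i], src_indptr[i + 1]):
                        vj = V_e[src_tgt[l]]
                        if vj >= th_plus:                      # LTP
                            nw = w[l] + delta
                            w[l] = nw if nw < w_max else w_max
                        elif vj >= th_minus:                   # homosynaptic LTD
                            nw = w[l] - delta
                            w[l] = nw if nw > 0.0 else 0.0
            for j in range(E):
                if V_e[j] >= th_plus:
                    for l in range(tgt_indptr[j], tgt_indptr[j + 1]):
                        if active[tgt_src[l]] == 0:            # heterosynaptic LTD
                            k = tgt_map[l]
                            nw = w[k] - delta
                            w[k] = nw if nw > 0.0 else 0.0
        # recording and interstimulus gating
        if track_members:
            for a in range(n_areas):
                member_counts[t, a] = 0
            for e in range(E):
                if member_mask[e] == 1 and phi[e] == 1:
                    member_counts[t, area_of[e]] += 1
        g = omG[gate_a] if omG[gate_a] > omG[gate_b] else omG[gate_b]
        if g > gate_peak_out[0]:
            gate_peak_out[0] = g
        if gate_mode and omG[gate_a] <= gate_thr and omG[gate_b] <= gate_thr:
            return t + 1
    return n_steps


@dataclass
class NetworkState:
    """Flat global state of all excitatory/inhibitory cells of a network."""

    V_e: np.ndarray
    V_i: np.ndarray
    omega: np.ndarray
    omega_E: np.ndarray
    omega_E_fast: np.ndarray   # tau_favg_readout rate estimate (readout only)
    omega_G: np.ndarray        # (n_areas,)
    phi: np.ndarray            # uint8 spikes

    @classmethod
    def zeros(cls, n_cells_total: int, n_areas: int) -> "NetworkState":
        return cls(np.zeros(n_cells_total), np.zeros(n_cells_total),
                   np.zeros(n_cells_total), np.zeros(n_cells_total),
                   np.zeros(n_cells_total), np.zeros(n_areas),
                   np.zeros(n_cells_total, np.uint8))

    def copy(self) -> "NetworkState":
        return NetworkState(self.V_e.copy(), self.V_i.copy(), self.omega.copy(),
                            self.omega_E.copy(), self.omega_E_fast.copy(),
                            self.omega_G.copy(), self.phi.copy())


class Network:
    """A network instance: architecture, compiled link structure, weights, state."""

    def __init__(self, cfg: SimConfig, synapses: SynapseSet,
                 arch: Architecture | None = None):
        self.cfg = cfg
        self.arch = arch or build_architecture()
        self.synapses = synapses
        self.n_areas = len(AREAS)
        self.n_cells = cfg.n_cells_per_area * self.n_areas
        self._compile(synapses)
        pool_indptr, pool_members = inhibitory_pool_indices(cfg)
        self.pool_indptr = pool_indptr
        self.pool_members = pool_members
        self.area_of = np.repeat(np.arange(self.n_areas, dtype=np.int64),
                                 cfg.n_cells_per_area)
        self.ctx_flag = np.zeros(self.n_cells, np.uint8)
        for a in PRIMARY_AREAS:
            lo = AREA_INDEX[a] * cfg.n_cells_per_area
            self.ctx_flag[lo:lo + cfg.n_cells_per_area] = 1
        self.state = NetworkState.zeros(self.n_cells, self.n_areas)

    # ------------------------------------------------------------------
    def _compile(self, syn: SynapseSet) -> None:
        """Sort links into source-major CSR order (the canonical weight store)
        and derive the target-major view that shares the same data."""
        E = self.n_cells
        order_mat = sparse.coo_matrix(
            (np.arange(syn.n_links, dtype=np.int64) + 1, (syn.src, syn.tgt)),
            shape=(E, E)).tocsr()
        order_mat.sort_indices()
        self._csr_order = np.asarray(order_mat.data, np.int64) - 1  # orig -> csr pos
        self.src_indptr = order_mat.indptr.astype(np.int64)
        self.src_tgt = order_mat.indices.astype(np.int64)
        self.w = syn.w[self._csr_order].astype(np.float64).copy()
        # target-major view: positions into self.w
        by_src = sparse.csr_matrix(
            (np.arange(self.w.size, dtype=np.int64) + 1,
             self.src_tgt, self.src_indptr), shape=(E, E))
        by_tgt = by_src.T.tocsr()
        by_tgt.sort_indices()
        self.tgt_indptr = by_tgt.indptr.astype(np.int64)
        self.tgt_src = by_tgt.indices.astype(np.int64)
        self.tgt_map = np.asarray(by_tgt.data, np.int64) - 1

    def sync_synapses(self) -> SynapseSet:
        """Write the current weights back into the block-partitioned view."""
        self.synapses.w[self._csr_order] = self.w
        return self.synapses

    def copy_with_weights(self) -> "Network":
        """Fresh network sharing structure but with independent weights/state."""
        net = Network.__new__(Network)
        net.__dict__.update(self.__dict__)
        net.synapses = self.synapses.copy()
        net.w = self.w.copy()
        net.state = NetworkState.zeros(self.n_cells, self.n_areas)
        return net

    @classmethod
    def build(cls, cfg: SimConfig, seed: int) -> "Network":
        return cls(cfg, build_synapses(seed, cfg))

    # ------------------------------------------------------------------
    def reset_state(self) -> None:
        self.state = NetworkState.zeros(self.n_cells, self.n_areas)

    def run_phase(self, stim: np.ndarray | None, n_steps: int, *,
                  plastic: bool = False,
                  gate_threshold: float | None = None,
                  track_response: bool = False,
                  member_mask: np.ndarray | None = None,
                  member_counts: np.ndarray | None = None,
                  tau_favg: float | None = None,
                  contextual: bool = True) -> dict:
        """Run the kernel for up to ``n_steps``; returns phase telemetry.

        With ``gate_threshold`` set, stops as soon as omega_G of both PB and
        PF_i fall below it.  ``track_response`` accumulates the per-cell
        maximum of the fast (tau_favg_readout) rate estimate into the result.
        """
        cfg = self.cfg
        st = self.state
        if stim is None:
            stim = np.zeros(self.n_cells)
        resp_max = np.zeros(self.n_cells) if track_response else np.zeros(1)
        track_members = member_mask is not None
        if track_members and member_counts is None:
            member_counts = np.zeros((n_steps, self.n_areas), np.int64)
        area_spikes = np.zeros(self.n_areas)
        gate_peak = np.zeros(1)
        steps = _run_phase(
            st.V_e, st.V_i, st.omega, st.omega_E, st.omega_E_fast, st.omega_G,
            st.phi,
            self.w, self.src_indptr, self.src_tgt,
            self.tgt_indptr, self.tgt_src, self.tgt_map,
            self.pool_indptr, self.pool_members, self.area_of, self.ctx_flag,
            np.asarray(stim, np.float64), n_steps,
            gate_threshold is not None,
            0.0 if gate_threshold is None else float(gate_threshold),
            AREA_INDEX["PB"], AREA_INDEX["PF_i"],
            cfg.tau_e, cfg.tau_i, cfg.k1, cfg.k2, cfg.k_G, cfg.thresh,
            cfg.alpha, cfg.tau_adapt,
            cfg.tau_favg if tau_favg is None else float(tau_favg),
            cfg.tau_favg_readout, cfg.tau_glob,
            cfg.inhib_gain,
            cfg.contextual_amplitude if contextual else 0.0,
            plastic, cfg.delta, cfg.theta_pre, cfg.theta_plus,
            cfg.theta_minus, cfg.w_max,
            track_response, resp_max,
            track_members,
            member_mask if track_members else np.zeros(1, np.uint8),
            member_counts if track_members else np.zeros((1, 1), np.int64),
            area_spikes, gate_peak)
        return {
            "steps": int(steps),
            "area_spikes": area_spikes,
            "gate_peak": float(gate_peak[0]),
            "responses": resp_max if track_response else None,
            "member_counts": member_counts if track_members else None,
        }

    # ------------------------------------------------------------------
    def area_state(self, area: str) -> AreaState:
        """Single-area view of the global state (copies)."""
        n = self.cfg.n_cells_per_area
        lo = AREA_INDEX[area] * n
        sl = slice(lo, lo + n)
        st = self.state
        return AreaState(V_e=st.V_e[sl].copy(), V_i=st.V_i[sl].copy(),
                         omega=st.omega[sl].copy(), omega_E=st.omega_E[sl].copy(),
                         omega_G=float(st.omega_G[AREA_INDEX[area]]),
                         phi_e=st.phi[sl].copy(),
                         phi_i=np.maximum(st.V_i[sl], 0.0))

    def cells_of(self, area: str, local_idx: np.ndarray) -> np.ndarray:
        return np.asarray(local_idx, np.int64) + AREA_INDEX[area] * self.cfg.n_cells_per_area
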