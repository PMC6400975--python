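"""Discretised Hebbian LTP/LTD rule on excitatory-to-excitatory links.

A presynaptic projection counts as *active* when the source cell's low-passed
rate estimate omega_E is at least theta_pre.  The weight of a link from i to j
then changes by a fixed quantum per step:

    +delta   active projection and V(j) >= theta_plus        (LTP)
    -delta   active projection and theta_minus <= V(j) < theta_plus
                                                (homosynaptic LTD)
    -delta   inactive projection and V(j) >= theta_plus      (heterosynaptic LTD)
     0       otherwise

Weights are clipped to [0, w_max]; links touching inhibitory cells never
change.  During production/recognition readout the rule is frozen.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .connectivity import SynapseSet


def weight_change(omega_E_pre: float, V_post: float, cfg: SimConfig) -> float:
    """The weight increment for one link, given presynaptic rate estimate and
    postsynaptic membrane potential at the current step."""
    pre_active = omega_E_pre >= cfg.theta_pre
    if pre_active and V_post >= cfg.theta_plus:
        return +cfg.delta
    if pre_active and cfg.theta_minus <= V_post < cfg.theta_plus:
        return -cfg.delta
    if (not pre_active) and V_post >= cfg.theta_plus:
        return -cfg.delta
    return 0.0


def apply_plasticity(synapses: SynapseSet, omega_E: np.ndarray,
                     V_post: np.ndarray, cfg: SimConfig) -> SynapseSet:
    """Apply the rule to every link of a SynapseSet, in place, vectorised.

    ``omega_E`` and ``V_post`` are global per-excitatory-cell arrays.  Returns
    the same SynapseSet with weights updated and clipped to [0, w_max].
    """
    pre_active = omega_E[synapses.src] >= cfg.theta_pre
    v = V_post[synapses.tgt]
    hot = v >= cfg.theta_plus
    mid = (v >= cfg.theta_minus) & ~hot
    dw = np.where(pre_active & hot, cfg.delta,
                  np.where((pre_active & mid) | (~pre_active & hot),
                           -cfg.delta, 0.0))
    np.clip(synapses.w + dw, 0.0, cfg.w_max, out=synapses.w)
    return synapses
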