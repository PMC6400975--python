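"""Single-cell and single-area dynamics against hand-computed oracles."""

import numpy as np
import pytest

from lexigrow import SimConfig
from lexigrow.network_core import (AreaState, adaptation_update, area_step,
                                   excitatory_output, inhibitory_output,
                                   membrane_update, single_area_pool,
                                   save_state, load_state)


@pytest.mark.parametrize("V,V_in,noise,tau,k1,expected", [
    (0.0, 0.0, 0.0, 2.5, 0.01, 0.0),          # silence is a fixed point
    (1.0, 0.0, 0.0, 2.5, 0.01, 0.6),          # pure leak: 1 - 1/2.5
    (0.0, 100.0, 0.0, 2.5, 0.01, 0.4),        # (1/2.5) * 0.01 * 100
])
def test_membrane_update_euler_step(V, V_in, noise, tau, k1, expected):
    got = membrane_update(V, V_in, noise, tau, k1, k2=0.0)
    assert got == pytest.approx(expected, abs=1e-12)


def test_membrane_update_rejects_bad_tau():
    with pytest.raises(ValueError):
        membrane_update(0.0, 0.0, 0.0, tau=0.0, k1=0.01, k2=0.0)


@pytest.mark.parametrize("V,omega,expected", [
    (0.0, 0.0, 0),
    (0.19, 0.0, 1),            # 0.19 > thresh = 0.18
    (0.19, 0.01, 0),           # 0.19 - 7*0.01 = 0.12 <= 0.18
])
def test_excitatory_output_threshold(V, omega, expected):
    assert excitatory_output(V, omega, alpha=7.0, thresh=0.18) == expected


@pytest.mark.parametrize("V,expected", [(-0.3, 0.0), (0.0, 0.0), (0.42, 0.42)])
def test_inhibitory_output_rectifies(V, expected):
    assert inhibitory_output(V) == expected


def test_adaptation_update_examples():
    assert adaptation_update(0.0, 0.0, 10.0) == 0.0
    assert adaptation_update(0.0, 1.0, 10.0) == pytest.approx(0.1, abs=1e-15)
    # constant drive converges to the fixed point at 1
    x = 0.0
    for _ in range(2000):
        x = adaptation_update(x, 1.0, 10.0)
    assert x == pytest.approx(1.0, abs=1e-9)


def test_lowpass_matches_discrete_closed_form():
    """x(t) = (1-1/tau)^t x0 + (1/tau) sum_s (1-1/tau)^(t-1-s) d(s), to 1e-12."""
    rng = np.random.default_rng(3)
    for tau in (2.5, 10.0, 30.0, 12.0):
        drive = rng.uniform(0, 2, size=40)
        x = 0.7
        for d in drive:
            x = adaptation_update(x, d, tau)
        a = 1.0 - 1.0 / tau
        t = drive.size
        closed = a ** t * 0.7 + (1 / tau) * sum(
            a ** (t - 1 - s) * drive[s] for s in range(t))
        assert x == pytest.approx(closed, abs=1e-12)


# ---------------------------------------------------------------------------
# area_step
# ---------------------------------------------------------------------------

def _naive_area_step(state, excitatory_input, cfg, noise):
    """Per-cell loop re-implementation of one synchronous area update."""
    g = cfg.grid_size
    n = cfg.n_cells_per_area
    half = cfg.inhib_neighbourhood // 2
    pooled = np.zeros(n)
    for r in range(g):
        for c in range(g):
            tot = 0.0
            for rr in range(max(0, r - half), min(g, r + half + 1)):
                for cc in range(max(0, c - half), min(g, c + half + 1)):
                    tot += float(state.phi_e[rr * g + cc])
            pooled[r * g + c] = tot
    V_i = np.empty(n)
    phi_i = np.empty(n)
    for i in range(n):
        V_i[i] = state.V_i[i] + (1.0 / cfg.tau_i) * (-state.V_i[i] + pooled[i])
        phi_i[i] = max(V_i[i], 0.0)
    V_e = np.empty(n)
    phi_e = np.zeros(n, np.uint8)
    for i in range(n):
        net = excitatory_input[i] - cfg.inhib_gain * phi_i[i] - cfg.k_G * state.omega_G
        V_e[i] = state.V_e[i] + (1.0 / cfg.tau_e) * (
            -state.V_e[i] + cfg.k1 * (net + cfg.k2 * noise[i]))
        if V_e[i] - cfg.alpha * state.omega[i] > cfg.thresh:
            phi_e[i] = 1
    omega = np.empty(n)
    omega_E = np.empty(n)
    for i in range(n):
        omega[i] = state.omega[i] + (1.0 / cfg.tau_adapt) * (-state.omega[i] + phi_e[i])
        omega_E[i] = state.omega_E[i] + (1.0 / cfg.tau_favg) * (-state.omega_E[i] + phi_e[i])
    omega_G = state.omega_G + (1.0 / cfg.tau_glob) * (-state.omega_G + float(phi_e.sum()))
    return AreaState(V_e, V_i, omega, omega_E, float(omega_G), phi_e, phi_i)


def test_area_step_silence_is_fixed_point(tiny_cfg):
    st = AreaState.zeros(tiny_cfg.n_cells_per_area)
    pool = single_area_pool(tiny_cfg)
    for _ in range(20):
        st = area_step(st, np.zeros(tiny_cfg.n_cells_per_area), tiny_cfg, pool=pool)
    assert not st.V_e.any() and not st.phi_e.any() and st.omega_G == 0.0


def test_area_step_matches_dense_per_cell_loop(tiny_cfg):
    """Vectorised area update agrees exactly with a naive per-cell loop."""
    rng = np.random.default_rng(11)
    n = tiny_cfg.n_cells_per_area
    st_a = AreaState.zeros(n)
    st_b = st_a.copy()
    pool = single_area_pool(tiny_cfg)
    for _ in range(30):
        drive = rng.uniform(0, 40, size=n)
        noise = rng.uniform(-0.5, 0.5, size=n)
        st_a = area_step(st_a, drive, tiny_cfg, pool=pool, noise=noise)
        st_b = _naive_area_step(st_b, drive, tiny_cfg, noise)
        np.testing.assert_array_equal(st_a.phi_e, st_b.phi_e)
        np.testing.assert_allclose(st_a.V_e, st_b.V_e, rtol=0, atol=0)
        np.testing.assert_allclose(st_a.V_i, st_b.V_i, rtol=0, atol=0)
        np.testing.assert_allclose(st_a.omega, st_b.omega, rtol=0, atol=0)
        assert st_a.omega_G == st_b.omega_G
    assert st_a.phi_e.sum() > 0  # the comparison exercised live dynamics


def test_area_step_single_driven_cell_recruits_twin_inhibition(tiny_cfg):
    """A spiking e-cell raises its twin i-cell's output within tau_i steps."""
    n = tiny_cfg.n_cells_per_area
    st = AreaState.zeros(n)
    drive = np.zeros(n)
    drive[12] = 100.0  # centre cell of the 5x5 grid
    pool = single_area_pool(tiny_cfg)
    for _ in range(int(tiny_cfg.tau_i) + 2):
        st = area_step(st, drive, tiny_cfg, pool=pool)
    assert st.phi_e[12] == 1 or st.omega[12] > 0
    assert st.phi_i[12] > 0.0


def test_area_step_omega_g_filter_arithmetic(tiny_cfg):
    n = tiny_cfg.n_cells_per_area
    st = AreaState.zeros(n)
    drive = np.full(n, 100.0)
    new = area_step(st, drive, tiny_cfg, pool=single_area_pool(tiny_cfg))
    expected = 0.0 + (1.0 / tiny_cfg.tau_glob) * (-0.0 + new.phi_e.sum())
    assert new.omega_G == pytest.approx(expected, abs=1e-15)


def test_area_step_shape_mismatch_raises(tiny_cfg):
    st = AreaState.zeros(tiny_cfg.n_cells_per_area)
    with pytest.raises(ValueError):
        area_step(st, np.zeros(7), tiny_cfg)


def test_state_snapshot_round_trip(tmp_path, tiny_cfg):
    rng = np.random.default_rng(0)
    n = tiny_cfg.n_cells_per_area
    st = AreaState(V_e=rng.normal(size=n), V_i=rng.normal(size=n),
                   omega=rng.uniform(size=n), omega_E=rng.uniform(size=n),
                   omega_G=1.25, phi_e=(rng.random(n) < 0.3).astype(np.uint8),
                   phi_i=rng.uniform(size=n))
    save_state(tmp_path / "snap", {"A1": st}, tiny_cfg, rng_state={"s": 1})
    loaded, cfg2, rs = load_state(tmp_path / "snap")
    assert cfg2 == tiny_cfg and rs == {"s": 1}
    for name in ("V_e", "V_i", "omega", "omega_E", "phi_e", "phi_i"):
        np.testing.assert_array_equal(getattr(loaded["A1"], name), getattr(st, name))
    assert loaded["A1"].omega_G == st.omega_G
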