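"""Repeated-measures ANOVA against a brute-force GLM oracle."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lexigrow.stats import (attach_area_factors, bonferroni_critical,
                            effect_size_label, planned_comparisons, rm_anova)


# ---------------------------------------------------------------------------
# oracle: classical sums of squares by inclusion-exclusion over marginal means
# ---------------------------------------------------------------------------

def _marginal(data, dims_kept):
    """Mean over every axis not in dims_kept; result broadcastable to data."""
    axes = tuple(i for i in range(data.ndim) if i not in dims_kept)
    return data.mean(axis=axes, keepdims=True)


def _pure_effect(data, dims):
    comp = np.zeros_like(_marginal(data, dims))
    for r in range(len(dims) + 1):
        for sub in combinations(dims, r):
            sign = (-1) ** (len(dims) - len(sub))
            comp = comp + sign * _marginal(data, set(sub))
    return comp


def oracle_rm_anova(data):
    """data: array (subjects, l1, ..., lk); returns {effect dims: (F, df1, df2)}.

    Subject is axis 0; the error term of an effect is its interaction with
    subject, following the full factorial decomposition.
    """
    k = data.ndim - 1
    total = data.size
    out = {}
    for r in range(1, k + 1):
        for dims in combinations(range(1, k + 1), r):
            eff = _pure_effect(data, set(dims))
            err = _pure_effect(data, set(dims) | {0})
            ss_eff = float((eff ** 2).sum()) * total / eff.size
            ss_err = float((err ** 2).sum()) * total / err.size
            df1 = int(np.prod([data.shape[d] - 1 for d in dims]))
            df2 = df1 * (data.shape[0] - 1)
            F = (ss_eff / df1) / (ss_err / df2)
            out[dims] = (F, df1, df2, ss_eff, ss_err)
    return out


def _long_frame(data, names):
    shape = data.shape
    rows = []
    for idx in product(*[range(s) for s in shape]):
        row = {"network": idx[0], "mean_count": data[idx]}
        for name, lev in zip(names, idx[1:]):
            row[name] = f"l{lev}"
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.mark.parametrize("shape", [(4, 2, 2), (5, 2, 3), (6, 2, 2, 3), (13, 2, 2, 12)])
def test_rm_anova_matches_glm_oracle(shape):
    rng = np.random.default_rng(hash(shape) % (2 ** 31))
    data = rng.normal(size=shape) + rng.normal(size=(shape[0],) + (1,) * (len(shape) - 1))
    names = [f"f{i}" for i in range(len(shape) - 1)]
    table = _long_frame(data, names)
    res = rm_anova(table, within=names).set_index("effect")
    oracle = oracle_rm_anova(data)
    for dims, (F, df1, df2, ss_eff, ss_err) in oracle.items():
        key = " x ".join(names[d - 1] for d in dims)
        row = res.loc[key]
        assert row["F"] == pytest.approx(F, abs=1e-8, rel=1e-8)
        assert (row["df1"], row["df2"]) == (df1, df2)
        assert row["ss_effect"] == pytest.approx(ss_eff, rel=1e-8)
        assert row["partial_eta_sq"] == pytest.approx(ss_eff / (ss_eff + ss_err), rel=1e-8)


def test_rm_anova_twenty_random_tables_match_oracle():
    rng = np.random.default_rng(1234)
    for _ in range(20):
        shape = (int(rng.integers(4, 8)), int(rng.integers(2, 4)), int(rng.integers(2, 5)))
        data = rng.normal(size=shape)
        names = ["a", "b"]
        res = rm_anova(_long_frame(data, names), within=names).set_index("effect")
        for dims, (F, df1, df2, *_rest) in oracle_rm_anova(data).items():
            key = " x ".join(names[d - 1] for d in dims)
            assert res.loc[key, "F"] == pytest.approx(F, abs=1e-8, rel=1e-8)


def test_rm_anova_constant_cells_have_zero_effect_ss():
    data = np.tile(np.arange(5.0)[:, None, None], (1, 2, 3))  # subject offsets only
    res = rm_anova(_long_frame(data, ["a", "b"]), within=["a", "b"])
    assert np.allclose(res["ss_effect"], 0.0)
    assert res["degenerate"].all()          # no within-cell variance left
    assert res["F"].isna().all()


def test_rm_anova_two_level_factor_has_unit_epsilon():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 2))
    res = rm_anova(_long_frame(data, ["a"]), within=["a"])
    assert res.loc[0, "epsilon"] == 1.0
    assert res.loc[0, "df1"] == 1


def test_rm_anova_epsilon_bounds_and_correction():
    rng = np.random.default_rng(7)
    data = rng.normal(size=(8, 5))
    res = rm_anova(_long_frame(data, ["a"]), within=["a"]).iloc[0]
    assert 1.0 / 4 <= res["epsilon"] <= 1.0
    # corrected p comes from the epsilon-scaled F distribution
    expect = sps.f.sf(res["F"], res["epsilon"] * res["df1"],
                      res["epsilon"] * res["df2"])
    assert res["p_corrected"] == pytest.approx(float(expect), rel=1e-12)


def test_rm_anova_agrees_with_pingouin_one_way():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    data = rng.normal(size=(10, 4))
    df = _long_frame(data, ["a"])
    ours = rm_anova(df, within=["a"]).iloc[0]
    theirs = pg.rm_anova(data=df, dv="mean_count", within="a",
                         subject="network", correction=True)
    assert ours["F"] == pytest.approx(float(theirs["F"].iloc[0]), rel=1e-6)
    assert ours["epsilon"] == pytest.approx(float(theirs["eps"].iloc[0]), rel=1e-6)


def test_rm_anova_rejects_unbalanced():
    rng = np.random.default_rng(0)
    df = _long_frame(rng.normal(size=(4, 2, 2)), ["a", "b"])
    with pytest.raises(ValueError):
        rm_anova(df.iloc[:-1], within=["a", "b"])


def test_permutation_null_p_values_are_uniform():
    """Permuting a two-level factor within subject gives uniform p-values."""
    rng = np.random.default_rng(99)
    n_sub, n_perm = 8, 500
    names = ["regime", "area"]
    pvals = np.empty(n_perm)
    for i in range(n_perm):
        data = rng.normal(size=(n_sub, 2, 3))
        flip = rng.random(n_sub) < 0.5   # within-subject label permutation
        data[flip] = data[flip][:, ::-1, :]
        res = rm_anova(_long_frame(data, names), within=names,
                       effects=[("regime",)])
        pvals[i] = res.loc[0, "p"]
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 1e-3


# ---------------------------------------------------------------------------
# planned comparisons and effect-size bands
# ---------------------------------------------------------------------------

def test_bonferroni_critical_threshold():
    assert round(bonferroni_critical(0.05, 6), 4) == 0.0083
    with pytest.raises(ValueError):
        bonferroni_critical(0.05, 0)


def test_planned_comparisons_behaviour():
    rng = np.random.default_rng(5)
    rows = []
    for net in range(8):
        for regime in ("sighted", "blind"):
            shift = 3.0 if regime == "blind" else 0.0
            rows.append({"network": net, "regime": regime, "area": "V1",
                         "mean_count": rng.normal() + shift + net})
            rows.append({"network": net, "regime": regime, "area": "A1",
                         "mean_count": 5.0})  # identical in both regimes
    table = pd.DataFrame(rows)
    res = planned_comparisons(table, "regime", areas=["V1", "A1"],
                              correction_m=6).set_index("area")
    assert res.loc["V1", "significant"]
    assert res.loc["A1", "t"] == 0.0 and not res.loc["A1", "significant"]
    assert res.loc["V1", "critical_p"] == pytest.approx(0.05 / 6)
    # p is monotone non-decreasing in m in terms of the criterion
    res1 = planned_comparisons(table, "regime", areas=["V1"], correction_m=1)
    assert res1.loc[0, "critical_p"] > res.loc["V1", "critical_p"]


@pytest.mark.parametrize("value,label", [
    (0.005, "negligible"), (0.01, "small"), (0.049, "small"),
    (0.06, "medium"), (0.14, "medium"), (0.141, "large"), (0.49, "large"),
])
def test_effect_size_bands(value, label):
    assert effect_size_label(value) == label


def test_effect_size_out_of_range():
    with pytest.raises(ValueError):
        effect_size_label(1.5)


def test_attach_area_factors_partition():
    df = pd.DataFrame({"area": ["A1", "V1", "PB", "M1_L"]})
    out = attach_area_factors(df)
    assert list(out["peri_extra"]) == ["perisylvian", "extrasylvian",
                                       "perisylvian", "extrasylvian"]
    assert list(out["area_level"]) == ["primary", "primary", "central", "primary"]
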