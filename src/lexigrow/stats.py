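"""Repeated-measures factorial ANOVA on cell-assembly count tables.

Network instances are the subjects; every factor (regime, word type, area
groupings) varies within subject because paired sighted/blind instances share
seeds.  Effects are computed from orthonormal within-subject contrasts: for an
effect E the data are projected onto the Kronecker product of mean-zero
contrasts (factors in E) and normalised means (factors not in E); the effect
sum of squares comes from the projected subject means, the error term from the
subject-by-effect residuals.  Sphericity is handled by the Greenhouse–Geisser
epsilon of the projected covariance, applied whenever an effect has more than
one numerator degree of freedom; partial eta squared is
SS_effect / (SS_effect + SS_error).  Planned comparisons are paired t-tests at
a Bonferroni-corrected criterion.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import AREAS

#: area-level factor metadata used by the factorial designs
AREA_FACTORS = pd.DataFrame({
    "area": list(AREAS),
    "peri_extra": ["perisylvian"] * 6 + ["extrasylvian"] * 6,
    "temporal_frontal": ["temporal", "temporal", "temporal",
                         "frontal", "frontal", "frontal",
                         "temporal", "temporal", "temporal",
                         "frontal", "frontal", "frontal"],
    "area_level": ["primary", "secondary", "central",
                   "central", "secondary", "primary",
                   "primary", "secondary", "central",
                   "central", "secondary", "primary"],
})


def attach_area_factors(table: pd.DataFrame) -> pd.DataFrame:
    """Join the PeriExtra / TemporalFrontal / AreaLevel factors onto a tidy
    count table that has an ``area`` column."""
    return table.merge(AREA_FACTORS, on="area", how="left")


def _orthonormal_contrasts(n: int) -> np.ndarray:
    """(n-1, n) orthonormal rows spanning the mean-zero subspace."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), np.eye(n)[:, : n - 1]]))
    return q[:, 1:].T


def _mean_vector(n: int) -> np.ndarray:
    return np.full((1, n), 1.0 / np.sqrt(n))


def rm_anova(table: pd.DataFrame, dv: str = "mean_count",
             within: list[str] | None = None, subject: str = "network",
             effects: list[tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Repeated-measures ANOVA over the listed within-subject factors.

    Factor columns present in ``table`` but not listed in ``within`` are
    averaged out first.  Returns one row per effect with F, degrees of
    freedom, Greenhouse–Geisser epsilon, uncorrected and corrected p, and
    partial eta squared.  Raises on unbalanced designs; a zero error variance
    yields F = NaN with a diagnostic flag.
    """
    if within is None or not within:
        raise ValueError("list at least one within-subject factor")
    cell = table.groupby([subject] + within, observed=True)[dv].mean().reset_index()
    subjects = np.sort(cell[subject].unique())
    levels = {f: np.sort(cell[f].unique()) for f in within}
    shape = tuple(len(levels[f]) for f in within)
    n_cells = int(np.prod(shape))
    counts = cell.groupby(subject, observed=True).size()
    if not (counts == n_cells).all() or cell.shape[0] != len(subjects) * n_cells:
        raise ValueError("unbalanced design: every subject needs every factor cell")
    wide = cell.pivot_table(index=subject, columns=within, values=dv)
    # enforce canonical level order on the column MultiIndex
    if len(within) == 1:
        wide = wide.reindex(columns=levels[within[0]])
    else:
        wide = wide.reindex(columns=pd.MultiIndex.from_product(
            [levels[f] for f in within], names=within))
    data = wide.to_numpy()                      # (S, prod shape)
    S = len(subjects)

    if effects is None:
        effects = [c for r in range(1, len(within) + 1)
                   for c in combinations(within, r)]
    rows = []
    for eff in effects:
        mats = []
        d = 1
        for f in within:
            if f in eff:
                c = _orthonormal_contrasts(len(levels[f]))
                d *= c.shape[0]
            else:
                c = _mean_vector(len(levels[f]))
            mats.append(c)
        M = mats[0]
        for c in mats[1:]:
            M = np.kron(M, c)
        Y = data @ M.T                          # (S, d)
        ybar = Y.mean(axis=0)
        ss_eff = S * float(ybar @ ybar)
        R = Y - ybar
        ss_err = float((R * R).sum())
        df1, df2 = d, (S - 1) * d
        if d > 1:
            cov = (R.T @ R) / max(S - 1, 1)
            tr = np.trace(cov)
            tr2 = float((cov * cov).sum())
            eps = (tr * tr) / (d * tr2) if tr2 > 0 else 1.0
            eps = float(np.clip(eps, 1.0 / d, 1.0))
        else:
            eps = 1.0
        scale = float(np.abs(data).max()) ** 2 * data.size
        degenerate = ss_err <= 1e-12 * max(scale, 1e-300)
        if degenerate:
            F = p = p_corr = float("nan")
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
            p_corr = float(sps.f.sf(F, eps * df1, eps * df2))
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append({
            "effect": " x ".join(eff), "F": F, "df1": df1, "df2": df2,
            "epsilon": eps, "p": p, "p_corrected": p_corr,
            "partial_eta_sq": peta,
            "ss_effect": ss_eff, "ss_error": ss_err,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def bonferroni_critical(alpha: float = 0.05, m: int = 6) -> float:
    """The corrected critical threshold alpha / m."""
    if m <= 0:
        raise ValueError("m must be > 0")
    return alpha / m


def planned_comparisons(table: pd.DataFrame, factor: str,
                        areas: list[str] | None = None,
                        dv: str = "mean_count", subject: str = "network",
                        correction_m: int = 6,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-area paired t-tests between the two levels of ``factor``,
    Bonferroni-corrected over ``correction_m`` comparisons."""
    crit = bonferroni_critical(alpha, correction_m)
    lv = np.sort(table[factor].unique())
    if lv.size != 2:
        raise ValueError(f"{factor!r} must have exactly two levels, got {lv}")
    areas = list(areas) if areas is not None else list(AREAS)
    rows = []
    for area in areas:
        sub = table[table["area"] == area]
        a = sub[sub[factor] == lv[0]].groupby(subject, observed=True)[dv].mean()
        b = sub[sub[factor] == lv[1]].groupby(subject, observed=True)[dv].mean()
        a, b = a.align(b, join="inner")
        diff = a.to_numpy() - b.to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a.to_numpy(), b.to_numpy())
        rows.append({"area": area, "level_a": lv[0], "level_b": lv[1],
                     "mean_diff": float(np.mean(diff)), "t": float(t),
                     "df": len(diff) - 1, "p": float(p),
                     "critical_p": crit, "significant": bool(p < crit)})
    return pd.DataFrame(rows)


def effect_size_label(partial_eta_sq: float) -> str:
    """Banded interpretation of partial eta squared: 0.01–0.06 small,
    0.06–0.14 medium, >0.14 large; below 0.01 reported as negligible."""
    x = float(partial_eta_sq)
    if not (0.0 <= x <= 1.0):
        raise ValueError("partial eta squared must lie in [0, 1]")
    if x < 0.01:
        return "negligible"
    if x < 0.06:
        return "small"
    if x <= 0.14:
        return "medium"
    return "large"
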