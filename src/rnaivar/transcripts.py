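"""Per-embryo transcript-count analysis: treated-vs-control tests,
excess-mass multimodality testing, and stage-adjusted ANCOVA.

Transcript counts come from single-molecule FISH: each embryo contributes
one integer count of intact target transcripts plus its developmental stage
(cell or nucleus count).  Location/scale comparisons between RNAi-treated
and control embryos use early-stage embryos only (default up to 4 cells),
where maternal transcript load is still high.  Strains whose response is
stochastic per individual produce a mixture of knocked-down and untouched
embryos; the Muller-Sawitzki excess-mass test probes exactly that kind of
bimodality.  Across a wider developmental window (default up to 30 nuclei)
transcript abundance declines roughly linearly with stage, so treatment
effects are assessed by ANCOVA with omega-squared effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "BimodalityResult",
    "AncovaResult",
    "compare_groups",
    "excess_mass_statistic",
    "bimodality_test",
    "ancova",
    "omega_squared",
]


def compare_groups(
    counts: pd.DataFrame, strain: str, stage_max: int = 4
) -> dict[str, float]:
    """Two-sided treated-vs-control tests on early-stage embryos of one strain.

    Returns the Welch t-test p (difference in means), variance-ratio F-test p
    (difference in spread), and Mann-Whitney p (distribution shift), plus the
    group means/variances.
    """
    sub = counts[(counts["strain"] == strain) & (counts["stage"] <= stage_max)]
    x = sub.loc[sub["treatment"] == "control", "count"].to_numpy(float)
    y = sub.loc[sub["treatment"] != "control", "count"].to_numpy(float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >= 2 embryos after the stage filter")
    t_res = stats.ttest_ind(x, y, equal_var=False)
    f_stat = np.var(x, ddof=1) / np.var(y, ddof=1)
    f_cdf = stats.f.cdf(f_stat, x.size - 1, y.size - 1)
    f_p = 2 * min(f_cdf, 1 - f_cdf)
    mw = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {
        "n_control": int(x.size),
        "n_treated": int(y.size),
        "mean_control": float(x.mean()),
        "mean_treated": float(y.mean()),
        "var_control": float(np.var(x, ddof=1)),
        "var_treated": float(np.var(y, ddof=1)),
        "t_p": float(t_res.pvalue),
        "f_p": float(min(1.0, f_p)),
        "mw_p": float(mw.pvalue),
    }


def _lambda_grid(x: np.ndarray, n_lambda: int) -> np.ndarray:
    """Log-spaced density levels spanning a plug-in kernel density estimate."""
    kde = stats.gaussian_kde(x)
    dens = kde(x)
    lo, hi = float(dens.min()), float(dens.max())
    if not np.isfinite(lo) or lo <= 0:
        lo = hi * 1e-3
    if hi <= lo:
        hi = lo * 10
    return np.geomspace(lo, hi, n_lambda)


def excess_mass_statistic(
    x: np.ndarray, n_lambda: int = 50, lambdas: np.ndarray | None = None
) -> float:
    """Muller-Sawitzki excess-mass difference D = max_lambda E(2) - E(1).

    E(m, lambda) is the largest total excess mass sum_j (F_n(I_j) -
    lambda |I_j|) attainable with m disjoint intervals (lambda-clusters);
    candidate interval endpoints are the data points, so E is computed
    exactly for the empirical distribution.  D is large when probability
    mass concentrates in two separated clumps; it is invariant to shifting
    the data and, with the default density-derived lambda grid, to rescaling.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x[0] == x[-1]:
        raise ValueError("degenerate constant data")
    lam = _lambda_grid(x, n_lambda) if lambdas is None else np.asarray(lambdas, float)

    i = np.arange(n)
    # interval [x_i, x_j] scores a_i + b_j with a_i = lam*x_i - i/n,
    # b_j = (j+1)/n - lam*x_j, i <= j
    a = lam[:, None] * x[None, :] - (i / n)[None, :]
    b = ((i + 1) / n)[None, :] - lam[:, None] * x[None, :]
    cummax_a = np.maximum.accumulate(a, axis=1)
    best_end_at = b + cummax_a  # best single interval ending exactly at j
    best_upto = np.maximum.accumulate(best_end_at, axis=1)
    e1 = best_upto[:, -1]

    sufmax_b = np.maximum.accumulate(b[:, ::-1], axis=1)[:, ::-1]
    best_start_at = a + sufmax_b  # best single interval starting exactly at i
    # two disjoint intervals: first ends at some j < i, second starts at i
    e2_candidates = best_upto[:, :-1] + best_start_at[:, 1:]
    e2 = np.maximum(e1, e2_candidates.max(axis=1))
    return float(np.maximum(e2 - e1, 0.0).max())


def _unimodal_rearrangement(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest unimodal CDF to the empirical CDF: greatest convex minorant
    left of the mode, least concave majorant right of it.

    The mode is placed at the data point of highest kernel density.  Returns
    (knots, cdf values) of the piecewise-linear unimodal CDF, suitable for
    inverse-transform sampling.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    F = (np.arange(n) + 1) / n
    kde = stats.gaussian_kde(xs)
    mode_idx = int(np.argmax(kde(xs)))

    # prepend the point (x_0 - tiny, 0) so the left branch starts at mass 0
    span = xs[-1] - xs[0]
    x_left = np.concatenate([[xs[0] - 1e-9 * max(span, 1.0)], xs[: mode_idx + 1]])
    f_left = np.concatenate([[0.0], F[: mode_idx + 1]])
    g_left = _convex_minorant(x_left, f_left)

    x_right = xs[mode_idx:]
    f_right = np.concatenate([[F[mode_idx - 1] if mode_idx > 0 else 0.0], F[mode_idx:]])
    # least concave majorant of points ((x_mode, F_before_mode) .. (x_max, 1))
    x_r = np.concatenate([[xs[mode_idx]], x_right])
    g_right = -_convex_minorant(x_r, -f_right)

    knots = np.concatenate([x_left, x_r[1:]])
    vals = np.concatenate([g_left, g_right[1:]])
    vals = np.maximum.accumulate(np.clip(vals, 0.0, 1.0))
    return knots, vals


def _convex_minorant(xp: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Greatest convex minorant of points (xp, yp), evaluated at xp.

    Lower-hull construction; xp must be nondecreasing.
    """
    hull: list[int] = []
    for i in range(len(xp)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # drop i1 if it lies above the chord i0 -> i
            lhs = (yp[i1] - yp[i0]) * (xp[i] - xp[i0])
            rhs = (yp[i] - yp[i0]) * (xp[i1] - xp[i0])
            if lhs >= rhs:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(xp, xp[hull], yp[hull])


@dataclass
class BimodalityResult:
    statistic: float  # excess-mass difference, 2 vs 1 modes
    p_value: float  # bootstrap, add-one corrected: p in (0, 1]
    B: int
    seed: int | None


def bimodality_test(
    counts: np.ndarray, B: int = 500, seed: int | None = None, n_lambda: int = 50
) -> BimodalityResult:
    """Excess-mass test of unimodality with bootstrap calibration.

    The null distribution of the statistic is estimated by resampling from
    the unimodal rearrangement of the empirical CDF (convex-minorant /
    concave-majorant construction around the kernel-density mode); the
    reported p-value is (1 + #{D* >= D}) / (B + 1).
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.unique(x).size < 3:
        raise ValueError("degenerate data: too few distinct values")
    stat = excess_mass_statistic(x, n_lambda=n_lambda)

    knots, cdf = _unimodal_rearrangement(x)
    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(B):
        u = rng.random(n)
        xb = np.interp(u, cdf, knots)
        if excess_mass_statistic(xb, n_lambda=n_lambda) >= stat:
            exceed += 1
    return BimodalityResult(
        statistic=stat,
        p_value=(1 + exceed) / (B + 1),
        B=B,
        seed=seed,
    )


def omega_squared(ss_term: float, df_term: float, ms_err: float, ss_total: float) -> float:
    """Low-bias ANOVA effect size: (SS_term - df * MS_err) / (SS_total + MS_err).

    Reported unclipped; small negative values occur under the null.
    """
    return (ss_term - df_term * ms_err) / (ss_total + ms_err)


@dataclass
class AncovaResult:
    slopes: dict[str, float]  # per-condition regression slope on stage
    r_squared: dict[str, float]  # per-condition R^2 of count ~ stage
    treatment_p: float  # count ~ stage vs + treatment (nested F)
    slope_change_p: float  # + treatment vs * treatment (nested F)
    omega2: dict[str, float]  # sequential ANOVA omega^2 per term
    anova: pd.DataFrame  # sequential (type I) table of the full model
    n: int


def ancova(counts: pd.DataFrame, strain: str, stage_max: int = 30) -> AncovaResult:
    """Stage-adjusted treatment analysis of transcript counts for one strain.

    Fits count ~ stage, count ~ stage + treatment and count ~ stage *
    treatment; the treatment effect and the change in slope are nested-model
    F tests, and omega^2 effect sizes come from the sequential ANOVA table
    of the full model.  Per-condition slopes and R^2 are from separate
    simple regressions.
    """
    sub = counts[(counts["strain"] == strain) & (counts["stage"] <= stage_max)].copy()
    conditions = list(pd.unique(sub["treatment"]))
    slopes, r2 = {}, {}
    for cond in conditions:
        grp = sub[sub["treatment"] == cond]
        if len(grp) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 embryos")
        if grp["stage"].nunique() < 2:
            raise ValueError(f"condition {cond!r} spans a single stage; slope inestimable")
        fit = smf.ols("count ~ stage", data=grp).fit()
        slopes[cond] = float(fit.params["stage"])
        r2[cond] = float(fit.rsquared)

    m1 = smf.ols("count ~ stage", data=sub).fit()
    m2 = smf.ols("count ~ stage + C(treatment)", data=sub).fit()
    m3 = smf.ols("count ~ stage * C(treatment)", data=sub).fit()
    cmp12 = sm.stats.anova_lm(m1, m2)
    cmp23 = sm.stats.anova_lm(m2, m3)

    table = sm.stats.anova_lm(m3, typ=1)
    ms_err = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    ss_total = float(table["sum_sq"].sum())
    om = {
        term: omega_squared(
            float(table.loc[term, "sum_sq"]),
            float(table.loc[term, "df"]),
            ms_err,
            ss_total,
        )
        for term in table.index
        if term != "Residual"
    }
    return AncovaResult(
        slopes=slopes,
        r_squared=r2,
        treatment_p=float(cmp12["Pr(>F)"].iloc[1]),
        slope_change_p=float(cmp23["Pr(>F)"].iloc[1]),
        omega2=om,
        anova=table,
        n=len(sub),
    )
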