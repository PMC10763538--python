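"""Penetrance GLMs for embryonic-lethality assays, pairwise contrasts, and
complementation-pattern calling.

Each replicate plate contributes a (dead, hatched) pair; penetrance is
modeled on the logit scale with a quasibinomial error structure, i.e. a
binomial GLM whose coefficient covariance is scaled by the Pearson
dispersion phi = X^2 / (n - p).  Plate-to-plate overdispersion (worms on a
plate share a mother, age and microenvironment) makes phi > 1 typical.

Complementation tests compare a wild parent strain P against its two F1
hybrids with N2: one carrying a functional ppw-1 allele (H+) and one
carrying the ppw-1 deletion (Hdel).  Four qualitative response patterns are
distinguished: no rescue; ppw-1-dependent rescue (H+ responds, Hdel does
not); ppw-1-dependent suppression (removing ppw-1 raises lethality); and
ppw-1-independent rescue (both hybrids respond equally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GLMFit",
    "LifespanModelFit",
    "ComplementationCall",
    "fit_quasibinomial",
    "pairwise_contrasts",
    "fit_lifespan_model",
    "fit_lifespan_reduced",
    "classify_complementation",
    "complementation_test",
]

PATTERNS = (
    "no_rescue",
    "ppw1_dependent_rescue",
    "ppw1_dependent_suppression",
    "ppw1_independent_rescue",
)


@dataclass
class GLMFit:
    """Quasibinomial logit fit of plate-level lethality on a genotype factor."""

    genotypes: list[str]
    params: pd.Series  # treatment coding; first genotype is the reference
    cov: pd.DataFrame  # phi-scaled coefficient covariance
    phi: float
    df_resid: int
    fitted_props: pd.Series  # genotype -> fitted proportion dead
    separated: list[str]  # genotypes with all-dead or all-hatched outcomes
    converged: bool
    n_plates: int

    def logit_estimates(self) -> pd.Series:
        """Per-genotype estimate on the logit scale (eta_g)."""
        beta = self.params.to_numpy()
        eta = beta[0] + np.concatenate([[0.0], beta[1:]])
        return pd.Series(eta, index=self.genotypes, name="logit")


def _validate_plates(records: pd.DataFrame) -> pd.DataFrame:
    req = {"genotype", "dead", "hatched"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"plate records missing columns: {sorted(missing)}")
    if ((records["dead"] + records["hatched"]) < 1).any():
        raise ValueError("each plate needs dead + hatched >= 1")
    if (records[["dead", "hatched"]] < 0).any().any():
        raise ValueError("negative counts")
    return records


def fit_quasibinomial(records: pd.DataFrame, factor: str = "genotype") -> GLMFit:
    """Fit lethality ~ genotype with a logit link and Pearson dispersion.

    Complete separation (a genotype whose plates are all dead or all
    hatched) is detected up front; such genotypes get half an embryo of the
    opposite outcome, bounding the fitted proportion at 0.5/(N+1) (or its
    complement) instead of an infinite logit, and are flagged.
    """
    records = _validate_plates(records).copy()
    if len(records) < 2:
        raise ValueError("need at least 2 plates")
    genotypes = list(pd.unique(records[factor]))
    counts = records.groupby(factor, sort=False)[["dead", "hatched"]].sum()
    if len(genotypes) == 1 and len(records) == 1:
        raise ValueError("dispersion undefined with a single plate")

    separated = [
        g for g in genotypes if counts.loc[g, "dead"] == 0 or counts.loc[g, "hatched"] == 0
    ]
    dead = records["dead"].to_numpy(dtype=float)
    hatched = records["hatched"].to_numpy(dtype=float)
    for g in separated:
        first = records.index[records[factor] == g][0]
        i = records.index.get_loc(first)
        dead[i] += 0.5
        hatched[i] += 0.5

    codes = pd.Categorical(records[factor], categories=genotypes).codes
    X = np.zeros((len(records), len(genotypes)))
    X[:, 0] = 1.0
    for j in range(1, len(genotypes)):
        X[codes == j, j] = 1.0

    model = sm.GLM(np.column_stack([dead, hatched]), X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # genotype-level separation is detected and bounded above; the
        # residual statsmodels warning on exact fits is spurious here
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit()
    p = len(genotypes)
    df_resid = len(records) - p
    if df_resid <= 0:
        raise ValueError("dispersion undefined: no residual degrees of freedom")
    # Pearson dispersion with plate as the unit: phi = X^2 / (n_plates - p)
    totals = dead + hatched
    prop = dead / totals
    fitted = np.asarray(res.fittedvalues)
    phi = float(
        ((prop - fitted) ** 2 * totals / (fitted * (1 - fitted))).sum() / df_resid
    )

    names = ["Intercept"] + [f"{factor}[{g}]" for g in genotypes[1:]]
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params() * phi, index=names, columns=names)
    eta = params.iloc[0] + np.concatenate([[0.0], params.iloc[1:].to_numpy()])
    fitted = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=genotypes, name="prop_dead")
    return GLMFit(
        genotypes=genotypes,
        params=params,
        cov=cov,
        phi=phi,
        df_resid=df_resid,
        fitted_props=fitted,
        separated=separated,
        converged=bool(res.converged),
        n_plates=len(records),
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_contrasts(
    fit: GLMFit,
    adjust: str = "single_step",
    seed: int | None = None,
    n_mc: int = 20_000,
) -> pd.DataFrame:
    """All pairwise genotype differences on the logit scale, Tukey-style.

    ``single_step`` adjusts the t-based p-values against the joint
    distribution of the maximum |t| over the contrast family, approximated
    by seeded Monte Carlo draws from the estimated coefficient covariance
    (multivariate t with the fit's residual df).  ``bonferroni`` and
    ``none`` are deterministic alternatives.
    """
    if adjust not in ("single_step", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    k = len(fit.genotypes)
    if k < 2:
        raise ValueError("need at least 2 genotypes for contrasts")
    # coefficient layout: [intercept, g2, ..., gk]; eta_g = b0 + b_g (b_ref = 0)
    pairs = [(a, b) for i, a in enumerate(fit.genotypes) for b in fit.genotypes[i + 1 :]]
    C = np.zeros((len(pairs), k))
    for r, (a, b) in enumerate(pairs):
        ia, ib = fit.genotypes.index(a), fit.genotypes.index(b)
        if ia > 0:
            C[r, ia] = 1.0
        if ib > 0:
            C[r, ib] = -1.0
    est = C @ fit.params.to_numpy()
    V = C @ fit.cov.to_numpy() @ C.T
    se = np.sqrt(np.clip(np.diag(V), 0, None))
    keep = se > 0
    if not keep.all():
        warnings.warn("rank-deficient contrasts dropped")
        pairs = [p for p, kk in zip(pairs, keep) if kk]
        C, est, V = C[keep], est[keep], V[np.ix_(keep, keep)]
        se = se[keep]
    t = est / se
    df = fit.df_resid
    p_raw = 2 * stats.t.sf(np.abs(t), df)

    if adjust == "none" or len(pairs) == 1:
        p_adj = p_raw.copy()
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, p_raw * len(pairs))
    else:
        R = V / np.outer(se, se)
        w, Q = np.linalg.eigh((R + R.T) / 2)
        L = Q @ np.diag(np.sqrt(np.clip(w, 0, None)))
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n_mc, R.shape[0])) @ L.T
        scale = np.sqrt(rng.chisquare(df, size=n_mc) / df)
        max_abs_t = np.abs(Z / scale[:, None]).max(axis=1)
        p_adj = np.array([(max_abs_t >= abs(ti)).mean() for ti in t])
        p_adj = np.maximum(p_adj, p_raw)  # single-step never beats unadjusted

    return pd.DataFrame(
        {
            "contrast": [f"{a} - {b}" for a, b in pairs],
            "a": [a for a, _ in pairs],
            "b": [b for _, b in pairs],
            "estimate": est,
            "se": se,
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "stars": [_stars(p) for p in p_adj],
        }
    )


@dataclass
class LifespanModelFit:
    """Sequential-F decomposition of plate lethality over strain, age and worm."""

    params: pd.Series
    anova: pd.DataFrame  # term, df, ss, F, p (sequential)
    sigma2: float
    r_squared: float
    full_rank: bool


def _lifespan_design(records: pd.DataFrame):
    strains = list(pd.unique(records["strain"]))
    prop = (records["dead"] / (records["dead"] + records["hatched"])).to_numpy()
    age = records["age_h"].to_numpy(dtype=float)
    n = len(records)

    blocks: list[tuple[str, np.ndarray]] = []
    X0 = np.ones((n, 1))
    strain_cols = np.column_stack(
        [(records["strain"] == s).to_numpy(float) for s in strains[1:]]
    ) if len(strains) > 1 else np.empty((n, 0))
    blocks.append(("strain", strain_cols))
    blocks.append(("age", age[:, None]))
    inter = strain_cols * age[:, None] if strain_cols.size else np.empty((n, 0))
    blocks.append(("strain:age", inter))
    worm_cols = []
    for s in strains:
        in_s = records["strain"] == s
        worms = list(pd.unique(records.loc[in_s, "worm"]))
        for w in worms[1:]:  # one reference worm per strain
            worm_cols.append(((records["worm"] == w) & in_s).to_numpy(float))
    worms_block = np.column_stack(worm_cols) if worm_cols else np.empty((n, 0))
    blocks.append(("worm(strain)", worms_block))
    return prop, X0, blocks


def fit_lifespan_model(records: pd.DataFrame) -> LifespanModelFit:
    """OLS of plate-level dead proportion on strain, age, their interaction,
    and worm nested in strain, with sequential F tests per term.

    Requires >= 2 strains, >= 2 worms per strain and >= 2 ages per worm;
    a design where worm effects are confounded with strain:age cells raises
    a rank error.
    """
    req = {"strain", "worm", "age_h", "dead", "hatched"}
    if req - set(records.columns):
        raise ValueError(f"lifespan records need columns {sorted(req)}")
    y, X0, blocks = _lifespan_design(records)

    X_full = np.column_stack([X0] + [b for _, b in blocks if b.size])
    n, p = X_full.shape
    rank = np.linalg.matrix_rank(X_full)
    if rank < p or n <= p:
        raise ValueError("confounded lifespan design: model matrix is rank deficient")

    # sequential (type I) sums of squares by growing the design block-wise
    rows = []
    X = X0
    rss_prev = _ols_rss(X, y)
    for name, b in blocks:
        if b.size == 0:
            continue
        X = np.column_stack([X, b])
        rss = _ols_rss(X, y)
        rows.append((name, b.shape[1], rss_prev - rss))
        rss_prev = rss
    df_resid = n - X.shape[1]
    sigma2 = rss_prev / df_resid
    anova = pd.DataFrame(rows, columns=["term", "df", "ss"])
    anova["F"] = (anova["ss"] / anova["df"]) / sigma2
    anova["p"] = stats.f.sf(anova["F"], anova["df"], df_resid)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return LifespanModelFit(
        params=pd.Series(beta),
        anova=anova,
        sigma2=float(sigma2),
        r_squared=float(1 - rss_prev / ss_tot) if ss_tot > 0 else 1.0,
        full_rank=True,
    )


def fit_lifespan_reduced(records: pd.DataFrame, strain: str) -> LifespanModelFit:
    """Per-strain reduced model: dead proportion ~ age + worm."""
    sub = records[records["strain"] == strain].copy()
    if sub.empty:
        raise ValueError(f"no records for strain {strain!r}")
    y = (sub["dead"] / (sub["dead"] + sub["hatched"])).to_numpy()
    age = sub["age_h"].to_numpy(float)[:, None]
    worms = list(pd.unique(sub["worm"]))
    worm_cols = (
        np.column_stack([(sub["worm"] == w).to_numpy(float) for w in worms[1:]])
        if len(worms) > 1
        else np.empty((len(sub), 0))
    )
    n = len(sub)
    X0 = np.ones((n, 1))
    blocks = [("age", age), ("worm", worm_cols)]
    X_full = np.column_stack([X0] + [b for _, b in blocks if b.size])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1] or n <= X_full.shape[1]:
        raise ValueError("rank-deficient reduced design")
    rows = []
    X = X0
    rss_prev = _ols_rss(X, y)
    for name, b in blocks:
        if b.size == 0:
            continue
        X = np.column_stack([X, b])
        rss = _ols_rss(X, y)
        rows.append((name, b.shape[1], rss_prev - rss))
        rss_prev = rss
    df_resid = n - X.shape[1]
    sigma2 = rss_prev / df_resid
    anova = pd.DataFrame(rows, columns=["term", "df", "ss"])
    anova["F"] = (anova["ss"] / anova["df"]) / sigma2
    anova["p"] = stats.f.sf(anova["F"], anova["df"], df_resid)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return LifespanModelFit(
        params=pd.Series(beta),
        anova=anova,
        sigma2=float(sigma2),
        r_squared=float(1 - rss_prev / ss_tot) if ss_tot > 0 else 1.0,
        full_rank=True,
    )


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


@dataclass
class ComplementationCall:
    """Qualitative ppw-1 complementation pattern for one wild strain."""

    estimates: dict[str, float]  # genotype -> fitted proportion dead
    pvalues: dict[tuple[str, str], float]  # adjusted pairwise p
    pattern: str
    ambiguous: bool = False
    alpha: float = 0.05


def classify_complementation(
    estimates: dict[str, float],
    pvalues: dict[tuple[str, str], float],
    parent: str = "parent",
    f1_plus: str = "f1_plus",
    f1_del: str = "f1_del",
    alpha: float = 0.05,
) -> ComplementationCall:
    """Call the complementation pattern from genotype estimates and adjusted
    pairwise p-values.

    Rules, checked in order (first match wins):
      1. no_rescue — neither hybrid significantly exceeds the parent;
      2. ppw1_dependent_rescue — H+ > parent and H+ > Hdel, both significant;
      3. ppw1_dependent_suppression — Hdel > H+ and Hdel > parent, both
         significant;
      4. ppw1_independent_rescue — both hybrids significantly exceed the
         parent and do not differ from each other.
    A layout matching none of the rules falls back to no_rescue with the
    ambiguity flag set.
    """
    for g in (parent, f1_plus, f1_del):
        if g not in estimates:
            raise ValueError(f"missing genotype estimate for {g!r}")

    def p_of(a, b):
        if (a, b) in pvalues:
            return pvalues[(a, b)]
        if (b, a) in pvalues:
            return pvalues[(b, a)]
        raise ValueError(f"missing pairwise p-value for {a} vs {b}")

    def greater(a, b):
        return estimates[a] > estimates[b] and p_of(a, b) < alpha

    if not greater(f1_plus, parent) and not greater(f1_del, parent):
        pattern, ambiguous = "no_rescue", False
    elif greater(f1_plus, parent) and greater(f1_plus, f1_del):
        pattern, ambiguous = "ppw1_dependent_rescue", False
    elif greater(f1_del, f1_plus) and greater(f1_del, parent):
        pattern, ambiguous = "ppw1_dependent_suppression", False
    elif (
        greater(f1_plus, parent)
        and greater(f1_del, parent)
        and p_of(f1_plus, f1_del) >= alpha
    ):
        pattern, ambiguous = "ppw1_independent_rescue", False
    else:
        pattern, ambiguous = "no_rescue", True
    return ComplementationCall(
        estimates={g: float(estimates[g]) for g in (parent, f1_plus, f1_del)},
        pvalues={k: float(v) for k, v in pvalues.items()},
        pattern=pattern,
        ambiguous=ambiguous,
        alpha=alpha,
    )


def complementation_test(
    records: pd.DataFrame,
    parent: str,
    f1_plus: str,
    f1_del: str,
    alpha: float = 0.05,
    adjust: str = "single_step",
    seed: int | None = None,
) -> ComplementationCall:
    """Fit the quasibinomial GLM on the three genotypes, run Tukey-style
    contrasts, and call the complementation pattern."""
    sub = records[records["genotype"].isin([parent, f1_plus, f1_del])]
    fit = fit_quasibinomial(sub)
    contrasts = pairwise_contrasts(fit, adjust=adjust, seed=seed)
    pvals = {(r["a"], r["b"]): r["p_adj"] for _, r in contrasts.iterrows()}
    est = fit.fitted_props.to_dict()
    return classify_complementation(
        est, pvals, parent=parent, f1_plus=f1_plus, f1_del=f1_del, alpha=alpha
    )
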