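"""Strain-wise expression variance and expression-matched resampling enrichment.

The central question this module answers: does a focal gene set (here, genes
known to mediate RNAi) show more between-strain expression variation than the
rest of the genome, once expression level is controlled for?  The workflow is

1. filter genes with negligible counts,
2. variance-stabilize the count matrix (median-of-ratios size factors +
   log2),
3. score each gene by the between-strain sum of squares from a one-way
   ANOVA of normalized expression on strain,
4. build many random gene sets matched to the focal set on mean expression
   percentile, and
5. compare the focal set's median variance (and differential-expression
   proportion) against that matched null.

Differential expression across strains is scored by a one-way ANOVA F-test on
the variance-stabilized values.  This is a deliberate stand-in for a negative
binomial likelihood-ratio test: the enrichment machinery only consumes the
resulting boolean flags and also accepts externally computed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountsMatrix",
    "EnrichmentResult",
    "filter_low_counts",
    "normalize_vst",
    "strain_variance",
    "de_test",
    "gene_variance_table",
    "match_expression_sets",
    "resampling_enrichment",
    "hypergeom_enrichment",
]

DE_FDR_THRESHOLD = 0.1


@dataclass
class CountsMatrix:
    """Integer gene x sample count matrix with a sample -> strain mapping."""

    counts: pd.DataFrame
    strains: pd.Series

    def __post_init__(self) -> None:
        self.strains = pd.Series(self.strains)
        missing = [s for s in self.counts.columns if s not in self.strains.index]
        if missing:
            raise ValueError(f"samples missing from the sample sheet: {missing}")
        self.strains = self.strains.loc[self.counts.columns]
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.strains.nunique() < 2:
            raise ValueError("need at least 2 strains")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def filter_low_counts(cm: CountsMatrix, threshold: int = 10) -> CountsMatrix:
    """Drop genes whose total count across all samples is <= ``threshold``.

    Gene order is otherwise preserved.
    """
    keep = cm.counts.sum(axis=1) > threshold
    if not keep.any():
        raise ValueError("low-count filter removed every gene")
    return CountsMatrix(cm.counts.loc[keep], cm.strains)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with a nonzero geometric mean."""
    vals = counts.to_numpy(dtype=float)
    if (vals.sum(axis=0) == 0).any():
        bad = counts.columns[vals.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero samples, size factors undefined: {bad}")
    usable = (vals > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(vals[usable])
    log_geo = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _common_dispersion(norm: np.ndarray, strain_codes: np.ndarray) -> float | None:
    """Method-of-moments NB dispersion pooled within strains.

    Uses genes with mean normalized count > 5; returns the median of the
    positive per-gene estimates a_g = (v_g - m_g) / m_g^2, or None when the
    design has no replication or too few usable genes.
    """
    n_strains = strain_codes.max() + 1
    reps = np.bincount(strain_codes, minlength=n_strains)
    df = norm.shape[1] - (reps > 0).sum()
    if df < 1:
        return None
    rss = np.zeros(norm.shape[0])
    for s in range(n_strains):
        sub = norm[:, strain_codes == s]
        if sub.shape[1] == 0:
            continue
        rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = rss / df
    m = norm.mean(axis=1)
    ok = m > 5
    if ok.sum() < 10:
        return None
    a_g = (v[ok] - m[ok]) / m[ok] ** 2
    a_g = a_g[a_g > 0]
    if a_g.size < 10:
        return None
    return float(np.median(a_g))


def normalize_vst(
    cm: CountsMatrix,
    pseudocount: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Variance-stabilizing normalization to the log2 scale.

    Library size is removed with median-of-ratios size factors.  The
    transform is the negative-binomial delta-method form

        f(x) = log2( (1 + 2 a x + 2 sqrt(a x (1 + a x))) / (4 a) ),

    which behaves as log2(x) + const for large x and makes the per-gene
    variance approximately independent of the mean when counts are NB with
    common dispersion ``a``.  The dispersion is estimated from within-strain
    replicate variation by moments unless supplied; with no usable estimate
    (e.g. no replication) the transform falls back to
    log2(x / size_factor + pseudocount).
    """
    if cm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sf = size_factors(cm.counts)
    norm = (cm.counts / sf).to_numpy(dtype=float)
    if dispersion is None:
        codes, _ = pd.factorize(cm.strains.loc[cm.counts.columns])
        dispersion = _common_dispersion(norm, codes)
    if dispersion is None or dispersion <= 0:
        vals = np.log2(norm + pseudocount)
    else:
        a = dispersion
        vals = np.log2((1 + 2 * a * norm + 2 * np.sqrt(a * norm * (1 + a * norm))) / (4 * a))
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def _group_stats(values: np.ndarray, strain_codes: np.ndarray, n_strains: int):
    """Per-strain means/counts for a (genes x samples) value matrix."""
    n_s = np.bincount(strain_codes, minlength=n_strains).astype(float)
    sums = np.zeros((values.shape[0], n_strains))
    for s in range(n_strains):
        sums[:, s] = values[:, strain_codes == s].sum(axis=1)
    return sums / n_s, n_s


def strain_variance(norm: pd.DataFrame, strains: pd.Series) -> pd.Series:
    """Between-strain sum of squares per gene: SS = sum_s n_s (ybar_s - ybar)^2.

    This is the strain-term sum of squares from the one-way ANOVA
    ``expression ~ strain``.  NaN values propagate to the gene's SS.
    """
    strains = pd.Series(strains).loc[norm.columns]
    codes, uniques = pd.factorize(strains)
    if len(uniques) < 2:
        raise ValueError("need at least 2 strains")
    vals = norm.to_numpy(dtype=float)
    if np.isnan(vals).any():
        warnings.warn("missing values present; NA propagated to strain_SS")
    means, n_s = _group_stats(vals, codes, len(uniques))
    grand = vals.mean(axis=1)
    ss = (n_s * (means - grand[:, None]) ** 2).sum(axis=1)
    return pd.Series(ss, index=norm.index, name="strain_SS")


def de_test(norm: pd.DataFrame, strains: pd.Series) -> pd.DataFrame:
    """Per-gene one-way ANOVA F-test of expression across strains, with BH FDR.

    Returns columns ``de_p``, ``de_fdr``, ``de_flag`` (fdr < 0.1) and
    ``degenerate`` (zero residual variance).  A gene with zero residual
    variance but a nonzero strain effect gets p = 0; a gene that is constant
    everywhere gets p = 1.  Both are flagged degenerate.
    """
    strains = pd.Series(strains).loc[norm.columns]
    codes, uniques = pd.factorize(strains)
    k = len(uniques)
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("need at least 2 replicates per strain")
    vals = norm.to_numpy(dtype=float)
    n = vals.shape[1]
    means, n_s = _group_stats(vals, codes, k)
    grand = vals.mean(axis=1)
    ss_between = (n_s * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_total = ((vals - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.maximum(ss_total - ss_between, 0.0)

    df1, df2 = k - 1, n - k
    tol = 1e-12
    degenerate = ss_within <= tol * np.maximum(ss_total, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    p = np.where(degenerate & (ss_between > tol), 0.0, p)
    p = np.where(degenerate & (ss_between <= tol), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "de_p": p,
            "de_fdr": fdr,
            "de_flag": fdr < DE_FDR_THRESHOLD,
            "degenerate": degenerate,
        },
        index=norm.index,
    )


def expression_quantiles(mean_expr: pd.Series) -> pd.Series:
    """Empirical quantile in (0, 1] of mean expression, average ranks for ties."""
    ranks = stats.rankdata(mean_expr.to_numpy(), method="average")
    return pd.Series(ranks / len(ranks), index=mean_expr.index, name="expr_quantile")


def gene_variance_table(cm: CountsMatrix) -> pd.DataFrame:
    """Full per-gene table: mean vst expression, expression quantile,
    between-strain SS, and differential-expression p/FDR/flag."""
    norm = normalize_vst(cm)
    mean_expr = norm.mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_expr": mean_expr,
            "expr_quantile": expression_quantiles(mean_expr),
            "strain_SS": strain_variance(norm, cm.strains),
        }
    )
    return table.join(de_test(norm, cm.strains))


def match_expression_sets(
    table: pd.DataFrame,
    focal: list[str],
    window: float = 0.005,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``B`` expression-matched null gene sets.

    For each focal gene, candidates are the non-focal genes whose expression
    quantile lies within ``window`` of the focal gene's quantile; one
    candidate is drawn uniformly (independently per slot, so duplicates
    within a set are possible when pools overlap).  Returns an integer array
    of shape (B, len(focal)) indexing rows of ``table``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    focal = list(focal)
    missing = [g for g in focal if g not in table.index]
    if missing:
        raise KeyError(f"focal genes absent from table: {missing}")
    q = table["expr_quantile"].to_numpy()
    is_focal = table.index.isin(focal)
    pools = []
    eps = 1e-12
    for g in focal:
        qf = table.at[g, "expr_quantile"]
        pool = np.flatnonzero((np.abs(q - qf) <= window + eps) & ~is_focal)
        if pool.size == 0:
            raise ValueError(f"no expression-matched candidates for focal gene {g!r}")
        pools.append(pool)
    sets = np.empty((B, len(focal)), dtype=np.intp)
    for j, pool in enumerate(pools):
        sets[:, j] = pool[rng.integers(0, pool.size, size=B)]
    return sets


def _mw_greater_pvalues(x: np.ndarray, null_values: np.ndarray) -> np.ndarray:
    """One-tailed Mann-Whitney p-values (x stochastically greater), vectorized.

    ``x`` has shape (m,), ``null_values`` shape (B, n).  Uses the normal
    approximation with tie and continuity corrections; callers with small
    samples should use scipy's exact routine instead.
    """
    m = x.size
    B, n = null_values.shape
    gt = (x[None, :, None] > null_values[:, None, :]).sum(axis=(1, 2))
    eq = (x[None, :, None] == null_values[:, None, :]).sum(axis=(1, 2))
    u = gt + 0.5 * eq
    N = m + n
    mu = m * n / 2.0
    # tie correction needs sum(t^3 - t) over tied groups of the pooled sample
    tie_term = np.zeros(B)
    rows_with_ties = np.flatnonzero(eq > 0)
    for b in rows_with_ties:
        pooled = np.concatenate([x, null_values[b]])
        _, t = np.unique(pooled, return_counts=True)
        tie_term[b] = (t**3 - t).sum()
    sigma2 = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (u - mu - 0.5) / sigma
    return stats.norm.sf(z)


@dataclass
class EnrichmentResult:
    """Expression-matched resampling enrichment of a focal gene set."""

    observed_median_SS: float
    null_median_SS: np.ndarray
    frac_null_below: float
    perm_p_median: float
    perm_p_median_add_one: float
    mw_significant_count: int
    observed_de_prop: float
    null_de_prop: np.ndarray = field(repr=False)
    frac_null_deprop_below: float = np.nan
    perm_p_deprop: float = np.nan
    perm_p_deprop_add_one: float = np.nan
    hypergeom_p: float = np.nan
    B: int = 0
    seed: int | None = None
    alpha: float = 0.05

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed_median_SS": self.observed_median_SS,
            "frac_null_below": self.frac_null_below,
            "perm_p_median": self.perm_p_median,
            "perm_p_median_add_one": self.perm_p_median_add_one,
            "mw_significant_count": self.mw_significant_count,
            "observed_de_prop": self.observed_de_prop,
            "frac_null_deprop_below": self.frac_null_deprop_below,
            "perm_p_deprop": self.perm_p_deprop,
            "perm_p_deprop_add_one": self.perm_p_deprop_add_one,
            "hypergeom_p": self.hypergeom_p,
            "B": self.B,
            "seed": self.seed,
            "alpha": self.alpha,
        }
        if include_null:
            d["null_median_SS"] = np.asarray(self.null_median_SS).tolist()
            d["null_de_prop"] = np.asarray(self.null_de_prop).tolist()
        return d


def resampling_enrichment(
    table: pd.DataFrame,
    focal: list[str],
    B: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    window: float = 0.005,
    null_sets: np.ndarray | None = None,
) -> EnrichmentResult:
    """Compare the focal set's median strain_SS and DE proportion against
    expression-matched null sets.

    For each of B null sets this computes the median strain_SS, a one-tailed
    Mann-Whitney test of focal strain_SS values against the null set's, and
    the null set's differential-expression proportion.  Permutation p-values
    follow the count/B convention with ties counted as >=; the
    (count+1)/(B+1) variant is reported alongside.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    focal = list(focal)
    if null_sets is None:
        null_sets = match_expression_sets(table, focal, window=window, B=B, seed=seed)
    else:
        B = null_sets.shape[0]

    ss = table["strain_SS"].to_numpy(dtype=float)
    de = table["de_flag"].to_numpy(dtype=bool)
    focal_idx = table.index.get_indexer(focal)
    focal_ss = ss[focal_idx]

    null_ss = ss[null_sets]  # (B, m)
    null_medians = np.median(null_ss, axis=1)
    obs_median = float(np.median(focal_ss))

    if len(focal) > 20 and null_sets.shape[1] > 20:
        mw_p = _mw_greater_pvalues(focal_ss, null_ss)
    else:
        mw_p = np.array(
            [
                stats.mannwhitneyu(focal_ss, row, alternative="greater").pvalue
                for row in null_ss
            ]
        )
    mw_sig = int((mw_p < alpha).sum())

    n_ge = int((null_medians >= obs_median).sum())
    obs_de = float(de[focal_idx].mean())
    null_de = de[null_sets].mean(axis=1)
    n_ge_de = int((null_de >= obs_de).sum())

    N, K, n = len(table), int(de.sum()), len(focal)
    k = int(de[focal_idx].sum())

    return EnrichmentResult(
        observed_median_SS=obs_median,
        null_median_SS=null_medians,
        frac_null_below=(B - n_ge) / B,
        perm_p_median=n_ge / B,
        perm_p_median_add_one=(n_ge + 1) / (B + 1),
        mw_significant_count=mw_sig,
        observed_de_prop=obs_de,
        null_de_prop=null_de,
        frac_null_deprop_below=(B - n_ge_de) / B,
        perm_p_deprop=n_ge_de / B,
        perm_p_deprop_add_one=(n_ge_de + 1) / (B + 1),
        hypergeom_p=hypergeom_enrichment(N, K, n, k),
        B=B,
        seed=seed if isinstance(seed, int) else None,
        alpha=alpha,
    )


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a population
    of ``N`` containing ``K`` successes.  Computed by exact summation of the
    pmf in log space.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    k_lo = max(k, 0)
    k_hi = min(n, K)
    if k_lo > k_hi:
        return 0.0
    ks = np.arange(k_lo, k_hi + 1)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_pmf = log_comb(K, ks) + log_comb(N - K, n - ks) - log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))
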