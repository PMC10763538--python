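"""Per-gene diversity statistics and allele-fate classification from
population variant data.

Strains are wild C. elegans isotypes, which reproduce primarily by selfing;
genotypes are therefore treated as haploid (a heterozygous call, should one
appear, is demoted to missing with a warning at read time).  For every gene
the module computes per-site nucleotide diversity (missing-aware, with the
n/(n-1) small-sample correction applied per site), haplotype diversity over
strains fully called at the locus, and variant counts per kb by functional
impact class.  Per (gene, strain) it classifies the allele's fate:

* ``pseudogenized`` — carries at least one high-confidence high-impact
  lesion (frameshift, stop-gain, ...) with >= 1% of sites diverged or
  missing, or has > 50% of sites uncalled;
* ``functional_diverged`` — >= 5 amino-acid substitutions, >= 1% of sites
  diverged, and no high-impact lesion at the locus;
* ``reference_like`` — everything else.

Alleles with > 75% of sites uncalled are additionally flagged
``possibly_missing``: such cases may represent gene loss rather than
pseudogenization in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "VariantTable",
    "AlleleSummary",
    "AlleleClassification",
    "Thresholds",
    "gene_pi",
    "variants_per_kb",
    "summarize_allele",
    "classify_allele",
    "haplotypes",
    "exclude_hyperdiverse",
    "geneset_compare",
]

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

MISSING = -1  # genotype code for a missed call
REF = 0
ALT = 1  # carries the alt allele of this record (one record per alt)


@dataclass
class VariantTable:
    """Site-level variant records plus a haploid genotype matrix.

    ``records`` has one row per (site, alt) with columns gene, chrom, pos
    (1-based), ref, alt, impact, subtype, high_conf.  ``genotypes`` is an
    int8 array of shape (n_records, n_strains): -1 missing, 0 reference,
    1 carries this record's alt.
    """

    records: pd.DataFrame
    genotypes: np.ndarray
    strains: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.records), len(self.strains)):
            raise ValueError("genotype matrix shape does not match records/strains")
        bad = ~np.isin(self.genotypes, (MISSING, REF, ALT))
        if bad.any():
            raise ValueError("genotype codes must be -1, 0 or 1")
        if not self.records.index.equals(pd.RangeIndex(len(self.records))):
            self.records = self.records.reset_index(drop=True)

    def gene_rows(self, gene: str) -> np.ndarray:
        if not hasattr(self, "_gene_index"):
            self._gene_index = {
                g: np.asarray(idx) for g, idx in self.records.groupby("gene").indices.items()
            }
        return self._gene_index.get(gene, np.array([], dtype=np.intp))

    def site_structure(self, gene: str) -> tuple[np.ndarray, np.ndarray, int]:
        """(rows, site id per row, number of distinct sites) for one gene.

        Records sharing a position belong to one site (multiallelic).
        Cached: the table is treated as immutable once built.
        """
        if not hasattr(self, "_site_cache"):
            self._site_cache: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        if gene not in self._site_cache:
            rows = self.gene_rows(gene)
            pos = self.records["pos"].to_numpy()[rows]
            _, site_id = np.unique(pos, return_inverse=True)
            n_sites = int(site_id.max()) + 1 if len(site_id) else 0
            self._site_cache[gene] = (rows, site_id, n_sites)
        return self._site_cache[gene]

    def record_masks(self, gene: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(high-impact, high-confidence, missense) masks over the gene's rows."""
        if not hasattr(self, "_mask_cache"):
            self._mask_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if gene not in self._mask_cache:
            rows, _, _ = self.site_structure(gene)
            rec = self.records.iloc[rows]
            impacts = rec["impact"].to_numpy()
            high = impacts == "HIGH"
            hc = rec["high_conf"].to_numpy(dtype=bool)
            missense = (impacts == "MODERATE") & (
                rec["subtype"].str.contains("missense", case=False).to_numpy()
            )
            self._mask_cache[gene] = (high, hc, missense)
        return self._mask_cache[gene]

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None


def gene_pi(vt: VariantTable, gene: str, gene_length: int) -> float:
    """Per-site nucleotide diversity of a gene, strains treated as haploid.

    pi = (1/L) * sum over sites of (n_s/(n_s-1)) * (1 - sum_a p_a^2), where
    n_s is the number of strains called at the site and p_a the allele
    frequencies among them.  Sites with fewer than two called strains are
    skipped; monomorphic sites (and the gene's unrecorded positions)
    contribute zero, so the denominator is the full gene length.
    """
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    rows, site_id, n_sites = vt.site_structure(gene)
    if rows.size == 0:
        return 0.0
    g = vt.genotypes[rows]
    site_rec_count = np.bincount(site_id, minlength=n_sites)

    total = 0.0
    # biallelic sites (one record) vectorized; multiallelic handled per site
    single = site_rec_count[site_id] == 1
    if single.any():
        gs = g[single]
        called = gs != MISSING
        n_s = called.sum(axis=1)
        n_alt = (gs == ALT).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = n_alt / n_s
            het = 2.0 * p * (1.0 - p)
            contrib = n_s / (n_s - 1.0) * het
        total += float(contrib[(n_s >= 2) & (het > 0)].sum())

    for sid in np.flatnonzero(site_rec_count > 1):
        sub = g[site_id == sid]  # (n_alts_at_site, n_strains)
        called = ~(sub == MISSING).any(axis=0)
        n_s = int(called.sum())
        if n_s < 2:
            continue
        # allele code per called strain: 0 = ref, i+1 = carries alt of row i
        carrier = sub[:, called] == ALT
        allele = np.zeros(n_s, dtype=np.intp)
        for i in range(sub.shape[0]):
            allele[carrier[i]] = i + 1
        counts = np.bincount(allele)
        p = counts[counts > 0] / n_s
        het = 1.0 - (p**2).sum()
        if het > 0:
            total += n_s / (n_s - 1) * het
    return total / gene_length


def variants_per_kb(vt: VariantTable, gene: str, gene_length: int) -> dict[str, float]:
    """Distinct variant records per kb, by impact class (one count per alt)."""
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    rows = vt.gene_rows(gene)
    impacts = vt.records["impact"].to_numpy()[rows]
    out = {}
    for cls in IMPACT_CLASSES:
        out[cls] = float((impacts == cls).sum()) * 1000.0 / gene_length
    return out


@dataclass
class AlleleSummary:
    gene: str
    strain: str
    n_sites: int
    n_diverged: int
    n_missing: int
    n_high_conf_high_impact: int
    n_high_impact_any: int
    n_aa_subs: int

    @property
    def frac_diverged(self) -> float:
        return self.n_diverged / self.n_sites

    @property
    def frac_missing(self) -> float:
        return self.n_missing / self.n_sites

    @property
    def frac_diverged_or_missing(self) -> float:
        return (self.n_diverged + self.n_missing) / self.n_sites


def summarize_allele(
    vt: VariantTable, gene: str, strain: str, gene_length: int
) -> AlleleSummary:
    """Count diverged/missing sites and impact-classified lesions carried by
    one strain at one gene.

    An amino-acid substitution is a MODERATE missense record carried by the
    strain; a high-impact lesion counts toward pseudogenization only when
    carried and flagged high-confidence.  A site both diverged and missing
    (possible at multiallelic sites) counts once, as diverged.
    """
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    s = vt.strain_index(strain)
    rows, site_id, n_sites = vt.site_structure(gene)
    g = vt.genotypes[rows, s]

    div_at = np.bincount(site_id, weights=(g == ALT), minlength=n_sites) > 0
    miss_at = np.bincount(site_id, weights=(g == MISSING), minlength=n_sites) > 0
    n_div = int(div_at.sum())
    n_miss = int((miss_at & ~div_at).sum())

    carried = g == ALT
    high, hc, missense = vt.record_masks(gene)
    return AlleleSummary(
        gene=gene,
        strain=strain,
        n_sites=int(gene_length),
        n_diverged=n_div,
        n_missing=n_miss,
        n_high_conf_high_impact=int((carried & high & hc).sum()),
        n_high_impact_any=int((carried & high).sum()),
        n_aa_subs=int((carried & missense).sum()),
    )


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for allele-fate classification (fractions of sites)."""

    min_div_or_missing: float = 0.01  # pseudogenized: diverged-or-missing floor
    missing_pseudo: float = 0.50  # pseudogenized: missing-call override
    min_aa_subs: int = 5  # functional divergence: amino-acid substitutions
    min_divergence: float = 0.01  # functional divergence: diverged-site floor
    possibly_missing: float = 0.75  # flag: gene may be absent, not pseudogenized


@dataclass
class AlleleClassification:
    label: str  # pseudogenized | functional_diverged | reference_like
    possibly_missing: bool


def classify_allele(
    summary: AlleleSummary, thresholds: Thresholds = Thresholds()
) -> AlleleClassification:
    """Rule-based allele fate call for one (gene, strain)."""
    t = thresholds
    pseudo = (
        summary.n_high_conf_high_impact >= 1
        and summary.frac_diverged_or_missing >= t.min_div_or_missing
    ) or summary.frac_missing > t.missing_pseudo
    if pseudo:
        label = "pseudogenized"
    elif (
        summary.n_aa_subs >= t.min_aa_subs
        and summary.frac_diverged >= t.min_divergence
        and summary.n_high_impact_any == 0
    ):
        label = "functional_diverged"
    else:
        label = "reference_like"
    return AlleleClassification(
        label=label,
        possibly_missing=summary.frac_missing > t.possibly_missing,
    )


def haplotypes(vt: VariantTable, gene: str):
    """Collapse strains into haplotypes at a gene and score their diversity.

    Strains with any missing call at the gene are excluded (and reported).
    Returns (assignment, n_haplotypes, haplotype_diversity, distance_matrix,
    excluded_strains) where ``assignment`` maps each usable strain to a
    haplotype id, diversity is Nei's H = (n/(n-1)) (1 - sum p_i^2) over
    haplotype frequencies, and the distance matrix holds Hamming distances
    between the distinct haplotypes.
    """
    rows = vt.gene_rows(gene)
    g = vt.genotypes[rows]  # (R, S)
    usable = ~(g == MISSING).any(axis=0) if rows.size else np.ones(len(vt.strains), bool)
    excluded = [s for s, u in zip(vt.strains, usable) if not u]
    n = int(usable.sum())
    if n < 2:
        raise ValueError(f"fewer than 2 fully called strains at {gene!r}")
    vectors = g[:, usable].T if rows.size else np.zeros((n, 0), dtype=np.int8)
    haps, inverse, counts = np.unique(
        vectors, axis=0, return_inverse=True, return_counts=True
    )
    p = counts / n
    h = n / (n - 1) * (1.0 - (p**2).sum())
    dist = (haps[:, None, :] != haps[None, :, :]).sum(axis=2)
    assignment = pd.Series(
        inverse, index=[s for s, u in zip(vt.strains, usable) if u], name="haplotype"
    )
    return assignment, len(counts), float(h), dist, excluded


def exclude_hyperdiverse(
    genes: pd.DataFrame, mask: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag and drop genes overlapping hyperdivergent intervals.

    ``genes`` has columns gene, chrom, start, end with 1-based inclusive
    spans; ``mask`` has chrom, start, end with 0-based half-open (BED)
    intervals, optionally a ``strain`` column — a gene is flagged if its
    span overlaps a masked interval in any strain.  Returns (filtered
    genes, boolean flag series indexed by gene).
    """
    trees: dict[str, IntervalTree] = {}
    for _, row in mask.iterrows():
        b0, b1 = int(row["start"]), int(row["end"])
        if b1 <= b0:
            raise ValueError(f"malformed interval {row['chrom']}:{b0}-{b1}")
        # BED [b0, b1) covers 1-based bases b0+1 .. b1
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(b0 + 1, b1 + 1)

    flags = {}
    for _, row in genes.iterrows():
        tree = trees.get(str(row["chrom"]))
        s, e = int(row["start"]), int(row["end"])
        flags[row["gene"]] = bool(tree is not None and tree.overlap(s, e + 1))
    flag_series = pd.Series(flags, name="hyperdiverse_flag")
    kept = genes[~genes["gene"].map(flag_series)].reset_index(drop=True)
    return kept, flag_series


def geneset_compare(
    values: pd.Series,
    focal: list[str],
    background: list[str],
    background_includes_focal: bool = False,
) -> dict:
    """Two-sided Mann-Whitney comparison of a per-gene statistic between a
    focal gene set and a background set, with medians.

    Exact enumeration when both sides have <= 10 observations (and no ties);
    tie-corrected normal approximation otherwise.
    """
    focal = list(focal)
    background = list(background)
    overlap = set(focal) & set(background)
    if overlap and not background_includes_focal:
        raise ValueError(
            f"focal and background overlap ({sorted(overlap)[:5]}...); "
            "pass background_includes_focal=True if intended"
        )
    if background_includes_focal:
        background = [g for g in background if g not in set(focal)]
    x = values.loc[focal].to_numpy(dtype=float)
    y = values.loc[background].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both gene sets must be nonempty")
    small = x.size <= 10 and y.size <= 10
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "median_focal": float(np.median(x)),
        "median_background": float(np.median(y)),
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_focal": int(x.size),
        "n_background": int(y.size),
        "method": method,
    }
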