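import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_force_pi, make_variant_table, random_variant_table
from rnaivar.popgen import (
    AlleleSummary,
    Thresholds,
    classify_allele,
    exclude_hyperdiverse,
    gene_pi,
    geneset_compare,
    haplotypes,
    summarize_allele,
    variants_per_kb,
)


class TestGenePi:
    def test_no_segregating_sites_zero(self):
        vt = make_variant_table([[0, 0, 0, 0]])
        assert gene_pi(vt, "g", 100) == 0.0

    def test_biallelic_two_two_hand_value(self):
        # 4 strains, one site at 2/2: pi = (4/3)(1 - 0.5)/100 = 1/150
        vt = make_variant_table([[1, 1, 0, 0]])
        assert gene_pi(vt, "g", 100) == pytest.approx(1 / 150, abs=1e-15)
        # equals brute-force mean pairwise differences: 4 of 6 pairs differ
        assert gene_pi(vt, "g", 100) == pytest.approx((4 / 6) / 100)

    def test_missing_aware_per_site_n(self):
        # one strain missing: n_s = 3, freq 1/3 -> (3/2)(2*(1/3)*(2/3)) = 2/3
        vt = make_variant_table([[1, 0, 0, -1]])
        assert gene_pi(vt, "g", 1) == pytest.approx(2 / 3)

    def test_site_with_single_called_strain_skipped(self):
        vt = make_variant_table([[1, -1, -1, -1]])
        assert gene_pi(vt, "g", 10) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            vt, L = random_variant_table(rng)
            assert gene_pi(vt, "g", L) == pytest.approx(
                brute_force_pi(vt, "g", L), abs=1e-12
            )


class TestVariantsPerKb:
    def test_simple_arithmetic(self):
        vt = make_variant_table(
            [[1, 0]] * 4, impacts=["MODERATE"] * 4
        )
        out = variants_per_kb(vt, "g", 2000)
        assert out["MODERATE"] == pytest.approx(2.0)
        assert out["HIGH"] == 0.0

    def test_no_variants_zero_vector(self):
        vt = make_variant_table([[0, 0]])
        out = variants_per_kb(vt, "other_gene", 500)
        assert all(v == 0.0 for v in out.values())

    def test_multiallelic_counts_once_per_class(self):
        # two alts at the same position with different impact classes
        vt = make_variant_table(
            [[1, 0], [0, 1]],
            positions=[10, 10],
            impacts=["HIGH", "MODERATE"],
        )
        out = variants_per_kb(vt, "g", 1000)
        assert out["HIGH"] == pytest.approx(1.0)
        assert out["MODERATE"] == pytest.approx(1.0)


class TestSummarizeAllele:
    def test_reference_strain_all_zero(self):
        vt = make_variant_table([[1, 0], [1, 0]], positions=[5, 9])
        s = summarize_allele(vt, "g", "s1", 1000)
        assert (s.n_diverged, s.n_missing, s.n_aa_subs) == (0, 0, 0)

    def test_diverged_and_missing_fractions(self):
        # 12 diverged + 3 missing sites of L=1000 -> 1.5%
        rows = [[1, 0]] * 12 + [[-1, 0]] * 3
        vt = make_variant_table(rows, positions=list(range(1, 16)))
        s = summarize_allele(vt, "g", "s0", 1000)
        assert (s.n_diverged, s.n_missing) == (12, 3)
        assert s.frac_diverged_or_missing == pytest.approx(0.015)

    def test_high_impact_requires_carrier(self):
        vt = make_variant_table(
            [[0, 1]], impacts=["HIGH"], subtypes=["stop_gained"]
        )
        s = summarize_allele(vt, "g", "s0", 100)
        assert s.n_high_conf_high_impact == 0
        assert summarize_allele(vt, "g", "s1", 100).n_high_conf_high_impact == 1

    def test_low_confidence_high_not_counted(self):
        vt = make_variant_table(
            [[1, 0]], impacts=["HIGH"], subtypes=["frameshift_variant"],
            high_conf=[False],
        )
        s = summarize_allele(vt, "g", "s0", 100)
        assert s.n_high_conf_high_impact == 0
        assert s.n_high_impact_any == 1

    def test_unknown_strain_errors(self):
        vt = make_variant_table([[0, 0]])
        with pytest.raises(KeyError, match="unknown strain"):
            summarize_allele(vt, "g", "nope", 100)


class TestClassifyAllele:
    @staticmethod
    def _summary(**kw):
        base = dict(gene="g", strain="s", n_sites=1000, n_diverged=0,
                    n_missing=0, n_high_conf_high_impact=0,
                    n_high_impact_any=0, n_aa_subs=0)
        base.update(kw)
        return AlleleSummary(**base)

    def test_high_impact_plus_divergence_is_pseudogenized(self):
        s = self._summary(n_high_conf_high_impact=1, n_high_impact_any=1,
                          n_diverged=12)  # 1.2% diverged
        assert classify_allele(s).label == "pseudogenized"

    def test_missense_divergence_is_functional_diverged(self):
        s = self._summary(n_aa_subs=7, n_diverged=15)  # 1.5%, no HIGH
        c = classify_allele(s)
        assert c.label == "functional_diverged" and not c.possibly_missing

    def test_mostly_uncalled_is_pseudogenized_possibly_missing(self):
        s = self._summary(n_missing=800)  # 80% uncalled
        c = classify_allele(s)
        assert c.label == "pseudogenized" and c.possibly_missing

    def test_below_thresholds_reference_like(self):
        s = self._summary(n_aa_subs=3, n_diverged=5)  # 0.5% diverged
        assert classify_allele(s).label == "reference_like"

    def test_high_impact_without_divergence_not_pseudogenized(self):
        s = self._summary(n_high_conf_high_impact=1, n_high_impact_any=1,
                          n_diverged=5)  # 0.5% < 1%
        assert classify_allele(s).label == "reference_like"

    def test_any_high_impact_blocks_functional_divergence(self):
        s = self._summary(n_aa_subs=8, n_diverged=20, n_high_impact_any=1)
        assert classify_allele(s).label == "reference_like"

    def test_possibly_missing_implies_pseudogenized(self):
        for frac in (0.76, 0.9, 1.0):
            s = self._summary(n_missing=int(1000 * frac))
            c = classify_allele(s)
            assert not c.possibly_missing or c.label == "pseudogenized"

    def test_custom_thresholds(self):
        s = self._summary(n_aa_subs=3, n_diverged=15)
        t = Thresholds(min_aa_subs=3)
        assert classify_allele(s, t).label == "functional_diverged"


class TestHaplotypes:
    def test_all_identical_single_haplotype(self):
        vt = make_variant_table([[1, 1, 1]])
        _, n_hap, h, dist, excluded = haplotypes(vt, "g")
        assert (n_hap, h) == (1, 0.0)
        assert excluded == []

    def test_all_distinct_maximal_diversity(self):
        vt = make_variant_table(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]]
        )
        _, n_hap, h, dist, _ = haplotypes(vt, "g")
        assert n_hap == 4
        assert h == pytest.approx(1.0)  # (4/3)(1 - 4/16)

    def test_two_one_frequencies(self):
        vt = make_variant_table([[1, 1, 0]])
        _, n_hap, h, dist, _ = haplotypes(vt, "g")
        assert n_hap == 2
        assert h == pytest.approx(2 / 3)  # (3/2)(1 - 5/9)
        assert dist[0, 1] == 1

    def test_missing_strain_excluded_and_reported(self):
        vt = make_variant_table([[1, 0, -1], [0, 1, 0]])
        assignment, n_hap, h, _, excluded = haplotypes(vt, "g")
        assert excluded == ["s2"]
        assert len(assignment) == 2

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        rows = rng.integers(0, 2, size=(6, 8)).tolist()
        vt = make_variant_table(rows)
        _, n1, h1, d1, _ = haplotypes(vt, "g")
        perm = rng.permutation(8)
        vt2 = make_variant_table([list(np.array(r)[perm]) for r in rows])
        _, n2, h2, d2, _ = haplotypes(vt2, "g")
        assert n1 == n2 and h1 == pytest.approx(h2)
        assert sorted(d1.flatten()) == sorted(d2.flatten())

    def test_too_few_usable_strains_errors(self):
        vt = make_variant_table([[1, -1, -1]])
        with pytest.raises(ValueError, match="fewer than 2"):
            haplotypes(vt, "g")


class TestExcludeHyperdiverse:
    @staticmethod
    def _genes(spans):
        return pd.DataFrame(
            [(f"g{i}", "I", s, e) for i, (s, e) in enumerate(spans)],
            columns=["gene", "chrom", "start", "end"],
        )

    def test_adjacent_bed_interval_does_not_overlap(self):
        # gene [100,200] 1-based; BED [200,300) covers 1-based 201-300
        genes = self._genes([(100, 200)])
        mask = pd.DataFrame([("I", 200, 300, None)],
                            columns=["chrom", "start", "end", "strain"])
        kept, flags = exclude_hyperdiverse(genes, mask)
        assert not flags["g0"]
        # but BED [199,300) covers base 200 -> overlap
        mask2 = pd.DataFrame([("I", 199, 300, None)],
                             columns=["chrom", "start", "end", "strain"])
        _, flags2 = exclude_hyperdiverse(genes, mask2)
        assert flags2["g0"]

    def test_gene_inside_interval_flagged(self):
        genes = self._genes([(150, 160)])
        mask = pd.DataFrame([("I", 100, 200, "AB1")],
                            columns=["chrom", "start", "end", "strain"])
        kept, flags = exclude_hyperdiverse(genes, mask)
        assert flags["g0"] and kept.empty

    def test_empty_mask_identity(self):
        genes = self._genes([(1, 10), (20, 30)])
        mask = pd.DataFrame(columns=["chrom", "start", "end", "strain"])
        kept, flags = exclude_hyperdiverse(genes, mask)
        assert not flags.any() and len(kept) == 2

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        genes = self._genes(
            [(int(s), int(s + rng.integers(1, 50))) for s in rng.integers(1, 1000, 40)]
        )
        mask = pd.DataFrame(
            [("I", int(s), int(s + rng.integers(1, 60)), None)
             for s in rng.integers(0, 1000, 15)],
            columns=["chrom", "start", "end", "strain"],
        )
        _, flags = exclude_hyperdiverse(genes, mask)
        for _, g in genes.iterrows():
            brute = any(
                g["start"] <= m["end"] and g["end"] >= m["start"] + 1
                for _, m in mask.iterrows()
            )
            assert flags[g["gene"]] == brute

    def test_malformed_interval_errors(self):
        genes = self._genes([(1, 10)])
        mask = pd.DataFrame([("I", 50, 40, None)],
                            columns=["chrom", "start", "end", "strain"])
        with pytest.raises(ValueError, match="malformed"):
            exclude_hyperdiverse(genes, mask)


class TestGenesetCompare:
    def test_exact_enumeration_small_sets(self):
        vals = pd.Series({"f1": 1.0, "f2": 2.0, "b1": 3.0, "b2": 4.0, "b3": 5.0})
        res = geneset_compare(vals, ["f1", "f2"], ["b1", "b2", "b3"])
        # enumerate all C(5,2) assignments of the focal labels
        pooled = [1.0, 2.0, 3.0, 4.0, 5.0]
        obs_u = sum(x > y for x in [1, 2] for y in [3, 4, 5])  # = 0
        us = []
        for combo in itertools.combinations(range(5), 2):
            x = [pooled[i] for i in combo]
            y = [pooled[i] for i in range(5) if i not in combo]
            us.append(sum(a > b for a in x for b in y))
        mu = np.mean(us)
        p_exact = np.mean([abs(u - mu) >= abs(obs_u - mu) for u in us])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(p_exact)
        assert res["median_focal"] == 1.5 and res["median_background"] == 4.0

    def test_overlap_requires_flag(self):
        vals = pd.Series(np.arange(30, dtype=float),
                         index=[f"g{i}" for i in range(30)])
        focal = [f"g{i}" for i in range(5)]
        with pytest.raises(ValueError, match="overlap"):
            geneset_compare(vals, focal, list(vals.index))
        res = geneset_compare(vals, focal, list(vals.index),
                              background_includes_focal=True)
        assert res["n_background"] == 25

    def test_shift_alternative_monotone_p(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=200)
        ps = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            reps = []
            for r in range(10):
                y = rng.normal(size=200)
                x = rng.normal(shift, 1, 40)
                vals = pd.Series(
                    np.concatenate([x, y]),
                    index=[f"f{i}" for i in range(40)] + [f"b{i}" for i in range(200)],
                )
                reps.append(
                    geneset_compare(vals, [f"f{i}" for i in range(40)],
                                    [f"b{i}" for i in range(200)])["p"]
                )
            ps.append(np.median(reps))
        assert ps[0] > ps[2] > ps[3]
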