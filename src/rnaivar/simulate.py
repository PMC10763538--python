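"""Seeded synthetic data with the statistical structure each analysis stage
assumes, plus ground-truth labels for recovery tests.

The generators emulate the study designs the downstream modules were built
for: a 5-strain x 3-replicate bulk RNA-seq experiment over ~18.6k genes with
a small focal set of variance-inflated genes; a 403-isotype variant table
whose (gene, strain) cells realize named allele-fate scenarios by
construction; overdispersed replicate-plate lethality counts, including
strains whose response is on/off per worm; and per-embryo transcript counts
that decline with embryonic stage, with knockdown and bimodal-mixture
treatment regimes.

Every generator is a pure function of its config: each draws from its own
RNG stream seeded by (config.seed, stage tag), so adding one stage never
perturbs another stage's draws.  Counts are negative binomial with
variance mu + dispersion * mu^2; plate counts are beta-binomial
parameterized by (mean, intra-plate correlation rho), which degenerates
exactly to binomial at rho = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .expression import CountsMatrix
from .popgen import VariantTable

__all__ = [
    "SimConfig",
    "TranscriptRegime",
    "SCENARIOS",
    "gen_counts",
    "gen_variant_table",
    "gen_penetrance",
    "gen_transcript_counts",
]

SCENARIOS = (
    "conserved",
    "pseudogenized",
    "functional_diverged",
    "possibly_missing",
    "sub_threshold",
)

_STAGE_TAGS = {"counts": 1, "variants": 2, "penetrance": 3, "transcripts": 4}


class TranscriptRegime(NamedTuple):
    intercept: float  # expected count at stage 0
    slope_per_stage: float  # linear change in expected count per stage unit
    knockdown_factor: float  # multiplicative effect on knocked-down embryos
    mix_weight: float  # probability an embryo is in the knocked-down component


def _default_scenario_mix() -> dict[str, float]:
    return {
        "conserved": 0.55,
        "pseudogenized": 0.15,
        "functional_diverged": 0.15,
        "possibly_missing": 0.05,
        "sub_threshold": 0.10,
    }


def _default_plate_design() -> list[tuple[str, int, int]]:
    # genotype, n replicate plates, mean embryos per plate
    return [("parent", 8, 150), ("f1_plus", 8, 150), ("f1_del", 8, 150)]


def _default_true_props() -> dict[str, float]:
    return {"parent": 0.05, "f1_plus": 0.60, "f1_del": 0.05}


def _default_transcript_regimes() -> dict[tuple[str, str], TranscriptRegime]:
    # a sensitive strain (full knockdown), a resistant one (none), and an
    # on/off strain (mixture), all sharing the stage-declining control mean
    return {
        ("sensitive", "control"): TranscriptRegime(130.0, -3.0, 1.0, 0.0),
        ("sensitive", "rnai"): TranscriptRegime(130.0, -3.0, 0.08, 1.0),
        ("resistant", "control"): TranscriptRegime(130.0, -3.0, 1.0, 0.0),
        ("resistant", "rnai"): TranscriptRegime(130.0, -3.0, 1.0, 0.0),
        ("onoff", "control"): TranscriptRegime(130.0, -3.0, 1.0, 0.0),
        ("onoff", "rnai"): TranscriptRegime(130.0, -3.0, 0.08, 0.3),
    }


@dataclass
class SimConfig:
    """Parameters of every synthetic stage.

    Defaults mirror the emulated study designs: 18,589 genes passing the
    low-count filter over 5 strains x 3 replicates with 61 focal genes, and
    403 population isotypes for the variant table.
    """

    seed: int = 0
    # RNA-seq counts
    n_genes: int = 18_589
    n_strains: int = 5
    n_reps_per_strain: int = 3
    focal_set_size: int = 61
    baseline_log_mean_range: tuple[float, float] = (1.0, 12.0)
    strain_sd_background: float = 0.2  # SD of per-(gene,strain) log2-fold effects
    strain_sd_focal: float = 0.6
    nb_dispersion: float = 0.05
    # population variant table
    n_popgen_strains: int = 403
    n_popgen_genes: int = 62
    gene_length_range: tuple[int, int] = (500, 5000)
    scenario_mix: dict[str, float] = field(default_factory=_default_scenario_mix)
    # penetrance plates
    plate_design: list[tuple[str, int, int]] = field(default_factory=_default_plate_design)
    true_props: dict[str, float] = field(default_factory=_default_true_props)
    overdispersion_rho: float = 0.05
    onoff_mix: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    lifespan_ages: tuple[float, ...] = (12.0, 24.0, 36.0, 48.0, 60.0, 72.0)
    lifespan_logit: dict[str, tuple[float, float]] = field(default_factory=dict)
    lifespan_worm_sd: float = 0.3  # SD of per-worm intercepts on the logit scale
    # transcript counts
    transcript_regimes: dict[tuple[str, str], TranscriptRegime] = field(
        default_factory=_default_transcript_regimes
    )
    n_embryos_per_regime: int = 60
    transcript_stage_max: int = 4
    transcript_dispersion: float = 0.05

    def validate(self) -> None:
        for name in ("n_genes", "n_strains", "n_reps_per_strain", "focal_set_size",
                     "n_popgen_strains", "n_popgen_genes", "n_embryos_per_regime"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.focal_set_size > self.n_genes:
            raise ValueError("focal set larger than the genome")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if self.strain_sd_background < 0 or self.strain_sd_focal < 0:
            raise ValueError("strain effect SDs must be >= 0")
        mix_total = sum(self.scenario_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError("scenario_mix must sum to 1")
        unknown = set(self.scenario_mix) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        for p in self.true_props.values():
            if not 0 <= p <= 1:
                raise ValueError("true_props must lie in [0, 1]")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene_length_range")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE_TAGS[stage]])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _beta_binomial(
    rng: np.random.Generator, n: int, p: float, rho: float
) -> int:
    """Beta-binomial draw with mean n*p and intra-unit correlation rho."""
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return int(n)
    if rho == 0.0:
        return int(rng.binomial(n, p))
    s = (1.0 - rho) / rho
    q = rng.beta(p * s, (1.0 - p) * s)
    return int(rng.binomial(n, q))


def gen_counts(config: SimConfig) -> tuple[CountsMatrix, pd.DataFrame]:
    """Gene x sample NB count matrix with per-(gene, strain) expression shifts.

    Each gene has a baseline mean 2^U(range); its per-strain log2-fold
    effects are N(0, sd) with sd = strain_sd_focal for the focal genes and
    strain_sd_background otherwise.  Returns the counts and a truth table
    (gene, strain_sd, focal).
    """
    config.validate()
    if config.n_strains < 2:
        raise ValueError("invalid design: need at least 2 strains")
    rng = config.rng("counts")
    G, S, R = config.n_genes, config.n_strains, config.n_reps_per_strain

    genes = [f"g{i:05d}" for i in range(G)]
    strains = [f"strain{j + 1}" for j in range(S)]
    samples = [f"{s}_r{r + 1}" for s in strains for r in range(R)]
    strain_of = pd.Series(
        [s for s in strains for _ in range(R)], index=samples, name="strain"
    )

    lo, hi = config.baseline_log_mean_range
    base_log2 = rng.uniform(lo, hi, size=G)
    focal_idx = rng.choice(G, size=config.focal_set_size, replace=False)
    sd = np.full(G, config.strain_sd_background)
    sd[focal_idx] = config.strain_sd_focal

    effects = rng.normal(0.0, 1.0, size=(G, S)) * sd[:, None]
    mean_gs = 2.0 ** (base_log2[:, None] + effects)  # (G, S)
    mean_full = np.repeat(mean_gs, R, axis=1)  # (G, S*R), sample order matches
    counts = _nb_draw(rng, mean_full, config.nb_dispersion)

    cm = CountsMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), strain_of
    )
    truth = pd.DataFrame(
        {"strain_sd": sd, "focal": np.isin(np.arange(G), focal_idx)}, index=genes
    )
    return cm, truth


def gen_variant_table(config: SimConfig) -> tuple[VariantTable, pd.DataFrame]:
    """Population variant table whose (gene, strain) cells realize allele-fate
    scenarios by construction.

    Scenario meanings (fractions are of gene length L):
      conserved          - one shared LOW site; classifier -> reference_like
      sub_threshold      - 3 missense + ~0.4% LOW sites; -> reference_like
      pseudogenized      - 1 high-confidence HIGH lesion + ~1.4% diverged
                           missense backbone; -> pseudogenized
      functional_diverged- >= 6 missense, >= 1.2% diverged, no HIGH;
                           -> functional_diverged
      possibly_missing   - ~80% of sites uncalled; -> pseudogenized with the
                           possibly_missing flag
    Returns the table plus the truth labels per (gene, strain).
    """
    config.validate()
    rng = config.rng("variants")
    strains = [f"iso{j + 1:03d}" for j in range(config.n_popgen_strains)]
    n_strains = len(strains)
    scen_names = list(config.scenario_mix)
    scen_probs = np.array([config.scenario_mix[s] for s in scen_names])

    rec_rows: list[tuple] = []
    geno_cols: list[np.ndarray] = []
    truth_rows: list[tuple] = []
    gene_models: list[tuple] = []

    cursor = 1000  # 1-based chromosome coordinate cursor, with inter-gene gaps
    lo, hi = config.gene_length_range
    for gi in range(config.n_popgen_genes):
        gene = f"rg{gi:03d}"
        L = int(rng.integers(lo, hi + 1))
        start = cursor
        end = start + L - 1
        cursor = end + 1 + int(rng.integers(200, 1000))
        gene_models.append((gene, "I", start, end))

        scen = rng.choice(len(scen_names), size=n_strains, p=scen_probs)
        scenario = np.array(scen_names, dtype=object)[scen]
        for s_name, sc in zip(strains, scenario):
            truth_rows.append((gene, s_name, sc))

        positions = rng.permutation(np.arange(start, end + 1))
        pos_cursor = 0

        def take(k: int) -> np.ndarray:
            nonlocal pos_cursor
            k = min(k, len(positions) - pos_cursor)
            out = positions[pos_cursor : pos_cursor + k]
            pos_cursor += k
            return out

        gene_recs: list[tuple] = []
        gene_genos: list[np.ndarray] = []

        def add_record(pos: int, impact: str, subtype: str, high_conf: bool,
                       carriers: np.ndarray, missing: np.ndarray | None = None):
            gene_recs.append((gene, "I", int(pos), "A", "T", impact, subtype, high_conf))
            g = np.zeros(n_strains, dtype=np.int8)
            g[carriers] = 1
            if missing is not None:
                g[missing & (g == 0)] = -1
            gene_genos.append(g)

        is_pseudo = scenario == "pseudogenized"
        is_fd = scenario == "functional_diverged"
        is_sub = scenario == "sub_threshold"
        is_cons = scenario == "conserved"
        is_pm = scenario == "possibly_missing"

        # shared missense backbone; diverged carriers drawn per strain from it
        n_backbone = max(int(np.ceil(0.015 * L)), 8)
        backbone_pos = take(n_backbone)
        n_backbone = len(backbone_pos)
        backbone_carriers = np.zeros((n_backbone, n_strains), dtype=bool)

        need_fd = max(int(np.ceil(0.012 * L)), 6)
        need_pseudo = max(int(np.ceil(0.014 * L)), 5)
        for j in np.flatnonzero(is_fd):
            pick = rng.choice(n_backbone, size=min(need_fd, n_backbone), replace=False)
            backbone_carriers[pick, j] = True
        for j in np.flatnonzero(is_pseudo):
            pick = rng.choice(n_backbone, size=min(need_pseudo, n_backbone), replace=False)
            backbone_carriers[pick, j] = True
        for j in np.flatnonzero(is_sub):
            pick = rng.choice(n_backbone, size=3, replace=False)
            backbone_carriers[pick, j] = True
        for k in range(n_backbone):
            if backbone_carriers[k].any():
                add_record(backbone_pos[k], "MODERATE", "missense_variant", True,
                           np.flatnonzero(backbone_carriers[k]))

        # one shared high-confidence HIGH lesion carried by pseudogenized strains
        if is_pseudo.any():
            add_record(take(1)[0], "HIGH", "frameshift_variant", True,
                       np.flatnonzero(is_pseudo))

        # low-impact shared sites: one for conserved, a sub-1% block for
        # sub_threshold strains
        if is_cons.any() or is_sub.any():
            add_record(take(1)[0], "LOW", "synonymous_variant", True,
                       np.flatnonzero(is_cons | is_sub))
        n_low = max(int(0.004 * L) - 1, 0)
        if is_sub.any() and n_low > 0:
            sub_idx = np.flatnonzero(is_sub)
            for pos in take(n_low):
                add_record(pos, "LOW", "synonymous_variant", True, sub_idx)

        # shared uncalled block covering ~80% of the gene
        if is_pm.any():
            n_miss = int(np.ceil(0.80 * L))
            miss_pos = positions[-n_miss:] if pos_cursor <= L - n_miss else take(n_miss)
            for pos in miss_pos:
                gene_recs.append((gene, "I", int(pos), "A", "T", "LOW",
                                  "synonymous_variant", False))
                g = np.zeros(n_strains, dtype=np.int8)
                g[is_pm] = -1
                gene_genos.append(g)

        rec_rows.extend(gene_recs)
        geno_cols.extend(gene_genos)

    records = pd.DataFrame(
        rec_rows,
        columns=["gene", "chrom", "pos", "ref", "alt", "impact", "subtype", "high_conf"],
    )
    genotypes = np.vstack(geno_cols) if geno_cols else np.zeros((0, n_strains), np.int8)
    vt = VariantTable(records=records, genotypes=genotypes, strains=strains)
    vt.gene_models = pd.DataFrame(  # type: ignore[attr-defined]
        gene_models, columns=["gene", "chrom", "start", "end"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene", "strain", "scenario"])
    return vt, truth


def gen_penetrance(config: SimConfig, lifespan: bool = False) -> pd.DataFrame:
    """Replicate-plate lethality counts.

    Plate mode: per-plate dead counts are beta-binomial with mean
    true_props[genotype] and intra-plate correlation overdispersion_rho;
    genotypes listed in ``onoff_mix`` instead place one worm per plate whose
    lethality is prop_on with probability p_on, else prop_off.  Lifespan
    mode emits per-worm, per-age-interval counts with a logistic-in-age mean
    and a per-worm intercept effect.
    """
    config.validate()
    if not config.plate_design:
        raise ValueError("plate_design is empty")
    rng = config.rng("penetrance")
    rows = []
    if lifespan:
        for genotype, n_worms, emb_mean in config.plate_design:
            a, b = config.lifespan_logit.get(genotype, (-2.0, 0.03))
            for w in range(n_worms):
                worm = f"{genotype}_w{w + 1}"
                worm_eff = rng.normal(0.0, config.lifespan_worm_sd)
                for age in config.lifespan_ages:
                    n = max(int(rng.poisson(emb_mean)), 1)
                    p = 1.0 / (1.0 + np.exp(-(a + b * age + worm_eff)))
                    dead = int(rng.binomial(n, p))
                    rows.append(
                        (f"{worm}_t{age:g}", genotype, dead, n - dead, worm, age)
                    )
    else:
        for genotype, n_plates, emb_mean in config.plate_design:
            onoff = config.onoff_mix.get(genotype)
            for i in range(n_plates):
                n = max(int(rng.poisson(emb_mean)), 1)
                if onoff is not None:
                    p_on, prop_on, prop_off = onoff
                    p = prop_on if rng.random() < p_on else prop_off
                    worm = f"{genotype}_w{i + 1}"
                else:
                    p = config.true_props.get(genotype, 0.5)
                    worm = None
                dead = _beta_binomial(rng, n, p, config.overdispersion_rho)
                rows.append((f"{genotype}_p{i + 1}", genotype, dead, n - dead, worm, np.nan))
    return pd.DataFrame(
        rows, columns=["plate", "genotype", "dead", "hatched", "worm", "age_h"]
    )


def gen_transcript_counts(config: SimConfig) -> pd.DataFrame:
    """Per-embryo transcript counts for each (strain, treatment) regime.

    Control counts are NB with mean intercept + slope * stage; treated
    embryos fall in the knocked-down component (mean scaled by
    knockdown_factor) with probability mix_weight.  Negative requested means
    are clipped at a floor of 1 with a warning.  The ``knocked`` column
    records the mixture-component truth.
    """
    config.validate()
    if not config.transcript_regimes:
        raise ValueError("no transcript regimes defined")
    rng = config.rng("transcripts")
    rows = []
    clipped = False
    for (strain, treatment), reg in config.transcript_regimes.items():
        n = config.n_embryos_per_regime
        stages = rng.integers(1, config.transcript_stage_max + 1, size=n)
        mean = reg.intercept + reg.slope_per_stage * stages.astype(float)
        if (mean < 1).any():
            clipped = True
            mean = np.maximum(mean, 1.0)
        if treatment == "control":
            knocked = np.zeros(n, dtype=bool)
        else:
            knocked = rng.random(n) < reg.mix_weight
            mean = np.where(knocked, np.maximum(mean * reg.knockdown_factor, 1.0), mean)
        cnt = _nb_draw(rng, mean, config.transcript_dispersion)
        for i in range(n):
            rows.append(
                (f"{strain}_{treatment}_e{i + 1}", strain, treatment,
                 int(stages[i]), int(cnt[i]), bool(knocked[i]))
            )
    if clipped:
        warnings.warn("negative requested transcript mean clipped at floor 1")
    return pd.DataFrame(
        rows, columns=["embryo", "strain", "treatment", "stage", "count", "knocked"]
    )
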