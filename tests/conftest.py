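import numpy as np
import pandas as pd
import pytest

from rnaivar.expression import CountsMatrix
from rnaivar.popgen import VariantTable


@pytest.fixture
def small_counts() -> CountsMatrix:
    """2 strains x 2 replicates, 4 genes, hand-sized counts."""
    counts = pd.DataFrame(
        {
            "a_r1": [10, 100, 0, 5],
            "a_r2": [12, 110, 0, 5],
            "b_r1": [50, 90, 1, 5],
            "b_r2": [55, 95, 0, 6],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    strains = pd.Series(
        {"a_r1": "A", "a_r2": "A", "b_r1": "B", "b_r2": "B"}
    )
    return CountsMatrix(counts, strains)


def make_variant_table(
    genotype_rows: list[list[int]],
    positions: list[int] | None = None,
    impacts: list[str] | None = None,
    subtypes: list[str] | None = None,
    high_conf: list[bool] | None = None,
    gene: str = "g",
    strains: list[str] | None = None,
) -> VariantTable:
    """Build a one-gene VariantTable from explicit genotype rows.

    ``genotype_rows[r][s]`` is the code for record r, strain s
    (-1 missing, 0 ref, 1 alt).
    """
    n_rec = len(genotype_rows)
    n_strains = len(genotype_rows[0]) if n_rec else 0
    if strains is None:
        strains = [f"s{j}" for j in range(n_strains)]
    if positions is None:
        positions = list(range(1, n_rec + 1))
    if impacts is None:
        impacts = ["MODERATE"] * n_rec
    if subtypes is None:
        subtypes = ["missense_variant"] * n_rec
    if high_conf is None:
        high_conf = [True] * n_rec
    records = pd.DataFrame(
        {
            "gene": [gene] * n_rec,
            "chrom": ["I"] * n_rec,
            "pos": positions,
            "ref": ["A"] * n_rec,
            "alt": ["T"] * n_rec,
            "impact": impacts,
            "subtype": subtypes,
            "high_conf": high_conf,
        }
    )
    return VariantTable(
        records=records,
        genotypes=np.array(genotype_rows, dtype=np.int8).reshape(n_rec, n_strains),
        strains=strains,
    )


def brute_force_pi(vt: VariantTable, gene: str, gene_length: int) -> float:
    """Mean pairwise difference oracle for nucleotide diversity.

    Per site, averages the unequal-allele indicator over all pairs of
    called strains (equivalent to the n/(n-1)-corrected frequency form),
    then divides the sum over sites by gene length.
    """
    rows = np.flatnonzero((vt.records["gene"] == gene).to_numpy())
    g = vt.genotypes[rows]
    pos = vt.records["pos"].to_numpy()[rows]
    total = 0.0
    for p in np.unique(pos):
        sub = g[pos == p]
        n_strains = sub.shape[1]
        alleles = []
        for s in range(n_strains):
            col = sub[:, s]
            if (col == -1).any():
                alleles.append(None)
            else:
                carried = np.flatnonzero(col == 1)
                # convention: with conflicting multi-alt carriage, the last
                # record wins (mirrors the implementation's assignment order)
                alleles.append(-1 if carried.size == 0 else int(carried[-1]))
        called = [a for a in alleles if a is not None]
        if len(called) < 2:
            continue
        diff = n_pairs = 0
        for i in range(len(called)):
            for j in range(i + 1, len(called)):
                n_pairs += 1
                diff += called[i] != called[j]
        total += diff / n_pairs
    return total / gene_length


def random_variant_table(rng: np.random.Generator) -> tuple[VariantTable, int]:
    """Random small table (<= 8 strains, <= 50 sites), duplicate positions
    allowed so multiallelic sites occur."""
    n_strains = int(rng.integers(2, 9))
    n_rec = int(rng.integers(1, 51))
    L = int(rng.integers(n_rec, 200))
    positions = rng.integers(1, L + 1, size=n_rec).tolist()
    rows = rng.choice([-1, 0, 1], size=(n_rec, n_strains), p=[0.15, 0.55, 0.30])
    vt = make_variant_table([list(r) for r in rows], positions=positions)
    return vt, L
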