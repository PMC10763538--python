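"""Readers and writers for the pipeline's external formats, plus coordinate
conversions.

Formats: counts TSV (genes x samples), sample sheet TSV, plate TSV, embryo
TSV, gene model TSV, plain-text gene lists, BED masks (0-based half-open),
VCF (1-based, SnpEff-style ANN annotations, read through cyvcf2) and a
simplified variant TSV dialect with columns

    gene  chrom  pos  ref  alt  impact  subtype  filter  <strain columns...>

where strain genotypes are 0 (reference), 1 (carries the alt) or ``.``
(missing).  All internal gene spans are 1-based inclusive; conversions to
and from BED coordinates are centralized here.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountsMatrix
from .popgen import IMPACT_CLASSES, VariantTable

__all__ = [
    "read_counts",
    "read_samples",
    "read_counts_matrix",
    "write_counts_matrix",
    "read_gene_list",
    "read_gene_models",
    "read_bed_mask",
    "read_plates",
    "read_embryos",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_vcf",
    "write_vcf",
    "bed_to_onebased",
    "onebased_to_bed",
    "write_manifest",
]


def bed_to_onebased(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open [start, end) interval to 1-based inclusive."""
    return start + 1, end


def onebased_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open [start, end)."""
    return start - 1, end


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            try:
                fractional = np.mod(vals.astype(float), 1) != 0
            except (TypeError, ValueError):
                fractional = np.ones(len(vals), dtype=bool)
            if fractional.any():
                gene = df.index[np.flatnonzero(fractional)[0]]
                raise ValueError(
                    f"non-integer count at gene {gene!r}, sample {col!r}"
                )
    return df.astype(np.int64)


def read_samples(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "strain"} <= set(df.columns):
        raise ValueError("sample sheet needs columns: sample, strain")
    return df.set_index("sample")["strain"]


def read_counts_matrix(counts_path: str | Path, samples_path: str | Path) -> CountsMatrix:
    counts = read_counts(counts_path)
    strains = read_samples(samples_path)
    extra = [s for s in counts.columns if s not in strains.index]
    if extra:
        raise ValueError(f"samples in matrix but not in sheet: {extra}")
    return CountsMatrix(counts, strains)


def write_counts_matrix(cm: CountsMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.strains.rename_axis("sample").rename("strain").reset_index().to_csv(
        samples_path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene model TSV: gene, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "chrom", "start", "end"}
    if need - set(df.columns):
        raise ValueError(f"gene models need columns {sorted(need)}")
    if (df["end"] < df["start"]).any():
        raise ValueError("gene model with end < start")
    return df


def read_bed_mask(path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based half-open); a 4th column, if present, is kept
    as the strain label."""
    rows = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED interval at line {lineno}: {ln!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed BED interval at line {lineno}: {ln!r}") from exc
        if end <= start:
            raise ValueError(f"malformed BED interval at line {lineno}: end <= start")
        rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else None))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strain"])


def read_plates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"plate", "genotype", "dead", "hatched"}
    if need - set(df.columns):
        raise ValueError(f"plate records need columns {sorted(need)}")
    return df


def read_embryos(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"embryo", "strain", "treatment", "stage", "count"}
    if need - set(df.columns):
        raise ValueError(f"embryo records need columns {sorted(need)}")
    return df


# ---------------------------------------------------------------- variants


def read_variants_tsv(path: str | Path) -> VariantTable:
    """Simplified variant TSV: fixed leading columns then one genotype
    column per strain (0 / 1 / .)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["gene", "chrom", "pos", "ref", "alt", "impact", "subtype", "filter"]
    if df.columns[: len(fixed)].tolist() != fixed:
        raise ValueError(f"variant TSV must start with columns {fixed}")
    strains = df.columns[len(fixed) :].tolist()
    if not strains:
        raise ValueError("variant TSV has no strain columns")
    geno = np.empty((len(df), len(strains)), dtype=np.int8)
    for j, s in enumerate(strains):
        col = df[s].to_numpy()
        vals = np.where(col == ".", -1, col)
        geno[:, j] = vals.astype(np.int8)
    records = df[fixed[:7]].copy()
    records["pos"] = records["pos"].astype(int)
    records["high_conf"] = df["filter"].eq("PASS").to_numpy()
    return VariantTable(records=records, genotypes=geno, strains=strains)


def write_variants_tsv(vt: VariantTable, path: str | Path) -> None:
    out = vt.records[["gene", "chrom", "pos", "ref", "alt", "impact", "subtype"]].copy()
    out["filter"] = np.where(vt.records["high_conf"], "PASS", "lowq")
    for j, s in enumerate(vt.strains):
        col = vt.genotypes[:, j].astype(object)
        out[s] = np.where(col == -1, ".", col)
    out.to_csv(path, sep="\t", index=False)


def write_vcf(vt: VariantTable, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Emit the variant table as an uncompressed VCF with SnpEff-style ANN
    INFO fields and diploid homozygous genotypes."""
    recs = vt.records
    if contig_lengths is None:
        contig_lengths = {
            str(c): int(recs.loc[recs["chrom"] == c, "pos"].max()) + 1000
            for c in recs["chrom"].unique()
        }
    lines = ["##fileformat=VCFv4.2"]
    for c, ln in contig_lengths.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "Allele|Annotation|Annotation_Impact|Gene_Name\">"
    )
    lines.append('##FILTER=<ID=lowq,Description="Low-confidence call">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vt.strains))
    order = np.lexsort((recs["pos"].to_numpy(), recs["chrom"].to_numpy()))
    for i in order:
        r = recs.iloc[i]
        ann = f"{r['alt']}|{r['subtype']}|{r['impact']}|{r['gene']}"
        filt = "PASS" if r["high_conf"] else "lowq"
        gts = []
        for g in vt.genotypes[i]:
            gts.append("./." if g == -1 else ("1/1" if g == 1 else "0/0"))
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t{filt}\tANN={ann}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, gene_models: pd.DataFrame | None = None) -> VariantTable:
    """Read a VCF into a VariantTable.

    Multiallelic records are split into one row per alt.  The confidence
    flag is FILTER == PASS.  Heterozygous calls are demoted to missing with
    a warning (strains are selfing isotypes, expected homozygous).  If gene
    models are given, records are assigned to genes by span overlap; records
    outside every gene keep gene = "" and are counted in ``vt.n_unassigned``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    strains = list(vcf.samples)
    rec_rows, geno_rows = [], []
    n_het = 0
    for v in vcf:
        ann_by_alt: dict[str, tuple[str, str]] = {}
        ann = v.INFO.get("ANN")
        if ann:
            for entry in str(ann).split(","):
                parts = entry.split("|")
                if len(parts) >= 3:
                    ann_by_alt.setdefault(parts[0], (parts[2], parts[1]))
        gts = v.genotypes  # [a1, a2, phased] per sample
        for alt_i, alt in enumerate(v.ALT, start=1):
            impact, subtype = ann_by_alt.get(alt, (None, None))
            if impact is None:
                warnings.warn(f"missing ANN for {v.CHROM}:{v.POS} {alt}; impact=MODIFIER")
                impact, subtype = "MODIFIER", "unknown"
            g = np.zeros(len(strains), dtype=np.int8)
            for j, gt in enumerate(gts):
                a = [x for x in gt[:-1] if x is not None]
                if not a or min(a) < 0:
                    g[j] = -1
                elif len(set(a)) > 1:
                    n_het += 1
                    g[j] = -1
                else:
                    g[j] = 1 if a[0] == alt_i else 0
            rec_rows.append(
                ("", v.CHROM, v.POS, v.REF, alt, impact, subtype,
                 v.FILTER is None or v.FILTER == "PASS")
            )
            geno_rows.append(g)
    if n_het:
        warnings.warn(f"{n_het} heterozygous calls treated as missing")
    records = pd.DataFrame(
        rec_rows,
        columns=["gene", "chrom", "pos", "ref", "alt", "impact", "subtype", "high_conf"],
    )
    n_unassigned = 0
    if gene_models is not None and len(records):
        gene_col = np.full(len(records), "", dtype=object)
        for _, gm in gene_models.iterrows():
            hit = (
                (records["chrom"] == gm["chrom"])
                & (records["pos"] >= gm["start"])
                & (records["pos"] <= gm["end"])
            ).to_numpy()
            gene_col[hit] = gm["gene"]
        records["gene"] = gene_col
        n_unassigned = int((gene_col == "").sum())
    geno = np.vstack(geno_rows) if geno_rows else np.zeros((0, len(strains)), np.int8)
    vt = VariantTable(records=records, genotypes=geno, strains=strains)
    vt.n_unassigned = n_unassigned  # type: ignore[attr-defined]
    return vt


# ---------------------------------------------------------------- manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    params: dict,
    inputs: dict[str, str | Path] | None = None,
) -> None:
    """Run manifest: stage, parameters (seeds included), input hashes and
    library versions, as JSON."""
    import rnaivar

    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
        "versions": {
            "rnaivar": rnaivar.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
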