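"""Readers and writers for the pipeline's tabular formats.

The dosage VCF dialect consumed here is the one produced by polyploid dosage
callers: one biallelic record per site, a ``GT`` FORMAT field whose number of
slash-separated allele indices equals the estimated ploidy of that call
(e.g. ``0/0/0/0/0/1`` for a hexaploid simplex site), and a per-sample ``DP``
field carrying the genomic (GBS) read depth supporting the call.  The
reference dosage ``alpha`` is the number of ``0`` alleles, the alternative
dosage ``beta`` the number of ``1`` alleles.  A call containing ``.`` is
missing (recorded with ploidy 0 and dosages 0).  When ``GT`` is absent for a
sample, a two-integer ``AD``-style field is accepted as ``alpha,beta``.
Records with more than one ALT allele are refused: the model is defined on
exactly two alleles.

Allele counts follow the ASEReadCounter-style schema with columns ``contig,
position, refAllele, altAllele, sample, replicate, refCount, totalCount``.
All paths accept gzip transparently.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

__all__ = [
    "CALL_COLUMNS",
    "COUNT_COLUMNS",
    "read_dosage_vcf",
    "write_dosage_vcf",
    "read_allele_counts",
    "write_allele_counts",
    "read_gene_maps",
    "read_units",
    "write_units",
    "write_results",
]

#: long-format per-call variant table: one row per site x genotype
CALL_COLUMNS = [
    "transcript",
    "position",
    "ref_allele",
    "alt_allele",
    "is_indel",
    "genotype",
    "alpha",
    "beta",
    "ploidy",
    "missing",
    "gbs_depth",
]

COUNT_COLUMNS = ["transcript", "position", "genotype", "replicate", "ref_count", "total_count"]

_COUNT_FILE_COLUMNS = {
    "contig": "transcript",
    "position": "position",
    "sample": "genotype",
    "replicate": "replicate",
    "refCount": "ref_count",
    "totalCount": "total_count",
}


def _is_indel(ref: str, alt: str) -> bool:
    return len(ref) != 1 or len(alt) != 1


def read_dosage_vcf(path: str | Path) -> pd.DataFrame:
    """Parse a polyploid dosage VCF into a long per-call table.

    Returns a DataFrame with :data:`CALL_COLUMNS`; ``gbs_depth`` comes from
    the per-sample ``DP`` field (0 if absent).  Raises on multi-allelic
    records and on GT allele indices above 1, naming the offending site.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            site = f"{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(
                    f"unsupported multi-allelic record at {site}: ALT={','.join(alts) or '.'}"
                )
            ref, alt = rec.ref, alts[0]
            indel = _is_indel(ref, alt)
            for sample in samples:
                call = rec.samples[sample]
                depth = call.get("DP")
                depth = 0 if depth is None else int(depth)
                gt = call.get("GT")
                if gt is not None and any(a is not None for a in gt):
                    # pysam maps allele indices beyond the ALT list to None
                    if any(a is None for a in gt):
                        raise ValueError(
                            f"malformed GT for {sample} at {site}: allele index beyond "
                            f"the single ALT, or partial call"
                        )
                    if any(a not in (0, 1) for a in gt):
                        raise ValueError(
                            f"unsupported multi-allelic GT for {sample} at {site}: "
                            f"allele index > 1"
                        )
                    alpha = sum(1 for a in gt if a == 0)
                    beta = len(gt) - alpha
                    missing = False
                elif gt is None and call.get("AD") is not None:
                    ad = call.get("AD")
                    if len(ad) != 2 or any(v is None for v in ad):
                        raise ValueError(f"malformed AD dosage for {sample} at {site}: {ad}")
                    alpha, beta = int(ad[0]), int(ad[1])
                    missing = False
                else:
                    alpha = beta = 0
                    missing = True
                rows.append(
                    (
                        rec.chrom,
                        rec.pos,
                        ref,
                        alt,
                        indel,
                        sample,
                        alpha,
                        beta,
                        alpha + beta,
                        missing,
                        depth,
                    )
                )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df


def write_dosage_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a per-call table back to the dosage VCF dialect.

    Missing calls are emitted as ``./.``; heterozygous and homozygous calls
    as a GT of length equal to the call's ploidy.  Output is deterministic
    (sites sorted by transcript then position; samples sorted by name).
    """
    path = Path(path)
    samples = sorted(calls["genotype"].unique())
    sites = (
        calls[["transcript", "position", "ref_allele", "alt_allele"]]
        .drop_duplicates()
        .sort_values(["transcript", "position"], kind="mergesort")
    )
    by_call = calls.set_index(["transcript", "position", "genotype"]).sort_index()
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Dosage genotype; length = ploidy">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Genomic (GBS) read depth">',
    ]
    for contig in sites["transcript"].unique():
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for site in sites.itertuples(index=False):
        fields = [
            site.transcript,
            str(site.position),
            ".",
            site.ref_allele,
            site.alt_allele,
            ".",
            "PASS",
            ".",
            "GT:DP",
        ]
        for sample in samples:
            try:
                call = by_call.loc[(site.transcript, site.position, sample)]
            except KeyError:
                fields.append("./.:.")
                continue
            depth = int(call["gbs_depth"])
            if bool(call["missing"]):
                fields.append(f"./.:{depth}")
            else:
                gt = "/".join(["0"] * int(call["alpha"]) + ["1"] * int(call["beta"]))
                fields.append(f"{gt}:{depth}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read an ASEReadCounter-style per-replicate allele count table.

    Validates the schema, rejects rows with ``refCount > totalCount`` and
    duplicate (site, genotype, replicate) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str, "sample": str, "contig": str})
    missing_cols = [c for c in _COUNT_FILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"allele count table {path} missing columns: {missing_cols}")
    df = df.rename(columns=_COUNT_FILE_COLUMNS)[list(_COUNT_FILE_COLUMNS.values())]
    bad = df[df["ref_count"] > df["total_count"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"refCount > totalCount at {row['transcript']}:{row['position']} "
            f"sample {row['genotype']} replicate {row['replicate']}"
        )
    key = ["transcript", "position", "genotype", "replicate"]
    dup = df.duplicated(key)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate count record for {row['transcript']}:{row['position']} "
            f"sample {row['genotype']} replicate {row['replicate']}"
        )
    return df.reset_index(drop=True)


def write_allele_counts(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.rename(columns={v: k for k, v in _COUNT_FILE_COLUMNS.items()})
    cols = ["contig", "position", "refAllele", "altAllele", "sample", "replicate", "refCount", "totalCount"]
    for c in ("refAllele", "altAllele"):
        if c not in out.columns:
            out[c] = "."
    out[cols].to_csv(path, sep="\t", index=False)


def read_gene_maps(
    path_genes: str | Path, path_go: str | Path
) -> tuple[dict[str, str], pd.DataFrame]:
    """Read transcript->gene and gene->GO mapping tables.

    Returns the transcript->gene mapping as a dict (duplicate rows mapping a
    transcript to the same gene are deduplicated; conflicting genes raise)
    and the gene->GO multi-mapping as a two-column DataFrame.
    """
    genes = pd.read_csv(path_genes, sep="\t", dtype=str).drop_duplicates()
    if not {"transcript_id", "gene_id"} <= set(genes.columns):
        raise ValueError(f"gene map {path_genes} must have columns transcript_id, gene_id")
    conflicts = genes.groupby("transcript_id")["gene_id"].nunique()
    conflicts = conflicts[conflicts > 1]
    if not conflicts.empty:
        raise ValueError(
            f"transcripts mapped to conflicting genes: {list(conflicts.index[:5])}"
        )
    go = pd.read_csv(path_go, sep="\t", dtype=str).drop_duplicates()
    if not {"gene_id", "go_term"} <= set(go.columns):
        raise ValueError(f"GO map {path_go} must have columns gene_id, go_term")
    return dict(zip(genes["transcript_id"], genes["gene_id"])), go.reset_index(drop=True)


_UNIT_LIST_COLUMNS = ("y_r", "n_r")


def write_units(units: pd.DataFrame, path: str | Path) -> None:
    """Serialize a testable-unit table; per-replicate counts comma-joined."""
    out = units.copy()
    for col in _UNIT_LIST_COLUMNS:
        out[col] = out[col].map(lambda xs: ",".join(str(int(x)) for x in xs))
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_units(path: str | Path) -> pd.DataFrame:
    units = pd.read_csv(path, sep="\t", dtype={"genotype": str, "transcript": str})
    for col in _UNIT_LIST_COLUMNS:
        units[col] = units[col].map(lambda s: tuple(int(v) for v in str(s).split(",")))
    return units


def write_results(
    results: pd.DataFrame,
    gene_summaries: pd.DataFrame,
    tallies: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write per-SNP results, per-gene summaries and per-genotype tallies.

    Floats (HDI bounds in particular) are written with 8 significant digits;
    column order is stable so write -> read -> write is idempotent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp_results": out_dir / "snp_results.tsv",
        "gene_summaries": out_dir / "gene_summaries.tsv",
        "tallies": out_dir / "tallies.tsv",
    }
    results.to_csv(paths["snp_results"], sep="\t", index=False, float_format="%.8g")
    gene_summaries.to_csv(paths["gene_summaries"], sep="\t", index=False, float_format="%.8g")
    tallies.to_csv(paths["tallies"], sep="\t", index=False, float_format="%.8g")
    return paths
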