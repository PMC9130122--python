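"""Site and unit filtering: from raw dosage calls to testable SNP x genotype units.

The cascade mirrors the post-genotyping filters of the study design:

1. drop sites where every genotype is homozygous or missing;
2. drop indel sites;
3. mask calls whose estimated ploidy falls outside the accepted window
   (default 6..14) and drop sites left without any heterozygous call;
4. keep, per SNP x genotype, only heterozygous calls supported by at least
   ``min_gbs_depth`` genomic reads (default 10) whose pooled RNA-Seq total
   across replicates reaches ``min_rna_reads`` (default 10).

The four predicates are independent, so the final retained set does not
depend on application order.  The 10-read RNA threshold applies to the pooled
replicate total: pooling matches the sufficient statistic of the conjugate
posterior.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "filter_variants",
    "build_testable_units",
    "validate_units",
    "relative_expression",
    "UNIT_COLUMNS",
]

logger = logging.getLogger(__name__)

UNIT_COLUMNS = [
    "transcript",
    "position",
    "genotype",
    "alpha",
    "beta",
    "ploidy",
    "gbs_depth",
    "P",
    "y_r",
    "n_r",
    "pooled_y",
    "pooled_n",
]

_SITE_KEY = ["transcript", "position"]


def _is_het(calls: pd.DataFrame) -> pd.Series:
    return (~calls["missing"]) & (calls["alpha"] >= 1) & (calls["beta"] >= 1)


def filter_variants(
    calls: pd.DataFrame,
    ploidy_window: tuple[int, int] = (6, 14),
    return_stats: bool = False,
):
    """Apply the site-level filter cascade to a long per-call table.

    A genotype call with ploidy outside the window is masked as missing
    (other genotypes at the site stay testable); the site is dropped only if
    no heterozygous call remains.  Per-step removal counts are logged and,
    with ``return_stats=True``, returned alongside the table.
    """
    lo, hi = ploidy_window
    if lo > hi:
        raise ValueError(f"invalid ploidy window: lo={lo} > hi={hi}")
    stats: dict[str, int] = {}
    df = calls.copy()
    n_sites = df.groupby(_SITE_KEY, sort=False).ngroups

    het_per_site = _is_het(df).groupby([df[k] for k in _SITE_KEY]).any()
    keep_sites = het_per_site[het_per_site].index
    df = df.set_index(_SITE_KEY).loc[lambda d: d.index.isin(keep_sites)].reset_index()
    stats["all_homozygous_or_missing"] = n_sites - len(keep_sites)

    n_before = df.groupby(_SITE_KEY, sort=False).ngroups
    df = df[~df["is_indel"]]
    stats["indel"] = n_before - df.groupby(_SITE_KEY, sort=False).ngroups

    out_of_window = (~df["missing"]) & ((df["ploidy"] < lo) | (df["ploidy"] > hi))
    stats["calls_masked_ploidy_window"] = int(out_of_window.sum())
    df = df.copy()
    df.loc[out_of_window, ["alpha", "beta", "ploidy"]] = 0
    df.loc[out_of_window, "missing"] = True

    n_before = df.groupby(_SITE_KEY, sort=False).ngroups
    het_per_site = _is_het(df).groupby([df[k] for k in _SITE_KEY]).any()
    keep_sites = het_per_site[het_per_site].index
    df = df.set_index(_SITE_KEY).loc[lambda d: d.index.isin(keep_sites)].reset_index()
    stats["no_heterozygous_call_left"] = n_before - len(keep_sites)

    df = df.sort_values(_SITE_KEY + ["genotype"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "filter_variants: %d sites in; removed %d all-homozygous/missing, %d indel, "
        "%d without heterozygous call after ploidy masking (%d calls masked); %d sites out",
        n_sites,
        stats["all_homozygous_or_missing"],
        stats["indel"],
        stats["no_heterozygous_call_left"],
        stats["calls_masked_ploidy_window"],
        df.groupby(_SITE_KEY, sort=False).ngroups,
    )
    return (df, stats) if return_stats else df


def build_testable_units(
    calls: pd.DataFrame,
    counts: pd.DataFrame,
    min_gbs_depth: int = 10,
    min_rna_reads: int = 10,
) -> pd.DataFrame:
    """Join filtered calls with replicate counts into testable units.

    One unit per SNP x genotype with a heterozygous call, GBS depth >=
    ``min_gbs_depth`` and pooled RNA total >= ``min_rna_reads``.  Replicate
    counts are carried through unmerged (tuples ordered by replicate id);
    ``P`` is the genomic ratio ``alpha / ploidy``.  Count records for sites
    absent from the genotype table are skipped with a warning.
    """
    key = ["transcript", "position", "genotype"]
    het = calls[_is_het(calls) & (calls["gbs_depth"] >= min_gbs_depth)]

    known = counts.merge(het[key], on=key, how="inner")
    n_orphans = len(
        counts.merge(
            calls[key].drop_duplicates(), on=key, how="left", indicator=True
        ).query("_merge == 'left_only'")
    )
    if n_orphans:
        warnings.warn(
            f"{n_orphans} count records have no genotype call and were skipped",
            stacklevel=2,
        )
    pooled = (
        known.sort_values(key + ["replicate"], kind="mergesort")
        .groupby(key, sort=True)
        .agg(
            y_r=("ref_count", lambda s: tuple(int(v) for v in s)),
            n_r=("total_count", lambda s: tuple(int(v) for v in s)),
            pooled_y=("ref_count", "sum"),
            pooled_n=("total_count", "sum"),
        )
        .reset_index()
    )
    units = het.merge(pooled, on=key, how="inner")
    units = units[units["pooled_n"] >= min_rna_reads].copy()
    units["P"] = units["alpha"] / units["ploidy"]
    units = units[UNIT_COLUMNS].sort_values(key, kind="mergesort").reset_index(drop=True)
    return units


def validate_units(units: pd.DataFrame, min_gbs_depth: int = 10, min_rna_reads: int = 10) -> None:
    """Re-check every testable-unit invariant post hoc; raise on violation."""
    if units.empty:
        return
    ok_het = ((units["alpha"] >= 1) & (units["beta"] >= 1)).all()
    ok_ploidy = (units["alpha"] + units["beta"] == units["ploidy"]).all()
    ok_depth = (units["gbs_depth"] >= min_gbs_depth).all()
    ok_rna = (units["pooled_n"] >= min_rna_reads).all()
    ok_pool = all(
        sum(y) == py and sum(n) == pn
        for y, n, py, pn in zip(units["y_r"], units["n_r"], units["pooled_y"], units["pooled_n"])
    )
    ok_p = np.allclose(units["P"], units["alpha"] / units["ploidy"]) and (
        (units["P"] > 0) & (units["P"] < 1)
    ).all()
    if not (ok_het and ok_ploidy and ok_depth and ok_rna and ok_pool and ok_p):
        raise AssertionError("testable-unit invariant violated")


def relative_expression(units: pd.DataFrame) -> pd.Series:
    """Pooled reference-allele expression fraction ``sum(y) / sum(n)`` per unit."""
    if (units["pooled_n"] <= 0).any():
        raise ValueError("unit with zero pooled RNA total: invariant violation")
    return units["pooled_y"] / units["pooled_n"]
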