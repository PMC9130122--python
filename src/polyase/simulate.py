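"""Synthetic mixed-ploid panels with known allele-specific-expression truth.

Emulates the study design the pipeline targets: a panel of K genotypes with R
RNA-Seq replicates each, SNPs on de-novo-assembled transcripts, per-site
ploidy varying across loci (aneuploidy), GBS read depths supporting the
dosage calls, and Binomial RNA-Seq allele counts whose success probability
``theta`` equals the relative genomic dosage ``P = alpha / (alpha + beta)``
for null SNPs and deviates from it for ASE SNPs.

Defaults mirror the study conditions: 6 genotypes x 3 replicates, ~4 SNPs per
transcript on average, and a ploidy spectrum over 6..14 with a dodecaploid
mode.  Read depths are negative binomial (mean + dispersion) to mimic
GBS/RNA-Seq overdispersion.  One seed governs the whole fixture, with fixed
per-stage substreams so each stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import io as pio

__all__ = [
    "SimConfig",
    "DEFAULT_PLOIDY_WEIGHTS",
    "simulate_panel",
    "simulate_gbs_depths",
    "simulate_rna_counts",
    "make_gene_maps",
    "write_fixture",
    "simulate_fixture",
]

#: per-SNP-call ploidy spectrum over 6..14, dodecaploid mode
DEFAULT_PLOIDY_WEIGHTS: dict[int, float] = {
    6: 0.05,
    7: 0.05,
    8: 0.10,
    9: 0.10,
    10: 0.12,
    11: 0.13,
    12: 0.25,
    13: 0.12,
    14: 0.08,
}

_BASES = np.array(list("ACGT"))

# fixed substream tags so stages are independently regenerable from one seed
_STREAM_PANEL, _STREAM_GBS, _STREAM_RNA, _STREAM_MAPS = 1, 2, 3, 4


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic panel; every field has a study-shaped default."""

    n_genotypes: int = 6
    n_replicates: int = 3
    n_transcripts: int = 200
    snps_per_transcript_mean: float = 4.0
    ploidy_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PLOIDY_WEIGHTS)
    )
    gbs_depth_mean: float = 30.0
    gbs_dispersion: float = 2.0
    rna_depth_mean: float = 100.0
    rna_dispersion: float = 2.0
    ase_fraction: float = 0.1
    effect_model: str = "logit_shift"  # or "fixed_theta"
    effect_size: float = 1.5
    missing_rate: float = 0.05
    indel_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genotypes", "n_replicates", "n_transcripts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("snps_per_transcript_mean", "gbs_depth_mean", "rna_depth_mean",
                     "gbs_dispersion", "rna_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ase_fraction", "missing_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not self.ploidy_weights or all(w == 0 for w in self.ploidy_weights.values()):
            raise ValueError("ploidy_weights is degenerate: all weights zero")
        total = sum(self.ploidy_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ploidy_weights must sum to 1, got {total}")
        if any(p < 2 or w < 0 for p, w in self.ploidy_weights.items()):
            raise ValueError("ploidy_weights keys must be ploidies >= 2 with weights >= 0")
        if self.effect_model not in ("fixed_theta", "logit_shift"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")
        if self.effect_model == "fixed_theta" and not 0.0 < self.effect_size < 1.0:
            raise ValueError("fixed_theta effect_size must be a probability in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ploidy_weights" in raw:
            raw["ploidy_weights"] = {int(k): float(v) for k, v in raw["ploidy_weights"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, stream])


def _genotype_names(k: int) -> list[str]:
    return [f"G{i + 1:02d}" for i in range(k)]


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the genotype panel: sites, ploidies, dosages and true theta.

    Returns ``(calls, truth)``.  ``calls`` is the long per-call variant table
    (without GBS depth; see :func:`simulate_gbs_depths`).  ``truth`` records,
    for every non-missing call, the true expressed reference proportion and
    whether it deviates from the genomic ratio.  Deterministic given the
    config (including seed).
    """
    config.validate()
    rng = _rng(config, _STREAM_PANEL)
    genotypes = _genotype_names(config.n_genotypes)
    ploidies = np.array(sorted(config.ploidy_weights))
    weights = np.array([config.ploidy_weights[p] for p in ploidies], dtype=float)
    weights = weights / weights.sum()

    call_rows, truth_rows = [], []
    for t in range(config.n_transcripts):
        transcript = f"tx{t + 1:05d}"
        n_snps = rng.poisson(config.snps_per_transcript_mean)
        if n_snps == 0:
            continue
        positions = np.sort(rng.choice(np.arange(1, 3001), size=min(n_snps, 3000), replace=False))
        for pos in positions:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            is_indel = rng.random() < config.indel_rate
            if is_indel:
                alt = alt + "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
            for genotype in genotypes:
                if rng.random() < config.missing_rate:
                    call_rows.append((transcript, int(pos), ref, alt, is_indel,
                                      genotype, 0, 0, 0, True))
                    continue
                ploidy = int(rng.choice(ploidies, p=weights))
                alpha = int(rng.integers(0, ploidy + 1))
                beta = ploidy - alpha
                p_ratio = alpha / ploidy
                theta, is_ase = p_ratio, False
                if 1 <= alpha <= ploidy - 1 and rng.random() < config.ase_fraction:
                    if config.effect_model == "fixed_theta":
                        theta = float(config.effect_size)
                    else:
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                        theta = float(expit(logit(p_ratio) + sign * config.effect_size))
                    is_ase = theta != p_ratio
                call_rows.append((transcript, int(pos), ref, alt, is_indel,
                                  genotype, alpha, beta, ploidy, False))
                truth_rows.append((transcript, int(pos), genotype, alpha, beta, theta, is_ase))

    calls = pd.DataFrame(
        call_rows,
        columns=["transcript", "position", "ref_allele", "alt_allele", "is_indel",
                 "genotype", "alpha", "beta", "ploidy", "missing"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript", "position", "genotype", "alpha", "beta",
                 "true_theta", "is_ase_truth"],
    )
    return calls, truth


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    # NB parameterized by mean m and shape k: var = m + m^2 / k
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_gbs_depths(calls: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Attach a per-call GBS read depth column (negative binomial)."""
    config.validate()
    rng = _rng(config, _STREAM_GBS)
    out = calls.copy()
    out["gbs_depth"] = _neg_binomial(rng, config.gbs_depth_mean, config.gbs_dispersion, len(out))
    return out


def simulate_rna_counts(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw per-replicate RNA-Seq allele counts ``y ~ Binomial(n, theta)``.

    One record per (SNP, genotype, replicate) for every truth entry; totals
    are negative binomial with mean ``rna_depth_mean`` per replicate.
    """
    config.validate()
    rng = _rng(config, _STREAM_RNA)
    reps = [f"r{i + 1}" for i in range(config.n_replicates)]
    base = truth.loc[truth.index.repeat(config.n_replicates)].reset_index(drop=True)
    base["replicate"] = np.tile(reps, len(truth))
    totals = _neg_binomial(rng, config.rna_depth_mean, config.rna_dispersion, len(base))
    ys = rng.binomial(totals, base["true_theta"].to_numpy())
    counts = base[["transcript", "position", "genotype", "replicate"]].copy()
    counts["ref_count"] = ys
    counts["total_count"] = totals
    return counts


def make_gene_maps(
    transcripts: list[str], config: SimConfig, n_go_terms: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build transcript->gene and gene->GO maps for the fixture.

    Transcripts are grouped two-per-gene (so gene aggregation is exercised);
    each gene draws 1-3 GO terms from a shared pool.
    """
    rng = _rng(config, _STREAM_MAPS)
    transcripts = sorted(transcripts)
    gene_ids = [f"gene{(i // 2) + 1:05d}" for i in range(len(transcripts))]
    gene_map = pd.DataFrame({"transcript_id": transcripts, "gene_id": gene_ids})
    terms = [f"GO:{i + 1:07d}" for i in range(n_go_terms)]
    go_rows = []
    for gene in sorted(set(gene_ids)):
        k = int(rng.integers(1, 4))
        for term in sorted(rng.choice(terms, size=k, replace=False)):
            go_rows.append((gene, term))
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "go_term"])
    return gene_map, go_map


def write_fixture(
    calls: pd.DataFrame,
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir: str | Path,
    config: SimConfig,
) -> dict[str, Path]:
    """Serialize a complete fixture: VCF, counts, truth and mapping tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    site_alleles = calls[["transcript", "position", "ref_allele", "alt_allele"]].drop_duplicates()
    counts_out = counts.merge(site_alleles, on=["transcript", "position"], how="left")
    gene_map, go_map = make_gene_maps(list(calls["transcript"].unique()), config)
    paths = {
        "vcf": out_dir / "panel.vcf",
        "counts": out_dir / "allele_counts.tsv",
        "truth": out_dir / "truth.tsv",
        "genes": out_dir / "gene_map.tsv",
        "go": out_dir / "go_map.tsv",
    }
    pio.write_dosage_vcf(calls, paths["vcf"])
    counts_out = counts_out.rename(columns={"ref_allele": "refAllele", "alt_allele": "altAllele"})
    pio.write_allele_counts(counts_out, paths["counts"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    gene_map.to_csv(paths["genes"], sep="\t", index=False)
    go_map.to_csv(paths["go"], sep="\t", index=False)
    return paths


def simulate_fixture(config: SimConfig, out_dir: str | Path | None = None):
    """Convenience wrapper: run all stages; optionally write files.

    Returns ``(calls, counts, truth)`` with GBS depths attached.
    """
    calls, truth = simulate_panel(config)
    calls = simulate_gbs_depths(calls, config)
    counts = simulate_rna_counts(truth, config)
    if out_dir is not None:
        write_fixture(calls, counts, truth, out_dir, config)
    return calls, counts, truth
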