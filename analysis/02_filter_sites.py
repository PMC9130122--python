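"""Apply the post-genotyping filter cascade and build testable units.

Reads the fixture written by 01_simulate_panel.py, removes sites that are
all-homozygous/missing or indels, masks calls with ploidy outside 6..14,
then keeps heterozygous SNP x genotype units with >= 10 genomic reads and a
pooled RNA-Seq total >= 10.  Writes results/units.tsv.
"""

from pathlib import Path

from polyase import build_testable_units, filter_variants, validate_units
from polyase import io as pio

FIXTURE = Path("results/fixture")


def main() -> None:
    calls = pio.read_dosage_vcf(FIXTURE / "panel.vcf")
    counts = pio.read_allele_counts(FIXTURE / "allele_counts.tsv")
    filtered, stats = filter_variants(calls, ploidy_window=(6, 14), return_stats=True)
    units = build_testable_units(filtered, counts, min_gbs_depth=10, min_rna_reads=10)
    validate_units(units)
    pio.write_units(units, "results/units.tsv")
    n_in = calls.groupby(["transcript", "position"]).ngroups
    n_out = filtered.groupby(["transcript", "position"]).ngroups
    print(f"sites: {n_in} in -> {n_out} after cascade "
          f"(removed {stats['all_homozygous_or_missing']} all-homozygous/missing, "
          f"{stats['indel']} indel, {stats['no_heterozygous_call_left']} after ploidy masking)")
    print(f"testable units: {len(units)} -> results/units.tsv")


if __name__ == "__main__":
    main()
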