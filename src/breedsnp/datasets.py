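"""Published summary inputs for the three-breed bovine pituitary RNA-seq cohort.

These are the printed per-breed summaries of the source study this package's
pipeline re-analyzes: read-mapping totals per breed and age (millions of
reads), per-animal average SNP counts before and after each stringent filter,
and the raw database total.  They serve as *inputs* to the arithmetic
consistency checks — retention, reduction and mapping percentages are always
recomputed from them through :mod:`breedsnp.filtering`, never stored.

The Hereford mapping table is shipped for completeness, but its printed
properly-paired column is internally inconsistent (the source table's columns
are shifted), so no percentage is derived from it.
"""

from __future__ import annotations

from .model import MappingSummary

POLISH_HF = "PolishHF"
POLISH_RED = "PolishRed"
HEREFORD = "Hereford"

BREEDS = (POLISH_HF, POLISH_RED, HEREFORD)
AGES_MONTHS = (6, 9, 12)
SAMPLES_PER_BREED = 6
N_SAMPLES = 18

# Raw SNP database total across all 18 libraries.
RAW_SNP_TOTAL = 13_775_885

# Per-animal average SNP counts: raw, after the >=10 reads & >=90% accuracy
# filter, and after the >=10 reads & =100% accuracy filter.
PER_BULL_AVERAGES: dict[str, dict[str, int]] = {
    POLISH_HF: {"raw": 880_442, "filter90": 39_730, "filter100": 31_978},
    HEREFORD: {"raw": 754_719, "filter90": 34_658, "filter100": 30_052},
    POLISH_RED: {"raw": 660_819, "filter90": 25_414, "filter100": 20_573},
}

# Read-mapping summaries per breed and age, in millions of reads
# (total, mapped, properly paired).
MAPPING_ROWS: dict[str, list[MappingSummary]] = {
    POLISH_HF: [
        MappingSummary(POLISH_HF, 6, 218.45, 218.45, 202.27),
        MappingSummary(POLISH_HF, 9, 159.83, 159.83, 148.29),
        MappingSummary(POLISH_HF, 12, 137.10, 137.10, 128.94),
    ],
    POLISH_RED: [
        MappingSummary(POLISH_RED, 6, 108.49, 108.49, 102.68),
        MappingSummary(POLISH_RED, 9, 56.89, 56.89, 54.14),
        MappingSummary(POLISH_RED, 12, 50.00, 50.00, 46.48),
    ],
    # properly-paired column not trusted for Hereford (see module docstring);
    # the "with itself and mate mapped" figures are carried in its place and
    # only the total/mapped columns should be consumed.
    HEREFORD: [
        MappingSummary(HEREFORD, 6, 207.07, 202.72, 200.69),
        MappingSummary(HEREFORD, 9, 105.39, 103.66, 102.80),
        MappingSummary(HEREFORD, 12, 95.58, 94.07, 93.30),
    ],
}

# Printed totals rows of the mapping tables.  These differ from the sum of
# the per-age rows by up to 0.01M (the source rounded each row independently);
# derived percentages use the printed totals, matching the published figures.
MAPPING_TOTALS: dict[str, MappingSummary] = {
    POLISH_HF: MappingSummary(POLISH_HF, None, 515.38, 515.38, 479.51),
    POLISH_RED: MappingSummary(POLISH_RED, None, 215.39, 215.39, 203.31),
    HEREFORD: MappingSummary(HEREFORD, None, 408.04, 401.97, 396.79),
}

# Breeds whose mapping percentages are derivable from consistent table columns.
MAPPING_PCT_BREEDS = (POLISH_HF, POLISH_RED)


def filtered_total(filter_name: str) -> int:
    """Cohort-wide filtered SNP count reconstructed from per-animal averages."""
    return sum(avgs[filter_name] * SAMPLES_PER_BREED
               for avgs in PER_BULL_AVERAGES.values())
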