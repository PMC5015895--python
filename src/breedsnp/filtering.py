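"""Stringent SNP filtering and database-reduction statistics.

Two filters are used to trim a raw SNP database to a high-confidence one:
at least ``min_alt_reads`` reads supporting the alternate base together with a
call accuracy (alt reads as a percentage of total reads) either at or above a
threshold (the ``>= 90%`` filter) or exactly 100% (the ``= 100%`` filter,
implemented as the integer condition ``alt_depth == total_depth``).

"10 SNP reads per base" is read as reads supporting the alternate allele, not
total site coverage; with the 100% filter the two readings coincide.  Both
interpretations are available via ``depth_mode``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .model import MappingSummary, SnpCall, SnpDb


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at *ndigits* decimals (printed-table style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def per_bull_average(total: int, n_samples: int, mode: str = "truncate") -> int:
    """Average call count per animal; published tables truncate the division."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if mode == "truncate":
        return total // n_samples
    if mode == "round":
        return int(round_half_up(total / n_samples, 0))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FilterSpec:
    """One stringent filter: read support plus accuracy criterion."""

    min_alt_reads: int = 10
    min_accuracy_pct: float = 90.0
    accuracy_is_exact: bool = False
    depth_mode: str = "alt"  # 'alt': alt-supporting reads; 'total': site coverage

    def __post_init__(self) -> None:
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if not (0 < self.min_accuracy_pct <= 100):
            raise ValueError("min_accuracy_pct must be in (0, 100]")
        if self.depth_mode not in ("alt", "total"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")

    def passes(self, call: SnpCall) -> bool:
        depth = call.alt_depth if self.depth_mode == "alt" else call.total_depth
        if depth < self.min_alt_reads:
            return False
        if self.accuracy_is_exact:
            # exact accuracy thresholds are integer-exact: 100% <=> alt == total
            frac = self.min_accuracy_pct / 100.0
            return call.alt_depth * 100 == call.total_depth * self.min_accuracy_pct \
                if self.min_accuracy_pct != 100.0 \
                else call.alt_depth == call.total_depth
        return call.accuracy_pct >= self.min_accuracy_pct - 1e-9


FILTER_90 = FilterSpec(min_alt_reads=10, min_accuracy_pct=90.0)
FILTER_100 = FilterSpec(min_alt_reads=10, min_accuracy_pct=100.0, accuracy_is_exact=True)


def apply_filter(db: SnpDb, spec: FilterSpec) -> SnpDb:
    """Retain exactly the calls satisfying *spec*; idempotent and monotone."""
    return db.subset(spec.passes)


@dataclass
class ReductionReport:
    """Database trimming summary: totals, percentages, per-breed averages."""

    raw_count: int
    filtered_count: int
    retention_pct: float
    reduction_pct: float
    per_breed_raw_avg: dict[str, int] = field(default_factory=dict)
    per_breed_filtered_avg: dict[str, int] = field(default_factory=dict)


def reduction_from_counts(raw_count: int, filtered_count: int) -> tuple[float, float]:
    """(retention_pct, reduction_pct) at 1 decimal, half-up."""
    if raw_count <= 0:
        raise ValueError("raw count must be positive (percentage undefined)")
    if filtered_count > raw_count:
        raise ValueError("filtered count exceeds raw count")
    retention = round_half_up(100.0 * filtered_count / raw_count, 1)
    reduction = round_half_up(100.0 - 100.0 * filtered_count / raw_count, 1)
    return retention, reduction


def reduction_report(raw: SnpDb, filtered: SnpDb, avg_mode: str = "truncate") -> ReductionReport:
    """Summarize trimming of *raw* into *filtered* (must be a key-subset)."""
    if len(raw) == 0:
        raise ValueError("raw database is empty; reduction undefined")
    if not filtered.key_set() <= raw.key_set():
        raise ValueError("filtered database is not a subset of the raw database")
    retention, reduction = reduction_from_counts(len(raw), len(filtered))
    raw_avg: dict[str, int] = {}
    filt_avg: dict[str, int] = {}
    for breed in raw.breeds:
        sids = raw.samples_of_breed(breed)
        raw_total = sum(len(raw.calls_of_sample(s)) for s in sids)
        filt_total = sum(len(filtered.calls_of_sample(s)) for s in sids)
        raw_avg[breed] = per_bull_average(raw_total, len(sids), avg_mode)
        filt_avg[breed] = per_bull_average(filt_total, len(sids), avg_mode)
    return ReductionReport(
        raw_count=len(raw),
        filtered_count=len(filtered),
        retention_pct=retention,
        reduction_pct=reduction,
        per_breed_raw_avg=raw_avg,
        per_breed_filtered_avg=filt_avg,
    )


def retention_pct_by_breed(raw_avg: float, filtered_avg: float) -> float:
    """Retained fraction (percent, 1 decimal) from per-animal average counts."""
    if raw_avg <= 0:
        raise ValueError("raw average must be positive")
    return round_half_up(100.0 * filtered_avg / raw_avg, 1)


def properly_paired_pct(summary: MappingSummary) -> float:
    """Percentage of reads properly paired, 2 decimals half-up."""
    if summary.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return round_half_up(100.0 * summary.properly_paired / summary.total_reads, 2)


def breed_totals(rows: list[MappingSummary]) -> MappingSummary:
    """Sum per-age mapping rows into one breed-total row."""
    if not rows:
        raise ValueError("no mapping rows to total")
    breeds = {r.breed for r in rows}
    if len(breeds) != 1:
        raise ValueError(f"rows span multiple breeds: {sorted(breeds)}")
    return MappingSummary(
        breed=rows[0].breed,
        age_months=None,
        total_reads=round(math.fsum(r.total_reads for r in rows), 2),
        mapped=round(math.fsum(r.mapped for r in rows), 2),
        properly_paired=round(math.fsum(r.properly_paired for r in rows), 2),
    )
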