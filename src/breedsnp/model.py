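"""Core data model for breed-specific SNP databases.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted at the boundary by the readers in :mod:`breedsnp.io`.  A SNP site is
identified across samples by ``(chrom, pos, alt_base)`` — the reference base is
carried on every call but is not part of the identity, so calls at unknown
reference positions (``ref_base == "N"``) compare like any other site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

VALID_REF = frozenset("ACGTN")
VALID_ALT = frozenset("ACGT")

SiteKey = tuple[str, int, str]
CallKey = tuple[str, str, int, str]  # (sample_id, chrom, pos, alt_base)


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome label: ``chr25``, ``BTA25`` and ``25`` compare equal.

    Upper-cases and strips a leading ``CHR`` or ``BTA`` prefix.
    """
    s = str(name).strip().upper()
    for prefix in ("CHR", "BTA"):
        if s.startswith(prefix) and len(s) > len(prefix):
            s = s[len(prefix):]
            break
    return s


class SnpDbError(ValueError):
    """Raised when a record violates the data-model invariants."""


@dataclass(frozen=True, slots=True)
class SnpCall:
    """One called single-base substitution in one sample.

    ``accuracy_pct`` is the percentage of reads at the site that support the
    called alternate base, ``100 * alt_depth / total_depth``.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    total_depth: int
    alt_depth: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SnpDbError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in VALID_REF:
            raise SnpDbError(f"invalid ref_base {self.ref_base!r}")
        if self.alt_base not in VALID_ALT:
            raise SnpDbError(f"invalid alt_base {self.alt_base!r}")
        if self.alt_base == self.ref_base:
            raise SnpDbError(
                f"alt_base equals ref_base ({self.alt_base}) at "
                f"{self.chrom}:{self.pos}"
            )
        if not (1 <= self.alt_depth <= self.total_depth):
            raise SnpDbError(
                f"require 1 <= alt_depth <= total_depth, got "
                f"alt={self.alt_depth} total={self.total_depth} at "
                f"{self.chrom}:{self.pos}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.alt_depth / self.total_depth

    @property
    def site_key(self) -> SiteKey:
        return (self.chrom, self.pos, self.alt_base)

    @property
    def key(self) -> CallKey:
        return (self.sample_id, self.chrom, self.pos, self.alt_base)


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Library identity within the cohort design (breed x age x replicate)."""

    sample_id: str
    breed: str
    age_months: int
    replicate: int = 1


@dataclass(frozen=True, slots=True)
class GeneInterval:
    """A candidate-gene / QTL locus, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SnpDbError(
                f"interval {self.gene}: start {self.start} > end {self.end}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True, slots=True)
class MappingSummary:
    """Read-mapping totals (in millions of reads) for one breed x age cell."""

    breed: str
    age_months: int | None
    total_reads: float
    mapped: float
    properly_paired: float

    def __post_init__(self) -> None:
        # tolerate 2-decimal rounding in published tables
        tol = 0.011
        if not (-tol <= self.properly_paired <= self.mapped + tol <= self.total_reads + 2 * tol):
            raise SnpDbError(
                f"require properly_paired <= mapped <= total, got "
                f"{self.properly_paired}/{self.mapped}/{self.total_reads}"
            )


class SnpDb:
    """Per-sample keyed collection of SNP calls plus the cohort's sample metadata.

    At most one record may exist per ``(sample_id, chrom, pos, alt_base)``.
    """

    def __init__(self, samples: Iterable[SampleMeta] = ()) -> None:
        self._calls: dict[CallKey, SnpCall] = {}
        self.samples: dict[str, SampleMeta] = {}
        for meta in samples:
            self.add_sample(meta)

    def add_sample(self, meta: SampleMeta) -> None:
        if meta.sample_id in self.samples:
            raise SnpDbError(f"duplicate sample_id {meta.sample_id!r}")
        self.samples[meta.sample_id] = meta

    def add_call(self, call: SnpCall) -> None:
        if call.sample_id not in self.samples:
            raise SnpDbError(
                f"call for unknown sample {call.sample_id!r}; add SampleMeta first"
            )
        if call.key in self._calls:
            raise SnpDbError(f"duplicate call key {call.key}")
        self._calls[call.key] = call

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[SnpCall]:
        return iter(self._calls.values())

    def __contains__(self, key: CallKey) -> bool:
        return key in self._calls

    def get(self, key: CallKey) -> SnpCall | None:
        return self._calls.get(key)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in first-seen sample order."""
        seen: dict[str, None] = {}
        for meta in self.samples.values():
            seen.setdefault(meta.breed, None)
        return list(seen)

    def samples_of_breed(self, breed: str) -> list[str]:
        return [s for s, m in self.samples.items() if m.breed == breed]

    def calls_of_sample(self, sample_id: str) -> list[SnpCall]:
        return [c for c in self._calls.values() if c.sample_id == sample_id]

    def site_keys(self) -> set[SiteKey]:
        return {c.site_key for c in self._calls.values()}

    def subset(self, predicate) -> "SnpDb":
        """New SnpDb with the same samples and the calls satisfying *predicate*."""
        out = SnpDb(self.samples.values())
        for call in self._calls.values():
            if predicate(call):
                out.add_call(call)
        return out

    def key_set(self) -> set[CallKey]:
        return set(self._calls)

    def equals(self, other: "SnpDb") -> bool:
        return (
            self._calls == other._calls
            and self.samples == other.samples
        )


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for individuals x loci (KASP-style validation panel).

    ``genotypes[i][j]`` is one of ``"AA"``, ``"AB"``, ``"BB"`` or ``None``
    (missing), coded relative to each locus' (normal, mutant) allele pair.
    """

    individuals: list[str]
    breeds: list[str]
    loci: list[str]
    alleles: list[tuple[str, str]]  # (normal, mutant) per locus
    genotypes: list[list[str | None]] = field(repr=False)

    def __post_init__(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        if len(self.breeds) != n:
            raise SnpDbError("breeds must align with individuals")
        if len(self.alleles) != L:
            raise SnpDbError("alleles must align with loci")
        if len(self.genotypes) != n or any(len(row) != L for row in self.genotypes):
            raise SnpDbError("genotype matrix must be rectangular")
        for row in self.genotypes:
            for g in row:
                if g is not None and g not in ("AA", "AB", "BB"):
                    raise SnpDbError(f"invalid genotype code {g!r}")

    @property
    def breed_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(b, None)
        return list(seen)

    def genotype_counts(self, locus: str, breed: str | None = None) -> tuple[int, int, int]:
        """(n_AA, n_AB, n_BB) at *locus*, optionally restricted to one breed."""
        j = self.loci.index(locus)
        counts = {"AA": 0, "AB": 0, "BB": 0}
        for i, row in enumerate(self.genotypes):
            if breed is not None and self.breeds[i] != breed:
                continue
            g = row[j]
            if g is not None:
                counts[g] += 1
        return counts["AA"], counts["AB"], counts["BB"]
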