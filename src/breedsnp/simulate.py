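"""Synthetic multi-breed RNA-seq SNP cohort with planted ground truth.

The generator emulates the data structure behind a breeds x ages x replicates
transcriptome SNP survey: per-breed allele frequencies diverge from an
ancestral frequency under a Balding–Nichols beta model with divergence ``fst``;
a chosen fraction of sites is planted fixed-alternate in exactly one breed
(and fixed-reference elsewhere), and another fraction sits at unknown-reference
positions (assembly base ``N``).  Per-sample genotypes are drawn under
Hardy–Weinberg proportions within breed, read depth per site per sample is
negative-binomial (RNA-seq-style overdispersion), and each read miscalls with
probability ``error_rate``.  A call is emitted only when at least one read
shows the alternate base, so the raw database contains noise calls just like a
permissive pileup scan.

Every emitted call traces to exactly one ground-truth site, which makes the
downstream filtering, categorization, gene-hit and phylogeny stages testable
against a known answer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .model import GenotypeMatrix, SampleMeta, SnpCall, SnpDb

DEFAULT_BREEDS = ("PolishHF", "PolishRed", "Hereford")
BASES = ("A", "C", "G", "T")

CATEGORY_BREED_UNIQUE = "breed_unique_fixed"
CATEGORY_SHARED = "shared"
CATEGORY_REF_N = "ref_N"


@dataclass(frozen=True)
class CohortDesign:
    """Layout and simulation parameters of a synthetic cohort.

    ``frac_breed_unique_fixed`` of the sites are fixed alternate in one breed
    and absent elsewhere; ``frac_ref_N`` sit at reference-N positions (fixed
    alternate in every breed — the true base simply is not the assembly's);
    the remainder are shared polymorphic sites.  ``min_depth`` truncates the
    negative-binomial depth draw from below, for studies of the regime where
    every site is sequenced to callable depth.
    """

    breeds: tuple[str, ...] = DEFAULT_BREEDS
    ages_months: tuple[int, ...] = (6, 9, 12)
    replicates_per_cell: int = 2
    n_sites: int = 1000
    frac_breed_unique_fixed: float = 0.1
    frac_ref_N: float = 0.02
    fst: float = 0.3
    mean_depth: float = 50.0
    error_rate: float = 0.002
    depth_dispersion: float = 5.0
    min_depth: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.breeds) < 1 or len(set(self.breeds)) != len(self.breeds):
            raise ValueError("breeds must be non-empty and distinct")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if not (0 <= self.frac_breed_unique_fixed <= 1 and 0 <= self.frac_ref_N <= 1):
            raise ValueError("planted fractions must lie in [0, 1]")
        if self.frac_breed_unique_fixed + self.frac_ref_N > 1:
            raise ValueError("planted fractions sum above 1")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")

    @property
    def samples(self) -> list[SampleMeta]:
        out = []
        i = 0
        for breed in self.breeds:
            for age in self.ages_months:
                for rep in range(1, self.replicates_per_cell + 1):
                    i += 1
                    out.append(
                        SampleMeta(
                            sample_id=f"CP{i:02d}", breed=breed,
                            age_months=age, replicate=rep,
                        )
                    )
        return out


@dataclass(frozen=True)
class TruthSite:
    """Ground truth for one simulated site."""

    chrom: str
    pos: int
    ref_base: str        # 'N' for unknown-reference sites
    hidden_ref: str      # the true base at ref-N sites (equals ref_base otherwise)
    alt_base: str
    category: str
    unique_breed: str | None       # set for breed_unique_fixed sites
    ancestral_freq: float
    breed_freqs: dict[str, float]

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)


@dataclass
class GroundTruth:
    """All planted sites plus the realized per-sample genotypes."""

    sites: list[TruthSite]
    genotypes: dict[str, np.ndarray] = field(repr=False)  # sample_id -> alt-allele dosage

    def planted_sites(self, category: str) -> set[tuple[str, int, str]]:
        return {s.site_key for s in self.sites if s.category == category}

    def unique_sites_of_breed(self, breed: str) -> set[tuple[str, int, str]]:
        return {
            s.site_key
            for s in self.sites
            if s.category == CATEGORY_BREED_UNIQUE and s.unique_breed == breed
        }


def truth_category_counts(truth: GroundTruth) -> dict[str, int]:
    """Site counts per planted category; they sum to ``n_sites``."""
    counts = {CATEGORY_BREED_UNIQUE: 0, CATEGORY_SHARED: 0, CATEGORY_REF_N: 0}
    for s in truth.sites:
        counts[s.category] += 1
    return counts


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # substream derived from (seed, sample_id): reproducible and independent of
    # the order samples are generated in
    digest = hashlib.sha256(sample_id.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


def _truncated_nbinom(rng: np.random.Generator, mean: float, dispersion: float,
                      min_depth: int, size: int) -> np.ndarray:
    r = dispersion
    p = r / (r + mean)
    if min_depth <= 0:
        return rng.negative_binomial(r, p, size=size)
    lo = stats.nbinom.cdf(min_depth - 1, r, p)
    u = rng.uniform(lo, 1.0, size=size)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def _draw_sites(design: CohortDesign, rng: np.random.Generator) -> list[TruthSite]:
    n = design.n_sites
    n_unique = round(design.frac_breed_unique_fixed * n)
    n_refn = round(design.frac_ref_N * n)
    categories = (
        [CATEGORY_BREED_UNIQUE] * n_unique
        + [CATEGORY_REF_N] * n_refn
        + [CATEGORY_SHARED] * (n - n_unique - n_refn)
    )
    sites: list[TruthSite] = []
    for i, category in enumerate(categories):
        chrom = str(1 + i % 29)          # bovine autosomes
        pos = 10_000 + (i // 29) * 1_000 + (i % 29)
        ref = BASES[rng.integers(4)]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
        if category == CATEGORY_BREED_UNIQUE:
            breed = design.breeds[i % len(design.breeds)]
            freqs = {b: (1.0 if b == breed else 0.0) for b in design.breeds}
            sites.append(TruthSite(chrom, pos, ref, ref, alt, category, breed, 0.0, freqs))
        elif category == CATEGORY_REF_N:
            freqs = {b: 1.0 for b in design.breeds}
            sites.append(TruthSite(chrom, pos, "N", ref, alt, category, None, 1.0, freqs))
        else:
            p = rng.uniform(0.05, 0.95)
            if design.fst > 0:
                a = p * (1 - design.fst) / design.fst
                b = (1 - p) * (1 - design.fst) / design.fst
                freqs = {br: float(rng.beta(a, b)) for br in design.breeds}
            else:
                freqs = {br: p for br in design.breeds}
            sites.append(TruthSite(chrom, pos, ref, ref, alt, category, None, p, freqs))
    return sites


def simulate_cohort(design: CohortDesign) -> tuple[SnpDb, GenotypeMatrix, GroundTruth]:
    """Generate (SnpDb, GenotypeMatrix, GroundTruth) for *design*.

    Deterministic for a fixed ``design.seed``; per-sample randomness comes
    from substreams keyed by (seed, sample_id).
    """
    rng = np.random.default_rng(design.seed)
    sites = _draw_sites(design, rng)
    samples = design.samples
    db = SnpDb(samples)
    genotypes: dict[str, np.ndarray] = {}

    freqs_by_breed = {
        b: np.array([s.breed_freqs[b] for s in sites]) for b in design.breeds
    }
    e = design.error_rate
    for meta in samples:
        srng = _sample_rng(design.seed, meta.sample_id)
        q = freqs_by_breed[meta.breed]
        g = srng.binomial(2, q)                      # alt-allele dosage under HWE
        genotypes[meta.sample_id] = g
        depth = _truncated_nbinom(
            srng, design.mean_depth, design.depth_dispersion,
            design.min_depth, len(sites),
        )
        p_alt = (g / 2.0) * (1 - e) + (1 - g / 2.0) * (e / 3.0)
        alt_depth = srng.binomial(depth, p_alt)
        for i, site in enumerate(sites):
            if alt_depth[i] >= 1:
                db.add_call(
                    SnpCall(
                        chrom=site.chrom, pos=site.pos, ref_base=site.ref_base,
                        alt_base=site.alt_base, total_depth=int(depth[i]),
                        alt_depth=int(alt_depth[i]), sample_id=meta.sample_id,
                    )
                )

    matrix = GenotypeMatrix(
        individuals=[m.sample_id for m in samples],
        breeds=[m.breed for m in samples],
        loci=[f"BTA{s.chrom}_{s.pos}" for s in sites],
        alleles=[(s.hidden_ref, s.alt_base) for s in sites],
        genotypes=[
            [("AA", "AB", "BB")[g] for g in genotypes[m.sample_id]]
            for m in samples
        ],
    )
    return db, matrix, GroundTruth(sites=sites, genotypes=genotypes)


def simulate_genotype_panel(
    n_per_breed: dict[str, int],
    locus_freqs: dict[str, dict[str, float]],
    seed: int = 0,
) -> GenotypeMatrix:
    """KASP-style validation panel: genotypes under within-breed HWE.

    ``locus_freqs`` maps locus id -> breed -> mutant-allele frequency.  Used
    both for emulating the validation cohort and for calibration studies of
    the exact tests (type-I error under true Hardy–Weinberg proportions).
    """
    rng = np.random.default_rng(seed)
    loci = list(locus_freqs)
    individuals, breeds, rows = [], [], []
    for breed, n in n_per_breed.items():
        for i in range(n):
            individuals.append(f"{breed}-{i + 1:02d}")
            breeds.append(breed)
    for sid, breed in zip(individuals, breeds):
        row = []
        for locus in loci:
            g = rng.binomial(2, locus_freqs[locus][breed])
            row.append(("AA", "AB", "BB")[g])
        rows.append(row)
    pairs = []
    for j, _locus in enumerate(loci):
        normal = BASES[rng.integers(4)]
        mutant = BASES[(BASES.index(normal) + 1 + rng.integers(3)) % 4]
        pairs.append((normal, mutant))
    return GenotypeMatrix(individuals, breeds, loci, pairs, rows)


def with_seed(design: CohortDesign, seed: int) -> CohortDesign:
    """Same design, different seed (convenience for replicated studies)."""
    return replace(design, seed=seed)
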