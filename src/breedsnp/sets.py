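"""Cross-breed set algebra over a filtered SNP database.

Every distinct site ``(chrom, pos, alt_base)`` is tabulated per breed by the
number of samples carrying it, and classified with four flags per breed:

``any``        carried by at least one of the breed's samples
``all``        carried by every one of the breed's samples ("breed-specific")
``any_unique`` ``any`` and absent from every sample of every other breed
``all_unique`` ``all`` and absent from every other breed
               ("breed-specific unique")

Uniqueness is by default evaluated against the *unfiltered* presence in other
breeds — a site carried by any other-breed sample at any depth is not unique —
which guards against depth artifacts; pass ``unique_vs="filtered"`` to relax.

Two special flags support database curation: ``de_novo`` marks filtered calls
at positions whose reference base is unknown (``N`` in the assembly), and
``ref_error_candidate`` marks sites where every sample of every breed carries
the same alternate allele at filter-passing quality, suggesting the assembly
base itself is wrong.  The latter rule (same single alternate in all samples)
is this module's explicit interpretation and is labelled as such in output.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .filtering import FilterSpec, apply_filter
from .model import SiteKey, SnpDb


@dataclass
class SiteOccurrence:
    """Per-breed carrier counts for one site."""

    site: SiteKey
    carriers: dict[str, int]       # breed -> number of samples carrying the site
    sample_totals: dict[str, int]  # breed -> number of samples in the cohort

    def __post_init__(self) -> None:
        for breed, c in self.carriers.items():
            if not (0 <= c <= self.sample_totals[breed]):
                raise ValueError(
                    f"carriers {c} outside [0, {self.sample_totals[breed]}] "
                    f"for breed {breed} at {self.site}"
                )


@dataclass
class CategorizedSite:
    """Four-way category flags for one site, per breed."""

    site: SiteKey
    any_: dict[str, bool] = field(default_factory=dict)
    all_: dict[str, bool] = field(default_factory=dict)
    any_unique: dict[str, bool] = field(default_factory=dict)
    all_unique: dict[str, bool] = field(default_factory=dict)
    de_novo: bool = False
    ref_error_candidate: bool = False


def tabulate_occurrence(db: SnpDb) -> list[SiteOccurrence]:
    """One :class:`SiteOccurrence` per distinct site key in *db*."""
    totals = {b: len(db.samples_of_breed(b)) for b in db.breeds}
    carriers: dict[SiteKey, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for call in db:
        breed = db.samples[call.sample_id].breed
        carriers[call.site_key][breed].add(call.sample_id)
    out = []
    for site in sorted(carriers):
        by_breed = carriers[site]
        out.append(
            SiteOccurrence(
                site=site,
                carriers={b: len(by_breed.get(b, ())) for b in totals},
                sample_totals=dict(totals),
            )
        )
    return out


def venn_counts(occ: list[SiteOccurrence]) -> dict[frozenset[str], int]:
    """Number of distinct sites per exact breed combination (Venn regions)."""
    counts: dict[frozenset[str], int] = defaultdict(int)
    for o in occ:
        present = frozenset(b for b, c in o.carriers.items() if c > 0)
        if present:
            counts[present] += 1
    return dict(counts)


def categorize(
    occ: list[SiteOccurrence],
    raw_occ: list[SiteOccurrence] | None = None,
    unique_vs: str = "raw",
) -> list[CategorizedSite]:
    """Assign the four per-breed flags to every site in *occ*.

    With ``unique_vs="raw"`` (default), *raw_occ* supplies unfiltered carrier
    counts used for the other-breed absence requirement; omit it (or pass
    ``unique_vs="filtered"``) to evaluate uniqueness against *occ* itself.
    """
    if unique_vs not in ("raw", "filtered"):
        raise ValueError(f"unknown unique_vs {unique_vs!r}")
    if not occ:
        return []
    totals = occ[0].sample_totals
    for breed, n in totals.items():
        if n == 0:
            raise ValueError(f"breed {breed!r} has zero samples")
    other_carriers: dict[SiteKey, dict[str, int]]
    if unique_vs == "raw" and raw_occ is not None:
        other_carriers = {o.site: o.carriers for o in raw_occ}
    else:
        other_carriers = {o.site: o.carriers for o in occ}

    out = []
    for o in occ:
        cat = CategorizedSite(site=o.site)
        others = other_carriers.get(o.site, {})
        for breed, n in totals.items():
            c = o.carriers.get(breed, 0)
            absent_elsewhere = all(
                others.get(b, 0) == 0 for b in totals if b != breed
            )
            cat.any_[breed] = c >= 1
            cat.all_[breed] = c == n
            cat.any_unique[breed] = cat.any_[breed] and absent_elsewhere
            cat.all_unique[breed] = cat.all_[breed] and absent_elsewhere
        out.append(cat)
    return out


def category_counts(cats: list[CategorizedSite]) -> dict[str, dict[str, int]]:
    """Per-breed totals of the four categories over a categorized site list."""
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for cat in cats:
        for breed in cat.any_:
            for name, flags in (
                ("any", cat.any_), ("all", cat.all_),
                ("any_unique", cat.any_unique), ("all_unique", cat.all_unique),
            ):
                if flags[breed]:
                    counts[breed][name] += 1
    return {b: dict(v) for b, v in counts.items()}


def unique_sites(cats: list[CategorizedSite], breed: str,
                 category: str = "all_unique") -> set[SiteKey]:
    attr = {"any": "any_", "all": "all_",
            "any_unique": "any_unique", "all_unique": "all_unique"}[category]
    return {c.site for c in cats if getattr(c, attr)[breed]}


def flag_de_novo(db: SnpDb, spec: FilterSpec) -> list[CategorizedSite]:
    """Sites at unknown-reference positions (ref N) passing *spec*."""
    filtered = apply_filter(db, spec)
    sites = sorted({c.site_key for c in filtered if c.ref_base == "N"})
    out = []
    for site in sites:
        cat = CategorizedSite(site=site)
        cat.de_novo = True
        out.append(cat)
    return out


def flag_ref_error_candidates(occ: list[SiteOccurrence], db: SnpDb,
                              spec: FilterSpec | None = None) -> list[CategorizedSite]:
    """Sites where every sample of every breed carries the same alternate allele.

    Each sample's call must pass *spec* (if given).  Positions with a known
    reference base only — unknown-reference (N) positions are reported by
    :func:`flag_de_novo` instead.
    """
    filtered = apply_filter(db, spec) if spec is not None else db
    n_samples = len(db.samples)
    by_site: dict[SiteKey, set[str]] = defaultdict(set)
    ref_of: dict[SiteKey, str] = {}
    alts_at_pos: dict[tuple[str, int], set[str]] = defaultdict(set)
    for call in filtered:
        by_site[call.site_key].add(call.sample_id)
        ref_of[call.site_key] = call.ref_base
        alts_at_pos[(call.chrom, call.pos)].add(call.alt_base)
    out = []
    for o in occ:
        site = o.site
        chrom, pos, _alt = site
        if ref_of.get(site) == "N":
            continue
        if len(alts_at_pos.get((chrom, pos), ())) != 1:
            continue  # discordant alternates at the position disqualify
        if len(by_site.get(site, ())) == n_samples:
            cat = CategorizedSite(site=site)
            cat.ref_error_candidate = True
            out.append(cat)
    return out
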