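from collections import defaultdict

import numpy as np
import pytest

from breedsnp.filtering import FILTER_90, FILTER_100, apply_filter
from breedsnp.model import SampleMeta, SnpCall, SnpDb
from breedsnp.sets import (
    categorize,
    category_counts,
    flag_de_novo,
    flag_ref_error_candidates,
    tabulate_occurrence,
    unique_sites,
    venn_counts,
)
from breedsnp.simulate import CATEGORY_REF_N, CohortDesign, simulate_cohort

from conftest import build_db, cohort_meta


def brute_force_flags(db: SnpDb):
    """Independent evaluation of the four category predicates per site/breed."""
    carriers = defaultdict(lambda: defaultdict(set))
    for call in db:
        carriers[call.site_key][db.samples[call.sample_id].breed].add(call.sample_id)
    totals = {b: len(db.samples_of_breed(b)) for b in db.breeds}
    flags = {}
    for site, by_breed in carriers.items():
        for breed in totals:
            c = len(by_breed.get(breed, ()))
            absent = all(len(by_breed.get(o, ())) == 0 for o in totals if o != breed)
            flags[(site, breed)] = {
                "any": c >= 1,
                "all": c == totals[breed],
                "any_unique": c >= 1 and absent,
                "all_unique": c == totals[breed] and absent,
            }
    return flags


def random_cohort_db(n_sites=200, seed=0):
    rng = np.random.default_rng(seed)
    meta = cohort_meta(breeds=("A", "B", "C"), per_breed=2)
    db = SnpDb(meta)
    for i in range(n_sites):
        chrom, pos, alt, ref = str(1 + i % 5), 100 + i, "G", "A"
        for m in meta:
            if rng.random() < 0.4:
                db.add_call(SnpCall(chrom, pos, ref, alt, 30, int(rng.integers(1, 31)),
                                    m.sample_id))
    return db


def test_single_breed_carrier_counts():
    meta = cohort_meta()
    db = build_db(meta, [("1", 10, "A", "G", 20, 20, "A1")])
    (occ,) = tabulate_occurrence(db)
    assert occ.carriers == {"A": 1, "B": 0, "C": 0}
    assert occ.sample_totals == {"A": 2, "B": 2, "C": 2}


def test_empty_db_empty_occurrence():
    assert tabulate_occurrence(SnpDb(cohort_meta())) == []


def test_venn_counts_match_bruteforce_set_intersections():
    db = random_cohort_db(n_sites=200, seed=12)
    occ = tabulate_occurrence(db)
    venn = venn_counts(occ)
    sites_of = {b: {c.site_key for c in db
                    if db.samples[c.sample_id].breed == b} for b in db.breeds}
    all_sites = set().union(*sites_of.values())
    expected = defaultdict(int)
    for site in all_sites:
        region = frozenset(b for b in db.breeds if site in sites_of[b])
        expected[region] += 1
    assert venn == dict(expected)


def test_categorize_definitions_on_toy_sites():
    meta = cohort_meta()
    calls = []
    for sid in ("A1", "A2"):                      # all of A, nowhere else
        calls.append(("1", 10, "C", "T", 20, 20, sid))
    for sid in ("A1", "A2", "B1", "B2"):          # all of A and B
        calls.append(("1", 20, "C", "T", 20, 20, sid))
    db = build_db(meta, calls)
    cats = {c.site: c for c in categorize(tabulate_occurrence(db))}
    s1 = cats[("1", 10, "T")]
    assert s1.any_["A"] and s1.all_["A"] and s1.any_unique["A"] and s1.all_unique["A"]
    assert not s1.any_["B"]
    s2 = cats[("1", 20, "T")]
    assert s2.all_["A"] and s2.all_["B"]
    assert not s2.any_unique["A"] and not s2.all_unique["B"]


def test_category_flags_equal_bruteforce_predicates():
    db = random_cohort_db(seed=3)
    cats = categorize(tabulate_occurrence(db))
    expected = brute_force_flags(db)
    for cat in cats:
        for breed in cat.any_:
            exp = expected[(cat.site, breed)]
            assert cat.any_[breed] == exp["any"]
            assert cat.all_[breed] == exp["all"]
            assert cat.any_unique[breed] == exp["any_unique"]
            assert cat.all_unique[breed] == exp["all_unique"]


def test_implication_chain_holds_everywhere():
    db = random_cohort_db(seed=5)
    for cat in categorize(tabulate_occurrence(db)):
        for b in cat.any_:
            assert not cat.all_[b] or cat.any_[b]
            assert not cat.any_unique[b] or cat.any_[b]
            assert not cat.all_unique[b] or (cat.all_[b] and cat.any_unique[b])


def test_counts_invariant_under_sample_reordering():
    db = random_cohort_db(seed=8)
    meta_rev = list(db.samples.values())[::-1]
    db_rev = SnpDb(meta_rev)
    for call in sorted(db, key=lambda c: c.key, reverse=True):
        db_rev.add_call(call)
    a = category_counts(categorize(tabulate_occurrence(db)))
    b = category_counts(categorize(tabulate_occurrence(db_rev)))
    assert a == b


def test_category_count_ordering_per_breed():
    db = random_cohort_db(seed=13)
    counts = category_counts(categorize(tabulate_occurrence(db)))
    for per in counts.values():
        assert per.get("all_unique", 0) <= per.get("any_unique", 0) <= per.get("any", 0)
        assert per.get("all_unique", 0) <= per.get("all", 0) <= per.get("any", 0)


def test_unique_vs_raw_is_stricter_than_vs_filtered():
    meta = cohort_meta()
    calls = [("1", 10, "C", "T", 30, 30, "A1"), ("1", 10, "C", "T", 30, 30, "A2"),
             ("1", 10, "C", "T", 30, 2, "B1")]  # B carries it below filter depth
    db = build_db(meta, calls)
    filtered = apply_filter(db, FILTER_90)
    occ = tabulate_occurrence(filtered)
    raw_occ = tabulate_occurrence(db)
    strict = {c.site: c for c in categorize(occ, raw_occ=raw_occ, unique_vs="raw")}
    loose = {c.site: c for c in categorize(occ, unique_vs="filtered")}
    site = ("1", 10, "T")
    assert not strict[site].all_unique["A"]
    assert loose[site].all_unique["A"]


def test_breed_with_zero_samples_is_an_error():
    meta = cohort_meta() + [SampleMeta("D0", "D", 6, 1)]
    db = SnpDb(meta)
    db.add_call(SnpCall("1", 5, "A", "G", 20, 20, "A1"))
    occ = tabulate_occurrence(db)
    occ[0].sample_totals["E"] = 0
    occ[0].carriers["E"] = 0
    with pytest.raises(ValueError, match="zero samples"):
        categorize(occ)


def test_de_novo_flags_ref_n_only():
    meta = cohort_meta()
    db = build_db(meta, [("1", 5, "N", "G", 12, 12, "A1"),
                         ("1", 6, "A", "G", 12, 12, "A1"),
                         ("1", 7, "N", "G", 12, 5, "A1")])  # fails both filters
    for spec in (FILTER_90, FILTER_100):
        flagged = {c.site for c in flag_de_novo(db, spec)}
        assert flagged == {("1", 5, "G")}


def test_de_novo_recovers_planted_ref_n_sites():
    d = CohortDesign(n_sites=400, frac_ref_N=0.05, frac_breed_unique_fixed=0.0,
                     error_rate=0.0, mean_depth=50.0, min_depth=10, seed=4)
    db, _, truth = simulate_cohort(d)
    planted = truth.planted_sites(CATEGORY_REF_N)
    for spec in (FILTER_90, FILTER_100):
        assert {c.site for c in flag_de_novo(db, spec)} == planted


def test_ref_error_candidates_require_every_sample():
    meta = cohort_meta()
    universal = [("1", 10, "C", "T", 30, 30, m.sample_id) for m in meta]
    partial = [("1", 20, "C", "T", 30, 30, m.sample_id) for m in meta[:-1]]
    db = build_db(meta, universal + partial)
    occ = tabulate_occurrence(db)
    flagged = {c.site for c in flag_ref_error_candidates(occ, db, FILTER_100)}
    assert flagged == {("1", 10, "T")}


def test_ref_error_discordant_alternates_disqualify():
    meta = cohort_meta()
    calls = [("1", 10, "C", "T", 30, 30, m.sample_id) for m in meta[:-1]]
    calls.append(("1", 10, "C", "G", 30, 30, meta[-1].sample_id))  # different alt
    calls.append(("1", 10, "C", "T", 30, 30, meta[-1].sample_id))
    db = build_db(meta, calls)
    occ = tabulate_occurrence(db)
    assert flag_ref_error_candidates(occ, db, FILTER_100) == []


def test_planted_breed_unique_sites_recovered_with_clean_reads():
    d = CohortDesign(n_sites=600, frac_breed_unique_fixed=0.1, frac_ref_N=0.0,
                     error_rate=0.0, mean_depth=50.0, min_depth=10, fst=0.3, seed=17)
    db, _, truth = simulate_cohort(d)
    filtered = apply_filter(db, FILTER_90)
    cats = categorize(tabulate_occurrence(filtered),
                      raw_occ=tabulate_occurrence(db))
    for breed in d.breeds:
        planted = truth.unique_sites_of_breed(breed)
        recovered = unique_sites(cats, breed, "all_unique")
        assert planted <= recovered  # 100% recall of planted sites
        # anything extra must be genuinely breed-unique in the true genotypes
        for site in recovered - planted:
            idx = [s.site_key for s in truth.sites].index(site)
            for m in d.samples:
                g = truth.genotypes[m.sample_id][idx]
                assert (g >= 1) == (m.breed == breed)
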