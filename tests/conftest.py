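import pytest

from breedsnp.model import SampleMeta, SnpCall, SnpDb


def build_db(samples: list[SampleMeta], calls: list[tuple]) -> SnpDb:
    """Construct a SnpDb from (chrom, pos, ref, alt, total, alt_depth, sample) tuples."""
    db = SnpDb(samples)
    for chrom, pos, ref, alt, total, ad, sid in calls:
        db.add_call(SnpCall(chrom, pos, ref, alt, total, ad, sid))
    return db


def cohort_meta(breeds=("A", "B", "C"), per_breed=2) -> list[SampleMeta]:
    out = []
    for b in breeds:
        for i in range(per_breed):
            out.append(SampleMeta(f"{b}{i + 1}", b, 6, i + 1))
    return out


@pytest.fixture
def three_breed_meta():
    return cohort_meta()
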