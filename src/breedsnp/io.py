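"""Readers and writers for SNP-call tables, gene intervals and genotype matrices.

Two variant-call dialects are supported:

``pileup_tsv``
    Tab-separated with a ``#``-prefixed header and columns
    ``chrom pos ref alt total_depth alt_depth sample_id``.  This is the
    package's native round-trippable format and mirrors what a pileup-based
    caller exports after depth annotation.

``vcf``
    VCF v4.x read through pysam.  Each record must carry per-sample ``DP``
    (or site ``INFO/DP``) and ``AD`` allele depths; multi-allelic records are
    split into one call per alternate allele.  Indel records are skipped and
    counted — only single-base substitutions enter the database.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pysam

from .model import (
    GeneInterval,
    GenotypeMatrix,
    SampleMeta,
    SnpCall,
    SnpDb,
    SnpDbError,
)

log = logging.getLogger(__name__)

PILEUP_COLUMNS = ("chrom", "pos", "ref", "alt", "total_depth", "alt_depth", "sample_id")


class ParseError(SnpDbError):
    """A malformed input record; message names the offending line."""


def read_snp_calls(
    path: str | Path,
    dialect: str = "pileup_tsv",
    sample_meta: SampleMeta | None = None,
) -> SnpDb:
    """Read one sample's variant calls into a single-sample :class:`SnpDb`.

    Indel records are skipped (and tallied on the returned db as
    ``db.indels_skipped``); only biallelic single-base substitutions are kept.
    """
    path = Path(path)
    if dialect == "pileup_tsv":
        return _read_pileup_tsv(path, sample_meta)
    if dialect == "vcf":
        return _read_vcf(path, sample_meta)
    raise ValueError(f"unknown dialect {dialect!r}")


def _meta_for(sample_id: str, sample_meta: SampleMeta | None) -> SampleMeta:
    if sample_meta is not None:
        if sample_meta.sample_id != sample_id:
            raise ParseError(
                f"sample_id {sample_id!r} does not match metadata "
                f"{sample_meta.sample_id!r}"
            )
        return sample_meta
    return SampleMeta(sample_id=sample_id, breed="unknown", age_months=0)


def _read_pileup_tsv(path: Path, sample_meta: SampleMeta | None) -> SnpDb:
    db: SnpDb | None = None
    indels = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(PILEUP_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(PILEUP_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, ref, alt, tot, ad, sample_id = fields
            if len(ref) > 1 or len(alt) > 1 or ref == "-" or alt == "-":
                indels += 1
                continue
            try:
                call = SnpCall(
                    chrom=chrom,
                    pos=int(pos),
                    ref_base=ref.upper(),
                    alt_base=alt.upper(),
                    total_depth=int(tot),
                    alt_depth=int(ad),
                    sample_id=sample_id,
                )
            except (ValueError, SnpDbError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if db is None:
                db = SnpDb([_meta_for(sample_id, sample_meta)])
            try:
                db.add_call(call)
            except SnpDbError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if db is None:
        db = SnpDb([sample_meta] if sample_meta else [])
    db.indels_skipped = indels  # type: ignore[attr-defined]
    return db


def _read_vcf(path: Path, sample_meta: SampleMeta | None) -> SnpDb:
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    if len(vcf_samples) != 1:
        raise ParseError(f"{path}: expected a single-sample VCF, got {vcf_samples}")
    sample_id = vcf_samples[0]
    db = SnpDb([_meta_for(sample_id, sample_meta)])
    indels = 0
    for rec in vf:
        ref = rec.ref or ""
        alts = rec.alts or ()
        sdata = rec.samples[sample_id]
        ad = sdata.get("AD")
        if ad is None:
            raise ParseError(
                f"{path}: record {rec.chrom}:{rec.pos} lacks the AD allele-depth field"
            )
        total = sdata.get("DP")
        if total is None:
            total = rec.info.get("DP")
        if total is None:
            raise ParseError(
                f"{path}: record {rec.chrom}:{rec.pos} lacks a DP depth field"
            )
        for i, alt in enumerate(alts):
            if alt is None:
                continue
            if len(ref) != 1 or len(alt) != 1 or alt in ("*", "<NON_REF>"):
                indels += 1
                continue
            alt_depth = ad[i + 1] if len(ad) > i + 1 else None
            if alt_depth is None:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} AD missing for alt {alt}"
                )
            if alt_depth == 0:
                continue  # alt never observed in this sample
            call = SnpCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_base=ref.upper(),
                alt_base=str(alt).upper(),
                total_depth=int(total),
                alt_depth=int(alt_depth),
                sample_id=sample_id,
            )
            db.add_call(call)
    db.indels_skipped = indels  # type: ignore[attr-defined]
    return db


def write_snp_db(db: SnpDb, path: str | Path) -> None:
    """Write *db* in the pileup_tsv dialect; ``read_snp_calls`` round-trips it.

    Calls are grouped per sample and sorted by (chrom, pos, alt) for stable
    output.  Multi-sample databases are written to one file; readers merge
    single-sample fragments with :func:`merge_sample_dbs`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        for sid in db.samples:
            for call in sorted(
                db.calls_of_sample(sid), key=lambda c: (c.chrom, c.pos, c.alt_base)
            ):
                fh.write(
                    f"{call.chrom}\t{call.pos}\t{call.ref_base}\t{call.alt_base}\t"
                    f"{call.total_depth}\t{call.alt_depth}\t{call.sample_id}\n"
                )


def merge_sample_dbs(fragments: list[SnpDb], samples: list[SampleMeta]) -> SnpDb:
    """Merge per-sample fragments into one cohort db with authoritative metadata."""
    db = SnpDb(samples)
    for frag in fragments:
        for call in frag:
            db.add_call(call)
    return db


def read_multi_sample_tsv(path: str | Path, samples: list[SampleMeta]) -> SnpDb:
    """Read a multi-sample pileup_tsv written by :func:`write_snp_db`."""
    path = Path(path)
    db = SnpDb(samples)
    indels = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(PILEUP_COLUMNS):
                raise ParseError(f"{path}:{lineno}: bad column count")
            chrom, pos, ref, alt, tot, ad, sample_id = fields
            if len(ref) > 1 or len(alt) > 1:
                indels += 1
                continue
            try:
                db.add_call(
                    SnpCall(chrom, int(pos), ref.upper(), alt.upper(), int(tot),
                            int(ad), sample_id)
                )
            except (ValueError, SnpDbError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    db.indels_skipped = indels  # type: ignore[attr-defined]
    return db


_CHROM_RE = re.compile(r"^(chr|BTA)?[0-9XYM]+$", re.IGNORECASE)


def read_gene_intervals(path: str | Path, dialect: str = "auto") -> list[GeneInterval]:
    """Read candidate-gene/QTL loci from a BED or native 1-based table.

    BED rows (``chrom start end gene``, 0-based half-open) are converted to the
    internal 1-based inclusive convention; native rows are
    ``gene chrom start end`` already 1-based inclusive.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return []
    if dialect == "auto":
        dialect = _sniff_interval_dialect(rows[0])
    intervals = []
    for fields in rows:
        if len(fields) < 4:
            raise ParseError(f"{path}: interval rows need 4 columns, got {fields}")
        if dialect == "bed":
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            start, end = start + 1, end  # 0-based half-open -> 1-based inclusive
        else:
            gene, chrom, start, end = fields[0], fields[1], int(fields[2]), int(fields[3])
        if not _CHROM_RE.match(chrom):
            log.warning("unusual chromosome label %r for gene %s", chrom, gene)
        intervals.append(GeneInterval(gene=gene, chrom=chrom, start=start, end=end))
    return intervals


def _sniff_interval_dialect(fields: list[str]) -> str:
    def is_int(s: str) -> bool:
        try:
            int(s)
            return True
        except ValueError:
            return False

    if len(fields) >= 4 and is_int(fields[1]) and is_int(fields[2]) and not is_int(fields[3]):
        return "bed"
    if len(fields) >= 4 and is_int(fields[2]) and is_int(fields[3]):
        return "native"
    raise ParseError(f"cannot determine interval dialect from row {fields}")


def write_gene_intervals(intervals: list[GeneInterval], path: str | Path,
                         dialect: str = "native") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "native":
            fh.write("#gene\tchrom\tstart\tend\n")
            for iv in intervals:
                fh.write(f"{iv.gene}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        elif dialect == "bed":
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


MISSING_GENOTYPE = "--"


def read_genotype_matrix(path: str | Path, meta_path: str | Path) -> GenotypeMatrix:
    """Read a genotype table plus its sample-metadata sidecar.

    The genotype table is tab-separated: a ``#alleles`` line declaring each
    locus' normal/mutant pair (e.g. ``G/C``), then a header row
    ``sample_id LOCUS1 LOCUS2 ...`` and one row per individual with raw
    two-letter genotypes (``GG``, ``GC``, ...) or ``--`` for missing.  The
    sidecar is ``sample_id breed age_months`` and supplies breed labels.
    """
    path, meta_path = Path(path), Path(meta_path)
    breed_of: dict[str, str] = {}
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            breed_of[fields[0]] = fields[1]

    alleles: list[tuple[str, str]] | None = None
    loci: list[str] | None = None
    individuals: list[str] = []
    breeds: list[str] = []
    genotypes: list[list[str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#alleles":
                alleles = []
                for pair in fields[1:]:
                    a, b = pair.split("/")
                    alleles.append((a.upper(), b.upper()))
                continue
            if line.startswith("#"):
                continue
            if loci is None:
                loci = fields[1:]
                continue
            if alleles is None:
                raise ParseError(f"{path}: missing #alleles declaration")
            sid = fields[0]
            if sid not in breed_of:
                raise ParseError(f"{path}:{lineno}: sample {sid!r} absent from sidecar")
            row: list[str | None] = []
            for j, raw in enumerate(fields[1:]):
                row.append(_code_genotype(raw, alleles[j], path, lineno))
            individuals.append(sid)
            breeds.append(breed_of[sid])
            genotypes.append(row)
    if loci is None or alleles is None:
        raise ParseError(f"{path}: empty genotype table")
    return GenotypeMatrix(individuals, breeds, loci, alleles, genotypes)


def _code_genotype(raw: str, pair: tuple[str, str], path: Path, lineno: int) -> str | None:
    raw = raw.strip().upper()
    if raw in (MISSING_GENOTYPE, "", "NA"):
        return None
    if len(raw) != 2:
        raise ParseError(f"{path}:{lineno}: bad genotype {raw!r}")
    normal, mutant = pair
    a, b = sorted(raw)
    if {a, b} - {normal, mutant}:
        raise ParseError(
            f"{path}:{lineno}: genotype {raw!r} uses alleles outside {pair}"
        )
    if a == b:
        return "AA" if a == normal else "BB"
    return "AB"


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path,
                          meta_path: str | Path) -> None:
    """Inverse of :func:`read_genotype_matrix` (raw allele spelling restored)."""
    with open(meta_path, "w") as fh:
        fh.write("#sample_id\tbreed\tage_months\n")
        for sid, breed in zip(gm.individuals, gm.breeds):
            fh.write(f"{sid}\t{breed}\t0\n")
    with open(path, "w") as fh:
        fh.write("#alleles\t" + "\t".join(f"{a}/{b}" for a, b in gm.alleles) + "\n")
        fh.write("sample_id\t" + "\t".join(gm.loci) + "\n")
        for sid, row in zip(gm.individuals, gm.genotypes):
            cells = []
            for g, (normal, mutant) in zip(row, gm.alleles):
                if g is None:
                    cells.append(MISSING_GENOTYPE)
                elif g == "AA":
                    cells.append(normal * 2)
                elif g == "BB":
                    cells.append(mutant * 2)
                else:
                    cells.append(normal + mutant)
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
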