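"""SNP hit counting inside candidate-gene / QTL intervals.

A filtered call hits a gene when it falls on the same (normalized) chromosome
and its position lies inside the gene's 1-based inclusive interval; overlapping
genes each receive the hit.  Counts are grouped per breed and age from the
cohort metadata, and genes are ranked by total hits.

Two counting modes are exported because per-age hit tables can be read either
way: ``call`` counts call-level events (the same site seen in k samples adds
k), ``distinct_site`` counts unique sites per (gene, breed, age) cell.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .model import GeneInterval, SnpDb


@dataclass
class GeneHitTable:
    """Hit counts per (gene, breed, age) plus per-gene totals."""

    genes: list[str]
    cells: dict[tuple[str, str, int], int] = field(default_factory=dict)

    def total(self, gene: str) -> int:
        return sum(c for (g, _b, _a), c in self.cells.items() if g == gene)

    def breed_total(self, gene: str, breed: str) -> int:
        return sum(c for (g, b, _a), c in self.cells.items()
                   if g == gene and b == breed)

    def totals(self) -> dict[str, int]:
        out = dict.fromkeys(self.genes, 0)
        for (g, _b, _a), c in self.cells.items():
            out[g] += c
        return out


def count_hits(db: SnpDb, intervals: list[GeneInterval],
               mode: str = "call") -> GeneHitTable:
    """Count SNP hits of *db* inside *intervals*, grouped by breed and age.

    ``mode="call"`` counts one hit per call; ``mode="distinct_site"`` counts
    each distinct site once per (gene, breed, age) cell.
    """
    if mode not in ("call", "distinct_site"):
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        # intervaltree is half-open; [start, end] inclusive -> [start, end+1)
        trees[iv.chrom].addi(iv.start, iv.end + 1, iv.gene)

    cells: dict[tuple[str, str, int], int] = defaultdict(int)
    seen: set[tuple[str, str, int, tuple[str, int, str]]] = set()
    for call in db:
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        meta = db.samples[call.sample_id]
        for hit in tree.at(call.pos):
            key = (hit.data, meta.breed, meta.age_months)
            if mode == "distinct_site":
                dedup = key + (call.site_key,)
                if dedup in seen:
                    continue
                seen.add(dedup)
            cells[key] += 1
    return GeneHitTable(genes=[iv.gene for iv in intervals], cells=dict(cells))


def rank_genes(table: GeneHitTable, top_n: int) -> list[tuple[str, int]]:
    """Genes by total hits, descending; ties broken alphabetically."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    totals = table.totals()
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]
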