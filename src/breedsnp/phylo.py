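"""Sample-level SNP phylogeny: presence distances, neighbor joining, bootstrap.

Per-sample SNP databases are presence/allele call sets, not genotypes, so the
pairwise distance is the Hamming fraction between site-presence vectors over
the union of filtered sites.  Trees are built with classical neighbor joining
(exact on additive distances), branch support comes from bootstrap resampling
of sites, and breed cohesion is checked as monophyly of each breed's leaves on
the unrooted tree.  This distance-based route replaces likelihood tree search:
it is deterministic, fast at cohort scale, and sufficient to test whether
samples cluster by breed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SampleMeta, SiteKey, SnpDb


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class Node:
    """Tree node; ``length`` is the edge above, ``support`` a bootstrap percent."""

    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}


@dataclass
class PhyloTree:
    """Unrooted tree, represented with a basal trifurcation (or star)."""

    root: Node

    def leaf_names(self) -> set[str]:
        return self.root.leaf_names()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side that does
        not contain the alphabetically first leaf."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below = set()
            for child in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(frozenset(side if anchor not in side
                                      else all_leaves - side))
                below |= side
            return below

        walk(self.root)
        return out

    def internal_edges(self) -> list[Node]:
        """Nodes whose parent edge is an internal (non-trivial) edge."""
        n = len(self.leaf_names())
        out = []

        def walk(node: Node, is_root: bool) -> None:
            for child in node.children:
                if not child.is_leaf:
                    size = len(child.leaf_names())
                    if 2 <= size <= n - 2:
                        out.append(child)
                walk(child, False)

        walk(self.root, True)
        return out

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.10g}"
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def parse_newick(text: str) -> PhyloTree:
    """Parse newick with branch lengths and numeric internal support labels."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        label = _take(lambda ch: ch not in ":,()")
        if label:
            if node.is_leaf:
                node.name = label
            else:
                node.support = float(label)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = float(_take(lambda ch: ch not in ",()"))
        return node

    def _take(pred) -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and pred(s[pos]):
            pos += 1
        return s[start:pos]

    return PhyloTree(root=parse_node())


# --------------------------------------------------------------------------

def presence_matrix(db: SnpDb, universe: list[SiteKey] | None = None
                    ) -> tuple[list[str], list[SiteKey], np.ndarray]:
    """Samples x sites boolean carriage matrix over *universe* (default: union)."""
    sids = list(db.samples)
    sites = sorted(universe) if universe is not None else sorted(db.site_keys())
    index = {site: j for j, site in enumerate(sites)}
    mat = np.zeros((len(sids), len(sites)), dtype=bool)
    row = {sid: i for i, sid in enumerate(sids)}
    for call in db:
        j = index.get(call.site_key)
        if j is not None:
            mat[row[call.sample_id], j] = True
    return sids, sites, mat


def snp_distance(db: SnpDb, universe: list[SiteKey] | None = None) -> DistanceMatrix:
    """Pairwise Hamming fraction of site-presence vectors; values in [0, 1]."""
    if len(db.samples) < 3:
        raise ValueError("need at least 3 samples for a phylogeny")
    sids, sites, mat = presence_matrix(db, universe)
    if not sites:
        raise ValueError("empty site universe")
    return DistanceMatrix(ids=sids, values=_hamming(mat))


def _hamming(mat: np.ndarray) -> np.ndarray:
    x = mat.astype(np.float64)
    same11 = x @ x.T
    same00 = (1 - x) @ (1 - x).T
    d = 1.0 - (same11 + same00) / mat.shape[1]
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ: Q-matrix minimization with deterministic tie-breaking.

    Ties pick the smallest (i, j) index pair.  A negative branch length is
    clamped to zero and the deficit moved to the sister edge so path lengths
    within the joined cherry are preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.values.copy()
    nodes: list[Node] = [Node(name=s) for s in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i][j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i][j] - li
        li, lj = _clamp_pair(li, lj)
        parent = Node()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the remainder
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k not in (i, j):
                new_row[k] = 0.5 * (d[i][k] + d[j][k] - d[i][j])
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0).reshape(-1, 1)])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    # three-point formulas for the final trifurcation
    li = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    lj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    lk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    root = Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, length)
        root.children.append(nodes[idx])
    return PhyloTree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def bootstrap_support(db: SnpDb, replicates: int = 100, seed: int = 0,
                      universe: list[SiteKey] | None = None) -> PhyloTree:
    """NJ tree with per-internal-edge bootstrap support (percent of replicates).

    Sites are resampled with replacement; each replicate rebuilds distances
    and the NJ tree; support for an edge is the percentage of replicate trees
    containing the same bipartition.  Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sids, sites, mat = presence_matrix(db, universe)
    if not sites:
        raise ValueError("empty site universe")
    tree = neighbor_joining(DistanceMatrix(ids=sids, values=_hamming(mat)))

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    n_sites = mat.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep_tree = neighbor_joining(
            DistanceMatrix(ids=sids, values=_hamming(mat[:, cols]))
        )
        for split in rep_tree.splits():
            counts[split] = counts.get(split, 0) + 1

    anchor = min(tree.leaf_names())
    all_leaves = tree.leaf_names()
    for node in tree.internal_edges():
        side = node.leaf_names()
        split = frozenset(side if anchor not in side else all_leaves - side)
        node.support = 100.0 * counts.get(split, 0) / replicates
    return tree


def is_breed_monophyletic(tree: PhyloTree, meta: dict[str, str] | list[SampleMeta]
                          ) -> dict[str, bool]:
    """Whether each breed's leaves form a bipartition of the unrooted tree."""
    if not isinstance(meta, dict):
        meta = {m.sample_id: m.breed for m in meta}
    leaves = tree.leaf_names()
    breeds: dict[str, set[str]] = {}
    for sid, breed in meta.items():
        breeds.setdefault(breed, set()).add(sid)
    for breed, members in breeds.items():
        if not members <= leaves:
            raise ValueError(f"breed {breed!r} has samples missing from the tree")
    splits = tree.splits()
    anchor = min(leaves)
    out = {}
    for breed, members in breeds.items():
        if len(members) <= 1 or len(members) >= len(leaves) - 1:
            out[breed] = True
        else:
            canon = frozenset(members if anchor not in members else leaves - members)
            out[breed] = canon in splits
    return out
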