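"""Distance-based phylogenetics: identity distances, neighbor joining,
most-divergent-leaf rooting, and column-resampling bootstrap.

Trees here orient gene lineages (which member is basal, which pairs are
sisters); absolute branch lengths are secondary.  Distances are uncorrected
identity distances (1 - identity fraction) by default, with an optional
Poisson correction.  Externally computed Newick trees can be substituted
wherever a tree is consumed.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .simnet import SimilarityNetwork

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered id list."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def index(self, gene_id: str) -> int:
        return self.ids.index(gene_id)

    def mean_distance(self, gene_id: str) -> float:
        i = self.index(gene_id)
        n = len(self.ids)
        if n < 2:
            return 0.0
        return float(self.d[i].sum() / (n - 1))


def distances_from_hits(
    net: SimilarityNetwork,
    members: Iterable[str],
    poisson_correct: bool = False,
) -> DistanceMatrix:
    """Identity distances (1 - identity fraction) from best pairwise hits.

    A pair with no network edge gets the maximal observed distance plus a
    small epsilon (logged).  ``poisson_correct`` applies d = -ln(1 - p).
    """
    ids = sorted(members)
    if len(ids) < 2:
        raise ValueError("need at least 2 members")
    missing_nodes = [m for m in ids if m not in net]
    if missing_nodes:
        raise KeyError(f"members absent from network: {missing_nodes[:5]}")
    n = len(ids)
    d = np.zeros((n, n))
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            data = net.edge(ids[i], ids[j])
            if data is None:
                missing.append((i, j))
            else:
                d[i, j] = d[j, i] = 1.0 - data["identity_pct"] / 100.0
    if missing:
        filler = d.max() + 0.05
        logger.info(
            "%d member pairs have no direct hit; distance set to %.3f",
            len(missing), filler,
        )
        for i, j in missing:
            d[i, j] = d[j, i] = filler
    if poisson_correct:
        p = np.clip(d, 0.0, 0.999)
        d = -np.log1p(-p)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, d=d)


# -- neighbor joining -----------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei Q-criterion).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, so path lengths through each cherry are preserved.
    Additive matrices are recovered exactly.  The returned tree is unrooted
    (trifurcating root node); ties in the Q matrix break toward the
    lexicographically smallest pair for determinism.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")

    taxon_namespace = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: dict[str, dendropy.Node] = {}
    for gid in dm.ids:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(gid))
        nodes[gid] = node

    active = list(dm.ids)
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, n):
            b = dm.ids[j]
            dist[_key(a, b)] = float(dm.d[i, j])

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[_key(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dist[_key(a, b)] - r[a] - r[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        dab = dist[_key(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        parent = dendropy.Node()
        parent.label = f"nj{counter}"
        counter += 1
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new_id = parent.label
        nodes[new_id] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[_key(new_id, c)] = 0.5 * (
                dist[_key(a, c)] + dist[_key(b, c)] - dab
            )
        active = [c for c in active if c not in (a, b)] + [new_id]

    # join the last three nodes at the (unrooted) root
    a, b, c = active
    la = 0.5 * (dist[_key(a, b)] + dist[_key(a, c)] - dist[_key(b, c)])
    lb = 0.5 * (dist[_key(a, b)] + dist[_key(b, c)] - dist[_key(a, c)])
    lc = 0.5 * (dist[_key(a, c)] + dist[_key(b, c)] - dist[_key(a, b)])
    root = dendropy.Node()
    for leaf_id, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[leaf_id])
        nodes[leaf_id].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def path_length_matrix(tree: dendropy.Tree, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf patristic distances in the order of *ids*."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out


# -- rooting --------------------------------------------------------------


def root_by_most_divergent(
    tree: dendropy.Tree, dm: DistanceMatrix
) -> dendropy.Tree:
    """Re-root on the pendant edge of the most divergent leaf.

    The outgroup is the leaf with maximal mean distance to all other
    members (ties break lexicographically), mirroring the practice of
    rooting a family tree on its most dissimilar sequence.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    extra = leaf_labels - set(dm.ids)
    if extra:
        raise ValueError(f"tree leaves missing from distance matrix: {sorted(extra)[:5]}")
    best = min(
        (lbl for lbl in dm.ids if lbl in leaf_labels),
        key=lambda lbl: (-dm.mean_distance(lbl), lbl),
    )
    tree = tree.clone(depth=1)
    leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == best
    )
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=True,
                        suppress_unifurcations=True)
    return tree


# -- bootstrap ------------------------------------------------------------


def read_alignment(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> {id: row}; all rows must be equal length."""
    from Bio import SeqIO

    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
    return aln


def p_distance_matrix(aln: Mapping[str, str], ids: Sequence[str]) -> DistanceMatrix:
    """Pairwise p-distances over columns where both rows are residues."""
    mats = np.array([list(aln[i]) for i in ids])
    gap = (mats == "-") | (mats == ".")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                d[i, j] = d[j, i] = 1.0
            else:
                diff = int((mats[i][ok] != mats[j][ok]).sum())
                d[i, j] = d[j, i] = diff / total
    return DistanceMatrix(ids=list(ids), d=d)


def bootstrap_support(
    members: Sequence[str],
    alignment: Mapping[str, str] | str | Path,
    B: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree from the full alignment with column-resampling supports.

    Each of B replicates resamples alignment columns with replacement,
    rebuilds an NJ tree, and every internal bipartition of the reference
    tree is scored by the fraction of replicates containing it.  Supports
    are stored as ``node.support`` (floats in [0, 1]) and as internal node
    labels.  Requires an alignment: supports cannot be computed from a hit
    table, which has no columns to resample.
    """
    if not isinstance(alignment, Mapping):
        alignment = read_alignment(alignment)
    ids = sorted(members)
    missing = [m for m in ids if m not in alignment]
    if missing:
        raise ValueError(f"alignment lacks members: {missing[:5]}")
    if B < 1:
        raise ValueError("B must be >= 1")
    ncols = len(next(iter(alignment.values())))
    rng = np.random.default_rng(seed)

    ref_tree = nj_tree(p_distance_matrix(alignment, ids))
    ref_biparts = _bipartitions(ref_tree, ids)

    counts = {bp: 0 for bp in ref_biparts}
    rows = {i: np.array(list(alignment[i])) for i in ids}
    for _ in range(B):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = {i: "".join(rows[i][cols]) for i in ids}
        rep_tree = nj_tree(p_distance_matrix(resampled, ids))
        rep_biparts = _bipartitions(rep_tree, ids)
        for bp in ref_biparts:
            if bp in rep_biparts:
                counts[bp] += 1

    for node in ref_tree.preorder_internal_node_iter():
        if node is ref_tree.seed_node:
            continue
        bp = _node_bipartition(node, ids)
        support = counts.get(bp, 0) / B
        node.support = support
        node.label = f"{support:.3f}"
    return ref_tree


def _node_bipartition(node: dendropy.Node, ids: Sequence[str]) -> frozenset:
    below = frozenset(lf.taxon.label for lf in node.leaf_iter())
    ref = min(ids)
    if ref in below:
        below = frozenset(ids) - below
    return below


def _bipartitions(tree: dendropy.Tree, ids: Sequence[str]) -> set[frozenset]:
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        bp = _node_bipartition(node, ids)
        if 0 < len(bp) < len(ids):
            out.add(bp)
    return out


# -- newick IO ------------------------------------------------------------


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    src = str(path_or_string)
    if src.lstrip().startswith("(") or src.rstrip().endswith(";"):
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
    return path
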