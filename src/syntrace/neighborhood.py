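"""Gene-neighborhood extraction and microsynteny scoring.

For every family gene a block of up to k neighbors on each side (default 15,
i.e. a 30-gene chromosome block) is extracted.  Neighbors are classified
into sequence clusters at a conservative e-value threshold (default E-50),
and a pair of family genes is connected by a synteny edge when their blocks
share neighbors from common clusters.

Three evidence sources weight each matched neighbor pair:

1. distance of the neighbors from the query genes (closer is stronger),
2. amino-acid similarity of the matched neighbors,
3. size of the sequence cluster the neighbors belong to (small clusters are
   more reliable: the probability that two members of a small family flank
   both query genes by chance is low).

The per-pair weight is the product ``w_dist * w_sim * w_clu`` with

* ``w_dist = ((k - offset_a + 1) + (k - offset_b + 1)) / (2k)``,
* ``w_sim`` = identity fraction between the matched neighbors (1.0 when the
  network has no direct edge, logged),
* ``w_clu = 1 / (1 + log10(cluster_size))``.

Edge strength is the sum of weights; the category is ``strong`` at
``strong_min`` (default 5) or more matched pairs, ``weak`` below that,
``none`` at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .family import FamilyResult
from .genome_db import GenomeSet, neighbors_on_contig
from .simnet import ClusterAssignment, SimilarityNetwork, cluster_at

logger = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_STRONG_MIN = 5
DEFAULT_CLUSTER_T = 1e-50
DEFAULT_FALLBACK_T = 1e-40

CATEGORY_NONE = "none"
CATEGORY_WEAK = "weak"
CATEGORY_STRONG = "strong"


class UnassignedNeighborError(KeyError):
    """A block neighbor has no cluster assignment at the working threshold."""


@dataclass
class NeighborBlock:
    """Ordered up/downstream neighbors of a query gene with contig-end flags."""

    query: str
    upstream: list[tuple[str, int]]  # (gene_id, offset 1..k) nearest-first
    downstream: list[tuple[str, int]]
    end_upstream: bool  # contig end within k genes upstream
    end_downstream: bool

    def neighbors(self) -> list[tuple[str, int]]:
        return self.upstream + self.downstream


@dataclass
class SyntenyMatch:
    neighbor_a: str
    neighbor_b: str
    cluster_id: str
    offset_a: int
    offset_b: int
    identity_pct: float
    cluster_size: int
    weight: float


@dataclass
class SyntenyEdge:
    """Shared-neighbor evidence between two family genes."""

    gene_a: str
    gene_b: str
    matches: list[SyntenyMatch]
    raw_count: int
    strength: float
    category: str
    evidence_level: str = "E-50"


@dataclass
class SyntenyWeights:
    """Tunable scoring parameters (defaults follow the module docstring)."""

    k: int = DEFAULT_K
    strong_min: int = DEFAULT_STRONG_MIN


def build_block(gs: GenomeSet, gene_id: str, k: int = DEFAULT_K) -> NeighborBlock:
    """Neighbor block around *gene_id*: up to k genes on each side."""
    up, down = neighbors_on_contig(gs, gene_id, k)
    return NeighborBlock(
        query=gene_id,
        upstream=[(l.gene_id, i + 1) for i, l in enumerate(up)],
        downstream=[(l.gene_id, i + 1) for i, l in enumerate(down)],
        end_upstream=len(up) < k,
        end_downstream=len(down) < k,
    )


def score_synteny(
    block_a: NeighborBlock,
    block_b: NeighborBlock,
    clusters: ClusterAssignment,
    net: SimilarityNetwork,
    weights_cfg: SyntenyWeights | None = None,
) -> SyntenyEdge:
    """Match shared-cluster neighbor pairs one-to-one and weight them.

    Matching is greedy per cluster by ascending offset sum, so conservation
    close to the query genes is credited first and one large cluster cannot
    claim more matches than it has members in the smaller block.  The two
    query genes themselves never count as shared neighbors.
    """
    cfg = weights_cfg or SyntenyWeights()
    queries = {block_a.query, block_b.query}

    by_cluster_a: dict[str, list[tuple[str, int]]] = {}
    by_cluster_b: dict[str, list[tuple[str, int]]] = {}
    for block, acc in ((block_a, by_cluster_a), (block_b, by_cluster_b)):
        for gene_id, offset in block.neighbors():
            if gene_id in queries:
                continue
            try:
                cid = clusters.cluster_of(gene_id)
            except KeyError:
                raise UnassignedNeighborError(
                    f"neighbor {gene_id!r} of {block.query!r} has no cluster "
                    f"assignment at threshold {clusters.threshold:g}"
                ) from None
            acc.setdefault(cid, []).append((gene_id, offset))

    matches: list[SyntenyMatch] = []
    for cid in sorted(set(by_cluster_a) & set(by_cluster_b)):
        size = clusters.sizes[cid]
        cands = sorted(
            (oa + ob, oa, ob, ga, gb)
            for ga, oa in by_cluster_a[cid]
            for gb, ob in by_cluster_b[cid]
        )
        used_a: set[str] = set()
        used_b: set[str] = set()
        for _, oa, ob, ga, gb in cands:
            if ga in used_a or gb in used_b:
                continue
            used_a.add(ga)
            used_b.add(gb)
            if ga == gb:
                # the two queries flank the same physical gene (nearby loci
                # on one contig): strongest possible shared-neighbor evidence
                identity_pct = 100.0
            else:
                edge = net.edge(ga, gb)
                if edge is None:
                    identity_pct = 100.0
                    logger.debug(
                        "no direct network edge %s--%s; similarity weight 1.0",
                        ga, gb,
                    )
                else:
                    identity_pct = edge["identity_pct"]
            w_dist = ((cfg.k - oa + 1) + (cfg.k - ob + 1)) / (2.0 * cfg.k)
            w_sim = identity_pct / 100.0
            w_clu = 1.0 / (1.0 + math.log10(size))
            matches.append(
                SyntenyMatch(
                    neighbor_a=ga,
                    neighbor_b=gb,
                    cluster_id=cid,
                    offset_a=oa,
                    offset_b=ob,
                    identity_pct=identity_pct,
                    cluster_size=size,
                    weight=w_dist * w_sim * w_clu,
                )
            )

    raw_count = len(matches)
    strength = sum(m.weight for m in matches)
    if raw_count == 0:
        category = CATEGORY_NONE
    elif raw_count >= cfg.strong_min:
        category = CATEGORY_STRONG
    else:
        category = CATEGORY_WEAK
    return SyntenyEdge(
        gene_a=block_a.query,
        gene_b=block_b.query,
        matches=matches,
        raw_count=raw_count,
        strength=strength,
        category=category,
    )


def synteny_network(
    fam: FamilyResult,
    gs: GenomeSet,
    net: SimilarityNetwork,
    cluster_t: float = DEFAULT_CLUSTER_T,
    fallback_t: float = DEFAULT_FALLBACK_T,
    k: int = DEFAULT_K,
    strong_min: int = DEFAULT_STRONG_MIN,
) -> list[SyntenyEdge]:
    """All-vs-all synteny edges among unflagged family members.

    Neighbors are clustered at the conservative threshold first.  Pairs that
    score ``none`` there but whose blocks both contain neighbors left
    unclustered (singletons) at the conservative threshold are rescored with
    clustering at the permissive fallback threshold; edges recovered that way
    carry ``evidence_level == "E-40"`` as corroboration-level evidence.
    """
    if not fam.members:
        raise ValueError("family is empty")
    members = sorted(fam.analysis_members())
    cfg = SyntenyWeights(k=k, strong_min=strong_min)
    blocks = {m: build_block(gs, m, k=k) for m in members}
    neighbor_ids = sorted(
        {g for b in blocks.values() for g, _ in b.neighbors() if g in net}
    )
    # genes absent from the network (no hits at all) still need an assignment
    absent = [
        g
        for b in blocks.values()
        for g, _ in b.neighbors()
        if g not in net
    ]
    clusters = cluster_at(net, cluster_t, include=neighbor_ids)
    for g in absent:
        clusters.member_map.setdefault(g, f"s_{g}")
        clusters.sizes.setdefault(f"s_{g}", 1)

    fallback_clusters: ClusterAssignment | None = None
    edges: list[SyntenyEdge] = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            edge = score_synteny(blocks[a], blocks[b], clusters, net, cfg)
            if edge.category == CATEGORY_NONE and _has_unclustered(
                blocks[a], clusters
            ) and _has_unclustered(blocks[b], clusters):
                if fallback_clusters is None:
                    fallback_clusters = cluster_at(
                        net, fallback_t, include=neighbor_ids
                    )
                    for g in absent:
                        fallback_clusters.member_map.setdefault(g, f"s_{g}")
                        fallback_clusters.sizes.setdefault(f"s_{g}", 1)
                retry = score_synteny(
                    blocks[a], blocks[b], fallback_clusters, net, cfg
                )
                if retry.category != CATEGORY_NONE:
                    retry.evidence_level = "E-40"
                    edge = retry
            edges.append(edge)
    return edges


def _has_unclustered(block: NeighborBlock, clusters: ClusterAssignment) -> bool:
    return any(
        clusters.sizes.get(clusters.member_map.get(g, f"s_{g}"), 1) == 1
        for g, _ in block.neighbors()
    )


# -- reports --------------------------------------------------------------


def write_neighborhood_report(
    blocks: Iterable[NeighborBlock],
    clusters: ClusterAssignment,
    path: str | Path,
    truncate: int | None = None,
) -> Path:
    """TSV of neighbor blocks (query, side, offset, neighbor, cluster, size).

    ``truncate`` limits the displayed offsets per side (display rule only:
    scoring always uses the full block).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("query\tside\toffset\tneighbor_id\tcluster_id\tcluster_size\n")
        for block in blocks:
            for side, pairs in (("up", block.upstream), ("down", block.downstream)):
                for gene_id, offset in pairs:
                    if truncate is not None and offset > truncate:
                        continue
                    cid = clusters.member_map.get(gene_id, f"s_{gene_id}")
                    size = clusters.sizes.get(cid, 1)
                    fh.write(
                        f"{block.query}\t{side}\t{offset}\t{gene_id}\t{cid}\t{size}\n"
                    )
                if (truncate is None or len(pairs) < truncate) and (
                    block.end_upstream if side == "up" else block.end_downstream
                ):
                    fh.write(
                        f"{block.query}\t{side}\t{len(pairs) + 1}\t0\tCONTIG_END\t0\n"
                    )
    return path


def write_synteny_edges(edges: Iterable[SyntenyEdge], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\traw_count\tstrength\tcategory\tevidence_level\n")
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.raw_count}\t{e.strength:.4f}\t"
                f"{e.category}\t{e.evidence_level}\n"
            )
    return path


def synteny_graph(edges: Iterable[SyntenyEdge]) -> nx.Graph:
    """networkx view of synteny edges (category != none)."""
    g = nx.Graph()
    for e in edges:
        if e.category != CATEGORY_NONE:
            g.add_edge(
                e.gene_a,
                e.gene_b,
                raw_count=e.raw_count,
                strength=e.strength,
                category=e.category,
                evidence_level=e.evidence_level,
            )
    return g
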