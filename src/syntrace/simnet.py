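"""All-vs-all protein similarity network and threshold-derived clusters.

The whole set of pairwise blastp-like relationships is treated as an
undirected graph whose edges carry the best (minimum) e-value of the two
directed hits, plus identity/similarity percentages and the alignment score.
Constraining the graph at an e-value threshold and taking connected
components yields sequence clusters; traversing from a seed yields a
candidate gene family (see :mod:`syntrace.family`).

E-values of exactly zero are floored at ``10**LOG_FLOOR`` so that log-scale
threshold grids behave; the floor is recorded on the network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .genome_db import GenomeSet

logger = logging.getLogger(__name__)

LOG_FLOOR = -180  # exponent substituted for e-value == 0


#: Karlin–Altschul gapped constants for BLOSUM62 with open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041


class HitParseError(ValueError):
    """Malformed row in a tabular hit file."""


@dataclass(frozen=True)
class PairwiseHit:
    """One directed local-alignment hit between two proteins."""

    query_id: str
    subject_id: str
    evalue: float
    identity_pct: float
    similarity_pct: float
    score: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not (0 <= self.identity_pct <= self.similarity_pct <= 100):
            raise ValueError(
                f"require 0 <= identity ({self.identity_pct}) <= similarity "
                f"({self.similarity_pct}) <= 100"
            )


@dataclass
class ClusterAssignment:
    """Partition of network nodes into sequence clusters at one threshold."""

    threshold: float
    member_map: dict[str, str]  # gene_id -> cluster_id
    sizes: dict[str, int]  # cluster_id -> member count

    def cluster_of(self, gene_id: str) -> str:
        return self.member_map[gene_id]

    def is_singleton(self, gene_id: str) -> bool:
        return self.sizes[self.member_map[gene_id]] == 1


class SimilarityNetwork:
    """Undirected best-e-value graph over gene ids.

    Backed by :class:`networkx.Graph`; edge attributes are ``best_evalue``,
    ``identity_pct``, ``similarity_pct`` and ``score``, taken from whichever
    directed hit achieved the minimum e-value.
    """

    def __init__(self, graph: nx.Graph | None = None, log_floor: int = LOG_FLOOR):
        self.graph = graph if graph is not None else nx.Graph()
        self.log_floor = log_floor

    @classmethod
    def from_hits(
        cls,
        hits: Iterable[PairwiseHit],
        nodes: Iterable[str] = (),
        log_floor: int = LOG_FLOOR,
    ) -> "SimilarityNetwork":
        """Symmetrize directed hits: each unordered pair keeps its best hit."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for h in hits:
            if h.query_id == h.subject_id:
                continue
            ev = max(h.evalue, 10.0 ** log_floor)
            g.add_node(h.query_id)
            g.add_node(h.subject_id)
            prev = g.get_edge_data(h.query_id, h.subject_id)
            if prev is None or ev < prev["best_evalue"]:
                g.add_edge(
                    h.query_id,
                    h.subject_id,
                    best_evalue=ev,
                    identity_pct=h.identity_pct,
                    similarity_pct=h.similarity_pct,
                    score=h.score,
                )
        return cls(g, log_floor=log_floor)

    @property
    def nodes(self):
        return self.graph.nodes

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.graph

    def edge(self, a: str, b: str) -> dict | None:
        return self.graph.get_edge_data(a, b)

    def constrain(self, threshold: float) -> "SimilarityNetwork":
        """Subgraph keeping edges with best_evalue <= threshold; all nodes kept."""
        if threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {threshold}")
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(
            (a, b, d)
            for a, b, d in self.graph.edges(data=True)
            if d["best_evalue"] <= threshold
        )
        return SimilarityNetwork(g, log_floor=self.log_floor)


def constrain(net: SimilarityNetwork, threshold: float) -> SimilarityNetwork:
    return net.constrain(threshold)


def cluster_at(
    net: SimilarityNetwork,
    threshold: float,
    include: Iterable[str] = (),
) -> ClusterAssignment:
    """Connected components of the thresholded network as sequence clusters.

    Nodes incident to at least one qualifying edge are grouped by component;
    genes in *include* with no qualifying edge become singleton clusters.
    Cluster ids are deterministic: components are sorted by their
    lexicographically smallest member.
    """
    include = set(include)
    unknown = include - set(net.graph.nodes)
    if unknown:
        raise KeyError(f"include genes absent from network: {sorted(unknown)[:5]}")
    sub = net.constrain(threshold)
    components = [
        sorted(c) for c in nx.connected_components(sub.graph) if len(c) > 1
    ]
    clustered = {g for comp in components for g in comp}
    singles = sorted(g for g in include if g not in clustered)
    member_map: dict[str, str] = {}
    sizes: dict[str, int] = {}
    components.sort(key=lambda c: c[0])
    for i, comp in enumerate(components):
        cid = f"c{i:05d}"
        for g in comp:
            member_map[g] = cid
        sizes[cid] = len(comp)
    for g in singles:
        cid = f"s_{g}"
        member_map[g] = cid
        sizes[cid] = 1
    return ClusterAssignment(threshold=threshold, member_map=member_map, sizes=sizes)


# -- tabular IO -----------------------------------------------------------


#: blast outfmt-6 column order; the optional 13th column is ppos (similarity %).
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def ingest_hits(path: str | Path) -> list[PairwiseHit]:
    """Parse a 12/13-column blast tabular file into directed hits.

    Self-hits (query == subject) are dropped.  A missing ppos column means
    similarity is imputed as identity (with a logged warning, once).
    """
    hits: list[PairwiseHit] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise HitParseError(
                    f"{path}:{lineno}: expected >= 12 columns, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                score = float(fields[11])
                if len(fields) >= 13:
                    ppos = float(fields[12])
                else:
                    ppos = pident
                    if not warned:
                        logger.warning(
                            "%s: no ppos column; similarity imputed as identity",
                            path,
                        )
                        warned = True
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from None
            if qid == sid:
                continue
            hits.append(
                PairwiseHit(
                    query_id=qid,
                    subject_id=sid,
                    evalue=evalue,
                    identity_pct=pident,
                    similarity_pct=max(pident, ppos),
                    score=score,
                    aln_length=length,
                )
            )
    return hits


def write_hits(hits: Iterable[PairwiseHit], path: str | Path) -> Path:
    """Emit hits as 13-column tabular (outfmt-6 plus ppos)."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t"
                f"{h.aln_length}\t0\t0\t1\t{h.aln_length}\t1\t{h.aln_length}\t"
                f"{h.evalue:.3g}\t{h.score:.1f}\t{h.similarity_pct:.2f}\n"
            )
    return path


def export_edge_list(net: SimilarityNetwork, path: str | Path) -> Path:
    """TSV with one row per undirected edge."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tbest_evalue\tidentity_pct\tsimilarity_pct\n")
        for a, b, d in sorted(net.graph.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{d['best_evalue']:.3g}\t"
                f"{d['identity_pct']:.2f}\t{d['similarity_pct']:.2f}\n"
            )
    return path


def read_edge_list(path: str | Path) -> SimilarityNetwork:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            a, b, ev, ident, sim = line.rstrip("\n").split("\t")
            g.add_edge(
                a,
                b,
                best_evalue=float(ev),
                identity_pct=float(ident),
                similarity_pct=float(sim),
                score=0.0,
            )
    return SimilarityNetwork(g)


def export_graphml(net: SimilarityNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(net.graph, str(path))
    return path


# -- in-package alignment -------------------------------------------------


@dataclass
class AlignmentParams:
    """Local-alignment parameters for :func:`compute_hits`.

    BLOSUM62 with affine gaps (open 11, extend 1) and gapped Karlin–Altschul
    constants; ``score_floor`` drops alignments whose raw score cannot give a
    meaningful e-value.
    """

    open_gap: int = 11
    extend_gap: int = 1
    matrix: str = "BLOSUM62"
    score_floor: float = 40.0
    evalue_ceiling: float = 10.0


def compute_hits(
    gs: GenomeSet, params: AlignmentParams | None = None
) -> list[PairwiseHit]:
    """Smith–Waterman all-vs-all hits with Karlin–Altschul e-values.

    The e-value uses the standard database search space: for a query of
    length m against a set with N total residues, ``E = K * m * N *
    exp(-lambda * S)``.  Identity/similarity percentages are measured over
    aligned columns (similarity counts positive substitution-matrix scores).
    Intended for small synthetic sets; externally computed tabular hits are
    the primary path for real data.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    params = params or AlignmentParams()
    loci = [l for l in gs.loci()]
    if len(loci) < 2:
        raise ValueError("need at least 2 loci to compute hits")
    matrix = substitution_matrices.load(params.matrix)
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        open_gap_score=-params.open_gap,
        extend_gap_score=-params.extend_gap,
    )
    total_residues = sum(len(l.protein) for l in loci)
    hits: list[PairwiseHit] = []
    alphabet = set(str(a) for a in matrix.alphabet)
    for i, qa in enumerate(loci):
        if not qa.protein:
            logger.warning("skipping empty sequence %s", qa.gene_id)
            continue
        for qb in loci[i + 1 :]:
            if not qb.protein:
                continue
            sa = "".join(c if c in alphabet else "X" for c in qa.protein.upper())
            sb = "".join(c if c in alphabet else "X" for c in qb.protein.upper())
            alns = aligner.align(sa, sb)
            if len(alns) == 0:
                continue
            aln = alns[0]
            score = aln.score
            if score < params.score_floor:
                continue
            ident, simil, cols = _alignment_stats(aln, matrix)
            if cols == 0:
                continue
            ev = karlin_altschul_evalue(score, len(sa), total_residues)
            if ev > params.evalue_ceiling:
                continue
            for q, s in ((qa, qb), (qb, qa)):
                hits.append(
                    PairwiseHit(
                        query_id=q.gene_id,
                        subject_id=s.gene_id,
                        evalue=ev,
                        identity_pct=100.0 * ident / cols,
                        similarity_pct=100.0 * simil / cols,
                        score=score,
                        aln_length=cols,
                    )
                )
    return hits


def karlin_altschul_evalue(
    score: float, m: int, n_total: int, lam: float = KA_LAMBDA, k: float = KA_K
) -> float:
    """E = K * m * N * exp(-lambda * S); decreasing in S at fixed space."""
    log10_e = math.log10(k) + math.log10(m) + math.log10(n_total) - lam * score / math.log(10)
    return 10.0 ** max(log10_e, LOG_FLOOR)


def _alignment_stats(aln, matrix) -> tuple[int, int, int]:
    """(identities, positives, aligned columns) over an alignment's blocks."""
    ident = simil = cols = 0
    a, b = aln[0], aln[1]
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        cols += 1
        if ca == cb:
            ident += 1
            simil += 1
        elif matrix[ca, cb] > 0:
            simil += 1
    return ident, simil, cols
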