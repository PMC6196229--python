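"""Sub-lineage partitioning and duplication-timing scenarios.

Family genes connected by synteny edges form sub-lineages, interpreted as
descendants of one ancestral locus.  Per-species copy counts of each
sub-lineage, laid over a species tree whose whole-genome-duplication (WGD)
branch is marked, let alternative duplication placements be compared by the
gene losses they imply:

* ``implied_species_losses`` — extant species descending from the candidate
  duplication branch that lack the sub-lineage (the per-species argument);
* ``implied_dollo_losses`` — the minimal number of branches whose loss
  explains every absence, assuming the gene is gained once on the
  duplication branch and never regained (Dollo parsimony).

``event_total = 1 (duplication) + implied_dollo_losses`` ranks scenarios:
fewer total events is more parsimonious, ties go to the more recent branch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .genome_db import GenomeSet
from .neighborhood import CATEGORY_NONE, SyntenyEdge
from .simnet import SimilarityNetwork

logger = logging.getLogger(__name__)

LABEL_SINGLETON = "singleton"
LABEL_TANDEM = "tandem"
LABEL_FRAGMENT = "fragment"


class DegenerateScenarioError(ValueError):
    """The sub-lineage is absent from every species under the branch."""


# -- species tree ---------------------------------------------------------


class SpeciesTree:
    """Rooted species tree with an optional WGD-marked branch.

    Leaves are species codes; a branch is identified by its head node (the
    node below the branch).  The WGD branch can be selected by internal
    node label or by the set of species whose MRCA heads it.
    """

    def __init__(self, tree: dendropy.Tree, wgd_node: dendropy.Node | None = None):
        self.tree = tree
        self.wgd_node = wgd_node
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("species codes must be unique")

    @classmethod
    def from_newick(
        cls,
        newick: str | Path,
        wgd: str | Iterable[str] | None = None,
    ) -> "SpeciesTree":
        src = str(newick)
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(
                data=src, schema="newick",
                suppress_internal_node_taxa=False,
            )
        else:
            tree = dendropy.Tree.get(
                path=src, schema="newick",
                suppress_internal_node_taxa=False,
            )
        tree.is_rooted = True
        st = cls(tree)
        if wgd is not None:
            st.wgd_node = st.find_branch(wgd)
        return st

    def find_branch(self, spec: str | Iterable[str]) -> dendropy.Node:
        """Resolve a branch by internal node label or by a leaf set (MRCA)."""
        if isinstance(spec, str):
            for node in self.tree.preorder_node_iter():
                if _node_label(node) == spec:
                    return node
            spec = spec.split(",")
        labels = sorted(spec)
        mrca = self.tree.mrca(taxon_labels=labels)
        if mrca is None:
            raise KeyError(f"no branch for species {labels}")
        return mrca

    def species(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def depth(self, node: dendropy.Node) -> int:
        d = 0
        while node.parent_node is not None:
            node = node.parent_node
            d += 1
        return d

    def path_down(
        self, ancestor: dendropy.Node, descendant: dendropy.Node
    ) -> list[dendropy.Node] | None:
        """Nodes from *ancestor* to *descendant* inclusive, or None."""
        path = [descendant]
        node = descendant
        while node is not ancestor:
            node = node.parent_node
            if node is None:
                return None
            path.append(node)
        return path[::-1]


def _node_label(node: dendropy.Node) -> str | None:
    if node.label:
        return node.label
    if node.taxon is not None:
        return node.taxon.label
    return None


def branch_name(node: dendropy.Node, st: SpeciesTree) -> str:
    label = _node_label(node)
    if label:
        return label
    return "|".join(sorted(st.leaves_under(node)))


# -- lineage graph --------------------------------------------------------


@dataclass
class LineageGraph:
    """Family genes partitioned into synteny-connected sub-lineages."""

    graph: nx.Graph
    sublineage: dict[str, str]  # gene_id -> sublineage_id
    labels: dict[str, set[str]] = field(default_factory=dict)

    def add_label(self, gene_id: str, label: str) -> None:
        self.labels.setdefault(gene_id, set()).add(label)

    def sublineage_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene_id, sl in self.sublineage.items():
            out.setdefault(sl, []).append(gene_id)
        for members in out.values():
            members.sort()
        return out


def partition_sublineages(
    edges: Iterable[SyntenyEdge],
    members: Iterable[str],
    fragments: Iterable[str] = (),
) -> LineageGraph:
    """Connected components over synteny edges (category >= weak).

    Isolated members become singleton sub-lineages with the ``singleton``
    label.  *fragments* are carried as labeled nodes for reporting but are
    excluded from presence counting downstream.
    """
    g = nx.Graph()
    members = sorted(set(members))
    g.add_nodes_from(members)
    for e in edges:
        if e.category == CATEGORY_NONE:
            continue
        if e.gene_a not in g or e.gene_b not in g:
            raise KeyError(
                f"synteny edge {e.gene_a}--{e.gene_b} references non-members"
            )
        g.add_edge(
            e.gene_a, e.gene_b,
            strength=e.strength, raw_count=e.raw_count,
            category=e.category, evidence_level=e.evidence_level,
        )
    lg = LineageGraph(graph=g, sublineage={})
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    for i, comp in enumerate(components):
        sl = f"SL{i:03d}"
        for gene_id in comp:
            lg.sublineage[gene_id] = sl
        if len(comp) == 1:
            lg.add_label(comp[0], LABEL_SINGLETON)
    for frag in sorted(set(fragments)):
        if frag not in lg.sublineage:
            g.add_node(frag)
            lg.sublineage[frag] = f"SLF_{frag}"
        lg.add_label(frag, LABEL_FRAGMENT)
    return lg


def detect_tandem(
    gs: GenomeSet, members: Iterable[str], max_gap: int = 3
) -> set[tuple[str, str]]:
    """Member pairs on one contig within ``max_gap`` positions of each other."""
    by_contig: dict[tuple[str, str], list] = {}
    for m in sorted(set(members)):
        locus = gs.get(m)
        by_contig.setdefault((locus.genome_id, locus.contig_id), []).append(locus)
    pairs: set[tuple[str, str]] = set()
    for loci in by_contig.values():
        loci.sort(key=lambda l: l.position)
        for i, a in enumerate(loci):
            for b in loci[i + 1 :]:
                if b.position - a.position > max_gap:
                    break
                pairs.add(tuple(sorted((a.gene_id, b.gene_id))))
    return pairs


def apply_tandem_labels(
    lg: LineageGraph, pairs: Iterable[tuple[str, str]]
) -> LineageGraph:
    for a, b in pairs:
        for gene_id in (a, b):
            if gene_id in lg.sublineage:
                lg.add_label(gene_id, LABEL_TANDEM)
    return lg


# -- presence matrix ------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Per-species, per-sub-lineage copy counts (pandas DataFrame inside)."""

    table: pd.DataFrame  # index: species_code; columns: sublineage_id; int

    def count(self, species: str, sublineage: str) -> int:
        if species not in self.table.index or sublineage not in self.table.columns:
            return 0
        return int(self.table.loc[species, sublineage])

    def carriers(self, sublineage: str) -> set[str]:
        if sublineage not in self.table.columns:
            return set()
        col = self.table[sublineage]
        return set(col.index[col > 0])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index_label="species_code")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PresenceMatrix":
        table = pd.read_csv(path, sep="\t", index_col="species_code")
        return cls(table=table.astype(int))


def presence_matrix(
    lg: LineageGraph,
    gs: GenomeSet,
    species: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Copy counts per species and sub-lineage, fragments excluded.

    When several strains of one species are present, counts collapse to the
    per-strain maximum (presence/absence arguments are species-level); a
    note is logged when collapsing actually occurs.  *species* optionally
    fixes the row set (listed species without family genes get zero rows).
    """
    per_genome: dict[str, dict[str, int]] = {}
    genome_species: dict[str, str] = {}
    for gene_id, sl in lg.sublineage.items():
        if LABEL_FRAGMENT in lg.labels.get(gene_id, set()):
            continue
        locus = gs.get(gene_id)
        genome_species[locus.genome_id] = locus.species_code
        per_genome.setdefault(locus.genome_id, {}).setdefault(sl, 0)
        per_genome[locus.genome_id][sl] += 1

    sublineages = sorted({sl for counts in per_genome.values() for sl in counts})
    species_rows: dict[str, dict[str, int]] = {}
    strains_per_species: dict[str, int] = {}
    for genome_id, counts in per_genome.items():
        sp = genome_species[genome_id]
        strains_per_species[sp] = strains_per_species.get(sp, 0) + 1
        row = species_rows.setdefault(sp, {})
        for sl, c in counts.items():
            row[sl] = max(row.get(sl, 0), c)
    collapsed = [sp for sp, n in strains_per_species.items() if n > 1]
    if collapsed:
        logger.info(
            "collapsed multiple strains by maximum copy count for species %s",
            sorted(collapsed),
        )

    rows = species if species is not None else sorted(species_rows)
    table = pd.DataFrame(0, index=list(rows), columns=sublineages, dtype=int)
    for sp, row in species_rows.items():
        if sp not in table.index:
            continue
        for sl, c in row.items():
            table.loc[sp, sl] = c
    return PresenceMatrix(table=table)


# -- duplication scenarios ------------------------------------------------


@dataclass
class EventScenario:
    """A duplication placement and the gene losses it implies."""

    duplication_branch: str
    implied_species_losses: int
    implied_dollo_losses: int
    event_total: int

    def as_dict(self) -> dict:
        return {
            "duplication_branch": self.duplication_branch,
            "implied_species_losses": self.implied_species_losses,
            "implied_dollo_losses": self.implied_dollo_losses,
            "event_total": self.event_total,
        }


def evaluate_scenario(
    pm: PresenceMatrix,
    st: SpeciesTree,
    sublineage: str,
    duplication_branch: dendropy.Node | str | Iterable[str],
) -> EventScenario:
    """Losses implied by placing the sub-lineage's duplication on a branch.

    Under the hypothesis the copy arose on *duplication_branch* it was
    present in that branch's ancestor, so every descendant species with a
    zero count implies loss.  Dollo losses are counted as the number of
    maximal all-absent subtrees hanging below the branch, which is the
    minimal loss-branch set when the gene cannot be regained.
    """
    if not isinstance(duplication_branch, dendropy.Node):
        duplication_branch = st.find_branch(duplication_branch)
    node = duplication_branch
    descendants = st.leaves_under(node)
    present = pm.carriers(sublineage) & descendants
    if not present:
        raise DegenerateScenarioError(
            f"sub-lineage {sublineage!r} is absent from every species under "
            f"branch {branch_name(node, st)!r}"
        )
    absent = descendants - present
    dollo = _count_maximal_absent_subtrees(node, present, st)
    return EventScenario(
        duplication_branch=branch_name(node, st),
        implied_species_losses=len(absent),
        implied_dollo_losses=dollo,
        event_total=1 + dollo,
    )


def _count_maximal_absent_subtrees(
    node: dendropy.Node, present: set[str], st: SpeciesTree
) -> int:
    if node.is_leaf():
        return 0
    losses = 0
    for child in node.child_nodes():
        leaves = st.leaves_under(child)
        if leaves & present:
            losses += _count_maximal_absent_subtrees(child, present, st)
        else:
            losses += 1
    return losses


def rank_scenarios(
    pm: PresenceMatrix,
    st: SpeciesTree,
    sublineage: str,
) -> list[EventScenario]:
    """Scenarios for every branch from the WGD branch down to the carriers'
    MRCA, sorted by total implied events (ties toward more recent branches).
    """
    if st.wgd_node is None:
        raise ValueError("species tree has no WGD branch marked")
    carriers = pm.carriers(sublineage) & set(st.species())
    if not carriers:
        raise DegenerateScenarioError(
            f"sub-lineage {sublineage!r} has no carrier species in the tree"
        )
    mrca = st.tree.mrca(taxon_labels=sorted(carriers))
    path = st.path_down(st.wgd_node, mrca)
    candidates = path if path is not None else [st.wgd_node]
    scenarios = []
    for node in candidates:
        try:
            scenarios.append((node, evaluate_scenario(pm, st, sublineage, node)))
        except DegenerateScenarioError:
            continue
    scenarios.sort(key=lambda ns: (ns[1].event_total, -st.depth(ns[0])))
    return [s for _, s in scenarios]


def write_scenarios(
    scenarios: Mapping[str, Sequence[EventScenario]], path: str | Path
) -> Path:
    """JSON report: sub-lineage -> ranked scenario list."""
    path = Path(path)
    payload = {
        sl: [s.as_dict() for s in ranked] for sl, ranked in sorted(scenarios.items())
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


# -- lateral-transfer heuristic ------------------------------------------


def lateral_transfer_candidates(
    net: SimilarityNetwork,
    members: Iterable[str],
    gs: GenomeSet,
    percentile: float = 99.0,
) -> list[tuple[str, str, float]]:
    """Cross-genus member pairs whose identity is suspiciously high.

    Flags pairs from different genera (first two letters of the species
    code) whose identity exceeds the given percentile of within-genus
    identities.  A warning report, not an inference of transfer.
    """
    members = sorted(set(members))
    within, cross = [], []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            data = net.edge(a, b)
            if data is None:
                continue
            same_genus = gs.species_of(a)[:2] == gs.species_of(b)[:2]
            (within if same_genus else cross).append((a, b, data["identity_pct"]))
    if not within or not cross:
        return []
    cutoff = float(np.percentile([x[2] for x in within], percentile))
    hits = [(a, b, ident) for a, b, ident in cross if ident > cutoff]
    for a, b, ident in hits:
        logger.warning(
            "cross-genus pair %s--%s identity %.1f%% exceeds the %.0fth "
            "percentile of within-genus identities (%.1f%%)",
            a, b, ident, percentile, cutoff,
        )
    return hits


def export_lineage_graph(lg: LineageGraph, path: str | Path) -> Path:
    g = lg.graph.copy()
    for node in g.nodes:
        g.nodes[node]["sublineage"] = lg.sublineage.get(node, "")
        g.nodes[node]["labels"] = ",".join(sorted(lg.labels.get(node, ())))
    nx.write_graphml(g, str(path))
    return Path(path)
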