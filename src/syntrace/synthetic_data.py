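"""Genome-evolution simulator with a known event history.

An ancestral genome of random proteins evolves down a species tree.  Along
each branch, in order: a whole-genome duplication (on the flagged branch)
doubles every contig; planted events (a dispersed duplication of the family
founder gene, a loss of one of its WGD copies) fire on their named
branches; background events hit genes independently (tandem duplication,
dispersed duplication, loss, translocation) and contigs (local gene-order
shuffles); finally proteins mutate under a uniform-rate 20-state
substitution process (Jukes-Cantor style, no indels by default).

Every event is recorded in an :class:`EventLog` whose replay from the root
genome reproduces the leaf genomes' gene content exactly, giving downstream
modules ground truth: which extant genes descend from which duplicate copy,
and on which branch each event happened.

The emitted "true hit table" is derived from known homology rather than
alignment heuristics: genes sharing an ancestral root gene (a homology
group) are compared column-wise, and the e-value is a fixed monotone map of
identity, ``exponent = -180 * identity_fraction`` (no hit below 25%
identity).  This places realistic families in the E-40..E-150 band where
the pipeline's thresholds operate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .genome_db import AMINO_ACIDS, GeneLocus, GenomeSet, emit_genome_set
from .lineage import PresenceMatrix, SpeciesTree, _node_label
from .simnet import LOG_FLOOR, PairwiseHit, write_hits

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_N_AA = len(AMINO_ACIDS)


#: species topology used as the default study condition: three pre-WGD
#: outgroups and a post-WGD clade of six genera (Nakaseomyces,
#: Naumovozyma, Kazachstania, Saccharomyces).  Internal labels name
#: branches; "postwgd" heads the WGD branch.
DEFAULT_SPECIES_NEWICK = (
    "((zyro:0.25,(lakl:0.20,klla:0.20)lk:0.05)prewgd:0.05,"
    "(cagl:0.18,((naca:0.08,nada:0.08)naum:0.08,"
    "((kaaf:0.07,kana:0.07)kaza:0.06,"
    "(sace:0.03,(sapa:0.03,(smik:0.025,skud:0.025)smsk:0.005)spar:0.005)"
    "sacch:0.08)kzsc:0.03)nnks:0.03)postwgd:0.08)root;"
)
DEFAULT_WGD_BRANCH = "postwgd"

WGD = "WGD"
DUP_TANDEM = "duplication_tandem"
DUP_DISPERSED = "duplication_dispersed"
LOSS = "loss"
TRANSLOCATION = "translocation"
SHUFFLE = "neighborhood_shuffle"


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class EventRates:
    """Per-gene (shuffle: per-contig) event probabilities per branch.

    Gene-movement rates (dispersed duplication, translocation) are scaled
    to the miniature genome size: what matters for synteny noise is the
    probability that a moved gene lands inside a specific 30-gene
    neighborhood, which in a ~200-gene simulated genome is ~30x higher per
    event than in a ~5,500-gene yeast genome.  The defaults keep the
    per-locus perturbation probability in the realistic range rather than
    the per-gene event count.
    """

    duplication_tandem: float = 0.005
    duplication_dispersed: float = 1e-4
    loss: float = 0.01
    translocation: float = 5e-5
    neighborhood_shuffle: float = 0.02

    def validate(self) -> None:
        for name, value in vars(self).items():
            if not (0.0 <= value <= 1.0):
                raise SimConfigError(f"rate {name}={value} outside [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for one simulated genome set."""

    species_newick: str = DEFAULT_SPECIES_NEWICK
    wgd_branch: str | None = DEFAULT_WGD_BRANCH
    genes_per_contig: int = 30
    contigs_per_genome: int = 3
    protein_length: int = 120
    family_seed_count: int = 1
    rates: EventRates = field(default_factory=EventRates)
    substitution: float = 1.0  # expected substitutions/site per unit branch length
    rng_seed: int = 0
    # planted history for parameter-recovery experiments
    planted_duplication_branch: str | None = None
    planted_loss_branch: str | None = None
    shuffle_window: int = 4

    def validate(self) -> None:
        self.rates.validate()
        if self.genes_per_contig < 2 or self.contigs_per_genome < 1:
            raise SimConfigError("need >= 2 genes per contig and >= 1 contig")
        if self.protein_length < 10:
            raise SimConfigError("protein_length must be >= 10")
        if self.family_seed_count < 1:
            raise SimConfigError("family_seed_count must be >= 1")
        # expected per-branch copy factor; with D branches root-to-leaf the
        # expected leaf genome size is n0 * factor**D
        factor = 1.0 - self.rates.loss + self.rates.duplication_tandem \
            + self.rates.duplication_dispersed
        st = SpeciesTree.from_newick(self.species_newick)
        depth = max(
            sum(1 for _ in leaf.ancestor_iter())
            for leaf in st.tree.leaf_node_iter()
        )
        n0 = self.genes_per_contig * self.contigs_per_genome
        if factor <= 0 or n0 * factor ** depth < 1.0:
            raise SimConfigError(
                f"rates imply empty genomes (expected leaf size "
                f"{n0 * max(factor, 0.0) ** depth:.2g} gene)"
            )


@dataclass
class SimEvent:
    """One recorded event; placement details make the log replayable."""

    branch: str  # label of the head node of the branch
    type: str
    uids: list[int]  # affected gene uids (source first)
    details: dict

    def as_dict(self) -> dict:
        return {
            "branch": self.branch,
            "type": self.type,
            "uids": list(self.uids),
            "details": self.details,
        }


@dataclass
class EventLog:
    """Root gene arrangement plus the ordered event list."""

    root_contigs: list[list[int]]  # uids per contig, in order
    events: list[SimEvent] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "root_contigs": self.root_contigs,
            "events": [e.as_dict() for e in self.events],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path


@dataclass
class _Gene:
    uid: int
    group: int  # homology group = uid of the ancestral root gene
    tag: str  # duplicate-copy lineage marker; planted copies get "dup"
    seq: np.ndarray  # uint8 indices into the amino-acid alphabet


@dataclass
class _Contig:
    ancestry: int  # index of the root contig this one descends from
    genes: list[_Gene]


@dataclass
class SimTruth:
    """Ground truth for recovery experiments."""

    founder_groups: list[int]
    family_gene_tags: dict[str, str]  # leaf gene_id -> copy tag ("anc"/"dup")
    duplication_branch: str | None
    loss_branch: str | None
    seed_genes: list[str]  # one extant family gene per founder group


@dataclass
class SimResult:
    genome_set: GenomeSet
    event_log: EventLog
    hits: list[PairwiseHit]
    truth: SimTruth
    species_tree: SpeciesTree


def simulate(cfg: SimConfig) -> SimResult:
    """Evolve an ancestral genome down the species tree; fully seeded."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    st = SpeciesTree.from_newick(cfg.species_newick, wgd=cfg.wgd_branch)
    _ensure_branch_labels(st)

    uid_counter = [0]

    def new_uid() -> int:
        uid_counter[0] += 1
        return uid_counter[0] - 1

    # ancestral genome
    root_contigs: list[_Contig] = []
    for c in range(cfg.contigs_per_genome):
        genes = []
        for _ in range(cfg.genes_per_contig):
            uid = new_uid()
            seq = rng.integers(0, _N_AA, size=cfg.protein_length).astype(np.uint8)
            genes.append(_Gene(uid=uid, group=uid, tag="anc", seq=seq))
        root_contigs.append(_Contig(ancestry=c, genes=genes))

    # family founders: mid-contig genes, one per contig, first contigs first
    founder_groups: list[int] = []
    for i in range(cfg.family_seed_count):
        contig = root_contigs[i % cfg.contigs_per_genome]
        founder_groups.append(contig.genes[len(contig.genes) // 2].group)

    log = EventLog(
        root_contigs=[[g.uid for g in c.genes] for c in root_contigs]
    )
    # in planted-history mode the planted events ARE the family's history:
    # background loss/translocation skip the focal group so ground truth
    # stays exact (background duplications of it remain possible)
    planted_mode = (
        cfg.planted_duplication_branch is not None
        or cfg.planted_loss_branch is not None
    )
    protected = set(founder_groups) if planted_mode else set()
    leaves: dict[str, list[_Contig]] = {}

    def evolve(node: dendropy.Node, contigs: list[_Contig]) -> None:
        for child in node.child_nodes():
            state = [
                _Contig(ancestry=c.ancestry, genes=[replace(g) for g in c.genes])
                for c in contigs
            ]
            label = _node_label(child)
            if st.wgd_node is not None and child is st.wgd_node:
                state = _apply_wgd(state, label, new_uid, log)
            if cfg.planted_loss_branch == label:
                _apply_planted_loss(state, founder_groups[0], label, log)
            if cfg.planted_duplication_branch == label:
                _apply_planted_duplication(
                    state, founder_groups[0], label, new_uid, log
                )
            _apply_background_events(
                state, cfg, label, new_uid, rng, log, protected
            )
            _apply_shuffles(state, cfg, label, rng, log)
            _apply_substitutions(state, cfg, child.edge.length or 0.0, rng)
            if child.is_leaf():
                if sum(len(c.genes) for c in state) == 0:
                    raise SimConfigError(
                        f"species {label} lost every gene; rates too high"
                    )
                leaves[label] = state
            else:
                evolve(child, state)

    evolve(st.tree.seed_node, root_contigs)

    gs, gene_names = _to_genome_set(leaves)
    hits = _true_hit_table(leaves, gene_names)
    truth = _collect_truth(leaves, gene_names, founder_groups, cfg)
    return SimResult(
        genome_set=gs, event_log=log, hits=hits, truth=truth, species_tree=st
    )


# -- per-branch event machinery -------------------------------------------


def _ensure_branch_labels(st: SpeciesTree) -> None:
    for i, node in enumerate(st.tree.preorder_node_iter()):
        if _node_label(node) is None:
            node.label = f"n{i}"


def _apply_wgd(
    state: list[_Contig], branch: str, new_uid, log: EventLog
) -> list[_Contig]:
    copies = []
    mapping: dict[int, int] = {}
    for contig in state:
        dup_genes = []
        for g in contig.genes:
            uid = new_uid()
            mapping[g.uid] = uid
            dup_genes.append(
                _Gene(uid=uid, group=g.group, tag=g.tag, seq=g.seq.copy())
            )
        copies.append(_Contig(ancestry=contig.ancestry, genes=dup_genes))
    log.events.append(
        SimEvent(
            branch=branch,
            type=WGD,
            uids=sorted(mapping),
            details={"copy_map": {str(k): v for k, v in sorted(mapping.items())}},
        )
    )
    return state + copies


def _family_positions(
    state: list[_Contig], group: int
) -> list[tuple[int, int]]:
    """(contig index, gene index) of every gene in *group*, in order."""
    return [
        (ci, gi)
        for ci, contig in enumerate(state)
        for gi, g in enumerate(contig.genes)
        if g.group == group
    ]


def _apply_planted_loss(
    state: list[_Contig], group: int, branch: str, log: EventLog
) -> None:
    positions = _family_positions(state, group)
    if len(positions) < 2:
        return  # nothing to lose without erasing the family
    ci, gi = positions[-1]  # the copy on the highest contig (the WGD block)
    gene = state[ci].genes.pop(gi)
    log.events.append(
        SimEvent(branch=branch, type=LOSS, uids=[gene.uid],
                 details={"planted": True})
    )


def _apply_planted_duplication(
    state: list[_Contig], group: int, branch: str, new_uid, log: EventLog
) -> None:
    positions = _family_positions(state, group)
    if not positions:
        return
    ci, gi = positions[0]
    src = state[ci].genes[gi]
    targets = [
        ti for ti, c in enumerate(state)
        if c.ancestry != state[ci].ancestry and c.genes
    ]
    ti = targets[0] if targets else (ci + 1) % len(state)
    # subtelomeric placement: the copy lands near the contig end, the
    # poorly-conserved region where relocated genes typically surface
    pos = max(0, len(state[ti].genes) - 2)
    uid = new_uid()
    copy = _Gene(uid=uid, group=src.group, tag="dup", seq=src.seq.copy())
    state[ti].genes.insert(pos, copy)
    log.events.append(
        SimEvent(
            branch=branch, type=DUP_DISPERSED, uids=[src.uid, uid],
            details={"planted": True, "target_contig": ti, "target_index": pos},
        )
    )


def _apply_background_events(
    state: list[_Contig], cfg: SimConfig, branch: str, new_uid,
    rng: np.random.Generator, log: EventLog,
    protected_groups: set[int] = frozenset(),
) -> None:
    rates = cfg.rates
    # snapshot: events hit the genes present at the start of the branch
    snapshot = [
        (ci, g.uid) for ci, contig in enumerate(state) for g in contig.genes
    ]
    for ci, uid in snapshot:
        contig = state[ci]
        gi = next(
            (i for i, g in enumerate(contig.genes) if g.uid == uid), None
        )
        if gi is None:
            continue  # already removed this branch
        gene = contig.genes[gi]
        draws = rng.random(4)
        shielded = gene.group in protected_groups
        if draws[0] < rates.duplication_tandem:
            copy_uid = new_uid()
            copy = _Gene(uid=copy_uid, group=gene.group, tag=gene.tag,
                         seq=gene.seq.copy())
            contig.genes.insert(gi + 1, copy)
            log.events.append(
                SimEvent(branch=branch, type=DUP_TANDEM,
                         uids=[gene.uid, copy_uid],
                         details={"contig": ci, "index": gi + 1})
            )
        if draws[1] < rates.duplication_dispersed:
            ti = int(rng.integers(0, len(state)))
            pos = int(rng.integers(0, len(state[ti].genes) + 1))
            copy_uid = new_uid()
            copy = _Gene(uid=copy_uid, group=gene.group, tag=gene.tag,
                         seq=gene.seq.copy())
            state[ti].genes.insert(pos, copy)
            log.events.append(
                SimEvent(branch=branch, type=DUP_DISPERSED,
                         uids=[gene.uid, copy_uid],
                         details={"target_contig": ti, "target_index": pos})
            )
        if draws[2] < rates.translocation and not shielded:
            gi_now = next(
                i for i, g in enumerate(contig.genes) if g.uid == uid
            )
            moved = contig.genes.pop(gi_now)
            ti = int(rng.integers(0, len(state)))
            pos = int(rng.integers(0, len(state[ti].genes) + 1))
            state[ti].genes.insert(pos, moved)
            log.events.append(
                SimEvent(branch=branch, type=TRANSLOCATION, uids=[uid],
                         details={"target_contig": ti, "target_index": pos})
            )
        if draws[3] < rates.loss and not shielded:
            gi_now = next(
                (i for i, g in enumerate(contig.genes) if g.uid == uid), None
            )
            if gi_now is None:  # translocated away; find it
                for c2 in state:
                    gi_now = next(
                        (i for i, g in enumerate(c2.genes) if g.uid == uid),
                        None,
                    )
                    if gi_now is not None:
                        c2.genes.pop(gi_now)
                        break
            else:
                contig.genes.pop(gi_now)
            log.events.append(
                SimEvent(branch=branch, type=LOSS, uids=[uid], details={})
            )


def _apply_shuffles(
    state: list[_Contig], cfg: SimConfig, branch: str,
    rng: np.random.Generator, log: EventLog,
) -> None:
    for ci, contig in enumerate(state):
        if len(contig.genes) < 2:
            continue
        if rng.random() >= cfg.rates.neighborhood_shuffle:
            continue
        w = min(cfg.shuffle_window, len(contig.genes))
        start = int(rng.integers(0, len(contig.genes) - w + 1))
        perm = rng.permutation(w)
        window = contig.genes[start : start + w]
        contig.genes[start : start + w] = [window[i] for i in perm]
        log.events.append(
            SimEvent(
                branch=branch, type=SHUFFLE,
                uids=[g.uid for g in window],
                details={"contig": ci, "start": start,
                         "order": [int(i) for i in perm]},
            )
        )


def _apply_substitutions(
    state: list[_Contig], cfg: SimConfig, branch_length: float,
    rng: np.random.Generator,
) -> None:
    t = cfg.substitution * branch_length
    if t <= 0:
        return
    # 20-state Jukes-Cantor: P(site differs) after t expected subs/site
    p = (_N_AA - 1) / _N_AA * (1.0 - np.exp(-_N_AA / (_N_AA - 1) * t))
    for contig in state:
        for gene in contig.genes:
            mask = rng.random(gene.seq.size) < p
            k = int(mask.sum())
            if k == 0:
                continue
            shifts = rng.integers(1, _N_AA, size=k).astype(np.uint8)
            # copy-on-write: sibling lineages share the parent array
            seq = gene.seq.copy()
            seq[mask] = (seq[mask] + shifts) % _N_AA
            gene.seq = seq


# -- output assembly ------------------------------------------------------


def _decode(seq: np.ndarray) -> str:
    return _AA[seq].tobytes().decode("ascii")


def _to_genome_set(
    leaves: dict[str, list[_Contig]],
) -> tuple[GenomeSet, dict[tuple[str, int], str]]:
    loci = []
    gene_names: dict[tuple[str, int], str] = {}
    species_map = {}
    for sp in sorted(leaves):
        genome_id = f"{sp}_1"
        species_map[genome_id] = sp
        for ci, contig in enumerate(leaves[sp]):
            for pos, gene in enumerate(contig.genes, start=1):
                gene_id = f"{sp}_g{gene.uid:05d}"
                gene_names[(sp, gene.uid)] = gene_id
                loci.append(
                    GeneLocus(
                        gene_id=gene_id,
                        genome_id=genome_id,
                        species_code=sp,
                        contig_id=f"c{ci:02d}",
                        position=pos,
                        strand="+",
                        protein=_decode(gene.seq),
                    )
                )
    return GenomeSet(loci, species_map=species_map), gene_names

_POSITIVE_PAIRS: np.ndarray | None = None


def _positive_pairs() -> np.ndarray:
    """Boolean 20x20 table: BLOSUM62 score > 0 for the residue pair."""
    global _POSITIVE_PAIRS
    if _POSITIVE_PAIRS is None:
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        table = np.zeros((_N_AA, _N_AA), dtype=bool)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                table[i, j] = blosum[a, b] > 0
        _POSITIVE_PAIRS = table
    return _POSITIVE_PAIRS


#: identity fraction -> e-value exponent scale of the true hit table.
TRUE_HIT_EXPONENT_SCALE = 180.0
TRUE_HIT_MIN_IDENTITY = 0.25


def _true_hit_table(
    leaves: dict[str, list[_Contig]],
    gene_names: dict[tuple[str, int], str],
) -> list[PairwiseHit]:
    by_group: dict[int, list[tuple[str, _Gene]]] = {}
    for sp in sorted(leaves):
        for contig in leaves[sp]:
            for gene in contig.genes:
                by_group.setdefault(gene.group, []).append((sp, gene))
    pos = _positive_pairs()
    hits: list[PairwiseHit] = []
    for group in sorted(by_group):
        genes = by_group[group]
        for i, (sp_a, a) in enumerate(genes):
            for sp_b, b in genes[i + 1 :]:
                ident = float(np.mean(a.seq == b.seq))
                if ident < TRUE_HIT_MIN_IDENTITY:
                    continue
                simil = float(np.mean(pos[a.seq, b.seq]))
                exponent = max(-TRUE_HIT_EXPONENT_SCALE * ident, LOG_FLOOR)
                ida = gene_names[(sp_a, a.uid)]
                idb = gene_names[(sp_b, b.uid)]
                qa, qb = (ida, idb) if ida < idb else (idb, ida)
                hits.append(
                    PairwiseHit(
                        query_id=qa,
                        subject_id=qb,
                        evalue=10.0 ** exponent,
                        identity_pct=100.0 * ident,
                        similarity_pct=100.0 * max(simil, ident),
                        score=round(4.0 * ident * a.seq.size, 1),
                        aln_length=int(a.seq.size),
                    )
                )
    return hits


def _collect_truth(
    leaves: dict[str, list[_Contig]],
    gene_names: dict[tuple[str, int], str],
    founder_groups: list[int],
    cfg: SimConfig,
) -> SimTruth:
    tags: dict[str, str] = {}
    per_group_candidates: dict[int, list[str]] = {g: [] for g in founder_groups}
    for sp in sorted(leaves):
        for contig in leaves[sp]:
            for gene in contig.genes:
                if gene.group in per_group_candidates:
                    gene_id = gene_names[(sp, gene.uid)]
                    tags[gene_id] = gene.tag
                    per_group_candidates[gene.group].append(gene_id)
    seeds = []
    for group in founder_groups:
        cands = sorted(per_group_candidates[group])
        preferred = [c for c in cands if c.startswith("sace")]
        if preferred:
            seeds.append(preferred[0])
        elif cands:
            seeds.append(cands[0])
    return SimTruth(
        founder_groups=list(founder_groups),
        family_gene_tags=tags,
        duplication_branch=cfg.planted_duplication_branch,
        loss_branch=cfg.planted_loss_branch,
        seed_genes=seeds,
    )


# -- replay oracle --------------------------------------------------------


def replay_event_log(
    log: EventLog,
    species_newick: str = DEFAULT_SPECIES_NEWICK,
    wgd_branch: str | None = DEFAULT_WGD_BRANCH,
) -> dict[str, list[list[int]]]:
    """Re-derive leaf gene content (uids per contig) from the event log.

    Independent of the simulator's internal state: only the logged
    placement details are used.  Comparing the result with the emitted
    genome set verifies that the log fully explains the leaf genomes.
    """
    st = SpeciesTree.from_newick(species_newick, wgd=wgd_branch)
    _ensure_branch_labels(st)
    by_branch: dict[str, list[SimEvent]] = {}
    for ev in log.events:
        by_branch.setdefault(ev.branch, []).append(ev)

    leaves: dict[str, list[list[int]]] = {}

    def walk(node: dendropy.Node, contigs: list[list[int]]) -> None:
        for child in node.child_nodes():
            state = [list(c) for c in contigs]
            label = _node_label(child)
            for ev in by_branch.get(label, ()):
                _replay_one(state, ev)
            if child.is_leaf():
                leaves[label] = state
            else:
                walk(child, state)

    walk(st.tree.seed_node, [list(c) for c in log.root_contigs])
    return leaves


def _find_uid(state: list[list[int]], uid: int) -> tuple[int, int]:
    for ci, contig in enumerate(state):
        for gi, u in enumerate(contig):
            if u == uid:
                return ci, gi
    raise KeyError(f"uid {uid} not present")


def _replay_one(state: list[list[int]], ev: SimEvent) -> None:
    if ev.type == WGD:
        copy_map = {int(k): v for k, v in ev.details["copy_map"].items()}
        state += [[copy_map[u] for u in contig] for contig in list(state)]
    elif ev.type == DUP_TANDEM:
        ci, gi = ev.details["contig"], ev.details["index"]
        state[ci].insert(gi, ev.uids[1])
    elif ev.type == DUP_DISPERSED:
        state[ev.details["target_contig"]].insert(
            ev.details["target_index"], ev.uids[1]
        )
    elif ev.type == LOSS:
        ci, gi = _find_uid(state, ev.uids[0])
        state[ci].pop(gi)
    elif ev.type == TRANSLOCATION:
        ci, gi = _find_uid(state, ev.uids[0])
        uid = state[ci].pop(gi)
        state[ev.details["target_contig"]].insert(
            ev.details["target_index"], uid
        )
    elif ev.type == SHUFFLE:
        ci, start = ev.details["contig"], ev.details["start"]
        order = ev.details["order"]
        window = state[ci][start : start + len(order)]
        state[ci][start : start + len(order)] = [window[i] for i in order]
    else:
        raise ValueError(f"unknown event type {ev.type!r}")


def leaf_uid_arrangement(result: SimResult) -> dict[str, list[list[int]]]:
    """Leaf gene uids per contig as emitted, for comparison with replay."""
    out: dict[str, list[list[int]]] = {}
    gs = result.genome_set
    for genome_id in sorted(gs.genomes):
        sp = gs.species_map[genome_id]
        contigs = []
        for contig_id in sorted(gs.genomes[genome_id]):
            contigs.append(
                [
                    int(l.gene_id.rsplit("_g", 1)[1])
                    for l in gs.genomes[genome_id][contig_id]
                ]
            )
        out[sp] = contigs
    return out


# -- emission -------------------------------------------------------------


def emit_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input format; byte-identical under a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = emit_genome_set(result.genome_set, outdir, prefix="sim")
    paths["hits"] = write_hits(result.hits, outdir / "sim.hits.tsv")
    tree_path = outdir / "sim.species.nwk"
    result.species_tree.tree.write(
        path=str(tree_path), schema="newick", suppress_rooting=True
    )
    paths["species_tree"] = tree_path
    paths["event_log"] = result.event_log.to_json(outdir / "sim.events.json")
    truth_path = outdir / "sim.truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "founder_groups": result.truth.founder_groups,
                "family_gene_tags": result.truth.family_gene_tags,
                "duplication_branch": result.truth.duplication_branch,
                "loss_branch": result.truth.loss_branch,
                "seed_genes": result.truth.seed_genes,
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    paths["truth"] = truth_path
    return paths


# -- hard-coded study pattern ---------------------------------------------

PRE_WGD_SPECIES = ("zyro", "lakl", "klla")
POST_WGD_LOSS_SPECIES = ("cagl", "naca", "nada", "kaaf", "kana")
SACCHAROMYCES_SPECIES = ("sace", "sapa", "smik", "skud")


def paper_pattern_fixture() -> tuple[PresenceMatrix, SpeciesTree]:
    """The study's qualitative presence pattern on its species topology.

    Two sub-lineages over three pre-WGD outgroups and a post-WGD clade:
    ``snq2`` has one copy in every species; ``pdr18`` occurs exclusively in
    the four Saccharomyces species.  The single-copy status of the five
    Nakaseomyces/Naumovozyma/Kazachstania species is what makes a
    WGD-placed duplication imply five independent losses, while a
    Saccharomyces-stem duplication implies none.
    """
    st = SpeciesTree.from_newick(DEFAULT_SPECIES_NEWICK, wgd=DEFAULT_WGD_BRANCH)
    species = list(PRE_WGD_SPECIES) + list(POST_WGD_LOSS_SPECIES) + list(
        SACCHAROMYCES_SPECIES
    )
    table = pd.DataFrame(0, index=species, columns=["snq2", "pdr18"], dtype=int)
    table["snq2"] = 1
    table.loc[list(SACCHAROMYCES_SPECIES), "pdr18"] = 1
    return PresenceMatrix(table=table), st
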