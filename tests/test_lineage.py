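"""Sub-lineage partitioning, presence counts and duplication scenarios."""

import itertools
import random

import pandas as pd
import pytest

from syntrace import (
    DegenerateScenarioError,
    PresenceMatrix,
    SpeciesTree,
    detect_tandem,
    evaluate_scenario,
    paper_pattern_fixture,
    partition_sublineages,
    presence_matrix,
    rank_scenarios,
)
from syntrace.genome_db import GeneLocus, GenomeSet
from syntrace.lineage import (
    LABEL_SINGLETON,
    LABEL_TANDEM,
    apply_tandem_labels,
    branch_name,
)
from syntrace.neighborhood import SyntenyEdge


def edge(a: str, b: str, category: str = "strong", strength: float = 3.0):
    return SyntenyEdge(
        gene_a=a, gene_b=b, matches=[], raw_count=5 if category == "strong" else 1,
        strength=strength, category=category,
    )


def gs_from_positions(spec: dict[str, list[tuple[str, int]]]) -> GenomeSet:
    """{genome: [(gene_id, rank)]} -> GenomeSet, one contig each, padded with
    filler genes so positions are consecutive."""
    loci = []
    for genome, genes in spec.items():
        by_pos = {pos: gid for gid, pos in genes}
        for pos in range(1, max(by_pos) + 1):
            gid = by_pos.get(pos, f"{genome}_fill{pos}")
            loci.append(GeneLocus(
                gene_id=gid, genome_id=genome, species_code=genome[:4],
                contig_id="c1", position=pos, strand="+", protein="MKT",
            ))
    return GenomeSet(loci)


class TestPartition:
    def test_two_components_two_sublineages(self):
        members = {"a1", "a2", "b1", "b2"}
        edges = [edge("a1", "a2"), edge("b1", "b2", category="weak")]
        lg = partition_sublineages(edges, members)
        assert lg.sublineage["a1"] == lg.sublineage["a2"]
        assert lg.sublineage["b1"] == lg.sublineage["b2"]
        assert lg.sublineage["a1"] != lg.sublineage["b1"]

    def test_no_edges_all_singletons(self):
        lg = partition_sublineages([], {"x", "y", "z"})
        assert len(set(lg.sublineage.values())) == 3
        for g in ("x", "y", "z"):
            assert LABEL_SINGLETON in lg.labels[g]

    def test_none_category_edges_do_not_connect(self):
        lg = partition_sublineages(
            [edge("a", "b", category="none")], {"a", "b"}
        )
        assert lg.sublineage["a"] != lg.sublineage["b"]

    def test_removing_weak_edges_never_merges(self):
        members = {"a", "b", "c", "d"}
        edges = [edge("a", "b"), edge("b", "c", category="weak"), edge("c", "d")]
        full = partition_sublineages(edges, members)
        strong_only = partition_sublineages(
            [e for e in edges if e.category == "strong"], members
        )
        # refinement: genes split in the full partition stay split
        for x in members:
            for y in members:
                if full.sublineage[x] != full.sublineage[y]:
                    assert strong_only.sublineage[x] != strong_only.sublineage[y]


class TestTandem:
    def test_adjacent_members_detected(self):
        gs = gs_from_positions({"spec_1": [("t1", 7), ("t2", 8), ("o", 20)]})
        pairs = detect_tandem(gs, {"t1", "t2", "o"}, max_gap=3)
        assert pairs == {("t1", "t2")}

    def test_distant_same_contig_not_tandem(self):
        gs = gs_from_positions({"spec_1": [("t1", 5), ("t2", 15)]})
        assert detect_tandem(gs, {"t1", "t2"}, max_gap=3) == set()

    def test_labels_applied(self):
        lg = partition_sublineages([edge("t1", "t2")], {"t1", "t2"})
        apply_tandem_labels(lg, {("t1", "t2")})
        assert LABEL_TANDEM in lg.labels["t1"]


class TestPresenceMatrix:
    def test_two_genes_one_sublineage_counts_two(self):
        gs = gs_from_positions({"aaaa_1": [("g1", 1), ("g2", 2)]})
        lg = partition_sublineages([edge("g1", "g2")], {"g1", "g2"})
        pm = presence_matrix(lg, gs)
        assert pm.table.loc["aaaa"].sum() == 2
        assert pm.count("aaaa", lg.sublineage["g1"]) == 2

    def test_empty_family_empty_matrix(self):
        gs = gs_from_positions({"aaaa_1": [("g1", 1)]})
        lg = partition_sublineages([], set())
        pm = presence_matrix(lg, gs)
        assert pm.table.empty

    def test_strains_collapse_by_maximum(self):
        gs = GenomeSet(
            [
                GeneLocus("s1a", "aaaa_1", "aaaa", "c1", 1, "+", "MKT"),
                GeneLocus("s1b", "aaaa_1", "aaaa", "c1", 2, "+", "MKT"),
                GeneLocus("s2a", "aaaa_2", "aaaa", "c1", 1, "+", "MKT"),
            ],
            species_map={"aaaa_1": "aaaa", "aaaa_2": "aaaa"},
        )
        lg = partition_sublineages(
            [edge("s1a", "s1b"), edge("s1a", "s2a")], {"s1a", "s1b", "s2a"}
        )
        pm = presence_matrix(lg, gs)
        assert pm.count("aaaa", lg.sublineage["s1a"]) == 2  # max over strains

    def test_counts_match_brute_force_tally(self):
        rnd = random.Random(0)
        genomes = {f"sp{i:02d}_1": [] for i in range(6)}
        members = []
        for gname, genes in genomes.items():
            for p in range(1, rnd.randint(2, 6)):
                gid = f"{gname}_m{p}"
                genes.append((gid, p))
                members.append(gid)
        gs = gs_from_positions(genomes)
        lg = partition_sublineages([], set(members))
        pm = presence_matrix(lg, gs)
        for gid in members:
            sp = gs.species_of(gid)
            assert pm.count(sp, lg.sublineage[gid]) == 1
        assert int(pm.table.values.sum()) == len(members)

    def test_tsv_round_trip(self, tmp_path):
        pm, _ = paper_pattern_fixture()
        path = pm.to_tsv(tmp_path / "pm.tsv")
        back = PresenceMatrix.read_tsv(path)
        assert back.table.equals(pm.table)


def random_species_tree(n_leaves: int, seed: int) -> SpeciesTree:
    rnd = random.Random(seed)
    parts = [f"s{i:02d}:1.0" for i in range(n_leaves)]
    counter = itertools.count()
    while len(parts) > 1:
        a = parts.pop(rnd.randrange(len(parts)))
        b = parts.pop(rnd.randrange(len(parts))) if len(parts) else None
        label = f"i{next(counter)}"
        parts.append(f"({a},{b}){label}:1.0")
    return SpeciesTree.from_newick(parts[0] + ";")


def brute_force_dollo(st: SpeciesTree, dup_node, present: set[str]) -> int:
    """Minimal edge set below dup_node whose subtrees cover all absences."""
    nodes_below = [
        n for n in dup_node.preorder_iter() if n is not dup_node
    ]
    absent = st.leaves_under(dup_node) - present
    if not absent:
        return 0
    for k in range(1, len(nodes_below) + 1):
        for combo in itertools.combinations(nodes_below, k):
            covered = set()
            ok = True
            for n in combo:
                leaves = st.leaves_under(n)
                if leaves & present:
                    ok = False
                    break
                covered |= leaves
            if ok and covered == absent:
                return k
    raise AssertionError("no covering loss set found")


class TestScenarios:
    def test_all_descendants_present_zero_losses(self):
        pm, st = paper_pattern_fixture()
        sc = evaluate_scenario(pm, st, "snq2", st.wgd_node)
        assert sc.implied_species_losses == 0
        assert sc.implied_dollo_losses == 0
        assert sc.event_total == 1

    def test_sister_pairs_plus_singleton_absence(self):
        """5 descendants; copy only in a 2-species cherry; the three absent
        species fall as one cherry plus one singleton -> 3 species losses
        explained by 2 Dollo losses."""
        st = SpeciesTree.from_newick(
            "(((a:1,b:1)ab:1,(c:1,d:1)cd:1)abcd:1,e:1)root;"
        )
        table = pd.DataFrame(
            {"x": {"a": 1, "b": 1, "c": 0, "d": 0, "e": 0}}
        )
        pm = PresenceMatrix(table=table)
        sc = evaluate_scenario(pm, st, "x", st.find_branch("root"))
        assert sc.implied_species_losses == 3
        assert sc.implied_dollo_losses == 2
        assert sc.event_total == 3

    def test_wgd_scenario_five_species_losses(self):
        pm, st = paper_pattern_fixture()
        sc = evaluate_scenario(pm, st, "pdr18", st.wgd_node)
        assert sc.implied_species_losses == 5

    def test_absent_everywhere_is_degenerate(self):
        pm, st = paper_pattern_fixture()
        with pytest.raises(DegenerateScenarioError):
            evaluate_scenario(pm, st, "pdr18", st.find_branch("nnks").child_nodes()[0])

    def test_dollo_equals_brute_force_on_random_patterns(self):
        rnd = random.Random(1)
        checked = 0
        for seed in range(40):
            n = rnd.randint(4, 10)
            st = random_species_tree(n, seed=seed)
            root = st.tree.seed_node
            species = sorted(st.species())
            present = {s for s in species if rnd.random() < 0.45}
            if not present:
                continue
            sc = evaluate_scenario(
                PresenceMatrix(pd.DataFrame({"x": {s: int(s in present) for s in species}})),
                st, "x", root,
            )
            assert sc.implied_dollo_losses == brute_force_dollo(st, root, present)
            assert sc.implied_dollo_losses <= sc.implied_species_losses
            checked += 1
        assert checked >= 30

    def test_rootward_moves_never_decrease_species_losses(self):
        pm, st = paper_pattern_fixture()
        losses = [
            evaluate_scenario(pm, st, "pdr18", st.find_branch(b)).implied_species_losses
            for b in ("sacch", "kzsc", "nnks", "postwgd")
        ]
        assert losses == sorted(losses)


class TestRankScenarios:
    def test_copy_confined_to_genus_ranks_genus_stem_first(self):
        pm, st = paper_pattern_fixture()
        ranked = rank_scenarios(pm, st, "pdr18")
        assert ranked[0].duplication_branch == "sacch"
        assert ranked[0].event_total == 1

    def test_copy_everywhere_ranks_wgd_first(self):
        pm, st = paper_pattern_fixture()
        ranked = rank_scenarios(pm, st, "snq2")
        assert ranked[0].duplication_branch == "postwgd"

    def test_saccharomyces_stem_beats_wgd_on_study_pattern(self):
        pm, st = paper_pattern_fixture()
        ranked = rank_scenarios(pm, st, "pdr18")
        order = [s.duplication_branch for s in ranked]
        assert order.index("sacch") < order.index("postwgd")

    def test_enumeration_covers_path_from_wgd_to_mrca(self):
        pm, st = paper_pattern_fixture()
        ranked = rank_scenarios(pm, st, "pdr18")
        assert {s.duplication_branch for s in ranked} == {
            "postwgd", "nnks", "kzsc", "sacch"
        }


class TestFixture:
    def test_saccharomyces_rows_have_both_copies(self):
        pm, _ = paper_pattern_fixture()
        for sp in ("sace", "sapa", "smik", "skud"):
            assert pm.count(sp, "snq2") == 1 and pm.count(sp, "pdr18") == 1

    def test_five_single_copy_species_lack_second_sublineage(self):
        pm, _ = paper_pattern_fixture()
        for sp in ("cagl", "naca", "nada", "kaaf", "kana"):
            assert pm.count(sp, "snq2") == 1 and pm.count(sp, "pdr18") == 0

    def test_wgd_branch_is_marked(self):
        _, st = paper_pattern_fixture()
        assert st.wgd_node is not None
        assert branch_name(st.wgd_node, st) == "postwgd"
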