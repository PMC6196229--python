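"""Shared fixtures: hand-built genome sets, random similarity networks,
and one reusable simulated dataset with a planted duplication history."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from syntrace import SimConfig, SimilarityNetwork, simulate
from syntrace.genome_db import GeneLocus, GenomeSet
from syntrace.simnet import PairwiseHit


def make_locus(
    gene_id: str,
    position: int,
    contig: str = "c1",
    genome: str = "genA_1",
    species: str = "genA",
    protein: str = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
) -> GeneLocus:
    return GeneLocus(
        gene_id=gene_id,
        genome_id=genome,
        species_code=species,
        contig_id=contig,
        position=position,
        strand="+",
        protein=protein,
    )


def make_contig_gs(n_genes: int = 30, **kwargs) -> GenomeSet:
    """One genome, one contig with n consecutive genes g1..gn."""
    loci = [make_locus(f"g{i}", i, **kwargs) for i in range(1, n_genes + 1)]
    return GenomeSet(loci)


def make_hit(q: str, s: str, evalue: float, ident: float = 80.0) -> PairwiseHit:
    return PairwiseHit(
        query_id=q, subject_id=s, evalue=evalue,
        identity_pct=ident, similarity_pct=min(100.0, ident + 10.0),
        score=200.0, aln_length=100,
    )


def chain_network(*links: tuple[str, str, float]) -> SimilarityNetwork:
    """Network from explicit (a, b, evalue) links."""
    return SimilarityNetwork.from_hits(
        [make_hit(a, b, ev) for a, b, ev in links]
    )


def random_network(
    n_nodes: int, p_edge: float, seed: int
) -> SimilarityNetwork:
    """Erdos-Renyi graph with random e-value exponents in [-180, -10]."""
    rng = random.Random(seed)
    hits = []
    nodes = [f"n{i}" for i in range(n_nodes)]
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            exponent = rng.uniform(-180, -10)
            hits.append(make_hit(a, b, 10.0 ** exponent))
    return SimilarityNetwork.from_hits(hits, nodes=nodes)


@pytest.fixture(scope="session")
def planted_sim():
    """One simulated genome set with a planted post-WGD duplication on the
    Saccharomyces stem and the ohnolog loss on the WGD branch."""
    cfg = SimConfig(
        rng_seed=7,
        planted_duplication_branch="sacch",
        planted_loss_branch="postwgd",
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def planted_net(planted_sim):
    _, res = planted_sim
    return SimilarityNetwork.from_hits(
        res.hits, nodes=res.genome_set.gene_ids()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
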