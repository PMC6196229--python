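"""Seeded gene-family delimitation over an e-value sweep.

A family is the connected component of the thresholded similarity network
that contains a seed gene.  Sweeping the threshold from stringent to
permissive traces how the family grows; the working threshold is chosen at
the most stringent opening of the longest stable plateau of the sweep curve.
Families traversed from several seeds are merged, and members that look like
protein fragments or unusually divergent sequences are flagged (never
removed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .genome_db import GenomeSet
from .simnet import SimilarityNetwork

logger = logging.getLogger(__name__)

#: default sweep grid: e-value exponents from stringent to permissive.
DEFAULT_GRID: tuple[int, ...] = tuple(range(-200, -18, 2))
DEFAULT_STABILITY_STEPS = 5
DEFAULT_TOL_FRAC = 0.01

FLAG_FRAGMENT = "fragment"
FLAG_LONG_BRANCH = "long_branch"
FLAG_MANUAL = "manual_exclude"


class NoPlateauError(RuntimeError):
    """The sweep curve has no stable run; a threshold must be chosen manually."""


@dataclass
class SweepCurve:
    """Family size at each threshold of a stringent-to-permissive grid."""

    seed_id: str
    grid: tuple[int, ...]  # e-value exponents, ascending (more permissive ->)
    counts: tuple[int, ...]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("exponent\tcount\n")
            for e, c in zip(self.grid, self.counts):
                fh.write(f"{e}\t{c}\n")
        return path


@dataclass
class FamilyResult:
    """Merged family membership with per-seed thresholds and quality flags."""

    seeds: list[str]
    threshold_per_seed: dict[str, float]
    members: set[str]
    flags: dict[str, set[str]] = field(default_factory=dict)

    def flag(self, gene_id: str, label: str) -> None:
        self.flags.setdefault(gene_id, set()).add(label)

    def unflagged_members(self) -> set[str]:
        """Members carrying no flag at all (for reporting)."""
        return {m for m in self.members if not self.flags.get(m)}

    def analysis_members(self) -> set[str]:
        """Members retained for pairwise analysis.

        Fragments and manually excluded interlopers are dropped;
        ``long_branch`` is advisory only — divergent members are kept (the
        most divergent sequence may legitimately be the family's outgroup)
        until a curator confirms they are artifacts.
        """
        drop = {FLAG_FRAGMENT, FLAG_MANUAL}
        return {
            m for m in self.members if not (self.flags.get(m, set()) & drop)
        }


def traverse(net: SimilarityNetwork, seed: str, threshold: float) -> set[str]:
    """Connected component of the thresholded network containing *seed*."""
    if seed not in net.graph:
        raise KeyError(f"seed {seed!r} not in network")
    sub = net.constrain(threshold)
    return set(nx.node_connected_component(sub.graph, seed))


def sweep(
    net: SimilarityNetwork, seed: str, grid: Sequence[int] = DEFAULT_GRID
) -> SweepCurve:
    """Family size at each grid exponent (traversal per threshold).

    The grid must be sorted stringent -> permissive (ascending exponents);
    counts are then non-decreasing.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted stringent -> permissive")
    counts = tuple(len(traverse(net, seed, 10.0 ** e)) for e in grid)
    return SweepCurve(seed_id=seed, grid=grid, counts=counts)


def select_threshold(
    curve: SweepCurve,
    stability_steps: int = DEFAULT_STABILITY_STEPS,
    tol_frac: float = DEFAULT_TOL_FRAC,
) -> float:
    """Most stringent grid point opening the longest stable run of the sweep.

    A run starting at grid index i extends while counts stay within
    ``tol_frac`` of ``counts[i]``.  Among runs of length >= stability_steps
    the longest wins; ties break toward stringency (smaller exponent).
    Raises :class:`NoPlateauError` when no run qualifies.
    """
    if stability_steps < 2:
        raise ValueError("stability_steps must be >= 2")
    counts = curve.counts
    n = len(counts)
    best_start, best_len = None, 0
    for i in range(n):
        tol = tol_frac * counts[i]
        j = i
        while j + 1 < n and abs(counts[j + 1] - counts[i]) <= tol:
            j += 1
        run_len = j - i + 1
        if run_len >= stability_steps and run_len > best_len:
            best_start, best_len = i, run_len
    if best_start is None:
        raise NoPlateauError(
            f"no run of >= {stability_steps} thresholds with counts within "
            f"{tol_frac:.0%} for seed {curve.seed_id!r}; choose manually"
        )
    return 10.0 ** curve.grid[best_start]


def merge_families(
    results: Iterable[tuple[str, float, set[str]]],
) -> FamilyResult:
    """Union per-seed traversal results; overlaps are logged, not an error."""
    results = list(results)
    if not results:
        raise ValueError("merge_families needs at least one traversal result")
    seeds: list[str] = []
    thresholds: dict[str, float] = {}
    members: set[str] = set()
    for seed, threshold, mset in results:
        overlap = members & mset
        if overlap:
            logger.warning(
                "seed %s: %d members overlap earlier traversals (expected "
                "disjoint sets)", seed, len(overlap),
            )
        seeds.append(seed)
        thresholds[seed] = threshold
        members |= set(mset)
    return FamilyResult(seeds=seeds, threshold_per_seed=thresholds, members=members)


def apply_exclude_list(fam: FamilyResult, exclude: Iterable[str]) -> FamilyResult:
    """Mark user-curated false positives (e.g. an interloper transporter family)."""
    for gene_id in exclude:
        if gene_id in fam.members:
            fam.flag(gene_id, FLAG_MANUAL)
    return fam


def flag_suspects(
    fam: FamilyResult,
    gs: GenomeSet,
    net: SimilarityNetwork,
    len_frac: float = 0.5,
    mad_factor: float = 3.0,
) -> FamilyResult:
    """Flag probable fragments and unusually divergent members.

    * ``fragment``: protein length below ``len_frac`` x median member length
      (frameshifts and truncated gene models produce short translations).
    * ``long_branch``: mean pairwise distance (1 - identity fraction from the
      network edge; missing edge counts as the maximal observed distance) to
      the other members exceeds median + ``mad_factor`` x MAD over members.

    Flags annotate members; nothing is removed.
    """
    members = sorted(fam.members)
    lengths = {m: len(gs.get(m).protein) for m in members}
    median_len = float(np.median(list(lengths.values())))
    for m in members:
        if lengths[m] < len_frac * median_len:
            fam.flag(m, FLAG_FRAGMENT)

    if len(members) >= 3:
        dist = np.zeros((len(members), len(members)))
        missing = []
        for i, a in enumerate(members):
            for j in range(i + 1, len(members)):
                b = members[j]
                data = net.edge(a, b)
                if data is None:
                    missing.append((i, j))
                else:
                    dist[i, j] = dist[j, i] = 1.0 - data["identity_pct"] / 100.0
        dmax = dist.max()
        for i, j in missing:
            dist[i, j] = dist[j, i] = dmax + 0.05
        mean_d = (dist.sum(axis=1)) / (len(members) - 1)
        med = np.median(mean_d)
        mad = np.median(np.abs(mean_d - med))
        cutoff = med + mad_factor * mad
        for i, m in enumerate(members):
            if mean_d[i] > cutoff:
                fam.flag(m, FLAG_LONG_BRANCH)
    return fam
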