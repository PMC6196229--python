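"""Multi-genome gene catalogs: protein sequences plus gene order.

The pipeline reasons about gene neighborhoods in *ordinal* coordinates: each
gene has a rank along its contig (1, 2, 3, ...) and neighborhood queries slice
that ranking. Base-pair coordinates, if present in the input table, are carried
as opaque metadata and never used.

Input formats
-------------
* Protein FASTA, one or several files; record id == gene_id.
* Gene-order table: TSV with header columns
  ``gene_id  genome_id  contig_id  position  strand  [start  end]``.
* Genome manifest (optional): TSV with ``genome_id  species_code
  [species_name]``.  Species codes follow the four-letter convention (first
  two letters of genus + species, optional strain suffix, e.g. ``sace``,
  ``zyro``).  Without a manifest the species code defaults to the first four
  characters of the genome id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class GenomeSetError(ValueError):
    """Validation failure while assembling a :class:`GenomeSet`."""


class UnknownGeneError(KeyError):
    """A gene id was not found in the genome set."""


@dataclass(frozen=True)
class GeneLocus:
    """One protein-coding gene: identity, location and product sequence."""

    gene_id: str
    genome_id: str
    species_code: str
    contig_id: str
    position: int  # ordinal rank along the contig, 1-based
    strand: str  # '+' or '-'
    protein: str
    meta: tuple = ()  # opaque (key, value) pairs, e.g. bp start/end

    def __post_init__(self) -> None:
        if self.position < 1:
            raise GenomeSetError(
                f"gene {self.gene_id}: position must be >= 1, got {self.position}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeSetError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.protein:
            raise GenomeSetError(f"gene {self.gene_id}: empty protein sequence")
        bad = set(self.protein.upper()) - _VALID_RESIDUES
        if bad:
            raise GenomeSetError(
                f"gene {self.gene_id}: invalid residues {sorted(bad)}"
            )


class GenomeSet:
    """Indexed collection of genomes, each a set of ordered contigs.

    Iterating a contig yields loci sorted by position; every gene id resolves
    in O(1) through :meth:`get`.
    """

    def __init__(
        self,
        loci: Iterable[GeneLocus],
        species_map: Mapping[str, str] | None = None,
    ) -> None:
        self.genomes: dict[str, dict[str, list[GeneLocus]]] = {}
        self._index: dict[str, GeneLocus] = {}
        for locus in loci:
            if locus.gene_id in self._index:
                other = self._index[locus.gene_id]
                raise GenomeSetError(
                    f"duplicate gene id {locus.gene_id!r} "
                    f"(genomes {other.genome_id!r} and {locus.genome_id!r})"
                )
            self._index[locus.gene_id] = locus
            self.genomes.setdefault(locus.genome_id, {}).setdefault(
                locus.contig_id, []
            ).append(locus)
        self.species_map: dict[str, str] = dict(species_map or {})
        for genome_id in self.genomes:
            self.species_map.setdefault(genome_id, genome_id[:4])
        self._validate()

    def _validate(self) -> None:
        for genome_id, contigs in self.genomes.items():
            for contig_id, loci in contigs.items():
                loci.sort(key=lambda l: l.position)
                positions = [l.position for l in loci]
                if positions != list(range(1, len(loci) + 1)):
                    raise GenomeSetError(
                        f"contig {contig_id!r} of genome {genome_id!r}: positions "
                        f"must be consecutive from 1, got {positions}"
                    )

    # -- lookups ---------------------------------------------------------

    def get(self, gene_id: str) -> GeneLocus:
        try:
            return self._index[gene_id]
        except KeyError:
            raise UnknownGeneError(gene_id) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def contig_of(self, gene_id: str) -> list[GeneLocus]:
        locus = self.get(gene_id)
        return self.genomes[locus.genome_id][locus.contig_id]

    def loci(self) -> Iterator[GeneLocus]:
        for contigs in self.genomes.values():
            for contig in contigs.values():
                yield from contig

    def gene_ids(self) -> list[str]:
        return list(self._index)

    def species_of(self, gene_id: str) -> str:
        return self.get(gene_id).species_code


def neighbors_on_contig(
    gs: GenomeSet, gene_id: str, k: int
) -> tuple[list[GeneLocus], list[GeneLocus]]:
    """Up to ``k`` genes on each side of *gene_id*, nearest-first.

    Membership is purely positional: strand is ignored, and the lists are
    truncated at contig ends (a gene at position 1 has no upstream
    neighbors).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    locus = gs.get(gene_id)
    contig = gs.contig_of(gene_id)
    i = locus.position - 1
    upstream = contig[max(0, i - k) : i][::-1]
    downstream = contig[i + 1 : i + 1 + k]
    return upstream, downstream


# -- IO -------------------------------------------------------------------

GENE_TABLE_COLUMNS = ["gene_id", "genome_id", "contig_id", "position", "strand"]


def load_genome_set(
    fasta_paths: Sequence[str | Path] | str | Path,
    gene_table_path: str | Path,
    manifest_path: str | Path | None = None,
) -> GenomeSet:
    """Read protein FASTA file(s) plus a gene-order table into a GenomeSet.

    Every FASTA record id must appear exactly once in the gene table and
    vice versa; violations raise :class:`GenomeSetError` naming the
    offending ids.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    seqs: dict[str, str] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise GenomeSetError(f"duplicate FASTA record id {rec.id!r}")
            seqs[rec.id] = str(rec.seq)

    table = pd.read_csv(gene_table_path, sep="\t", dtype={"contig_id": str})
    missing_cols = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise GenomeSetError(f"gene table missing columns {sorted(missing_cols)}")
    dup = table["gene_id"][table["gene_id"].duplicated()]
    if not dup.empty:
        raise GenomeSetError(f"duplicate gene ids in table: {sorted(dup)}")

    table_ids = set(table["gene_id"])
    only_fasta = sorted(set(seqs) - table_ids)
    only_table = sorted(table_ids - set(seqs))
    if only_fasta or only_table:
        raise GenomeSetError(
            f"gene id mismatch: {only_fasta[:5]} only in FASTA, "
            f"{only_table[:5]} only in gene table"
        )

    extra_cols = [c for c in table.columns if c not in GENE_TABLE_COLUMNS]
    species_map = None
    if manifest_path is not None:
        manifest = pd.read_csv(manifest_path, sep="\t")
        species_map = dict(zip(manifest["genome_id"], manifest["species_code"]))

    loci = []
    for row in table.itertuples(index=False):
        meta = tuple(
            (c, getattr(row, c)) for c in extra_cols if pd.notna(getattr(row, c))
        )
        genome_id = str(row.genome_id)
        species = (species_map or {}).get(genome_id, genome_id[:4])
        loci.append(
            GeneLocus(
                gene_id=str(row.gene_id),
                genome_id=genome_id,
                species_code=species,
                contig_id=str(row.contig_id),
                position=int(row.position),
                strand=str(row.strand),
                protein=seqs[str(row.gene_id)],
                meta=meta,
            )
        )
    return GenomeSet(loci, species_map=species_map)


def emit_genome_set(
    gs: GenomeSet, outdir: str | Path, prefix: str = "genomes"
) -> dict[str, Path]:
    """Write FASTA + gene-order table + manifest; inverse of load_genome_set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / f"{prefix}.faa"
    table_path = outdir / f"{prefix}.genes.tsv"
    manifest_path = outdir / f"{prefix}.manifest.tsv"

    records = []
    rows = []
    for genome_id in sorted(gs.genomes):
        for contig_id in sorted(gs.genomes[genome_id]):
            for locus in gs.genomes[genome_id][contig_id]:
                records.append(
                    SeqRecord(Seq(locus.protein), id=locus.gene_id, description="")
                )
                rows.append(
                    {
                        "gene_id": locus.gene_id,
                        "genome_id": locus.genome_id,
                        "contig_id": locus.contig_id,
                        "position": locus.position,
                        "strand": locus.strand,
                        **dict(locus.meta),
                    }
                )
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    manifest = pd.DataFrame(
        sorted(
            {(g, gs.species_map[g]) for g in gs.genomes},
        ),
        columns=["genome_id", "species_code"],
    )
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return {"fasta": fasta_path, "gene_table": table_path, "manifest": manifest_path}
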