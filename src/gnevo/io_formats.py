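"""Readers and writers for the formats the pipeline touches.

GenBank flat files carry the annotated genomes (one file per genome, one
record per scaffold); domain hits arrive as a minimal four-column TSV
(``gene_id<TAB>family<TAB>subfamily<TAB>score``); gene trees are Newick.
Coordinates follow the GenBank convention (1-based, inclusive). All window
arithmetic downstream runs on the 0-based ``rank`` of a gene along its
scaffold, which isolates it from nucleotide coordinates entirely.

Users converting HMMER ``--domtblout`` output to the hit TSV map columns as
follows: target name -> ``gene_id``, query name -> ``family``, an optional
clade/subfamily annotation -> ``subfamily`` (empty if none), full-sequence
bit score -> ``score``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates;
    ``rank`` is the 0-based position of the gene along its scaffold when
    genes are ordered by ascending start. ``protein`` may be ``None`` for
    genes lacking a translation; such genes still count for neighbourhood
    membership but are excluded from sequence-based indices.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: int
    rank: int
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.gene_id}: strand must be +1/-1")


@dataclass(frozen=True)
class DomainHit:
    """Assignment of a Pfam-style domain family to a gene.

    ``subfamily`` is the empty string when only the family is known
    (e.g. family ``p450`` with subfamily ``CYP705A``, or family
    ``Transferase`` with subfamily ``ACT_IIIa``).
    """

    gene_id: str
    family: str
    subfamily: str = ""
    score: float = 0.0

    def name_at(self, level: str) -> str:
        """Domain name at the requested granularity.

        At ``subfamily`` level the subfamily name is used when present,
        falling back to the family for hits without one.
        """
        if level == "subfamily" and self.subfamily:
            return self.subfamily
        if level not in ("family", "subfamily"):
            raise ValueError(f"unknown level {level!r}")
        return self.family


@dataclass
class AnnotatedGenome:
    """A genome as a flat gene table plus its domain hits."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    hits: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_scaffold: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            self._by_scaffold.setdefault(g.scaffold_id, []).append(g)
        for scaf, gs in self._by_scaffold.items():
            gs.sort(key=lambda g: g.rank)
            if [g.rank for g in gs] != list(range(len(gs))):
                raise ValueError(f"scaffold {scaf}: ranks are not consecutive from 0")
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in genome")

    def scaffold(self, scaffold_id: str) -> list[GeneRecord]:
        return self._by_scaffold[scaffold_id]

    @property
    def scaffolds(self) -> list[str]:
        return list(self._by_scaffold)

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def attach_hits(self, hits: Iterable[DomainHit], strict: bool = True) -> None:
        for h in hits:
            if h.gene_id not in self._by_id:
                if strict:
                    raise ValueError(f"domain hit references unknown gene {h.gene_id!r}")
                logger.warning("dropping hit for unknown gene %s", h.gene_id)
                continue
            self.hits.append(h)


def _assign_ranks(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Re-derive ranks per scaffold from start positions (stable on ties)."""
    out: list[GeneRecord] = []
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for gs in by_scaffold.values():
        gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
        out.extend(replace(g, rank=i) for i, g in enumerate(gs))
    return out


def parse_genbank(path: str | Path, genome_id: str | None = None) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    Each record becomes one scaffold; each CDS feature becomes one
    :class:`GeneRecord`. The gene identifier is taken from ``locus_tag``,
    ``gene`` or ``protein_id`` (in that order). Compound (join) locations
    take the minimum start and maximum end — only gene order matters
    downstream. ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    genome_id = genome_id or path.stem
    genes: list[GeneRecord] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        scaffold_id = record.name or record.id
        for feat in record.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = None
            for key in ("locus_tag", "gene", "protein_id"):
                if quals.get(key):
                    gene_id = quals[key][0]
                    break
            if gene_id is None:
                raise FormatError(
                    f"{path.name}:{scaffold_id}: CDS at {feat.location} has no "
                    "locus_tag/gene/protein_id identifier"
                )
            if feat.location is None:
                raise FormatError(f"{path.name}:{scaffold_id}: CDS {gene_id} has no location")
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = -1 if feat.location.strand == -1 else 1
            protein = quals.get("translation", [None])[0]
            genes.append(
                GeneRecord(gene_id, scaffold_id, start, end, strand, rank=0, protein=protein)
            )
    if n_records == 0:
        raise FormatError(f"{path}: no records")
    return AnnotatedGenome(genome_id, _assign_ranks(genes))


DOMAIN_TABLE_COLUMNS = ("gene_id", "family", "subfamily", "score")


def parse_domain_table(path: str | Path) -> list[DomainHit]:
    """Read the tab-separated domain-hit table.

    The header row must name the columns ``gene_id``, ``family``,
    ``subfamily`` and ``score``. A blank subfamily is allowed; a
    non-numeric score is an error reported with its line number.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != DOMAIN_TABLE_COLUMNS:
            raise FormatError(
                f"{path}: unknown column layout {header!r}; expected "
                + "\\t".join(DOMAIN_TABLE_COLUMNS)
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            gene_id, family, subfamily, score_s = (c.strip() for c in row)
            try:
                score = float(score_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score {score_s!r}") from None
            if score != score:  # NaN
                raise FormatError(f"{path}:{lineno}: score is not finite")
            hits.append(DomainHit(gene_id, family, subfamily, score))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DOMAIN_TABLE_COLUMNS)
        for h in hits:
            writer.writerow([h.gene_id, h.family, h.subfamily, repr(h.score)])


def parse_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    Missing branch lengths default to 1.0 (the root edge to 0.0); duplicate
    leaf names are an error. Underscores in labels are preserved verbatim.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise FormatError(f"{path}: unparseable newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate leaf names: {sorted(dupes)}")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.head_node is tree.seed_node else 1.0
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string with the same conventions as :func:`parse_newick`."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf names: {sorted(dupes)}")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.head_node is tree.seed_node else 1.0
    return tree


def write_neighbourhood_genbank(gn, genome: AnnotatedGenome, path: str | Path) -> None:
    """Export one genome neighbourhood as a GenBank record.

    Coordinates are shifted so the window starts at 1; gene ids, order and
    strands survive a round trip through :func:`parse_genbank`. The
    nucleotide sequence of the window is not retained by the pipeline, so
    the record carries an ``N`` run of the right length.
    """
    members = []
    for gid in gn.member_gene_ids:
        if gid not in genome:
            raise ValueError(f"GN {gn.gn_id} references missing gene {gid!r}")
        members.append(genome.gene(gid))
    members.sort(key=lambda g: g.start)
    offset = members[0].start - 1
    length = members[-1].end - offset
    locus = gn.gn_id.replace(":", "_").replace("-", "_")
    record = SeqRecord(Seq("N" * length), id=locus, name=locus, description=f"GN {gn.gn_id}")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["source"] = gn.genome_id
    for g in members:
        quals = {"locus_tag": [g.gene_id]}
        if g.protein is not None:
            quals["translation"] = [g.protein]
        loc = SimpleLocation(g.start - offset - 1, g.end - offset, strand=g.strand)
        record.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write([record], fh, "genbank")


def write_protein_fasta(
    genes: Iterable[GeneRecord], path: str | Path, skip_missing: bool = True
) -> int:
    """Write protein sequences to FASTA; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            if g.protein is None:
                if not skip_missing:
                    raise ValueError(f"gene {g.gene_id} has no translation")
                continue
            fh.write(f">{g.gene_id}\n{g.protein}\n")
            n += 1
    return n
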