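"""Species-resolved genome catalog and the concatenated multi-genome reference.

The catalog holds one :class:`MemberGenome` per consortium member, each with its
contig sequences and gene models (GFF3 convention: 1-based, inclusive
coordinates). For read attribution, all member contigs are concatenated into a
single reference sequence — an "artificial chromosome" — with runs of ambiguous
``N`` bases between consecutive contigs so that reads spanning a contig
boundary can be recognized and discarded rather than mis-assigned. Positions on
the concatenated reference are 0-based; :func:`liftover` maps them back to
(genome, contig, 1-based local position).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`liftover` for positions inside an inter-contig spacer.
SPACER = "SPACER"

TAXON_GROUPS = ("Cyanobacteria", "Alphaproteobacteria", "Gammaproteobacteria", "Bacteroidetes")


@dataclass
class Gene:
    """A protein-coding gene (1-based inclusive coordinates on its contig)."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    marker_labels: set = field(default_factory=set)

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class MemberGenome:
    """One consortium member: contig sequences plus gene models.

    ``completeness`` (fraction of the genome recovered, from single-copy-gene
    analysis of the upstream reconstruction) is carried as metadata only; no
    gene content is imputed for incomplete bins, so capability predictions made
    from the catalog are conservative.
    """

    genome_id: str
    contigs: dict  # contig_id -> nucleotide sequence (str)
    genes: list  # list[Gene]
    taxon_group: str = ""
    source: str = "isolate"  # {isolate, metagenome_bin}
    completeness: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError(f"{self.genome_id}: completeness must be in [0, 1]")
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in genome {self.genome_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(
                    f"gene {g.gene_id}: contig {g.contig_id!r} not present in genome "
                    f"{self.genome_id}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} exceeds contig {g.contig_id} length "
                    f"{len(self.contigs[g.contig_id])}"
                )

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class Segment:
    """One contig's slice of the concatenated reference (0-based global offset)."""

    genome_id: str
    contig_id: str
    offset: int
    length: int


@dataclass
class ConcatenatedReference:
    """Concatenation of all member contigs, spacer_len ``N``s between contigs."""

    sequence: str
    spacer_len: int
    segments: list  # list[Segment], ordered by offset

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_at(self, global_pos: int):
        """Segment containing ``global_pos``, or None if it falls in a spacer."""
        if not 0 <= global_pos < len(self.sequence):
            raise IndexError(f"global position {global_pos} outside reference of length {len(self)}")
        offsets = self._offsets()
        i = bisect_right(offsets, global_pos) - 1
        seg = self.segments[i]
        if global_pos < seg.offset + seg.length:
            return seg
        return None

    def _offsets(self):
        if not hasattr(self, "_offset_cache"):
            self._offset_cache = [s.offset for s in self.segments]
        return self._offset_cache

    def liftover(self, global_pos: int):
        """Map a 0-based global position to (genome_id, contig_id, local 1-based pos).

        Returns the :data:`SPACER` sentinel for inter-contig spacer positions.
        """
        seg = self.segment_at(global_pos)
        if seg is None:
            return SPACER
        return (seg.genome_id, seg.contig_id, global_pos - seg.offset + 1)

    def global_position(self, genome_id: str, contig_id: str, local_pos: int) -> int:
        """Inverse of :meth:`liftover` for non-spacer positions (local_pos is 1-based)."""
        for seg in self.segments:
            if seg.genome_id == genome_id and seg.contig_id == contig_id:
                if not 1 <= local_pos <= seg.length:
                    raise IndexError(
                        f"local position {local_pos} outside contig {contig_id} "
                        f"of length {seg.length}"
                    )
                return seg.offset + local_pos - 1
        raise KeyError(f"({genome_id}, {contig_id}) not in reference")


def liftover(ref: ConcatenatedReference, global_pos: int):
    """Functional alias for :meth:`ConcatenatedReference.liftover`."""
    return ref.liftover(global_pos)


def build_concatenated_reference(
    catalog: Sequence[MemberGenome], spacer_len: int = 10
) -> ConcatenatedReference:
    """Concatenate all contigs of all genomes into a single reference.

    Segment order is deterministic: genomes sorted by genome_id, contigs by
    contig_id within each genome. Consecutive contigs are separated by
    ``spacer_len`` ambiguous ``N`` nucleotides.
    """
    if not catalog:
        raise ValueError("cannot build a reference from an empty catalog")
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    parts, segments = [], []
    offset = 0
    for genome in sorted(catalog, key=lambda g: g.genome_id):
        for contig_id in sorted(genome.contigs):
            seq = genome.contigs[contig_id]
            if segments:  # spacer before every contig except the first
                parts.append("N" * spacer_len)
                offset += spacer_len
            segments.append(Segment(genome.genome_id, contig_id, offset, len(seq)))
            parts.append(seq)
            offset += len(seq)
    return ConcatenatedReference(sequence="".join(parts), spacer_len=spacer_len, segments=segments)


def _as_path_map(paths) -> dict:
    """Normalize a path list / mapping into {genome_id: Path} (list items keyed by stem)."""
    if isinstance(paths, Mapping):
        return {k: Path(v) for k, v in paths.items()}
    return {Path(p).stem: Path(p) for p in paths}


def _parse_gff3(path: Path, genome_id: str) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    feature_types = ["gene"] if "gene" in set(db.featuretypes()) else ["CDS"]
    genes = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by="start"):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            product = feat.attributes.get("product", [""])[0]
            if feat.end < feat.start:
                raise ValueError(f"gene {gene_id}: end {feat.end} < start {feat.start}")
            genes.append(
                Gene(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    product=product,
                )
            )
    return genes


def load_catalog(
    genome_fastas,
    gene_models,
    marker_table=None,
    metadata=None,
) -> list:
    """Load a cross-linked genome catalog from FASTA + GFF3 + marker-table files.

    Parameters
    ----------
    genome_fastas, gene_models
        Mappings ``{genome_id: path}`` (or path lists, keyed by file stem) of
        nucleotide FASTAs and the matching GFF3 gene models.
    marker_table
        Optional TSV with columns ``genome_id, gene_id, marker_label[, subsystem]``.
        Labels are attached to ``Gene.marker_labels``; rows referencing unknown
        genes are reported via a logged warning.
    metadata
        Optional TSV with columns ``genome_id, taxon_group, source, completeness``.

    Returns the list of :class:`MemberGenome`, sorted by genome_id.
    """
    fasta_map = _as_path_map(genome_fastas)
    gff_map = _as_path_map(gene_models)
    if set(fasta_map) != set(gff_map):
        raise ValueError(
            f"genome ids differ between FASTA ({sorted(fasta_map)}) and GFF3 ({sorted(gff_map)})"
        )
    meta = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep="\t")
        meta = {row["genome_id"]: row for _, row in mdf.iterrows()}

    catalog = []
    for genome_id in sorted(fasta_map):
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_map[genome_id]), "fasta")}
        genes = _parse_gff3(gff_map[genome_id], genome_id)
        for g in genes:
            if g.contig_id not in contigs:
                raise ValueError(
                    f"gene {g.gene_id}: contig {g.contig_id!r} missing from FASTA of {genome_id}"
                )
        row = meta.get(genome_id)
        catalog.append(
            MemberGenome(
                genome_id=genome_id,
                contigs=contigs,
                genes=genes,
                taxon_group=str(row["taxon_group"]) if row is not None else "",
                source=str(row["source"]) if row is not None else "isolate",
                completeness=float(row["completeness"]) if row is not None else 1.0,
            )
        )

    if marker_table is not None:
        attach_markers(catalog, marker_table)
    return catalog


def attach_markers(catalog: Sequence[MemberGenome], marker_table) -> pd.DataFrame:
    """Attach marker labels from a TSV to catalog genes; return unreferenced rows."""
    table = marker_table if isinstance(marker_table, pd.DataFrame) else pd.read_csv(marker_table, sep="\t")
    by_genome = {g.genome_id: {gene.gene_id: gene for gene in g.genes} for g in catalog}
    missing = []
    for _, row in table.iterrows():
        gene_map = by_genome.get(row["genome_id"], {})
        gene = gene_map.get(row["gene_id"])
        if gene is None:
            missing.append(row)
        else:
            gene.marker_labels.add(row["marker_label"])
    unreferenced = pd.DataFrame(missing)
    if len(unreferenced):
        logger.warning(
            "%d marker rows reference genes absent from the catalog (e.g. %s)",
            len(unreferenced),
            unreferenced.iloc[0].to_dict(),
        )
    return unreferenced


def genes_of(catalog: Iterable[MemberGenome]):
    """Iterate over all genes of a catalog."""
    for genome in catalog:
        yield from genome.genes


def gene_index(catalog: Iterable[MemberGenome]) -> dict:
    """{gene_id: Gene} across the whole catalog (gene ids are catalog-unique)."""
    index = {}
    for gene in genes_of(catalog):
        if gene.gene_id in index:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r} across catalog")
        index[gene.gene_id] = gene
    return index


def write_reference(ref: ConcatenatedReference, fasta_path, segments_path=None, name="concatenated"):
    """Write the reference FASTA plus an optional segments TSV sidecar."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(ref.sequence), 80):
            fh.write(ref.sequence[i : i + 80] + "\n")
    if segments_path is not None:
        pd.DataFrame(
            [
                {"genome_id": s.genome_id, "contig_id": s.contig_id, "offset": s.offset, "length": s.length}
                for s in ref.segments
            ]
        ).to_csv(segments_path, sep="\t", index=False)
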