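"""Transcriptome read attribution and per-organism RPKM normalization.

Reads are placed on the concatenated multi-genome reference by exact k-mer
seeding plus full-length verification; a read counts toward a gene when its
mapped interval overlaps the gene by at least half the read length. Reads that
match more than one locus, span an inter-contig spacer, or fall between genes
are tallied as unassigned (by category) so that reads are conserved:
``assigned + unassigned = processed`` per sample.

The normalization statistic is the study's per-organism RPKM: reads per
kilobase of gene per **million reads mapped to that organism's genes** in the
same sample,

    RPKM_{g,s} = c_{g,s} / (L_g / 1e3) / (R_{o(g),s} / 1e6),

with R_{o,s} = sum of counts over the organism's genes. Rescaling one
organism's sequencing depth by any positive factor leaves its RPKM values
unchanged, which makes within-species comparisons across time valid while
values are *not* comparable across species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_catalog import ConcatenatedReference, MemberGenome, gene_index

logger = logging.getLogger(__name__)

UNASSIGNED_CATEGORIES = ("unmatched", "multimapped", "spacer", "intergenic", "ambiguous_gene")


@dataclass
class GeneCountMatrix:
    """Gene × sample read counts plus per-sample unassigned tallies.

    ``samples`` is indexed by sample_id with ``day`` and ``replicate`` columns;
    ``unassigned`` is category × sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unassigned: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")

    def total_processed(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned.sum(axis=0)


@dataclass
class RPKMMatrix:
    """Per-organism RPKM values with the genome × sample basis R_{o,s}."""

    values: pd.DataFrame
    basis: pd.DataFrame
    samples: pd.DataFrame
    zero_basis: pd.DataFrame = field(default=None)  # genome × sample bool flags


@dataclass
class SpeciesActivity:
    """Genome × sample fractions of assigned reads (sum to 1 per sample)."""

    shares: pd.DataFrame
    basis: pd.Series  # total assigned reads per sample


@dataclass
class ReplicateSummary:
    mean: float
    ci_low: float
    ci_high: float
    n: int


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

def _iter_reads(source):
    """Yield (read_id, sequence) from a FASTQ path/handle or an iterable of pairs."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        try:
            for rec in SeqIO.parse(str(source), "fastq"):
                yield rec.id, str(rec.seq).upper()
        except ValueError as exc:  # malformed record aborts the rest of the stream
            logger.warning("malformed FASTQ record in %s: %s", source, exc)
        return
    for item in source:
        rid, seq = item[0], item[1]
        yield rid, seq.upper()


def build_kmer_index(sequence: str, k: int) -> dict:
    """Exact k-mer index: k-mer -> list of 0-based start positions."""
    index: dict = {}
    for i in range(len(sequence) - k + 1):
        index.setdefault(sequence[i : i + k], []).append(i)
    return index


class _GeneLocator:
    """Per-(genome, contig) interval trees over gene coordinates."""

    def __init__(self, catalog: Sequence[MemberGenome]):
        from intervaltree import IntervalTree

        self.trees: dict = {}
        for genome in catalog:
            for gene in genome.genes:
                key = (genome.genome_id, gene.contig_id)
                tree = self.trees.setdefault(key, IntervalTree())
                # store genes 0-based half-open
                tree[gene.start - 1 : gene.end] = gene.gene_id

    def best_gene(self, genome_id, contig_id, start0, end0, min_overlap):
        """Gene with the largest overlap >= min_overlap, or None ('' on tie)."""
        tree = self.trees.get((genome_id, contig_id))
        if tree is None:
            return None
        best, best_ov, tie = None, 0, False
        for iv in tree.overlap(start0, end0):
            ov = min(end0, iv.end) - max(start0, iv.begin)
            if ov > best_ov:
                best, best_ov, tie = iv.data, ov, False
            elif ov == best_ov and best is not None:
                tie = True
        if best_ov < min_overlap:
            return None
        return "" if tie else best


def assign_reads(
    reads_by_sample: Mapping,
    ref: ConcatenatedReference,
    catalog: Sequence[MemberGenome],
    samples: Optional[pd.DataFrame] = None,
    k: int = 30,
    min_overlap_frac: float = 0.5,
) -> GeneCountMatrix:
    """Assign reads to genes on the concatenated reference by exact matching.

    Parameters
    ----------
    reads_by_sample
        ``{sample_id: fastq_path_or_iterable_of_(id, seq)}``.
    samples
        Optional metadata frame (index sample_id; ``day``/``replicate``
        columns). Defaults to a bare frame over the sample ids.
    k
        Seed length; reads shorter than ``k`` are unmatched.
    min_overlap_frac
        A read counts toward a gene only when the overlap is at least this
        fraction of the read length.

    A read is mapped when exactly one reference position verifies over its full
    length (multi-locus matches go to ``multimapped``); mapped reads whose
    interval crosses a spacer are ``spacer``; mapped reads overlapping no gene
    at the threshold are ``intergenic`` and equal-overlap ties are
    ``ambiguous_gene``.
    """
    if not ref.sequence:
        raise ValueError("empty reference")
    index = build_kmer_index(ref.sequence, k)
    locator = _GeneLocator(catalog)
    genes = [g.gene_id for genome in sorted(catalog, key=lambda x: x.genome_id)
             for g in genome.genes]

    sample_ids = list(reads_by_sample)
    counts = pd.DataFrame(0, index=genes, columns=sample_ids, dtype=int)
    unassigned = pd.DataFrame(0, index=list(UNASSIGNED_CATEGORIES), columns=sample_ids, dtype=int)

    for sample_id, source in reads_by_sample.items():
        for _, seq in _iter_reads(source):
            if len(seq) < k:
                unassigned.loc["unmatched", sample_id] += 1
                continue
            candidates = index.get(seq[:k], ())
            hits = [p for p in candidates if ref.sequence[p : p + len(seq)] == seq]
            if not hits:
                unassigned.loc["unmatched", sample_id] += 1
                continue
            if len(hits) > 1:
                unassigned.loc["multimapped", sample_id] += 1
                continue
            pos = hits[0]
            seg = ref.segment_at(pos)
            end_seg = ref.segment_at(pos + len(seq) - 1)
            if seg is None or end_seg is None or seg is not end_seg:
                unassigned.loc["spacer", sample_id] += 1
                continue
            local_start0 = pos - seg.offset
            gene = locator.best_gene(
                seg.genome_id, seg.contig_id, local_start0, local_start0 + len(seq),
                min_overlap=math.ceil(min_overlap_frac * len(seq)),
            )
            if gene is None:
                unassigned.loc["intergenic", sample_id] += 1
            elif gene == "":
                unassigned.loc["ambiguous_gene", sample_id] += 1
            else:
                counts.loc[gene, sample_id] += 1

    if samples is None:
        samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return GeneCountMatrix(counts=counts, samples=samples, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Normalization and shares
# ---------------------------------------------------------------------------

def _gene_annotations(counts: pd.DataFrame, catalog: Sequence[MemberGenome]):
    idx = gene_index(catalog)
    missing = [g for g in counts.index if g not in idx]
    if missing:
        raise KeyError(f"genes absent from catalog: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    genome_of = pd.Series({g: idx[g].genome_id for g in counts.index}, name="genome_id")
    lengths = pd.Series({g: idx[g].length_bp for g in counts.index}, name="length_bp").astype(float)
    return genome_of, lengths


def rpkm_per_organism(counts: GeneCountMatrix, catalog: Sequence[MemberGenome]) -> RPKMMatrix:
    """Compute per-organism RPKM; zero-basis cells are set to 0 and flagged."""
    genome_of, lengths = _gene_annotations(counts.counts, catalog)
    basis = counts.counts.groupby(genome_of).sum()  # genome × sample
    zero_basis = basis == 0
    per_gene_basis = basis.reindex(genome_of.values).set_axis(counts.counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = counts.counts.div(lengths / 1e3, axis=0) / (per_gene_basis / 1e6)
    values = values.fillna(0.0).replace([np.inf, -np.inf], 0.0)
    if zero_basis.values.any():
        logger.warning(
            "zero per-organism basis for %d (genome, sample) cells; RPKM set to 0",
            int(zero_basis.values.sum()),
        )
    return RPKMMatrix(values=values, basis=basis, samples=counts.samples, zero_basis=zero_basis)


def species_read_share(counts: GeneCountMatrix, catalog: Sequence[MemberGenome]) -> SpeciesActivity:
    """Fraction of assigned reads attributed to each genome, per sample."""
    if counts.counts.empty:
        raise ValueError("empty count matrix")
    genome_of, _ = _gene_annotations(counts.counts, catalog)
    basis = counts.counts.groupby(genome_of).sum()
    totals = basis.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero assigned reads: {list(empty.index)}")
    return SpeciesActivity(shares=basis / totals, basis=totals)


def replicate_summary(values: Iterable[float], confidence: float = 0.95,
                      normal: bool = False) -> ReplicateSummary:
    """Mean with a t-based (default) or normal-approximation CI of the mean."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("replicate_summary requires at least 2 replicates")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n))
    q = (1 + confidence) / 2
    crit = stats.norm.ppf(q) if normal else stats.t.ppf(q, df=n - 1)
    half = crit * sem
    return ReplicateSummary(mean=mean, ci_low=mean - half, ci_high=mean + half, n=n)


def day_replicate_groups(samples: pd.DataFrame) -> dict:
    """{day: [sample_id, ...]} in increasing day order."""
    if "day" not in samples.columns:
        raise ValueError("sample metadata lacks a 'day' column")
    return {day: list(group.index) for day, group in samples.groupby("day", sort=True)}


def write_counts_tsv(counts: GeneCountMatrix, catalog, path):
    genome_of, lengths = _gene_annotations(counts.counts, catalog)
    out = counts.counts.copy()
    out.insert(0, "genome_id", genome_of)
    out.insert(1, "length_bp", lengths.astype(int))
    out.to_csv(path, sep="\t", index_label="gene_id")
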