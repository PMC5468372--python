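"""Peptide-to-protein mapping, parsimony inference, and spectral counting.

Input is the downstream object of a spectral search: a table of confidently
identified peptides with per-sample spectral counts. Peptides are mapped to
every protein of the multi-species catalog whose in-silico tryptic digest
contains them; protein inference then applies the study's two filters:

1. a protein must be supported by at least two distinct peptides, and
2. a *minimum protein list* is derived — a smallest set of proteins explaining
   every mappable peptide (greedy set cover with lexicographic tie-breaks,
   pruned to irreducibility; an exhaustive minimum is available for small
   instances).

Protein abundance is the sum of spectral counts of a protein's peptides.
Species-level shares of the metaproteome are computed from peptides uniquely
attributable to one species (cross-species-shared peptides are excluded by
default, or split fractionally); within-species percentages are per-sample
percentages of the species' total counts over retained proteins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from pyteomics import parser as _pyt_parser

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Cleave C-terminal to K/R except before P.
TRYPSIN_RULE = r"[KR](?=[^P])"


def tryptic_digest(
    protein_seq: str,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> set:
    """In-silico tryptic peptides of a protein (set of sequences)."""
    if not protein_seq:
        return set()
    bad = set(protein_seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid symbols in protein sequence: {sorted(bad)}")
    peptides = _pyt_parser.cleave(
        protein_seq, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=min_len
    )
    return {p for p in peptides if len(p) <= max_len}


@dataclass
class PeptideProteinMap:
    """Bipartite peptide–protein structure over the observed peptides."""

    edges: dict  # peptide -> frozenset of protein_ids
    protein_to_genome: dict  # protein_id -> genome_id
    unmapped: set  # observed peptides absent from every digest
    digest_params: dict

    def proteins_of(self, peptide: str):
        return self.edges.get(peptide, frozenset())

    def cross_species_peptides(self) -> set:
        """Peptides shared by proteins of more than one species."""
        out = set()
        for pep, prots in self.edges.items():
            if len({self.protein_to_genome[p] for p in prots}) > 1:
                out.add(pep)
        return out


def _load_protein_catalog(proteins) -> dict:
    """Normalize to {protein_id: (genome_id, sequence)}.

    Accepts a mapping (values either sequences or (genome_id, seq) tuples) or a
    FASTA path whose headers carry ``genome_id=<id>``.
    """
    if isinstance(proteins, Mapping):
        out = {}
        for pid, val in proteins.items():
            if isinstance(val, tuple):
                out[pid] = (val[0], val[1])
            else:
                out[pid] = ("", val)
        return out
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(proteins), "fasta"):
        genome_id = ""
        for tok in rec.description.split():
            if tok.startswith("genome_id="):
                genome_id = tok.split("=", 1)[1]
        out[rec.id] = (genome_id, str(rec.seq).upper())
    return out


def map_peptides(
    peptides: Iterable[str],
    proteins,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> PeptideProteinMap:
    """Map observed peptides to all catalog proteins whose digest contains them."""
    catalog = _load_protein_catalog(proteins)
    observed = list(dict.fromkeys(peptides))  # preserve order, drop duplicates
    observed_set = set(observed)

    edges: dict = {}
    for protein_id, (_, seq) in catalog.items():
        for pep in tryptic_digest(seq, missed_cleavages, min_len, max_len) & observed_set:
            edges.setdefault(pep, set()).add(protein_id)
    return PeptideProteinMap(
        edges={p: frozenset(v) for p, v in edges.items()},
        protein_to_genome={pid: gid for pid, (gid, _) in catalog.items()},
        unmapped=observed_set - set(edges),
        digest_params={
            "missed_cleavages": missed_cleavages, "min_len": min_len, "max_len": max_len
        },
    )


@dataclass
class MinimalProteinList:
    """Result of the two-peptide filter plus minimum-protein-list parsimony."""

    retained: list  # protein_ids, in selection order
    distinct_peptides: dict  # protein_id -> distinct mapped peptide count
    coverage: dict  # protein_id -> set of peptides it explains
    uncovered: set  # mappable peptides left unexplained (empty by construction)
    dropped_few_peptides: set  # proteins failing the min_distinct threshold
    optimal_size: Optional[int] = None  # exhaustive minimum, when computed


def parsimony_filter(
    pmap: PeptideProteinMap, min_distinct: int = 2, exhaustive: bool = False
) -> MinimalProteinList:
    """Derive the minimum protein list.

    Proteins with fewer than ``min_distinct`` distinct mapped peptides are
    dropped first; peptides whose every protein was dropped become
    unexplainable and are excluded from the cover universe. Greedy set cover
    then retains, at each step, the protein explaining the most unexplained
    peptides (ties broken lexicographically by protein_id), followed by a
    pruning pass so that no retained protein is removable without uncovering a
    peptide. With ``exhaustive=True`` (feasible up to ~20 eligible proteins)
    the true minimum cover size is also computed and recorded.
    """
    if not pmap.edges:
        raise ValueError("peptide-protein map is empty")
    peptides_of: dict = {}
    for pep, prots in pmap.edges.items():
        for prot in prots:
            peptides_of.setdefault(prot, set()).add(pep)

    distinct = {prot: len(peps) for prot, peps in peptides_of.items()}
    eligible = {prot for prot, n in distinct.items() if n >= min_distinct}
    dropped = set(peptides_of) - eligible
    universe = {pep for pep, prots in pmap.edges.items() if prots & eligible}

    uncovered = set(universe)
    retained: list = []
    while uncovered:
        candidates = eligible - set(retained)
        if not candidates:
            break
        best = min(candidates, key=lambda p: (-len(peptides_of[p] & uncovered), p))
        if not (peptides_of[best] & uncovered):
            break
        retained.append(best)
        uncovered -= peptides_of[best]

    # prune redundant proteins (lexicographic order, repeat to fixpoint)
    changed = True
    while changed:
        changed = False
        for prot in sorted(retained):
            others = set().union(*(peptides_of[p] for p in retained if p != prot)) if len(retained) > 1 else set()
            if peptides_of[prot] & universe <= others:
                retained.remove(prot)
                changed = True

    optimal_size = None
    if exhaustive:
        optimal_size = _exhaustive_min_cover(sorted(eligible), peptides_of, universe)

    return MinimalProteinList(
        retained=retained,
        distinct_peptides={p: distinct[p] for p in retained},
        coverage={p: peptides_of[p] & universe for p in retained},
        uncovered=uncovered,
        dropped_few_peptides=dropped,
        optimal_size=optimal_size,
    )


def _exhaustive_min_cover(proteins, peptides_of, universe):
    """Smallest number of proteins covering the universe (ascending-size search)."""
    if not universe:
        return 0
    for size in range(1, len(proteins) + 1):
        for combo in itertools.combinations(proteins, size):
            covered = set()
            for p in combo:
                covered |= peptides_of[p]
            if universe <= covered:
                return size
    return len(proteins)


@dataclass
class ProteinAbundance:
    """Spectral-count quantities: per protein, within species, and across species."""

    protein_counts: pd.DataFrame  # retained protein × sample summed counts
    within_species_pct: pd.DataFrame  # same index; percent of species total per sample
    species_shares: pd.DataFrame  # genome × sample fractions (sum to 1)
    attributed_totals: pd.Series  # per-sample species-attributed counts
    protein_to_genome: dict = field(default_factory=dict)


def quantify_proteins(
    obs: pd.DataFrame,
    pmap: PeptideProteinMap,
    minimal: MinimalProteinList,
    shared_peptides: str = "per_protein",
    cross_species: str = "exclude",
) -> ProteinAbundance:
    """Quantify retained proteins and species shares from spectral counts.

    Parameters
    ----------
    obs
        Peptide × sample spectral counts (index: peptide sequence).
    shared_peptides
        ``per_protein`` (default): a peptide shared among retained proteins of
        one species counts toward each of them; ``unique_only`` counts only
        peptides mapping to a single retained protein.
    cross_species
        ``exclude`` (default) drops peptides shared across species from the
        species-share computation; ``fractional`` splits their counts equally
        among the species involved.
    """
    if shared_peptides not in ("per_protein", "unique_only"):
        raise ValueError(f"unknown shared_peptides mode {shared_peptides!r}")
    if cross_species not in ("exclude", "fractional"):
        raise ValueError(f"unknown cross_species mode {cross_species!r}")

    samples = list(obs.columns)
    retained = list(minimal.retained)
    retained_set = set(retained)

    # --- per-protein counts over retained proteins
    rows = []
    for prot in retained:
        peps = [p for p in minimal.coverage[prot] if p in obs.index]
        if shared_peptides == "unique_only":
            peps = [p for p in peps if len(pmap.proteins_of(p) & retained_set) == 1]
        rows.append(obs.loc[peps, samples].sum(axis=0) if peps else pd.Series(0.0, index=samples))
    protein_counts = pd.DataFrame(rows, index=pd.Index(retained, name="protein_id"))

    # --- species shares from peptide-level attribution (pre-parsimony)
    pep_genomes = {
        pep: {pmap.protein_to_genome[p] for p in pmap.proteins_of(pep)} for pep in obs.index
    }
    unique_map = pd.Series(
        {pep: next(iter(gs)) for pep, gs in pep_genomes.items() if len(gs) == 1}
    )
    attributed = (
        obs.loc[unique_map.index, samples].groupby(unique_map).sum()
        if len(unique_map)
        else pd.DataFrame(columns=samples, dtype=float)
    )
    if cross_species == "fractional":
        for pep, genomes in pep_genomes.items():
            if len(genomes) > 1:
                frac = obs.loc[pep, samples] / len(genomes)
                for gid in genomes:
                    if gid in attributed.index:
                        attributed.loc[gid] = attributed.loc[gid] + frac
                    else:
                        attributed.loc[gid] = frac
    if attributed.empty:
        raise ValueError("no species-attributable spectral counts")
    attributed = attributed.reindex(sorted(attributed.index))
    totals = attributed.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero attributed spectral counts: {list(empty.index)}")
    species_shares = attributed / totals

    # --- within-species percentages over retained proteins
    genome_of_protein = pd.Series({p: pmap.protein_to_genome[p] for p in retained})
    species_totals = protein_counts.groupby(genome_of_protein).transform("sum") if retained else protein_counts
    within_pct = 100.0 * protein_counts / species_totals.where(species_totals > 0)

    return ProteinAbundance(
        protein_counts=protein_counts,
        within_species_pct=within_pct,
        species_shares=species_shares,
        attributed_totals=totals,
        protein_to_genome={p: pmap.protein_to_genome[p] for p in retained},
    )


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide TSV (column ``peptide_seq`` + one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if "peptide_seq" not in df.columns:
        raise ValueError("peptide table must have a 'peptide_seq' column")
    return df.set_index("peptide_seq")


def write_protein_fasta(proteins: Mapping, path):
    """Write {protein_id: (genome_id, seq)} to FASTA with genome_id in headers."""
    with open(Path(path), "w") as fh:
        for pid, (gid, seq) in proteins.items():
            fh.write(f">{pid} genome_id={gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
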