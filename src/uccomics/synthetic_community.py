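"""Synthetic unicyanobacterial consortium with full ground truth.

Generates a desk-scale counterpart of the study system: 19 members (one
dominant cyanobacterium plus Alphaproteobacteria, Gammaproteobacteria, and
Bacteroidetes heterotrophs) sampled at days 7/14/21/28 in triplicate, with

* planted marker-gene content per member (including rhodopsin transport motifs
  and form I–III vs form IV RbcL sequences), so the capability engine's output
  has an exact expected answer;
* succession-structured species abundances (gammaproteobacteria decline,
  alphaproteobacteria/Bacteroidetes rise, the cyanobacterium holds ~50–60% of
  transcripts and ~85–90% of spectra);
* per-species transcript:protein detection bias factors spanning 0.2–16×,
  the planted counterpart of the observed activity-ratio span;
* expression programs: 4-fold phosphate-transporter induction in P-limited
  members, coupled or decoupled amt/glnA nitrogen responses, and a constant
  housekeeping gene (rpoC analog) per species;
* multinomial read and spectral-count sampling at configurable depths, with
  the generating truth recorded alongside every dataset.

Everything is deterministic for a fixed seed. Member genomes are random
nucleotide sequences with non-overlapping single-exon genes; protein sequences
are generated independently of the nucleotide sequence (the proteome pipeline
is sequence-level only), except that rhodopsin and RbcL proteins embed exactly
the features their planted labels claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from zlib import crc32

from .capability_engine import P_TRANSPORTER_HIERARCHY
from .genome_catalog import Gene, MemberGenome
from .proteome_quant import tryptic_digest
from .transcript_quant import GeneCountMatrix, UNASSIGNED_CATEGORIES

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_R = _AA.replace("R", "")
_NT = "ACGT"

N_CLASSES = ("coupled", "decoupled", "low_expression")


@dataclass(frozen=True)
class SpeciesSpec:
    """Planted properties of one consortium member."""

    genome_id: str
    taxon_group: str
    bias: float  # transcript:protein detection bias b_o (counterpart of rho)
    weights: tuple  # relative abundance weight per sampled day
    markers: tuple  # marker tokens present in the genome
    rhodopsin: Optional[str] = None  # None | proton_pumping | NQ
    rbcl_form: Optional[str] = None  # None | form_I_III | form_IV
    p_limited: bool = False
    n_class: str = "coupled"
    source: str = "metagenome_bin"
    completeness: float = 0.99


def default_panel() -> list:
    """The default 19-member panel (1 cyanobacterium + 18 heterotrophs).

    Biases span 0.2–16; gammaproteobacterial weights decline over succession
    while alphaproteobacteria and Bacteroidetes rise. Marker endowments give a
    varied capability truth table: nitrate assimilators (including via
    dissimilatory-reductase substitution), nitrite-only ammonifiers, members
    lacking sulfate reduction, rhodopsins of both motif types, and one
    form-IV RbcL carrier.
    """
    S = SpeciesSpec
    pst = ("pstS", "pstA", "pstB", "pstC")
    sulf_full = ("sat", "cysNC", "cysH", "sir")
    sulf_act = ("sat", "cysNC")
    return [
        S("cyano01", "Cyanobacteria", 0.55, (11.0, 13.0, 15.0, 17.0),
          ("nasA", "nirB", "amt", "glnA", "nifH", *sulf_full, *pst, "pitA", "phoA", "pyc", "rbcS"),
          rbcl_form="form_I_III", p_limited=True, n_class="coupled",
          source="isolate", completeness=1.0),
        # --- Gammaproteobacteria (decliners)
        S("gamma01", "Gammaproteobacteria", 3.5, (1.6, 1.0, 0.6, 0.35),
          ("nasA", "nirB", "amt", "glnA", *sulf_full, *pst, "pitA", "phoA", "ppc"),
          n_class="coupled", source="isolate", completeness=1.0),
        S("gamma02", "Gammaproteobacteria", 4.0, (1.2, 0.8, 0.5, 0.3),
          ("nasA", "nirB", "amt", "glnA", *sulf_act, *pst, "phoD", "ppc"),
          n_class="low_expression"),
        S("gamma03", "Gammaproteobacteria", 2.5, (0.9, 0.6, 0.4, 0.25),
          ("narG", "nirB", "amt", "glnA", *sulf_full, *pst, "pitA", "ppc"),
          n_class="coupled"),
        S("gamma04", "Gammaproteobacteria", 5.0, (0.7, 0.5, 0.35, 0.2),
          ("napA", "nirB", "amt", "glnA", *sulf_act, *pst, "ppc"),
          n_class="low_expression"),
        S("gamma05", "Gammaproteobacteria", 3.0, (1.8, 1.2, 0.7, 0.4),
          ("amt", "glnA", *sulf_full, *pst, "pitA", "phoA", "pyc"),
          p_limited=True, n_class="decoupled", source="isolate", completeness=1.0),
        S("gamma06", "Gammaproteobacteria", 4.5, (0.6, 0.45, 0.3, 0.2),
          ("narG", "amt", "glnA", *sulf_act, *pst, "yjbB", "ppc"),
          n_class="low_expression"),
        # --- Alphaproteobacteria (risers; the protein-rich low-ratio members are rare)
        S("alpha01", "Alphaproteobacteria", 0.35, (0.12, 0.18, 0.24, 0.32),
          ("bch", "puf", "amt", "glnA", *sulf_full, *pst, "pitA", "phoA", "pyc"),
          p_limited=True, n_class="coupled", source="isolate", completeness=1.0),
        S("alpha02", "Alphaproteobacteria", 3.0, (0.4, 0.55, 0.75, 1.0),
          ("bch", "puf", "narG", "amt", "glnA", *sulf_act, *pst, "phoD", "pyc"),
          p_limited=True, n_class="decoupled"),
        S("alpha03", "Alphaproteobacteria", 5.0, (0.35, 0.5, 0.7, 0.95),
          ("amt", "glnA", *sulf_full, *pst, "yjbB", "pyc"),
          rhodopsin="proton_pumping", p_limited=True, n_class="coupled"),
        S("alpha04", "Alphaproteobacteria", 7.0, (0.3, 0.4, 0.55, 0.75),
          ("amt", "glnA", *sulf_act, *pst, "pyc"),
          rhodopsin="NQ", p_limited=True, n_class="low_expression"),
        S("alpha05", "Alphaproteobacteria", 0.5, (0.15, 0.2, 0.28, 0.36),
          ("narG", "amt", "glnA", *sulf_full, *pst, "pitA", "phoA", "ppc"),
          p_limited=True, n_class="coupled", source="isolate", completeness=1.0),
        S("alpha06", "Alphaproteobacteria", 2.0, (0.35, 0.5, 0.65, 0.85),
          ("amt", "glnA", *sulf_act, *pst, "phoD", "ppc"),
          p_limited=True, n_class="decoupled"),
        S("alpha07", "Alphaproteobacteria", 0.2, (0.06, 0.08, 0.11, 0.15),
          ("amt", "glnA", *sulf_full, *pst, "pitA", "ppc"),
          p_limited=True, n_class="coupled"),
        S("alpha08", "Alphaproteobacteria", 3.5, (0.3, 0.4, 0.55, 0.7),
          ("amt", "glnA", *sulf_act, *pst, "yjbB", "phoA", "pyc"),
          rhodopsin="proton_pumping", p_limited=True, n_class="low_expression"),
        # --- Bacteroidetes (risers; PNaS-family transporters only)
        S("bact01", "Bacteroidetes", 8.0, (0.4, 0.6, 0.9, 1.3),
          ("nrfA", "amt", "glnA", *sulf_act, "yjbB", "phoA", "pyc"),
          rhodopsin="NQ", rbcl_form="form_IV", p_limited=True, n_class="decoupled"),
        S("bact02", "Bacteroidetes", 16.0, (0.4, 0.6, 0.85, 1.2),
          ("amt", "glnA", *sulf_full, "yjbB", "phoD", "pyc"),
          rhodopsin="proton_pumping", p_limited=False, n_class="decoupled",
          source="isolate", completeness=1.0),
        S("bact03", "Bacteroidetes", 10.0, (0.3, 0.45, 0.6, 0.85),
          ("narG", "nrfA", "amt", "glnA", *sulf_full, "yjbB", "phoA", "ppc"),
          p_limited=True, n_class="coupled"),
        S("bact04", "Bacteroidetes", 9.0, (0.25, 0.35, 0.5, 0.7),
          ("amt", "glnA", *sulf_act, "yjbB", "phoD", "pyc"),
          rhodopsin="NQ", p_limited=True, n_class="low_expression"),
    ]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic consortium."""

    species: list = field(default_factory=default_panel)
    days: tuple = (7, 14, 21, 28)
    replicates: int = 3
    n_genes: int = 24  # total genes per genome (markers + housekeeping + filler)
    marker_gene_len: int = 600
    rpoc_len: int = 900
    rhodopsin_len: int = 750  # 250 aa
    filler_len_range: tuple = (300, 1500)
    intergenic_len: int = 100
    read_depth: int = 100_000  # reads per sample
    spectra_depth: int = 10_000  # spectra per sample
    read_len: int = 50
    bias_sigma: float = 0.1  # lognormal jitter (log2 sd) around planted biases
    transporter_induction: float = 4.0  # final-day/first-day transporter ratio
    amt_decline: float = 4.0  # amt decline in decoupled members
    coupled_trajectory: tuple = (1.0, 0.55, 1.3, 0.5)  # shared amt/glnA multipliers
    baseline_rpoc: float = 4.0
    baseline_n_markers: float = 2.0
    baseline_transporter: float = 1.0
    low_expression_level: float = 1e-6
    digest_missed_cleavages: int = 2
    digest_min_len: int = 6
    digest_max_len: int = 50

    def validate(self):
        if len(self.days) < 2:
            raise ValueError("need at least two sampled days")
        ids = [s.genome_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in panel")
        for spec in self.species:
            if len(spec.weights) != len(self.days):
                raise ValueError(f"{spec.genome_id}: weights/days length mismatch")
            if min(spec.weights) <= 0 or spec.bias <= 0:
                raise ValueError(f"{spec.genome_id}: weights and bias must be positive")
            if spec.n_class not in N_CLASSES:
                raise ValueError(f"{spec.genome_id}: unknown n_class {spec.n_class!r}")
            if spec.rbcl_form == "form_I_III" and "rbcS" not in spec.markers:
                raise ValueError(f"{spec.genome_id}: form I–III RbcL planted without rbcS")
            if not {"amt", "glnA"} <= set(spec.markers):
                raise ValueError(f"{spec.genome_id}: panel members need amt and glnA markers")
        if self.read_depth <= 0 or self.spectra_depth <= 0:
            raise ValueError("depths must be positive")
        if min(self.coupled_trajectory) <= 0:
            raise ValueError("negative/zero expression multipliers")


@dataclass
class GroundTruth:
    """The generating truth recorded next to every synthetic dataset."""

    capabilities: pd.DataFrame  # genome × capability (incl. typed labels)
    dependencies: pd.DataFrame  # genome × dependency element (bool)
    read_shares: pd.DataFrame  # genome × sample transcript shares
    protein_shares: pd.DataFrame  # genome × sample spectral shares
    rho: pd.DataFrame  # genome × sample true activity ratios
    bias: pd.Series  # realized per-species bias b_o
    rpkm: pd.DataFrame  # gene × sample true per-organism RPKM
    p_score: pd.Series  # per genome, from true RPKM
    p_limited: pd.Series
    n_class: pd.Series
    p_transporter: pd.Series
    seed: int


@dataclass
class SimulatedCommunity:
    config: SimConfig
    seed: int
    catalog: list  # list[MemberGenome]
    proteins: dict  # gene_id -> (genome_id, amino-acid sequence)
    samples: pd.DataFrame  # index sample_id; columns day, replicate
    expression: pd.DataFrame  # gene × sample within-species expression level
    read_weights: pd.DataFrame  # gene × sample read-sampling probabilities
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Planted truth (hand-coded; deliberately independent of the rule engine)
# ---------------------------------------------------------------------------

def _planted_capability_row(spec: SpeciesSpec) -> dict:
    m = set(spec.markers)
    nitrate = bool(m & {"nasA", "narG", "napA"})
    nitrite = bool(m & {"nirB", "nrfA"})
    row = {
        "nitrate_reduction": nitrate,
        "nitrite_ammonification": nitrite,
        "nitrate_assimilation": nitrate and nitrite,
        "ammonium_incorporation": "amt" in m and "glnA" in m,
        "n2_fixation": "nifH" in m,
        "sulfate_activation": bool(m & {"sat", "cysNC"}),
        "sulfate_to_sulfide": bool(m & {"sat", "cysNC"}) and bool(m & {"cysH", "aprA"}) and "sir" in m,
        "p_uptake": bool(m & {"pstS", "pitA", "yjbB"}),
        "pst_uptake": "pstS" in m,
        "alkaline_phosphatase": bool(m & {"phoA", "phoD"}),
        "autotrophy": spec.rbcl_form == "form_I_III" and "rbcS" in m,
        "anaplerotic_carbon": bool(m & {"pyc", "ppc"}),
        "aap": "bch" in m and "puf" in m,
        "rhodopsin_type": spec.rhodopsin if spec.rhodopsin else "none",
    }
    p_type = "none"
    for fam in P_TRANSPORTER_HIERARCHY:
        if fam in m:
            p_type = {"pstS": "pst", "yjbB": "yjbB", "pitA": "pitA"}[fam]
            break
    row["p_transporter_type"] = p_type
    return row


def _planted_dependency_row(cap: dict) -> dict:
    return {
        "N_reduced": not cap["nitrate_assimilation"] and not cap["n2_fixation"],
        "S_reduced": not cap["sulfate_to_sulfide"],
        "C_organic": not cap["autotrophy"],
        "P_uptake_limited": not cap["pst_uptake"],
    }


# ---------------------------------------------------------------------------
# Genome and protein construction
# ---------------------------------------------------------------------------

def _random_protein(rng, n_aa, alphabet=_AA):
    return "".join(rng.choice(list(alphabet), size=n_aa))


def _rhodopsin_protein(rng, n_aa, motif_type):
    """Rhodopsin with exactly one planted transport motif (no stray arginines)."""
    body = list(_random_protein(rng, n_aa, _AA_NO_R))
    spacer = _random_protein(rng, 10, _AA_NO_R)
    x = rng.choice(list(_AA_NO_R))
    if motif_type == "proton_pumping":
        motif = "RY" + x + "D" + spacer + "E"
    elif motif_type == "NQ":
        motif = "RY" + x + "N" + spacer + "Q"
    else:
        raise ValueError(f"unknown rhodopsin type {motif_type!r}")
    pos = 100 if n_aa > 120 else 0
    body[pos : pos + len(motif)] = motif
    return "".join(body[:n_aa])


def _rbcl_protein(rng, form):
    """RbcL protein: form I–III is reference-length with Glu204; form IV is
    100 residues shorter with His at the aligned position."""
    if form == "form_I_III":
        seq = list(_random_protein(rng, 470))
        seq[203] = "E"
    elif form == "form_IV":
        seq = list(_random_protein(rng, 370))
        seq[203] = "H"
    else:
        raise ValueError(f"unknown rbcL form {form!r}")
    return "".join(seq)


def _species_gene_plan(config: SimConfig, spec: SpeciesSpec, rng):
    """Ordered (name, marker_label, length_nt) plan for one genome."""
    plan = [("rpoC", "rpoC", config.rpoc_len)]
    for token in spec.markers:
        plan.append((token, token, config.marker_gene_len))
    if spec.rbcl_form is not None:
        n_aa = 470 if spec.rbcl_form == "form_I_III" else 370
        plan.append(("rbcL", "rbcL", n_aa * 3))
    if spec.rhodopsin is not None:
        plan.append(("rhodopsin", "rhodopsin", config.rhodopsin_len))
    n_filler = max(0, config.n_genes - len(plan))
    lo, hi = config.filler_len_range
    for i in range(n_filler):
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        plan.append((f"g{i:02d}", None, length))
    return plan


def simulate_genomes(config: Optional[SimConfig] = None, seed: int = 0):
    """Generate the member genomes and protein catalog.

    Returns ``(catalog, proteins)`` where ``proteins`` maps gene_id ->
    (genome_id, amino-acid sequence). Deterministic for a fixed seed.
    """
    config = config or SimConfig()
    config.validate()
    catalog, proteins = [], {}
    for spec in sorted(config.species, key=lambda s: s.genome_id):
        rng = np.random.default_rng([seed, crc32(spec.genome_id.encode()) % (2**31)])
        plan = _species_gene_plan(config, spec, rng)
        genes, pos = [], 1 + config.intergenic_len
        contig_id = f"{spec.genome_id}_c1"
        for name, label, length in plan:
            gene_id = f"{spec.genome_id}_{name}"
            gene = Gene(
                gene_id=gene_id,
                genome_id=spec.genome_id,
                contig_id=contig_id,
                start=pos,
                end=pos + length - 1,
                strand="+",
                product=name,
                marker_labels={label} if label else set(),
            )
            genes.append(gene)
            pos = gene.end + 1 + config.intergenic_len
            n_aa = length // 3
            if name == "rhodopsin":
                proteins[gene_id] = (spec.genome_id, _rhodopsin_protein(rng, n_aa, spec.rhodopsin))
            elif name == "rbcL":
                proteins[gene_id] = (spec.genome_id, _rbcl_protein(rng, spec.rbcl_form))
            else:
                proteins[gene_id] = (spec.genome_id, _random_protein(rng, n_aa))
        contig_len = pos - 1
        contig = "".join(rng.choice(list(_NT), size=contig_len))
        catalog.append(
            MemberGenome(
                genome_id=spec.genome_id,
                contigs={contig_id: contig},
                genes=genes,
                taxon_group=spec.taxon_group,
                source=spec.source,
                completeness=spec.completeness,
            )
        )
    return catalog, proteins


# ---------------------------------------------------------------------------
# Expression programs
# ---------------------------------------------------------------------------

def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"d{day:02d}r{rep}", "day": day, "replicate": rep}
        for day in config.days
        for rep in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _geometric_ramp(fold: float, n: int) -> np.ndarray:
    return fold ** (np.arange(n) / (n - 1))


def simulate_expression(config: Optional[SimConfig] = None, seed: int = 0,
                        catalog: Optional[list] = None) -> tuple:
    """Per-gene expression levels (within-species scale) for every sample.

    Expression = per-gene lognormal baseline × day-specific program
    multiplier. The rpoC analog is constant; in P-limited members the
    highest-affinity phosphate transporter ramps geometrically to
    ``transporter_induction``-fold by the final day; amt/glnA follow the
    planted nitrogen class. Replicates share the same true expression.

    Returns ``(expression, samples)``.
    """
    config = config or SimConfig()
    config.validate()
    if catalog is None:
        catalog, _ = simulate_genomes(config, seed)
    samples = _sample_frame(config)
    n_days = len(config.days)
    ramp = _geometric_ramp(config.transporter_induction, n_days)
    amt_down = _geometric_ramp(1.0 / config.amt_decline, n_days)
    coupled = np.asarray(config.coupled_trajectory[:n_days], dtype=float)
    spec_by_id = {s.genome_id: s for s in config.species}

    rows = []
    for genome in catalog:
        spec = spec_by_id[genome.genome_id]
        rng = np.random.default_rng([seed, 7, crc32(genome.genome_id.encode()) % (2**31)])
        transporter = next((f for f in P_TRANSPORTER_HIERARCHY
                            if any(f in g.marker_labels for g in genome.genes)), None)
        for gene in genome.genes:
            label = next(iter(gene.marker_labels)) if gene.marker_labels else None
            if label == "rpoC":
                baseline = config.baseline_rpoc
            elif label in ("amt", "glnA"):
                baseline = (config.low_expression_level
                            if spec.n_class == "low_expression"
                            else config.baseline_n_markers)
            elif label == transporter:
                baseline = config.baseline_transporter
            else:
                baseline = float(rng.lognormal(mean=0.0, sigma=1.0))
            mult = np.ones(n_days)
            if spec.p_limited and label == transporter:
                mult = ramp
            elif spec.n_class == "coupled" and label in ("amt", "glnA"):
                mult = coupled
            elif spec.n_class == "decoupled" and label == "amt":
                mult = amt_down
            per_day = baseline * mult
            values = {s: per_day[list(config.days).index(samples.loc[s, "day"])]
                      for s in samples.index}
            rows.append(pd.Series(values, name=gene.gene_id))
    expression = pd.DataFrame(rows)
    return expression, samples


# ---------------------------------------------------------------------------
# Assembly of the full simulated community with truth
# ---------------------------------------------------------------------------

def simulate_community(config: Optional[SimConfig] = None, seed: int = 0) -> SimulatedCommunity:
    """Build genomes, expression, abundances, and the full ground truth."""
    config = config or SimConfig()
    config.validate()
    catalog, proteins = simulate_genomes(config, seed)
    expression, samples = simulate_expression(config, seed, catalog)
    specs = sorted(config.species, key=lambda s: s.genome_id)
    genome_ids = [s.genome_id for s in specs]

    # species abundance (transcript) shares per day, identical across replicates
    weights = pd.DataFrame(
        {s.genome_id: list(s.weights) for s in specs}, index=list(config.days)
    ).T
    day_shares = weights / weights.sum(axis=0)
    read_shares = pd.DataFrame(
        {s: day_shares[samples.loc[s, "day"]] for s in samples.index}
    )

    # realized per-species bias (lognormal jitter around the planted value)
    rng_bias = np.random.default_rng([seed, 11])
    bias = pd.Series(
        {s.genome_id: s.bias * float(2.0 ** rng_bias.normal(0.0, config.bias_sigma))
         for s in specs}
    ).loc[genome_ids]

    # protein shares: p ∝ a / b, normalized per sample; true rho = a / p
    raw = read_shares.div(bias, axis=0)
    protein_shares = raw / raw.sum(axis=0)
    rho = read_shares / protein_shares

    # read-sampling weights: share × expression × length, normalized per organism
    gene_meta = {g.gene_id: (g.genome_id, g.length_bp) for genome in catalog for g in genome.genes}
    genome_of = pd.Series({gid: meta[0] for gid, meta in gene_meta.items()})
    lengths = pd.Series({gid: float(meta[1]) for gid, meta in gene_meta.items()})
    expr_mass = expression.mul(lengths, axis=0)  # e × L
    organism_mass = expr_mass.groupby(genome_of).transform("sum")
    within = expr_mass / organism_mass
    read_weights = within.mul(read_shares.loc[genome_of.values].set_axis(expression.index))

    # true per-organism RPKM: 1e9 × e / Σ_o(eL)
    rpkm_true = 1e9 * expression / organism_mass

    # limitation truth
    first = samples.index[samples["day"] == config.days[0]][0]
    last = samples.index[samples["day"] == config.days[-1]][0]
    p_score, p_limited, p_marker = {}, {}, {}
    for spec in specs:
        genome = next(g for g in catalog if g.genome_id == spec.genome_id)
        fam = next((f for f in P_TRANSPORTER_HIERARCHY
                    if any(f in g.marker_labels for g in genome.genes)), None)
        p_marker[spec.genome_id] = fam
        if fam is None:
            p_score[spec.genome_id] = np.nan
            p_limited[spec.genome_id] = False
            continue
        gene_id = f"{spec.genome_id}_{fam}"
        score = float(np.log2(rpkm_true.loc[gene_id, last] / rpkm_true.loc[gene_id, first]))
        p_score[spec.genome_id] = score
        p_limited[spec.genome_id] = spec.p_limited

    cap_rows = {s.genome_id: _planted_capability_row(s) for s in specs}
    capabilities = pd.DataFrame(cap_rows).T.loc[genome_ids]
    capabilities.index.name = "genome_id"
    dependencies = pd.DataFrame(
        {gid: _planted_dependency_row(cap_rows[gid]) for gid in genome_ids}
    ).T.loc[genome_ids].astype(bool)
    dependencies.index.name = "genome_id"

    truth = GroundTruth(
        capabilities=capabilities,
        dependencies=dependencies,
        read_shares=read_shares,
        protein_shares=protein_shares,
        rho=rho,
        bias=bias,
        rpkm=rpkm_true,
        p_score=pd.Series(p_score).loc[genome_ids],
        p_limited=pd.Series(p_limited).loc[genome_ids],
        n_class=pd.Series({s.genome_id: s.n_class for s in specs}).loc[genome_ids],
        p_transporter=pd.Series(p_marker).loc[genome_ids],
        seed=seed,
    )
    return SimulatedCommunity(
        config=config, seed=seed, catalog=catalog, proteins=proteins,
        samples=samples, expression=expression, read_weights=read_weights, truth=truth,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_read_counts(sim: SimulatedCommunity, depth: Optional[int] = None,
                       seed: Optional[int] = None) -> GeneCountMatrix:
    """Multinomial gene-level read counts at the configured depth.

    Statistically equivalent to sampling error-free reads fully contained in
    genes and assigning them exactly; the base-level path is
    :func:`sample_reads` + ``transcript_quant.assign_reads``.
    """
    if depth is None:
        depth = sim.config.read_depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([sim.seed if seed is None else seed, 23])
    counts = {}
    for s in sim.samples.index:
        p = sim.read_weights[s].values
        counts[s] = rng.multinomial(depth, p / p.sum())
    frame = pd.DataFrame(counts, index=sim.read_weights.index)
    unassigned = pd.DataFrame(0, index=list(UNASSIGNED_CATEGORIES), columns=frame.columns)
    return GeneCountMatrix(counts=frame, samples=sim.samples, unassigned=unassigned)


def sample_reads(sim: SimulatedCommunity, sample_id: str, depth: Optional[int] = None,
                 read_len: Optional[int] = None, seed: Optional[int] = None) -> list:
    """Error-free reads for one sample: list of (read_id, sequence).

    Genes are drawn multinomially with weight expression × length; start
    positions are uniform within the gene so every read is fully contained in
    its source gene. Read ids encode the true source gene.
    """
    if depth is None:
        depth = sim.config.read_depth
    read_len = read_len or sim.config.read_len
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([sim.seed if seed is None else seed, 29,
                                 crc32(sample_id.encode()) % (2**31)])
    p = sim.read_weights[sample_id].values
    gene_counts = rng.multinomial(depth, p / p.sum())
    gene_lookup = {g.gene_id: (genome, g) for genome in sim.catalog for g in genome.genes}
    reads = []
    for gene_id, n in zip(sim.read_weights.index, gene_counts):
        if n == 0:
            continue
        genome, gene = gene_lookup[gene_id]
        contig = genome.contigs[gene.contig_id]
        span = gene.length_bp - read_len
        if span < 0:
            continue
        starts = rng.integers(0, span + 1, size=n)  # 0-based offset within gene
        for i, off in enumerate(starts):
            begin = gene.start - 1 + int(off)
            reads.append((f"{gene_id}|{len(reads)}", contig[begin : begin + read_len]))
    return reads


def write_fastq(reads, path):
    with open(Path(path), "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def sample_peptides(sim: SimulatedCommunity, depth: Optional[int] = None,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Peptide × sample spectral counts drawn from the planted proteome.

    Spectra are multinomial over in-silico tryptic peptides; a peptide's
    weight is its species' planted spectral share times its source gene's
    expression (normalized within species), so shared-peptide ambiguity
    arises naturally from sequence reuse.
    """
    if depth is None:
        depth = sim.config.spectra_depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    cfg = sim.config
    rng = np.random.default_rng([sim.seed if seed is None else seed, 31])

    peptides, gene_ids = [], []
    for gene_id, (genome_id, seq) in sorted(sim.proteins.items()):
        for pep in sorted(tryptic_digest(seq, cfg.digest_missed_cleavages,
                                         cfg.digest_min_len, cfg.digest_max_len)):
            peptides.append(pep)
            gene_ids.append(gene_id)
    pep_index = pd.Index(peptides)
    genome_of = pd.Series(
        [sim.proteins[g][0] for g in gene_ids], index=np.arange(len(gene_ids))
    )

    counts = {}
    expr = sim.expression
    for s in sim.samples.index:
        e = expr[s].reindex(gene_ids).values
        w = pd.Series(e).groupby(genome_of).transform(lambda v: v / v.sum()).values
        shares = sim.truth.protein_shares[s].reindex(genome_of.values).values
        p = w * shares
        total = p.sum()
        if total <= 0:
            raise ValueError(f"all-zero peptide weights in sample {s}")
        counts[s] = rng.multinomial(depth, p / total)
    obs = pd.DataFrame(counts, index=pep_index)
    # aggregate identical peptides emitted by different proteins
    obs = obs.groupby(level=0).sum()
    obs.index.name = "peptide_seq"
    return obs


def simulate_foldchange_records(sim: SimulatedCommunity, noise_sigma: float = 0.05,
                                seed: Optional[int] = None) -> pd.DataFrame:
    """Paired fold-change records with equal planted transcript/protein truth.

    The true between-day fold change of each species' transcript share is the
    common truth for both omics; lognormal measurement noise (sd
    ``noise_sigma`` in log2 units) is applied to the protein side, which the
    study observed to be the more variable measurement. Columns: genome_id,
    day_from, day_to, fc_t, fc_p.
    """
    rng = np.random.default_rng([sim.seed if seed is None else seed, 37,
                                 int(noise_sigma * 1e6)])
    days = list(sim.config.days)
    day_cols = {d: sim.samples.index[sim.samples["day"] == d][0] for d in days}
    shares = sim.truth.read_shares
    records = []
    for d0, d1 in zip(days, days[1:]):
        fc_true = shares[day_cols[d1]] / shares[day_cols[d0]]
        for gid, fc in fc_true.items():
            records.append(
                {"genome_id": gid, "day_from": d0, "day_to": d1,
                 "fc_t": float(fc),
                 "fc_p": float(fc * 2.0 ** rng.normal(0.0, noise_sigma))}
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# On-disk export (FASTA/GFF3/TSV bundle + truth)
# ---------------------------------------------------------------------------

def write_community(sim: SimulatedCommunity, outdir) -> dict:
    """Write the community as standard files; returns the path map."""
    from .proteome_quant import write_protein_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": {}, "gff3": {}}
    marker_rows = []
    meta_rows = []
    for genome in sim.catalog:
        fasta = outdir / f"{genome.genome_id}.fna"
        with open(fasta, "w") as fh:
            for contig_id, seq in genome.contigs.items():
                fh.write(f">{contig_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gff = outdir / f"{genome.genome_id}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genome.genes:
                attrs = f"ID={g.gene_id};product={g.product}"
                fh.write(
                    f"{g.contig_id}\tuccomics_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
        paths["fasta"][genome.genome_id] = fasta
        paths["gff3"][genome.genome_id] = gff
        meta_rows.append(
            {"genome_id": genome.genome_id, "taxon_group": genome.taxon_group,
             "source": genome.source, "completeness": genome.completeness}
        )
        for g in genome.genes:
            for label in g.marker_labels:
                marker_rows.append(
                    {"genome_id": genome.genome_id, "gene_id": g.gene_id,
                     "marker_label": label, "subsystem": ""}
                )
    markers = outdir / "markers.tsv"
    pd.DataFrame(marker_rows).to_csv(markers, sep="\t", index=False)
    metadata = outdir / "genome_metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(metadata, sep="\t", index=False)
    protein_fasta = outdir / "proteins.faa"
    write_protein_fasta(sim.proteins, protein_fasta)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    sim.truth.capabilities.to_csv(truth_dir / "capabilities.tsv", sep="\t")
    sim.truth.read_shares.to_csv(truth_dir / "read_shares.tsv", sep="\t")
    sim.truth.protein_shares.to_csv(truth_dir / "protein_shares.tsv", sep="\t")
    sim.truth.rho.to_csv(truth_dir / "rho.tsv", sep="\t")
    paths.update(markers=markers, metadata=metadata, proteins=protein_fasta, truth=truth_dir)
    return paths
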