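"""Rule-based prediction of energy and macronutrient acquisition capabilities.

Each consortium member's genome is reduced to the set of marker-gene tokens it
carries (e.g. ``nasA``, ``pstS``, ``cysH``); capabilities are boolean formulas
over those tokens, evaluated per genome to give a capability matrix with
per-cell provenance (the marker genes that satisfy the formula). Two
sequence-level classifiers refine ambiguous markers:

* rhodopsins are typed by their ion-transport motif — ``RYXD(X10)E`` marks a
  proton pump, ``RYXN(X10)Q`` the sodium-pumping NQ family;
* RbcL homologs are split into catalytically competent forms I–III versus
  form IV (RuBisCo-like proteins, ~100 residues shorter with the catalytic
  glutamate substituted), which cannot fix CO2 and therefore do not support
  autotrophy.

Default rules (negation-free, so gaining genes never removes a capability):

==========================  ====================================================
capability                  formula
==========================  ====================================================
nitrate_reduction           nasA | narG | napA   (dissimilatory reductases can
                            substitute for nasA; strict mode restricts to nasA)
nitrite_ammonification      nirB | nrfA
nitrate_assimilation        nitrate_reduction & nitrite_ammonification
ammonium_incorporation      amt & glnA
n2_fixation                 nifH
sulfate_activation          sat | cysNC
sulfate_to_sulfide          (sat | cysNC) & (cysH | aprA) & sir
p_uptake                    pstS | pitA | yjbB
pst_uptake                  pstS            (high-affinity ABC system)
alkaline_phosphatase        phoA | phoD
autotrophy                  rbcL_form_I_III & rbcS
anaplerotic_carbon          pyc | ppc
aap                         bch & puf       (aerobic anoxygenic phototrophy)
==========================  ====================================================

Dependency prediction inverts the matrix: a member depends on community-supplied
reduced nitrogen when it can neither assimilate nitrate nor fix N2, on reduced
sulfur when it cannot reduce sulfate to sulfide, and on organic carbon when it
is not autotrophic; members lacking the high-affinity Pst system are flagged as
uptake-limited under phosphate scarcity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome_catalog import MemberGenome

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Controlled vocabulary of marker-gene tokens (plus derived sequence-typed tokens).
VOCABULARY = frozenset(
    {
        # nitrogen
        "nasA", "narG", "napA", "nirB", "nrfA", "amt", "glnA", "glnT", "nifH",
        # sulfur
        "sat", "cysNC", "cysH", "aprA", "sir",
        # phosphorus
        "pstS", "pstA", "pstB", "pstC", "pitA", "yjbB", "phoA", "phoD",
        # carbon / energy
        "rbcL", "rbcS", "pyc", "ppc", "bch", "puf", "rhodopsin",
        # housekeeping (not used by rules, present in marker tables)
        "rpoC",
        # derived from sequence classification
        "rbcL_form_I_III", "rbcL_form_IV",
    }
)

PROTON_MOTIF = re.compile(r"RY.D.{10}E")
NQ_MOTIF = re.compile(r"RY.N.{10}Q")

#: Affinity hierarchy of phosphate transporter families (highest first).
P_TRANSPORTER_HIERARCHY = ("pstS", "yjbB", "pitA")


# ---------------------------------------------------------------------------
# Boolean rule language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<not>NOT\b|!)|(?P<and>AND\b|&)"
                       r"|(?P<or>OR\b|\|)|(?P<name>[A-Za-z_][A-Za-z0-9_]*))")


def _tokenize(expression: str):
    pos, out = 0, []
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            if expression[pos:].strip() == "":
                break
            raise ValueError(f"cannot parse rule expression at {expression[pos:]!r}")
        out.append((m.lastgroup, m.group().strip()))
        pos = m.end()
    return out


class _Parser:
    """Recursive-descent parser for `token`, NOT/!, AND/&, OR/| and parentheses."""

    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.i != len(self.tokens):
            raise ValueError("trailing tokens in rule expression")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "or":
            self.next()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_unary()
        while self.peek() == "and":
            self.next()
            node = ("and", node, self.parse_unary())
        return node

    def parse_unary(self):
        kind = self.peek()
        if kind == "not":
            self.next()
            return ("not", self.parse_unary())
        if kind == "lpar":
            self.next()
            node = self.parse_or()
            if self.peek() != "rpar":
                raise ValueError("unbalanced parentheses in rule expression")
            self.next()
            return node
        if kind == "name":
            _, name = self.next()
            return ("name", name)
        raise ValueError("malformed rule expression")


def parse_expression(expression: str):
    return _Parser(_tokenize(expression)).parse()


def _ast_names(node) -> set:
    if node[0] == "name":
        return {node[1]}
    if node[0] == "not":
        return _ast_names(node[1])
    return _ast_names(node[1]) | _ast_names(node[2])


def _ast_eval(node, present: set) -> bool:
    op = node[0]
    if op == "name":
        return node[1] in present
    if op == "not":
        return not _ast_eval(node[1], present)
    if op == "and":
        return _ast_eval(node[1], present) and _ast_eval(node[2], present)
    return _ast_eval(node[1], present) or _ast_eval(node[2], present)


@dataclass
class MarkerRule:
    """One capability rule: a boolean formula over marker tokens."""

    capability: str
    element: str  # {energy, C, N, P, S}
    expression: str
    value_type: str = "boolean"
    note: str = ""
    ast: tuple = field(init=False, repr=False)

    def __post_init__(self):
        self.ast = parse_expression(self.expression)
        unknown = self.tokens - VOCABULARY
        if unknown:
            raise ValueError(
                f"rule {self.capability!r} references unknown tokens: {sorted(unknown)}"
            )

    @property
    def tokens(self) -> set:
        return _ast_names(self.ast)

    def evaluate(self, present: set) -> bool:
        return _ast_eval(self.ast, present)


def default_rules(strict_assimilatory: bool = False) -> list:
    """The shipped rule set. ``strict_assimilatory`` excludes dissimilatory
    nitrate reductases (narG/napA) from counting toward assimilation."""
    nitrate = "nasA" if strict_assimilatory else "nasA | narG | napA"
    return [
        MarkerRule("nitrate_reduction", "N", nitrate),
        MarkerRule("nitrite_ammonification", "N", "nirB | nrfA"),
        MarkerRule("nitrate_assimilation", "N", f"({nitrate}) & (nirB | nrfA)"),
        MarkerRule("ammonium_incorporation", "N", "amt & glnA"),
        MarkerRule("n2_fixation", "N", "nifH"),
        MarkerRule("sulfate_activation", "S", "sat | cysNC"),
        MarkerRule("sulfate_to_sulfide", "S", "(sat | cysNC) & (cysH | aprA) & sir"),
        MarkerRule("p_uptake", "P", "pstS | pitA | yjbB"),
        MarkerRule("pst_uptake", "P", "pstS"),
        MarkerRule("alkaline_phosphatase", "P", "phoA | phoD"),
        MarkerRule("autotrophy", "C", "rbcL_form_I_III & rbcS"),
        MarkerRule("anaplerotic_carbon", "C", "pyc | ppc"),
        MarkerRule("aap", "energy", "bch & puf"),
    ]


def load_rules(path) -> list:
    """Load rules from a YAML file: a list of {capability, element, expression, ...}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [MarkerRule(**entry) for entry in raw]


# ---------------------------------------------------------------------------
# Sequence classifiers
# ---------------------------------------------------------------------------

def classify_rhodopsin(protein_seq: str) -> str:
    """Type a rhodopsin candidate by its transport motif.

    Returns ``proton_pumping`` for the RYXD(X10)E motif, ``NQ`` for
    RYXN(X10)Q (sodium-pumping family), ``other`` if neither occurs (or the
    sequence is empty). If both motifs occur the call is ambiguous: ``other``
    with a warning.
    """
    if not protein_seq:
        return "other"
    bad = set(protein_seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid symbols in rhodopsin sequence: {sorted(bad)}")
    proton = PROTON_MOTIF.search(protein_seq) is not None
    nq = NQ_MOTIF.search(protein_seq) is not None
    if proton and nq:
        warnings.warn("rhodopsin sequence carries both transport motifs; typed as 'other'")
        return "other"
    if proton:
        return "proton_pumping"
    if nq:
        return "NQ"
    return "other"


def classify_rubisco(rbcl_len: int, catalytic_residue: str, reference_len: int = 470) -> str:
    """Discriminate form I–III RbcL from form IV (RuBisCo-like protein).

    ``catalytic_residue`` is the amino acid at the position aligned to the
    canonical catalytic glutamate (Glu204 in reference numbering; the aligned
    position is the caller's responsibility). A homolog is form IV iff it is at
    least 80 residues shorter than the reference *and* the catalytic glutamate
    is substituted.
    """
    if reference_len <= 0:
        raise ValueError("reference_len must be positive")
    residue = catalytic_residue.upper()
    if residue not in AMINO_ACIDS:
        raise ValueError(f"invalid amino-acid symbol {catalytic_residue!r}")
    if (reference_len - rbcl_len) >= 80 and residue != "E":
        return "form_IV"
    return "form_I_III"


# ---------------------------------------------------------------------------
# Capability matrix and dependencies
# ---------------------------------------------------------------------------

@dataclass
class CapabilityMatrix:
    """Genome × capability calls with per-cell provenance.

    ``values`` holds booleans for rule capabilities plus typed-label columns
    (``rhodopsin_type``, ``p_transporter_type``). ``provenance[(genome_id,
    capability)]`` lists the marker genes supporting a true/typed cell.
    """

    values: pd.DataFrame
    provenance: dict
    completeness: pd.Series

    def to_tsv(self, path):
        out = self.values.copy()
        out.insert(0, "completeness", self.completeness)
        out.to_csv(path, sep="\t", index_label="genome_id")


@dataclass
class DependencyReport:
    genome_id: str
    dependent_elements: set
    rationale: dict  # element -> capability cells implying the dependency


RUBISCO_ALIGNED_POS = 204  # reference numbering of the catalytic glutamate


def _genome_tokens(genome: MemberGenome, proteins: Optional[Mapping],
                   aligned_pos: int, reference_len: int):
    """Marker tokens present in a genome, with supporting genes per token.

    Genes labeled ``rbcL`` are re-typed from their protein sequence (when
    available) into the derived ``rbcL_form_I_III`` / ``rbcL_form_IV`` tokens;
    rhodopsin genes yield the typed label instead of a boolean token.
    """
    token_genes: dict = {}
    rhodopsin_type = "none"
    rhodopsin_genes = []
    for gene in genome.genes:
        for label in gene.marker_labels:
            if label == "rbcL":
                derived = "rbcL_form_I_III"
                if proteins is not None and gene.gene_id in proteins:
                    seq = proteins[gene.gene_id]
                    seq = seq[1] if isinstance(seq, tuple) else seq
                    residue = seq[aligned_pos - 1] if len(seq) >= aligned_pos else "A"
                    derived = "rbcL_" + classify_rubisco(len(seq), residue, reference_len)
                token_genes.setdefault(derived, []).append(gene.gene_id)
                token_genes.setdefault("rbcL", []).append(gene.gene_id)
            elif label == "rhodopsin":
                rtype = "other"
                if proteins is not None and gene.gene_id in proteins:
                    seq = proteins[gene.gene_id]
                    seq = seq[1] if isinstance(seq, tuple) else seq
                    rtype = classify_rhodopsin(seq)
                rhodopsin_type = rtype
                rhodopsin_genes.append(gene.gene_id)
                token_genes.setdefault("rhodopsin", []).append(gene.gene_id)
            else:
                token_genes.setdefault(label, []).append(gene.gene_id)
    return token_genes, rhodopsin_type, rhodopsin_genes


def evaluate_capabilities(
    catalog: Sequence[MemberGenome],
    rules: Optional[Sequence[MarkerRule]] = None,
    proteins: Optional[Mapping] = None,
    strict_assimilatory: bool = False,
    aligned_pos: int = RUBISCO_ALIGNED_POS,
    reference_len: int = 470,
) -> CapabilityMatrix:
    """Evaluate the rule set against every genome in the catalog.

    ``proteins`` optionally maps gene_id -> amino-acid sequence (or
    ``(genome_id, sequence)``) for rhodopsin/RbcL typing; without sequences,
    rbcL markers are taken at face value as form I–III and rhodopsins are typed
    ``other``.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    if rules is None:
        rules = default_rules(strict_assimilatory=strict_assimilatory)

    rows, provenance = [], {}
    completeness = {}
    for genome in sorted(catalog, key=lambda g: g.genome_id):
        token_genes, rhodopsin_type, rhodopsin_genes = _genome_tokens(
            genome, proteins, aligned_pos, reference_len
        )
        present = set(token_genes)
        row = {}
        for rule in rules:
            value = rule.evaluate(present)
            row[rule.capability] = value
            if value:
                support = sorted(
                    {g for tok in rule.tokens & present for g in token_genes[tok]}
                )
                provenance[(genome.genome_id, rule.capability)] = support
        row["rhodopsin_type"] = rhodopsin_type if rhodopsin_genes else "none"
        if rhodopsin_genes:
            provenance[(genome.genome_id, "rhodopsin_type")] = sorted(rhodopsin_genes)
        p_type = "none"
        for fam in P_TRANSPORTER_HIERARCHY:
            if fam in present:
                p_type = {"pstS": "pst", "yjbB": "yjbB", "pitA": "pitA"}[fam]
                provenance[(genome.genome_id, "p_transporter_type")] = sorted(token_genes[fam])
                break
        row["p_transporter_type"] = p_type
        row["genome_id"] = genome.genome_id
        rows.append(row)
        completeness[genome.genome_id] = genome.completeness

    values = pd.DataFrame(rows).set_index("genome_id")
    return CapabilityMatrix(
        values=values, provenance=provenance, completeness=pd.Series(completeness)
    )


_DEPENDENCY_RULES = {
    "N_reduced": (
        ["nitrate_assimilation", "n2_fixation"],
        lambda row: not row["nitrate_assimilation"] and not row["n2_fixation"],
    ),
    "S_reduced": (["sulfate_to_sulfide"], lambda row: not row["sulfate_to_sulfide"]),
    "C_organic": (["autotrophy"], lambda row: not row["autotrophy"]),
    "P_uptake_limited": (["pst_uptake"], lambda row: not row["pst_uptake"]),
}


def predict_dependencies(matrix: CapabilityMatrix) -> list:
    """Derive which community-supplied resources each member depends on."""
    required = {cap for caps, _ in _DEPENDENCY_RULES.values() for cap in caps}
    missing = required - set(matrix.values.columns)
    if missing:
        raise ValueError(f"capability matrix lacks required columns: {sorted(missing)}")
    reports = []
    for genome_id, row in matrix.values.iterrows():
        elements, rationale = set(), {}
        for element, (caps, pred) in _DEPENDENCY_RULES.items():
            if pred(row):
                elements.add(element)
                rationale[element] = {cap: bool(row[cap]) for cap in caps}
        reports.append(DependencyReport(genome_id, elements, rationale))
    return reports


def dependency_table(reports: Iterable[DependencyReport]) -> pd.DataFrame:
    """Tidy boolean table genome × dependency element."""
    elements = list(_DEPENDENCY_RULES)
    rows = [
        {"genome_id": r.genome_id, **{e: e in r.dependent_elements for e in elements}}
        for r in reports
    ]
    return pd.DataFrame(rows).set_index("genome_id")
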