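"""Tryptic digest, peptide mapping, parsimony inference, spectral counting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uccomics.proteome_quant import (
    map_peptides,
    parsimony_filter,
    quantify_proteins,
    tryptic_digest,
)


class TestTrypticDigest:
    def test_canonical_cleavage(self):
        assert tryptic_digest("AAAKCCCR", missed_cleavages=0, min_len=1) == {"AAAK", "CCCR"}

    def test_no_cleavage_before_proline(self):
        assert tryptic_digest("AAKPGGR", missed_cleavages=0, min_len=1) == {"AAKPGGR"}

    def test_missed_cleavage_enumeration(self):
        assert tryptic_digest("AKCK", missed_cleavages=1, min_len=1) == {"AK", "CK", "AKCK"}

    def test_empty_sequence(self):
        assert tryptic_digest("") == set()

    def test_length_window_applied(self):
        peps = tryptic_digest("AAAKCCCCCCR", missed_cleavages=0, min_len=5, max_len=7)
        assert peps == {"CCCCCCR"}

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            tryptic_digest("AAB1K")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_peptides_are_substrings_and_within_limits(self, seq):
        peps = tryptic_digest(seq, missed_cleavages=2, min_len=6, max_len=50)
        for p in peps:
            assert p in seq
            assert 6 <= len(p) <= 50


def brute_force_edges(peptides, proteins, **digest_kw):
    """Independent oracle: direct substring-of-digest scan."""
    edges = {}
    for pid, (_, seq) in proteins.items():
        digest = tryptic_digest(seq, **digest_kw)
        for pep in peptides:
            if pep in digest:
                edges.setdefault(pep, set()).add(pid)
    return edges


class TestMapPeptides:
    def test_unique_and_shared_edges(self):
        proteins = {
            "p1": ("gA", "AAACCCKDDDEEEK"),
            "p2": ("gB", "AAACCCKFFFGGGK"),
        }
        pmap = map_peptides(["AAACCCK", "DDDEEEK", "ZZZZZZZ"], proteins, missed_cleavages=0)
        assert pmap.proteins_of("DDDEEEK") == {"p1"}
        assert pmap.proteins_of("AAACCCK") == {"p1", "p2"}
        assert pmap.cross_species_peptides() == {"AAACCCK"}
        assert pmap.unmapped == {"ZZZZZZZ"}

    def test_edges_match_brute_force_on_random_catalog(self):
        rng = np.random.default_rng(42)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        proteins = {
            f"p{i:02d}": (f"g{i % 3}", "".join(rng.choice(aa, size=80))) for i in range(12)
        }
        # observed peptides: some real (from digests), some absent
        digest_kw = dict(missed_cleavages=1, min_len=6, max_len=30)
        all_peps = sorted(set().union(*(tryptic_digest(s, **digest_kw) for _, s in proteins.values())))
        observed = all_peps[::2] + ["WWWWWWWWWW"]
        pmap = map_peptides(observed, proteins, **digest_kw)
        oracle = brute_force_edges(observed, proteins, **digest_kw)
        assert {p: set(v) for p, v in pmap.edges.items()} == oracle


class TestParsimonyFilter:
    def _pmap(self, edges, genome_of=None):
        from uccomics.proteome_quant import PeptideProteinMap

        proteins = set().union(*edges.values())
        return PeptideProteinMap(
            edges={p: frozenset(v) for p, v in edges.items()},
            protein_to_genome={p: (genome_of or {}).get(p, "g1") for p in proteins},
            unmapped=set(),
            digest_params={},
        )

    def test_single_peptide_protein_dropped(self):
        pmap = self._pmap({"pep1": {"A"}})
        result = parsimony_filter(pmap)
        assert result.retained == []
        assert result.dropped_few_peptides == {"A"}

    def test_greedy_cover_on_worked_example(self):
        # A covers p1-p3, B covers p3-p4, C covers p4 only: C fails the
        # two-peptide rule; greedy retains {A, B} (the exhaustive minimum).
        pmap = self._pmap(
            {"p1": {"A"}, "p2": {"A"}, "p3": {"A", "B"}, "p4": {"B", "C"}}
        )
        result = parsimony_filter(pmap, exhaustive=True)
        assert sorted(result.retained) == ["A", "B"]
        assert result.optimal_size == 2
        assert result.uncovered == set()

    def test_unique_mapping_reduces_to_two_peptide_filter(self):
        edges = {f"pep{i}": {f"P{i % 4}"} for i in range(8)}  # each protein: 2 peptides
        edges["solo"] = {"P9"}
        result = parsimony_filter(self._pmap(edges))
        assert sorted(result.retained) == ["P0", "P1", "P2", "P3"]
        assert "P9" in result.dropped_few_peptides

    def test_lexicographic_tie_break(self):
        pmap = self._pmap({"p1": {"A", "B"}, "p2": {"A", "B"}})
        result = parsimony_filter(pmap)
        assert result.retained == ["A"]

    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_bipartite_graphs_give_irreducible_valid_covers(self, graph_seed):
        """Greedy output is a valid, irreducible cover respecting the
        two-peptide threshold; on small instances its size matches the
        exhaustive minimum in the overwhelming majority of cases."""
        rng = np.random.default_rng(graph_seed)
        n_prot = int(rng.integers(2, 13))
        n_pep = int(rng.integers(2, 25))
        edges = {}
        for i in range(n_pep):
            owners = rng.choice(n_prot, size=int(rng.integers(1, min(4, n_prot + 1))), replace=False)
            edges[f"pep{i:02d}"] = {f"P{j:02d}" for j in owners}
        pmap = self._pmap(edges)
        result = parsimony_filter(pmap, exhaustive=True)
        peptides_of = {}
        for pep, prots in edges.items():
            for p in prots:
                peptides_of.setdefault(p, set()).add(pep)
        eligible = {p for p, peps in peptides_of.items() if len(peps) >= 2}
        universe = {pep for pep, prots in edges.items() if prots & eligible}
        # threshold respected
        assert all(len(peptides_of[p]) >= 2 for p in result.retained)
        # valid cover of the mappable universe
        covered = set().union(*(peptides_of[p] for p in result.retained)) if result.retained else set()
        assert universe <= covered
        # irreducible: no retained protein is redundant
        for p in result.retained:
            others = set().union(
                *(peptides_of[q] for q in result.retained if q != p)
            ) if len(result.retained) > 1 else set()
            assert not (peptides_of[p] & universe <= others)
        # greedy vs exhaustive minimum (greedy may exceed; never undercut)
        assert len(result.retained) >= result.optimal_size


class TestQuantifyProteins:
    def _setup(self):
        proteins = {
            "X": ("gA", "AAACCCKDDDEEEK"),
            "Y": ("gA", "FFFGGGKHHHIIIK"),
            "Z": ("gB", "LLLMMMKNNNQQQK"),
        }
        peptides = ["AAACCCK", "DDDEEEK", "FFFGGGK", "HHHIIIK", "LLLMMMK", "NNNQQQK"]
        obs = pd.DataFrame(
            {"s1": [10, 20, 30, 40, 5, 5]}, index=pd.Index(peptides, name="peptide_seq")
        )
        pmap = map_peptides(peptides, proteins, missed_cleavages=0)
        minimal = parsimony_filter(pmap)
        return obs, pmap, minimal

    def test_within_species_percentages(self):
        obs, pmap, minimal = self._setup()
        ab = quantify_proteins(obs, pmap, minimal)
        assert ab.within_species_pct.loc["X", "s1"] == pytest.approx(30.0)
        assert ab.within_species_pct.loc["Y", "s1"] == pytest.approx(70.0)

    def test_species_shares(self):
        obs, pmap, minimal = self._setup()
        obs["s1"] = [20, 25, 20, 25, 5, 5]  # gA: 90 counts, gB: 10 counts
        ab = quantify_proteins(obs, pmap, minimal)
        assert ab.species_shares.loc["gA", "s1"] == pytest.approx(0.9)
        assert ab.species_shares.loc["gB", "s1"] == pytest.approx(0.1)

    def test_cross_species_peptides_excluded_or_split(self):
        proteins = {"X": ("gA", "AAACCCKDDDEEEK"), "Z": ("gB", "AAACCCKNNNQQQK")}
        peptides = ["AAACCCK", "DDDEEEK", "NNNQQQK"]
        obs = pd.DataFrame({"s1": [100, 10, 10]}, index=pd.Index(peptides, name="peptide_seq"))
        pmap = map_peptides(peptides, proteins, missed_cleavages=0)
        minimal = parsimony_filter(pmap)
        excl = quantify_proteins(obs, pmap, minimal)
        assert excl.species_shares.loc["gA", "s1"] == pytest.approx(0.5)
        frac = quantify_proteins(obs, pmap, minimal, cross_species="fractional")
        assert frac.species_shares.loc["gA", "s1"] == pytest.approx(60 / 120)
        assert frac.attributed_totals["s1"] == pytest.approx(120)

    def test_zero_attributed_sample_is_error(self):
        obs, pmap, minimal = self._setup()
        obs["s2"] = 0
        with pytest.raises(ValueError, match="s2"):
            quantify_proteins(obs, pmap, minimal)

    def test_percentages_sum_to_100_per_species_sample(self, default_sim):
        from uccomics.synthetic_community import sample_peptides

        obs = sample_peptides(default_sim, depth=5000, seed=2)
        pmap = map_peptides(obs.index, default_sim.proteins)
        minimal = parsimony_filter(pmap)
        ab = quantify_proteins(obs, pmap, minimal)
        genome_of = pd.Series(ab.protein_to_genome)
        sums = ab.within_species_pct.groupby(genome_of).sum()
        observed = sums.values[~np.isnan(sums.values)]
        assert np.allclose(observed, 100.0, atol=1e-9)
        assert np.allclose(ab.species_shares.sum(axis=0), 1.0, atol=1e-9)
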