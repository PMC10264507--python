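"""Peptide tiling, toy predictor scoring, filter cascade, panel selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seroneo.expressed_variants import ProteinChange
from seroneo.neoepitope import (
    AMINO_ACIDS,
    ResidueMismatchError,
    ToyPredictor,
    filter_candidates,
    gravy,
    panel_sort_key,
    score_candidates,
    select_panel,
    tile_peptides,
)


def oracle_windows(L, p, lengths):
    """Exhaustive enumeration of mutation-covering in-bounds windows."""
    out = []
    for k in lengths:
        for start in range(1, L - k + 2):
            if start <= p <= start + k - 1:
                out.append((start, k))
    return out


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


class TestTilePeptides:
    def test_interior_mutation_yields_27_pairs(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 40)
        p = 20
        mut = ProteinChange(seq[p - 1], p, "W" if seq[p - 1] != "W" else "Y")
        cands = tile_peptides(seq, mut)
        assert len(cands) == 27  # 8 + 9 + 10 windows

    def test_terminal_mutation_one_window_per_length(self):
        rng = np.random.default_rng(1)
        seq = random_protein(rng, 40)
        mut = ProteinChange(seq[0], 1, "W" if seq[0] != "W" else "Y")
        cands = tile_peptides(seq, mut)
        assert len(cands) == 3
        assert all(c.protein_start == 1 for c in cands)

    def test_residue_mismatch_errors(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        wrong = "W" if seq[4] != "W" else "Y"
        with pytest.raises(ResidueMismatchError):
            tile_peptides(seq, ProteinChange(wrong, 5, "A"))

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            tile_peptides("ACDEFGHIKL", ProteinChange("A", 99, "V"))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(12, 120), st.data())
    def test_matches_exhaustive_enumeration(self, L, data):
        rng = np.random.default_rng(L)
        seq = random_protein(rng, L)
        p = data.draw(st.integers(1, L))
        wt = seq[p - 1]
        mut_res = data.draw(st.sampled_from([a for a in AMINO_ACIDS if a != wt]))
        cands = tile_peptides(seq, ProteinChange(wt, p, mut_res))
        assert sorted((c.protein_start, c.length) for c in cands) == sorted(
            oracle_windows(L, p, (8, 9, 10))
        )
        for c in cands:
            diffs = [
                i for i, (a, b) in enumerate(zip(c.mutant_peptide, c.wildtype_peptide)) if a != b
            ]
            assert len(diffs) == 1
            assert c.protein_start + diffs[0] == p

    def test_count_formula(self):
        # sum over lengths of (min(p, L-k+1) - max(1, p-k+1) + 1) when positive
        for L, p in [(40, 20), (40, 1), (40, 40), (12, 6), (9, 5)]:
            rng = np.random.default_rng(L * 100 + p)
            seq = random_protein(rng, L)
            wt = seq[p - 1]
            mut = ProteinChange(wt, p, "W" if wt != "W" else "Y")
            expected = sum(
                max(0, min(p, L - k + 1) - max(1, p - k + 1) + 1)
                for k in (8, 9, 10)
            )
            assert len(tile_peptides(seq, mut)) == expected


class TestToyPredictor:
    def test_deterministic_and_in_range(self):
        pred = ToyPredictor()
        pep = "ACDEFGHIK"
        a1 = pred.affinity(pep, "HLA-A*02:01")
        a2 = pred.affinity(pep, "HLA-A*02:01")
        assert a1 == a2 and a1 > 0
        s = pred.processing_score(pep, "HLA-A*02:01")
        assert 0.0 <= s <= 1.0

    def test_alleles_rank_differently(self):
        pred = ToyPredictor()
        rng = np.random.default_rng(3)
        peps = [random_protein(rng, 9) for _ in range(20)]
        order_a = sorted(peps, key=lambda p: pred.affinity(p, "HLA-A*02:01"))
        order_b = sorted(peps, key=lambda p: pred.affinity(p, "HLA-B*07:02"))
        assert order_a != order_b

    def test_unsupported_length_rejected(self):
        with pytest.raises(ValueError):
            ToyPredictor().affinity("ACDEFGH", "HLA-A*02:01")  # 7-mer


class FailingPredictor:
    def affinity(self, peptide, allele):
        raise RuntimeError("boom")

    def processing_score(self, peptide, allele):
        raise RuntimeError("boom")


def make_scored(rng, n=12, seed_seq=None):
    seq = seed_seq or random_protein(rng, 60)
    p = 30
    wt = seq[p - 1]
    mut = ProteinChange(wt, p, "W" if wt != "W" else "Y")
    cands = tile_peptides(seq, mut, gene_id="G1", patient_id="P1")
    return score_candidates(cands, ToyPredictor(), "HLA-A*02:01")


class TestScoreAndFilter:
    def test_scoring_populates_and_repeats_identically(self):
        rng = np.random.default_rng(5)
        scored = make_scored(rng)
        again = make_scored(np.random.default_rng(5))
        assert [
            (c.mutant_peptide, c.mut_affinity_nM, c.wt_affinity_nM, c.combined_score)
            for c in scored
        ] == [
            (c.mutant_peptide, c.mut_affinity_nM, c.wt_affinity_nM, c.combined_score)
            for c in again
        ]

    def test_predictor_failure_flags_unscored(self):
        rng = np.random.default_rng(6)
        seq = random_protein(rng, 40)
        wt = seq[19]
        cands = tile_peptides(seq, ProteinChange(wt, 20, "W" if wt != "W" else "Y"))
        scored = score_candidates(cands, FailingPredictor(), "HLA-A*02:01")
        assert all(c.passes == {"scored": False} for c in scored)
        assert filter_candidates(scored) == []

    def test_filter_rules(self):
        rng = np.random.default_rng(7)
        scored = make_scored(rng)
        passing = filter_candidates(scored, 500.0, 0.6)
        for c in passing:
            assert c.mut_affinity_nM < 500.0
            assert c.combined_score > 0.6
            assert c.mut_affinity_nM < c.wt_affinity_nM
        # verdicts independently recomputable from stored scores
        for c in passing:
            assert c.passes["affinity"] == (c.mut_affinity_nM < 500.0)
            assert c.passes["combined_score"] == (c.combined_score > 0.6)
            assert c.passes["mut_stronger"] == (c.mut_affinity_nM < c.wt_affinity_nM)

    def test_relaxing_affinity_yields_superset(self):
        rng = np.random.default_rng(8)
        scored = []
        for _ in range(10):
            scored.extend(make_scored(rng, seed_seq=random_protein(rng, 50)))
        tight = {c.mutant_peptide for c in filter_candidates(scored, 500.0, 0.0, False)}
        loose = {c.mutant_peptide for c in filter_candidates(scored, 1000.0, 0.0, False)}
        assert tight <= loose

    def test_wildtype_stronger_fails(self):
        rng = np.random.default_rng(9)
        scored = make_scored(rng)
        wt_stronger = [c for c in scored if c.wt_affinity_nM <= c.mut_affinity_nM]
        passing = filter_candidates(scored, 1e9, -1.0, True)
        assert not {c.mutant_peptide for c in wt_stronger} & {
            c.mutant_peptide for c in passing
        }


class TestSelectPanel:
    def _passing_pool(self, seed=10, n_prot=6):
        rng = np.random.default_rng(seed)
        pool = []
        for i in range(n_prot):
            seq = random_protein(rng, 60)
            p = int(rng.integers(15, 45))
            wt = seq[p - 1]
            mut = ProteinChange(wt, p, "W" if wt != "W" else "Y")
            cands = tile_peptides(seq, mut, gene_id=f"G{i}", patient_id="P1")
            scored = score_candidates(cands, ToyPredictor(), "HLA-A*02:01")
            pool.extend(filter_candidates(scored, 5000.0, 0.3))
        return pool

    def test_cap_at_n_max(self):
        pool = self._passing_pool()
        assert len(pool) > 9
        panel = select_panel(pool, hydropathy_limit=None)
        assert len(panel) == 9

    def test_below_minimum_warns(self):
        pool = self._passing_pool()[:1]
        with pytest.warns(UserWarning, match="below the requested minimum"):
            panel = select_panel(pool, hydropathy_limit=None)
        assert len(panel) == 1

    def test_ordering_matches_brute_force_sort(self):
        pool = self._passing_pool(seed=12)
        panel = select_panel(pool, n_max=len(pool), hydropathy_limit=None)
        # brute-force: stable sort on the stated key, then dedup by (gene, mutation, length)
        expected = []
        seen = set()
        for c in sorted(pool, key=panel_sort_key):
            key = (c.gene_id, str(c.mutation), c.length)
            if key not in seen:
                seen.add(key)
                expected.append(c.mutant_peptide)
        assert [c.mutant_peptide for c in panel] == expected

    def test_dedup_per_gene_mutation_length(self):
        pool = self._passing_pool(seed=13)
        panel = select_panel(pool, n_max=50, hydropathy_limit=None)
        keys = [(c.gene_id, str(c.mutation), c.length) for c in panel]
        assert len(keys) == len(set(keys))

    def test_hydropathy_exclusion(self):
        pool = self._passing_pool(seed=14)
        limit = 0.0
        panel = select_panel(pool, n_max=50, hydropathy_limit=limit)
        assert all(gravy(c.mutant_peptide) <= limit for c in panel)

    def test_panel_input_order_invariant(self):
        pool = self._passing_pool(seed=15)
        a = select_panel(pool, hydropathy_limit=None)
        b = select_panel(list(reversed(pool)), hydropathy_limit=None)
        assert [c.mutant_peptide for c in a] == [c.mutant_peptide for c in b]

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            select_panel([], n_min=5, n_max=2)
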