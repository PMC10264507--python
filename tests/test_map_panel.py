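"""MAP-to-proteome matching, annotation, and screening-panel assembly."""

import re

import numpy as np
import pytest

from seroneo.map_panel import (
    MapPeptide,
    annotate_maps,
    match_to_proteome,
    read_peptide_list,
    read_proteome_fasta,
    select_map_panel,
)
from seroneo.repertoire_sets import GeneSet

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_scan(peptide, proteome):
    """Independent oracle: regex search of the literal peptide in each protein."""
    return {g for g, seq in proteome.items() if re.search(re.escape(peptide), seq)}


@pytest.fixture(scope="module")
def proteome():
    rng = np.random.default_rng(31)
    prot = {f"GENE{i:03d}": "".join(rng.choice(list(AA), size=120)) for i in range(40)}
    # plant a shared 9-mer in two paralogs
    motif = "WYWHKDCEA"
    prot["GENE000"] = prot["GENE000"][:50] + motif + prot["GENE000"][59:]
    prot["GENE001"] = prot["GENE001"][:10] + motif + prot["GENE001"][19:]
    return prot


class TestMatchToProteome:
    def test_unique_match(self, proteome):
        pep = proteome["GENE005"][10:19]
        (mp,) = match_to_proteome([pep], proteome)
        assert mp.matched_genes == naive_scan(pep, proteome)
        assert "GENE005" in mp.matched_genes

    def test_paralog_peptide_matches_both(self, proteome):
        (mp,) = match_to_proteome(["WYWHKDCEA"], proteome)
        assert {"GENE000", "GENE001"} <= mp.matched_genes
        assert mp.matched_genes == naive_scan("WYWHKDCEA", proteome)

    def test_decoy_matches_nothing(self, proteome):
        rng = np.random.default_rng(32)
        while True:
            pep = "".join(rng.choice(list(AA), size=10))
            if not naive_scan(pep, proteome):
                break
        (mp,) = match_to_proteome([pep], proteome)
        assert mp.matched_genes == frozenset()

    def test_oracle_equivalence_on_random_peptides(self, proteome):
        rng = np.random.default_rng(33)
        peptides = []
        genes = sorted(proteome)
        for _ in range(100):
            g = genes[rng.integers(len(genes))]
            k = int(rng.integers(8, 12))
            s = int(rng.integers(0, len(proteome[g]) - k))
            peptides.append(proteome[g][s : s + k])
        for mp in match_to_proteome(peptides, proteome):
            assert mp.matched_genes == naive_scan(mp.sequence, proteome)

    def test_bad_length_and_residue_skipped(self, proteome):
        with pytest.warns(UserWarning):
            out = match_to_proteome(["SHORT", "ACDEFGHIX"], proteome)
        assert out == []

    def test_il_equivalence_toggle(self):
        prot = {"G1": "AAAAILKAAAAA"}
        assert match_to_proteome(["AAILKAAA"], prot)[0].matched_genes == {"G1"}
        # L in place of I fails exact matching but passes with I/L collapsing
        assert match_to_proteome(["AALLKAAA"], prot)[0].matched_genes == frozenset()
        assert match_to_proteome(["AALLKAAA"], prot, il_equivalent=True)[0].matched_genes == {
            "G1"
        }

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            match_to_proteome(["ACDEFGHI"], {})


class TestAnnotateMaps:
    def make(self, seq, genes):
        return MapPeptide("P1", seq, frozenset(genes))

    def test_geneset_and_repertoire_flags(self):
        cta = GeneSet("CTA", frozenset({"G1"}))
        rep = GeneSet("autoAb", frozenset({"G2"}))
        maps = [self.make("ACDEFGHI", {"G1"}), self.make("KLMNPQRS", {"G2"})]
        out = annotate_maps(maps, [cta], rep)
        assert "CTA" in out[0].annotations and "autoAb_target" not in out[0].annotations
        assert "autoAb_target" in out[1].annotations

    def test_known_epitope_exact_sequence_only(self):
        maps = [self.make("ACDEFGHI", {"G1"}), self.make("ACDEFGHK", {"G1"})]
        out = annotate_maps(maps, [], None, [("ACDEFGHI", "G1")])
        assert "known_A2_epitope" in out[0].annotations
        assert "known_A2_epitope" not in out[1].annotations

    def test_monotone_in_geneset_growth(self):
        maps = [self.make("ACDEFGHI", {"G1"}), self.make("KLMNPQRS", {"G2"})]
        small = annotate_maps(maps, [GeneSet("CTA", frozenset({"G1"}))])
        large = annotate_maps(maps, [GeneSet("CTA", frozenset({"G1", "G2"}))])
        for a, b in zip(small, large):
            assert a.annotations <= b.annotations

    def test_flag_counts_match_brute_force(self, proteome, cohort_bundle):
        gs = GeneSet("CTA", frozenset(list(proteome)[:10]))
        rng = np.random.default_rng(34)
        peptides = [
            proteome[g][s : s + 9]
            for g in sorted(proteome)
            for s in [int(rng.integers(0, 100))]
        ]
        matched = match_to_proteome(peptides, proteome)
        out = annotate_maps(matched, [gs])
        expected = sum(1 for mp in matched if mp.matched_genes & gs.genes)
        assert sum(1 for mp in out if "CTA" in mp.annotations) == expected


class TestSelectMapPanel:
    def annotated(self, n_known, n_autoab, n_plain=5):
        maps = []
        for i in range(n_known):
            maps.append(
                MapPeptide("P1", f"KNOWNPE{chr(65 + i)}A"[:9].ljust(9, "A"),
                           frozenset({f"K{i}"}), frozenset({"known_A2_epitope"}))
            )
        for i in range(n_autoab):
            maps.append(
                MapPeptide("P1", f"AUTOABP{chr(65 + i)}A"[:9].ljust(9, "A"),
                           frozenset({f"A{i}"}), frozenset({"autoAb_target"}))
            )
        for i in range(n_plain):
            maps.append(MapPeptide("P1", f"PLAINPE{chr(65 + i)}A"[:9], frozenset({f"X{i}"})))
        return maps

    def test_ten_known_plus_two_autoab_gives_twelve(self):
        panel = select_map_panel(self.annotated(10, 2))
        assert len(panel) == 12
        assert sum(1 for mp in panel if "known_A2_epitope" in mp.annotations) == 10
        assert sum(1 for mp in panel if "autoAb_target" in mp.annotations) == 2

    def test_caps_respected(self):
        panel = select_map_panel(self.annotated(15, 6))
        assert len(panel) == 12

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="empty panel"):
            assert select_map_panel([]) == []

    def test_deterministic_across_input_orderings(self):
        maps = self.annotated(8, 4)
        a = select_map_panel(maps)
        b = select_map_panel(list(reversed(maps)))
        assert [mp.sequence for mp in a] == [mp.sequence for mp in b]

    def test_dedup_by_sequence(self):
        dup = MapPeptide("P1", "AAAAAAAAA", frozenset({"K0"}),
                         frozenset({"known_A2_epitope"}))
        panel = select_map_panel([dup, dup])
        assert len(panel) == 1


class TestIO:
    def test_fasta_and_peptide_list_round_trip(self, tmp_path, cohort_bundle):
        proteome = read_proteome_fasta(cohort_bundle.paths["proteome"])
        assert len(proteome) == cohort_bundle.config.n_proteins
        pid = next(iter(cohort_bundle.paths["maps"]))
        peptides = read_peptide_list(cohort_bundle.paths["maps"][pid])
        assert peptides
        assert all(8 <= len(p) <= 11 for p in peptides)
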