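"""Minigene library construction: random libraries, epitope encoding,
scrambling, panning selection, screen-scale arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fretscreen.design import (AMINO_ACIDS, LKNFISEI, OVA_SCRAMBLE_PERMUTATION,
                               SIINFEKL, EpitopePlacement, LibrarySpec, Minigene,
                               design_panning_library, encode_minigene,
                               generate_random_minigenes, required_screen_scale,
                               scramble_epitope, translate_nt)
from fretscreen.enrichment import CountTable, call_hits


class TestRandomMinigenes:
    def test_lengths_and_count(self):
        mgs = generate_random_minigenes(5, length_nt=48, seed=1)
        assert len(mgs) == 5
        assert all(len(m.nt_seq) == 48 for m in mgs)

    def test_seed_determinism(self):
        a = generate_random_minigenes(50, seed=7)
        b = generate_random_minigenes(50, seed=7)
        assert [m.nt_seq for m in a] == [m.nt_seq for m in b]

    def test_length_not_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            generate_random_minigenes(3, length_nt=47, seed=0)

    def test_stop_fraction_matches_closed_form(self):
        # P(no in-frame stop in 16 codons) = (61/64)^16; brute-force check of
        # the per-codon stop probability backs the closed form
        n_stop_codons = sum(
            1 for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if translate_nt(a + b + c) == "*")
        assert n_stop_codons == 3
        p_expected = 1.0 - (61 / 64) ** 16
        n = 100_000
        mgs = generate_random_minigenes(n, length_nt=48, seed=123)
        p_obs = sum(m.peptide is None for m in mgs) / n
        sigma = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(p_obs - p_expected) < 3 * sigma

    def test_base_composition_uniform(self):
        mgs = generate_random_minigenes(3000, length_nt=48, seed=5)
        seq = "".join(m.nt_seq for m in mgs)  # 144k draws
        counts = [seq.count(b) for b in "ACGT"]
        chi2, p = stats.chisquare(counts)
        assert p > 0.001

    def test_productive_round_trip(self):
        for m in generate_random_minigenes(500, seed=2):
            if m.peptide is not None:
                assert translate_nt(m.nt_seq) == m.peptide
                assert "*" not in m.peptide


class TestEncodeMinigene:
    def test_siinfekl_short_format(self):
        m = encode_minigene("SIINFEKL", 16, 4, "random", "most-frequent", 0)
        assert len(m.peptide) == 16
        assert m.peptide[4:12] == "SIINFEKL"
        assert m.epitope_span == (4, 12)

    def test_positional_variants_differ(self):
        a = encode_minigene("KVPRNQDWL", 16, 0, seed=0)
        b = encode_minigene("KVPRNQDWL", 16, 7, seed=0)
        assert a.nt_seq != b.nt_seq
        assert a.peptide[0:9] == b.peptide[7:16] == "KVPRNQDWL"
        assert a.epitope_span == (0, 9) and b.epitope_span == (7, 16)

    def test_epitope_does_not_fit(self):
        with pytest.raises(ValueError):
            encode_minigene("SIINFEKL", 16, 9)

    def test_flanking_source_string(self):
        ctx = "A" * 40
        m = encode_minigene("SIINFEKL", 40, 16, flanking_source=ctx)
        assert m.peptide == "A" * 16 + "SIINFEKL" + "A" * 16

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12),
           st.integers(0, 8), st.sampled_from(["most-frequent", "seeded-random"]))
    def test_round_trip_translation(self, epitope, position, policy):
        total = position + len(epitope) + 3
        m = encode_minigene(epitope, total, position, codon_policy=policy, seed=9)
        assert translate_nt(m.nt_seq) == m.peptide
        assert m.peptide[position:position + len(epitope)] == epitope


class TestScramble:
    def test_paper_control(self):
        assert scramble_epitope(SIINFEKL, OVA_SCRAMBLE_PERMUTATION) == LKNFISEI

    def test_identity(self):
        assert scramble_epitope("SIINFEKL", range(8)) == "SIINFEKL"

    @given(st.permutations(range(8)))
    def test_residue_multiset_preserved(self, perm):
        out = scramble_epitope("SIINFEKL", perm)
        assert sorted(out) == sorted("SIINFEKL")

    def test_invalid_permutation(self):
        with pytest.raises(ValueError):
            scramble_epitope("SIINFEKL", [0, 1, 2, 3, 4, 5, 6, 6])


def _enrichment_from_counts(rows):
    """rows: list of (seq, shifted, unshifted)."""
    df = pd.DataFrame({"shifted": [r[1] for r in rows],
                       "unshifted": [r[2] for r in rows]},
                      index=pd.Index([r[0] for r in rows], name="id"))
    return call_hits(CountTable(df), k=10)


class TestPanningLibrary:
    @staticmethod
    def _random_rows(n, seed):
        mgs = generate_random_minigenes(n, seed=seed)
        rng = np.random.default_rng(seed)
        return [(m.nt_seq, int(rng.integers(0, 1000)), int(rng.integers(1, 1000)))
                for m in mgs]

    def test_top_n_selection(self):
        enr = _enrichment_from_counts(self._random_rows(1000, 3))
        lib = design_panning_library(enr, top_n=480)
        assert len(lib.clones) == 480
        ab = lib.effective_abundances()
        assert np.allclose(list(ab.values()), 1 / 480)

    def test_top_n_equals_total(self):
        rows = self._random_rows(50, 4)
        enr = _enrichment_from_counts(rows)
        lib = design_panning_library(enr, top_n=50)
        assert {m.nt_seq for m, _ in lib.clones} == {r[0] for r in rows}
        # library order follows the delta ranking
        assert [m.nt_seq for m, _ in lib.clones] == enr.ranking

    def test_top_n_exceeds_available(self):
        enr = _enrichment_from_counts(self._random_rows(10, 5))
        with pytest.raises(ValueError):
            design_panning_library(enr, top_n=11)

    def test_tie_break_by_shifted_then_sequence(self):
        # identical delta; shifted counts then sequence decide the boundary
        rows = [("CCC", 30, 30), ("AAA", 20, 20), ("TTT", 20, 20), ("GGG", 10, 10)]
        enr = _enrichment_from_counts(rows)
        lib = design_panning_library(enr, top_n=2)
        seqs = [m.nt_seq for m, _ in lib.clones]
        assert seqs == ["CCC", "AAA"]  # delta tie: 30 > 20; AAA < TTT lexicographic

    def test_idempotent_on_own_output(self):
        rows = self._random_rows(100, 6)
        enr = _enrichment_from_counts(rows)
        first = design_panning_library(enr, top_n=40)
        seqs = {m.nt_seq for m, _ in first.clones}
        enr2 = _enrichment_from_counts([r for r in rows if r[0] in seqs])
        second = design_panning_library(enr2, top_n=40)
        assert {m.nt_seq for m, _ in second.clones} == seqs

    def test_epitope_variant_substitution(self):
        canonical = encode_minigene("KVPRNQDWL", 40, 15, seed=1)
        rows = [(canonical.nt_seq, 500, 1)] + self._random_rows(50, 7)
        enr = _enrichment_from_counts(rows)
        placements = [EpitopePlacement(16, 0), EpitopePlacement(16, 4),
                      EpitopePlacement(16, 7)]
        lib = design_panning_library(enr, top_n=20, epitope="KVPRNQDWL",
                                     epitope_variants=placements)
        long_forms = [m for m, _ in lib.clones if m.nt_seq == canonical.nt_seq]
        assert not long_forms
        variants = [m for m, _ in lib.clones
                    if m.peptide and "KVPRNQDWL" in m.peptide]
        assert len(variants) == 3
        assert sorted(m.epitope_span[0] for m in variants) == [0, 4, 7]
        assert all(len(m.peptide) == 16 for m in variants)


class TestScreenScale:
    def test_proteome_scale(self):
        assert required_screen_scale(1_000_000, 300) == 300_000_000

    def test_identity(self):
        assert required_screen_scale(1, 1) == 1

    def test_spiked_library_scale(self):
        assert required_screen_scale(10_000, 300) == 3_000_000

    def test_invalid(self):
        with pytest.raises(ValueError):
            required_screen_scale(0, 300)


class TestLibrarySpec:
    def test_abundances_sum_to_one_after_spiking(self):
        mgs = generate_random_minigenes(10, seed=1)
        spike = encode_minigene("SIINFEKL", 16, 4, seed=0, id="ova")
        spec = LibrarySpec.uniform(mgs, spikes=[(spike, 1e-4, "cell")])
        assert abs(sum(spec.effective_abundances().values()) - 1) < 1e-9

    def test_bad_spike_fraction(self):
        mgs = generate_random_minigenes(5, seed=1)
        spike = encode_minigene("SIINFEKL", 16, 4, seed=0, id="ova")
        with pytest.raises(ValueError):
            LibrarySpec.uniform(mgs, spikes=[(spike, 1.5, "cell")])

    def test_minigene_invariant_enforced(self):
        with pytest.raises(ValueError):
            Minigene(id="x", nt_seq="ATGTAA", peptide="M*")  # stop in peptide
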