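"""Generative screen model: transduction, spiking, sorting, sequencing."""

import numpy as np
import pytest

from fretscreen.design import LibrarySpec, Minigene, encode_minigene, generate_random_minigenes
from fretscreen.pipeline import merge_read_pairs
from fretscreen.simulate import (DEFAULT_FLANK3, DEFAULT_FLANK5, CellPopulation,
                                 CocultureParams, SequencingModel, SortResult,
                                 TransductionModel, build_cell_library,
                                 simulate_amplicon_reads, simulate_coculture_sort)


def _productive_minigenes(n, seed=0, length_nt=48):
    out = []
    s = seed
    while len(out) < n:
        for m in generate_random_minigenes(2 * n, length_nt=length_nt, seed=s,
                                           id_prefix=f"c{s}_"):
            if m.peptide is not None:
                out.append(m)
            if len(out) == n:
                break
        s += 1
    return out


class TestBuildCellLibrary:
    def test_total_cells_conserved(self):
        spec = LibrarySpec.uniform(_productive_minigenes(20))
        pop = build_cell_library(spec, 10_000, seed=1)
        assert pop.n_cells == 10_000

    def test_single_integrant_fraction_closed_form(self):
        # P(k=1 | k>=1) = lam*exp(-lam)/(1-exp(-lam)) ~ 0.9508 at lam=0.1
        lam = 0.1
        tm = TransductionModel(moi_lambda=lam, condition_on_transduced=True)
        expected = tm.single_integrant_fraction()
        assert expected == pytest.approx(0.9508, abs=5e-4)
        spec = LibrarySpec.uniform(_productive_minigenes(10))
        n = 100_000
        pop = build_cell_library(spec, n, tm, seed=42)
        singles = int(pop.single_counts.sum())
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(singles / n - expected) < 3 * sigma

    def test_cell_spike_expected_count(self):
        # 1:10,000 of 3e6 cells -> ~300 spike cells
        spec = LibrarySpec.uniform(
            _productive_minigenes(50),
            spikes=[(encode_minigene("SIINFEKL", 16, 4, seed=0, id="ova"), 1e-4, "cell")])
        pop = build_cell_library(spec, 3_000_000, seed=3)
        idx = pop.ids.index("ova")
        n_spike = int(pop.single_counts[idx])
        assert abs(n_spike - 300) < 3 * np.sqrt(300)

    def test_dna_spike_enters_abundance_vector(self):
        spike = encode_minigene("SIINFEKL", 16, 4, seed=0, id="ova")
        spec = LibrarySpec.uniform(_productive_minigenes(50),
                                   spikes=[(spike, 0.01, "dna")])
        pop = build_cell_library(spec, 200_000, seed=4)
        idx = pop.ids.index("ova")
        carriers = pop.counts_by_clone()[idx]
        assert abs(carriers / 200_000 - 0.01) < 0.002

    def test_purity_sort_excludes_nonproductive_singles(self):
        mgs = generate_random_minigenes(200, seed=9)  # ~half non-productive
        assert any(m.peptide is None for m in mgs)
        spec = LibrarySpec.uniform(mgs)
        pop = build_cell_library(spec, 20_000, seed=5, purity_sorted=True)
        productive = np.array([spec.minigenes[i].peptide is not None for i in pop.ids])
        assert pop.single_counts[~productive].sum() == 0
        # every multi-integrant cell carries at least one productive insert
        if pop.multi_clones.size:
            ok = (productive[np.clip(pop.multi_clones, 0, None)]
                  & (pop.multi_clones >= 0)).any(axis=1)
            assert ok.all()

    def test_unconditioned_moi_leaves_untransduced(self):
        tm = TransductionModel(moi_lambda=0.1, condition_on_transduced=False)
        spec = LibrarySpec.uniform(_productive_minigenes(10))
        pop = build_cell_library(spec, 50_000, tm, seed=6)
        expected = 50_000 * np.exp(-0.1)
        assert abs(pop.untransduced - expected) < 3 * np.sqrt(expected)
        assert pop.n_cells == 50_000

    def test_invalid_total(self):
        spec = LibrarySpec.uniform(_productive_minigenes(5))
        with pytest.raises(ValueError):
            build_cell_library(spec, 0, seed=1)


class TestCocultureSort:
    def _pop(self, n_cog=1000, n_other=1000):
        return CellPopulation.from_counts({"cog": n_cog, "other": n_other})

    def test_perfect_sort(self):
        sr = simulate_coculture_sort(
            self._pop(), CocultureParams(p_hit=1, f_reactive=1, et_ratio=1, p_fp=0),
            {"cog"}, seed=1)
        assert sr.shifted[sr.ids.index("cog")] == 1000
        assert sr.shifted[sr.ids.index("other")] == 0

    def test_no_reactive_effectors_gives_fp_rate(self):
        # with f_reactive=0 every cell, cognate included, shifts at p_fp
        pop = self._pop(50_000, 50_000)
        cp = CocultureParams(p_hit=0.6, f_reactive=0.0, p_fp=1e-3)
        sr = simulate_coculture_sort(pop, cp, {"cog"}, seed=2)
        expected = 100_000 * 1e-3
        assert abs(sr.n_cells_shifted - expected) < 3 * np.sqrt(expected)

    def test_binary_mix_cognate_fraction(self):
        # closed form: 0.6/(0.6 + 1e-4) of the Shifted gate is cognate
        pop = self._pop(100_000, 100_000)
        cp = CocultureParams(p_hit=0.6, p_fp=1e-4)
        sr = simulate_coculture_sort(pop, cp, {"cog"}, seed=3)
        frac = sr.shifted[sr.ids.index("cog")] / sr.n_cells_shifted
        expected = 0.6 / (0.6 + 1e-4)
        assert expected == pytest.approx(0.99983, abs=1e-5)
        assert abs(frac - expected) < 3 * np.sqrt(1e-4 * 100_000) / sr.n_cells_shifted

    def test_gate_conservation(self):
        pop = self._pop(12_345, 23_456)
        sr = simulate_coculture_sort(pop, CocultureParams(), {"cog"}, seed=4)
        assert (sr.shifted + sr.unshifted == pop.single_counts).all()

    def test_gate_capacity_subsamples(self):
        pop = self._pop(50_000, 50_000)
        sr = simulate_coculture_sort(pop, CocultureParams(p_hit=1.0, p_fp=0.5),
                                     {"cog"}, gate_capacity=1000, seed=5)
        assert sr.n_cells_shifted == 1000
        assert (sr.shifted + sr.unshifted <= pop.single_counts).all()

    def test_effective_probability_cap(self):
        cp = CocultureParams(p_hit=0.6, f_reactive=1.0, et_ratio=10.0)
        assert cp.p_effective == 1.0

    def test_multi_integrant_cell_contributes_all_inserts(self):
        # one cell carrying cognate + passenger: both clones appear in the
        # Shifted gate counts when the cell shifts
        pop = CellPopulation(
            ids=("cog", "passenger"),
            single_counts=np.array([0, 0], dtype=np.int64),
            multi_clones=np.array([[0, 1]], dtype=np.int32))
        cp = CocultureParams(p_hit=1.0, p_fp=0.0)
        sr = simulate_coculture_sort(pop, cp, {"cog"}, seed=6)
        assert sr.shifted.tolist() == [1, 1]
        assert sr.n_cells_shifted == 1

    def test_unknown_cognate_id(self):
        with pytest.raises(ValueError):
            simulate_coculture_sort(self._pop(), CocultureParams(), {"nope"}, seed=1)


class TestAmpliconSequencing:
    def _sort_result(self, counts):
        ids = tuple(counts)
        arr = np.array([counts[i] for i in ids], dtype=np.int64)
        return SortResult(ids=ids, shifted=arr, unshifted=arr.copy(),
                          n_cells_shifted=int(arr.sum()),
                          n_cells_unshifted=int(arr.sum()))

    def _clone_seqs(self, n=4):
        return {f"c{i}": m.nt_seq for i, m in enumerate(_productive_minigenes(n, seed=1))}

    def test_exact_read_count(self):
        seqs = self._clone_seqs()
        sr = self._sort_result({k: 10 for k in seqs})
        sm = SequencingModel(reads_per_gate=1000)
        b1, b2, clones = simulate_amplicon_reads(sr, "shifted", sm, seqs, seed=1)
        assert len(b1) == len(b2) == len(clones) == 1000

    def test_noiseless_reads_reconstruct_amplicon(self):
        seqs = self._clone_seqs()
        sr = self._sort_result({k: 50 for k in seqs})
        sm = SequencingModel(reads_per_gate=2000, sub_error_rate=0.0,
                             amp_lognorm_sigma=0.0)
        b1, b2, clones = simulate_amplicon_reads(sr, "shifted", sm, seqs, seed=2)
        merged, failures = merge_read_pairs((b1, b2))
        assert not failures
        amplicons = {cid: DEFAULT_FLANK5 + s + DEFAULT_FLANK3 for cid, s in seqs.items()}
        for i in range(0, 2000, 97):
            assert merged.record(i).seq == amplicons[sr.ids[clones[i]]]
        # read proportions track cell proportions within multinomial error
        frac = np.bincount(clones, minlength=4) / 2000
        assert np.abs(frac - 0.25).max() < 3 * np.sqrt(0.25 * 0.75 / 2000)

    def test_outie_geometry_merged_length(self):
        # 248-nt amplicon sequenced with 250-nt reads: overhang on each end,
        # merged contig equals the 248-nt amplicon
        seqs = self._clone_seqs(2)
        assert all(len(DEFAULT_FLANK5 + s + DEFAULT_FLANK3) == 248 for s in seqs.values())
        sr = self._sort_result({k: 5 for k in seqs})
        sm = SequencingModel(reads_per_gate=100, sub_error_rate=0.0,
                             amp_lognorm_sigma=0.0, read_len=250)
        b1, b2, _ = simulate_amplicon_reads(sr, "shifted", sm, seqs, seed=3)
        assert (b1.lengths == 250).all()
        merged, failures = merge_read_pairs((b1, b2))
        assert not failures
        assert (merged.lengths == 248).all()
        assert (merged.overlap_len == 248).all()

    def test_error_rate_observed(self):
        seqs = self._clone_seqs(1)
        sr = self._sort_result({k: 5 for k in seqs})
        sm = SequencingModel(reads_per_gate=2000, sub_error_rate=0.01,
                             amp_lognorm_sigma=0.0)
        b1, _, clones = simulate_amplicon_reads(sr, "shifted", sm, seqs, seed=4)
        cid = sr.ids[0]
        template = (DEFAULT_FLANK5 + seqs[cid] + DEFAULT_FLANK3 + "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC")[:250]
        tarr = np.frombuffer(template.encode(), dtype=np.uint8)
        mism = (b1.seqs[:, :250] != tarr[None, :]).mean()
        # substituted base differs from the original with certainty
        assert mism == pytest.approx(0.01, rel=0.15)

    def test_empty_gate_with_reads_errors(self):
        sr = self._sort_result({"c0": 0})
        with pytest.raises(ValueError):
            simulate_amplicon_reads(sr, "shifted", SequencingModel(reads_per_gate=10),
                                    {"c0": "ATG" * 16}, seed=1)

    def test_missing_clone_sequence(self):
        sr = self._sort_result({"c0": 5})
        with pytest.raises(ValueError):
            simulate_amplicon_reads(sr, "shifted", SequencingModel(reads_per_gate=10),
                                    {}, seed=1)
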