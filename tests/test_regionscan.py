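import math

import numpy as np
import pytest

from superbarcode.errors import CoordinateError, ParameterError
from superbarcode.regionscan import (
    DiversityTrack,
    Window,
    call_hvrs,
    derive_igs,
    extract_region,
    nucleotide_diversity,
    sliding_window_pi,
)
from superbarcode.seqio import Feature, FeatureTable

from _oracles import bf_pi_complete
from conftest import make_alignment, random_alignment


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = make_alignment(["ACGT", "ACGT"])
        assert nucleotide_diversity(aln) == 0.0

    def test_three_pair_hand_enumeration(self, aln_three):
        # pairs: (0.25 + 0.50 + 0.25) / 3
        assert nucleotide_diversity(aln_three) == pytest.approx(1 / 3, abs=1e-12)

    def test_undefined_vs_zero(self):
        # every column carries a gap -> undefined, not 0
        aln = make_alignment(["A-", "-A"])
        assert math.isnan(nucleotide_diversity(aln))
        assert nucleotide_diversity(make_alignment(["AA", "AA"])) == 0.0

    def test_complete_deletion_drops_gapped_columns(self):
        # column 2 has a gap: complete deletion scores only columns 1,3,4
        aln = make_alignment(["AAAA", "A-AT"])
        assert nucleotide_diversity(aln, "complete") == pytest.approx(1 / 3)
        # pairwise deletion compares the same sites for n=2
        assert nucleotide_diversity(aln, "pairwise") == pytest.approx(1 / 3)

    def test_matches_exact_fraction_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            aln = random_alignment(rng, int(rng.integers(2, 8)), int(rng.integers(10, 60)))
            expected = bf_pi_complete([r.sequence for r in aln.records])
            got = nucleotide_diversity(aln)
            if expected is None:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(float(expected), abs=1e-12)

    def test_requires_two_sequences(self):
        with pytest.raises(ParameterError):
            nucleotide_diversity(make_alignment(["ACGT"]))


class TestSlidingWindow:
    def test_window_arithmetic(self):
        aln = make_alignment(["A" * 1000, "A" * 1000])
        track = sliding_window_pi(aln, 600, 200)
        assert [(w.start, w.end) for w in track.windows] == [
            (0, 600), (200, 800), (400, 1000),
        ]

    def test_truncated_terminal_window(self):
        aln = make_alignment(["A" * 1100, "A" * 1100])
        track = sliding_window_pi(aln, 600, 200)
        assert [(w.start, w.end) for w in track.windows][-1] == (600, 1100)
        # a tail shorter than the step is not emitted
        aln2 = make_alignment(["A" * 1150, "A" * 1150])
        track2 = sliding_window_pi(aln2, 600, 200)
        assert track2.windows[-1].end == 1150 and track2.windows[-1].start == 600

    def test_constant_alignment_all_zero(self):
        aln = make_alignment(["ACGT" * 300] * 3)
        track = sliding_window_pi(aln)
        assert all(w.pi == 0.0 for w in track.windows)

    def test_window_pi_equals_direct_recomputation(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 6, 900)
        track = sliding_window_pi(aln, 300, 150)
        for w in track.windows:
            sub = aln.slice_columns(np.arange(w.start, w.end))
            direct = nucleotide_diversity(sub, "complete")
            if math.isnan(direct):
                assert not w.defined
            else:
                assert w.pi == pytest.approx(direct, abs=1e-12)
        best = max(w.pi for w in track.windows if w.defined)
        assert best == pytest.approx(track.max_pi())

    def test_coverage_when_step_le_window(self):
        aln = make_alignment(["A" * 1234, "A" * 1234])
        track = sliding_window_pi(aln, 600, 200)
        covered = set()
        for w in track.windows:
            covered.update(range(w.start, w.end))
        assert covered == set(range(1234))

    def test_bad_parameters(self):
        aln = make_alignment(["A" * 100, "A" * 100])
        with pytest.raises(ParameterError):
            sliding_window_pi(aln, 0, 10)
        with pytest.raises(ParameterError):
            sliding_window_pi(aln, 600, 200)  # shorter than the window


def _track(pis, start=0, wlen=100, step=100):
    windows = tuple(
        Window(start + i * step, start + i * step + wlen, pi, wlen)
        for i, pi in enumerate(pis)
    )
    return DiversityTrack(windows, wlen, step)


class TestCallHvrs:
    def test_nothing_passes(self):
        assert call_hvrs(_track([0.001, 0.002]), 0.01, 200) == []

    def test_merge_rule(self):
        # two passing windows 200 bp apart merge under merge_gap 400
        windows = (
            Window(0, 100, 0.05, 100),
            Window(300, 400, 0.05, 100),
        )
        track = DiversityTrack(windows, 100, 300)
        calls = call_hvrs(track, 0.01, 400)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (0, 400)
        assert calls[0].peak_pi == 0.05
        # and stay separate when the gap is not smaller than merge_gap
        assert len(call_hvrs(track, 0.01, 200)) == 2

    def test_order_invariance(self):
        windows = (
            Window(400, 500, 0.05, 100),
            Window(0, 100, 0.04, 100),
            Window(200, 300, 0.001, 100),
        )
        track = DiversityTrack(windows, 100, 200)
        a = call_hvrs(track, 0.01, 150)
        b = call_hvrs(DiversityTrack(tuple(reversed(windows)), 100, 200), 0.01, 150)
        assert a == b

    def test_feature_naming(self):
        track = _track([0.0, 0.08, 0.08, 0.0])
        genes = FeatureTable(
            [Feature("matK", "gene", 90, 160), Feature("trnG", "gene", 250, 320)]
        )
        calls = call_hvrs(track, 0.05, 100, features=genes)
        assert [c.name for c in calls] == ["matK-trnG"]


class TestExtract:
    def test_slice(self):
        aln = make_alignment(["ACGTACGT", "ACGAACGA"])
        sub = extract_region(aln, Feature("x", "gene", 0, 4))
        assert [r.sequence for r in sub.records] == ["ACGT", "ACGA"]
        assert sub.name == "x"

    def test_minus_strand_reverse_complement(self):
        aln = make_alignment(["ACGT", "ACGT"])
        sub = extract_region(aln, Feature("x", "gene", 0, 4, "-"))
        assert [r.sequence for r in sub.records] == ["ACGT", "ACGT"]
        sub2 = extract_region(make_alignment(["AACC", "AACC"]), Feature("y", "gene", 0, 4, "-"))
        assert [r.sequence for r in sub2.records] == ["GGTT", "GGTT"]

    def test_all_gap_columns_dropped(self):
        aln = make_alignment(["AC--GT", "AG--GT"])
        sub = extract_region(aln, Feature("x", "gene", 0, 6))
        assert sub.length == 4

    def test_out_of_bounds(self):
        aln = make_alignment(["ACGT", "ACGT"])
        with pytest.raises(CoordinateError):
            extract_region(aln, Feature("x", "gene", 2, 9))

    def test_extraction_preserves_column_identity(self):
        """Pi of an extracted slice equals Pi computed on those columns directly."""
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 8, 50, p_gap=0.0, p_n=0.0)
        for start, end in [(0, 10), (5, 30), (20, 50)]:
            sub = extract_region(aln, Feature("r", "HVR", start, end))
            expected = bf_pi_complete([r.sequence[start:end] for r in aln.records])
            assert nucleotide_diversity(sub) == pytest.approx(float(expected), abs=1e-12)


class TestDeriveIgs:
    def test_gap_between_genes(self):
        genes = FeatureTable(
            [Feature("g1", "gene", 0, 100), Feature("g2", "gene", 150, 300)]
        )
        igs = derive_igs(genes)
        assert len(igs) == 1
        f = igs.features[0]
        assert (f.name, f.kind, f.start, f.end) == ("g1-g2", "IGS", 100, 150)

    def test_overlapping_genes_skipped(self):
        genes = FeatureTable(
            [Feature("g1", "gene", 0, 100), Feature("g2", "gene", 80, 200)]
        )
        assert len(derive_igs(genes)) == 0

    def test_multi_exon_gene_uses_full_span(self):
        genes = FeatureTable(
            [
                Feature("g1", "gene", 0, 50),
                Feature("g1", "gene", 80, 120),  # second exon
                Feature("g2", "gene", 200, 260),
            ]
        )
        igs = derive_igs(genes)
        assert [(f.name, f.start, f.end) for f in igs] == [("g1-g2", 120, 200)]
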