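"""Encoder: window arithmetic, pileups, smoothing, standardization."""

import numpy as np
import pytest

from atacre import simulate
from atacre.encoder import (
    AlignmentFragmentSource,
    EncoderConfig,
    ListFragmentSource,
    cut_count_rows,
    encode_dataset,
    encode_peak_raw,
    fit_stats,
    apply_stats,
    fragment_length_rows,
    insert_pileup_row,
    load_encoded_dataset,
    peak_window,
    save_encoded_dataset,
    sequence_frequency_rows,
    smooth_track,
    standardize_dataset,
)
from atacre.genomic_io import GenomicInterval

from conftest import make_fragments, make_peak

CFG = EncoderConfig()


class TestPeakWindow:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1000, 1600, (1000, 1600)),   # center 1300
            (1000, 1601, (1000, 1600)),   # floor of midpoint
            (2000, 3000, (2200, 2800)),
        ],
    )
    def test_floor_center_rule(self, start, end, expected):
        w = peak_window(make_peak(start, end), CFG)
        assert (w.start, w.end) == expected

    def test_window_length_is_fixed(self):
        for start, end in [(0, 1), (100, 5000), (7, 613)]:
            assert len(peak_window(make_peak(start, end), CFG)) == 600


class TestSequenceFrequencyRows:
    def test_frequencies_at_depth(self):
        counts = np.zeros((4, 3))
        counts[:, 1] = [14, 6, 0, 0]  # 14 A, 6 C
        rows = sequence_frequency_rows(counts, "GGG", CFG)
        assert np.allclose(rows[:, 1], [0.7, 0.3, 0, 0])

    def test_low_depth_falls_back_to_reference(self):
        counts = np.zeros((4, 1))
        counts[2, 0] = 9  # 9 G calls, below min_depth
        rows = sequence_frequency_rows(counts, "A", CFG)
        assert np.allclose(rows[:, 0], [1, 0, 0, 0])

    def test_zero_fragments_one_hot_reference(self):
        rows = sequence_frequency_rows(np.zeros((4, 4)), "ACGT", CFG)
        assert np.allclose(rows, np.eye(4))

    def test_n_reference_low_depth_gives_zero_column(self):
        rows = sequence_frequency_rows(np.zeros((4, 2)), "NA", CFG)
        assert rows[:, 0].sum() == 0
        assert rows[:, 1].sum() == 1


class TestInsertPileup:
    def test_single_fragment_contributes_its_span(self):
        w = GenomicInterval("chr1", 1000, 1600)
        row = insert_pileup_row(make_fragments([(1250, 1350)]), w)
        assert row.sum() == 100
        assert set(np.unique(row)) == {0.0, 1.0}

    def test_matches_bruteforce_enumeration(self, rng):
        w = GenomicInterval("chr1", 1000, 1600)
        spans = [
            (int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(700, 1700, 200), rng.integers(30, 400, 200)
            )
        ]
        row = insert_pileup_row(make_fragments(spans), w)
        brute = np.zeros(600)
        for p in range(600):
            pos = 1000 + p
            brute[p] = sum(1 for s, e in spans if s <= pos < e)
        assert np.array_equal(row, brute)

    def test_fragment_outside_window_is_zero(self):
        w = GenomicInterval("chr1", 1000, 1600)
        assert insert_pileup_row(make_fragments([(0, 500)]), w).sum() == 0


class TestCutRows:
    def test_raw_rows_are_endpoint_histograms(self, rng):
        w = GenomicInterval("chr1", 1000, 1600)
        spans = [
            (int(s), int(s) + int(l))
            for s, l in zip(rng.integers(900, 1650, 150), rng.integers(40, 300, 150))
        ]
        frags = make_fragments(spans)
        raw = cut_count_rows(frags, w, CFG, smooth=False)
        # conservation: totals equal endpoint counts inside the window
        n_left = sum(1 for s, _ in spans if 1000 <= s < 1600)
        n_right = sum(1 for _, e in spans if 1000 <= e - 1 < 1600)
        assert raw[0].sum() == n_left
        assert raw[1].sum() == n_right
        brute5 = np.zeros(600)
        for s, _ in spans:
            if 1000 <= s < 1600:
                brute5[s - 1000] += 1
        assert np.array_equal(raw[0], brute5)

    def test_smoothed_impulse_support_is_window(self):
        w = GenomicInterval("chr1", 0, 600)
        frags = make_fragments([(300, 400)] * 8)
        smoothed = cut_count_rows(frags, w, CFG, smooth=True)
        support = np.flatnonzero(np.abs(smoothed[0]) > 1e-12)
        assert len(support) == CFG.smooth_window
        assert support[0] == 300 - CFG.smooth_window // 2

    def test_no_fragments_all_zero(self):
        w = GenomicInterval("chr1", 0, 600)
        assert not cut_count_rows([], w, CFG).any()


class TestFragmentLengthRows:
    def test_median_of_lengths_cutting_at_position(self):
        w = GenomicInterval("chr1", 0, 600)
        frags = make_fragments([(100, 200), (100, 250), (100, 310)])
        raw = fragment_length_rows(frags, w, CFG, smooth=False)
        assert raw[0, 100] == 150  # median of {100, 150, 210}

    def test_single_fragment_length_at_both_ends(self):
        w = GenomicInterval("chr1", 0, 600)
        raw = fragment_length_rows(make_fragments([(100, 180)]), w, CFG, smooth=False)
        assert raw[0, 100] == 80
        assert raw[1, 179] == 80

    def test_cut_free_positions_are_zero(self):
        w = GenomicInterval("chr1", 0, 600)
        raw = fragment_length_rows(make_fragments([(100, 180)]), w, CFG, smooth=False)
        assert raw[0].sum() == 80  # single nonzero entry


class TestSmoothing:
    def test_constant_track_unchanged(self):
        track = np.full(600, 3.7)
        assert np.allclose(smooth_track(track, CFG), track, atol=1e-12)

    def test_impulse_support(self):
        track = np.zeros(600)
        track[300] = 1.0
        out = smooth_track(track, CFG)
        support = np.flatnonzero(np.abs(out) > 1e-12)
        assert len(support) == 15
        assert support[0] == 293 and support[-1] == 307

    def test_interior_matches_polyfit_oracle(self, rng):
        track = rng.normal(size=200)
        out = smooth_track(track, CFG)
        half = CFG.smooth_window // 2
        for center in range(half, 200 - half, 13):
            xs = np.arange(-half, half + 1)
            coeffs = np.polyfit(xs, track[center - half : center + half + 1],
                                CFG.smooth_polyorder)
            assert abs(out[center] - np.polyval(coeffs, 0.0)) < 1e-9

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(np.zeros(10), CFG)


class TestStandardization:
    def _raw(self, insert_values):
        from atacre.encoder import RawPeakTracks

        out = []
        for v in insert_values:
            L = 600
            out.append(
                RawPeakTracks(
                    seq_freq=np.zeros((4, L)),
                    insert_raw=np.full(L, float(v)),
                    cut5_raw=np.zeros(L),
                    cut3_raw=np.zeros(L),
                    len5_raw=np.zeros(L),
                    len3_raw=np.zeros(L),
                    indicator=np.zeros(L),
                )
            )
        return out

    def test_two_point_column(self):
        stats, mats = standardize_dataset(self._raw([1.0, 3.0]), CFG)
        assert np.allclose(mats[0][4], -1.0)  # row 5 = first signal row
        assert np.allclose(mats[1][4], 1.0)

    def test_constant_column_maps_to_zero(self):
        stats, mats = standardize_dataset(self._raw([2.0, 2.0, 2.0]), CFG)
        assert not mats[0][4].any()

    def test_moments_after_standardization(self, tiny_encoded):
        encodings, stats, cfg, _ = tiny_encoded
        stack = np.stack([e.matrix[4:9] for e in encodings])  # (n, 5, L)
        nondeg = stats.std > 0
        means = stack.mean(axis=0)[nondeg]
        stds = stack.std(axis=0)[nondeg]
        assert np.abs(means).max() < 1e-6
        assert np.abs(stds - 1).max() < 1e-6

    def test_reapplying_fitted_stats_is_bit_identical(self):
        raw = self._raw([1.0, 2.0, 5.0])
        stats = fit_stats(raw, CFG)
        first = [apply_stats(r, stats) for r in raw]
        second = [apply_stats(r, stats) for r in raw]
        for a, b in zip(first, second):
            assert np.array_equal(a, b)


class TestEncodeDataset:
    def test_shapes_and_column_sum_property(self, tiny_encoded, tiny_study):
        encodings, stats, cfg, _ = tiny_encoded
        assert len(encodings) == len(tiny_study.peaks)
        for e in encodings:
            assert e.matrix.shape == (10, 600)
            colsums = e.matrix[:4].sum(axis=0)
            assert np.all(
                (np.abs(colsums - 1) < 1e-9) | (np.abs(colsums) < 1e-9)
            )
            assert set(np.unique(e.matrix[9])) <= {0.0, 1.0}

    def test_order_invariance(self, tiny_study):
        ref = tiny_study.reference()
        source = ListFragmentSource(tiny_study.fragments)
        peaks = tiny_study.peaks[:10]
        enc_fwd, _ = encode_dataset(peaks, source, ref, CFG)
        enc_rev, _ = encode_dataset(peaks[::-1], source, ref, CFG)
        for a, b in zip(enc_fwd, enc_rev[::-1]):
            # standardization moments are order-independent up to float
            # summation order
            assert np.allclose(a.matrix, b.matrix, atol=1e-10)

    def test_empty_fragment_source_zeroes_signal_rows(self, tiny_study):
        ref = tiny_study.reference()
        source = ListFragmentSource([])
        encodings, _ = encode_dataset(tiny_study.peaks[:3], source, ref, CFG)
        for e in encodings:
            assert not e.matrix[4:9].any()

    def test_alignment_and_bed_sources_agree(self, tmp_path, rng):
        # fragments whose mates tile the span with reference bases must
        # encode identically through SAM and fragments-BED routes
        seqs = {"chr1": simulate.random_sequence(rng, 4000)}
        fasta = str(tmp_path / "ref.fa")
        simulate.write_fasta(seqs, fasta)
        spans = [
            (int(s), int(s) + int(l))
            for s, l in zip(rng.integers(500, 3000, 120), rng.integers(50, 260, 120))
        ]
        frags = make_fragments(spans)
        sam = str(tmp_path / "frags.sam")
        simulate.fragments_to_sam(frags, seqs, sam)
        from atacre.genomic_io import ReferenceGenome

        ref = ReferenceGenome(fasta)
        peaks = [make_peak(1200, 1800), make_peak(1900, 2500)]
        enc_bed, _ = encode_dataset(peaks, ListFragmentSource(frags), ref, CFG)
        enc_sam, _ = encode_dataset(
            peaks, AlignmentFragmentSource(sam), ref, CFG
        )
        for a, b in zip(enc_bed, enc_sam):
            assert np.allclose(a.matrix, b.matrix, atol=1e-12)

    def test_persistence_roundtrip(self, tmp_path, tiny_encoded):
        encodings, stats, cfg, _ = tiny_encoded
        prefix = str(tmp_path / "ds")
        save_encoded_dataset(prefix, encodings[:5], stats, cfg)
        back, back_stats, back_cfg = load_encoded_dataset(prefix)
        assert back_cfg == cfg
        assert np.allclose(back_stats.mean, stats.mean)
        for a, b in zip(encodings[:5], back):
            assert np.array_equal(a.matrix, b.matrix)
            assert a.peak.name == b.peak.name
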