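"""Synthetic-data generators: determinism, distributions, consistency."""

import numpy as np
import pandas as pd
import pytest

from atacre import simulate
from atacre.genomic_io import GenomicInterval
from atacre.ground_truth import FunctionalClass, annotate_peak
from atacre.simulate import (
    CohortConfig,
    DEFAULT_ARCHETYPES,
    cohort_fragments,
    gen_genotyped_cohort,
    gen_peak_fragments,
    gen_reference,
    gen_segmentation,
)


class TestGenReference:
    def test_deterministic_per_seed(self):
        a = gen_reference(5, {"chr1": 5000})
        b = gen_reference(5, {"chr1": 5000})
        assert a == b
        c = gen_reference(6, {"chr1": 5000})
        assert a != c

    def test_exact_lengths(self):
        seqs = gen_reference(1, {"chr1": 100_000, "chr2": 777})
        assert len(seqs["chr1"]) == 100_000
        assert len(seqs["chr2"]) == 777

    def test_gc_within_binomial_band(self):
        n, gc = 100_000, 0.6
        seq = gen_reference(2, {"chr1": n}, gc=gc)["chr1"]
        observed = (seq.count("G") + seq.count("C")) / n
        sd = np.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) < 3 * sd

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            gen_reference(1, {"chr1": 100}, gc=1.5)


class TestGenPeakFragments:
    LOCUS = GenomicInterval("chr1", 10_000, 10_600)

    def test_exact_fragment_count(self):
        arch = DEFAULT_ARCHETYPES[FunctionalClass.ENHANCER]
        frags = gen_peak_fragments(arch, self.LOCUS, 500, 3)
        assert len(frags) == 500

    def test_fragments_near_locus(self):
        arch = DEFAULT_ARCHETYPES[FunctionalClass.PROMOTER]
        frags = gen_peak_fragments(arch, self.LOCUS, 300, 3)
        center = 10_300
        max_extent = 6 * arch.nfr_width + 500  # positional tail + max length
        for fr in frags:
            assert abs((fr.interval.start + fr.interval.end) / 2 - center) < max_extent

    def test_promoter_size_mixture_is_subnucleosomal_rich(self):
        arch = DEFAULT_ARCHETYPES[FunctionalClass.PROMOTER]
        frags = gen_peak_fragments(arch, self.LOCUS, 2000, 4)
        lengths = np.array([f.length for f in frags])
        sub = (lengths < 147).mean()
        mono = ((lengths >= 147) & (lengths < 294)).mean()
        assert sub > mono

    def test_other_archetype_is_mononucleosomal_rich(self):
        arch = DEFAULT_ARCHETYPES[FunctionalClass.OTHER]
        lengths = np.array(
            [f.length for f in gen_peak_fragments(arch, self.LOCUS, 2000, 4)]
        )
        assert (lengths >= 147).mean() > (lengths < 147).mean()


class TestGenSegmentation:
    def test_roundtrip_recovers_planted_labels(self, tiny_study):
        recovered = 0
        for peak, cls in zip(tiny_study.peaks, tiny_study.classes):
            lp = annotate_peak(peak, tiny_study.segmentation, tiny_study.scheme)
            assert lp is not None
            recovered += lp.label is cls
        assert recovered == len(tiny_study.peaks)

    def test_sorted_and_non_overlapping(self, tiny_study):
        by_chrom = {}
        for rec in tiny_study.segmentation:
            by_chrom.setdefault(rec.interval.chrom, []).append(rec)
        for records in by_chrom.values():
            for a, b in zip(records, records[1:]):
                assert a.interval.end <= b.interval.start

    def test_promoter_locus_covered_by_tss_state(self, tiny_study):
        for peak, cls in zip(tiny_study.peaks, tiny_study.classes):
            if cls is FunctionalClass.PROMOTER:
                covering = [
                    r.state_label
                    for r in tiny_study.segmentation
                    if peak.interval.overlap(r.interval) > 0
                ]
                assert set(covering) == {"1_TssA"}
                break

    def test_overlapping_loci_rejected(self):
        from conftest import make_peak

        loci = [
            (make_peak(100, 700), FunctionalClass.PROMOTER),
            (make_peak(500, 1100), FunctionalClass.ENHANCER),
        ]
        with pytest.raises(ValueError, match="overlap"):
            gen_segmentation(loci, {"chr1": 2000})


class TestGenotypedCohort:
    def test_deterministic_per_seed(self):
        a = gen_genotyped_cohort(CohortConfig(n_loci=10, seed=5))
        b = gen_genotyped_cohort(CohortConfig(n_loci=10, seed=5))
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.activity, b.activity)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_null_effect_gives_null_correlations(self):
        cohort = gen_genotyped_cohort(
            CohortConfig(n_samples=40, n_loci=60, effect_size=0.0, seed=8)
        )
        merged = cohort.genotypes.merge(cohort.activity, on=["snp_id", "sample"])
        dosage = merged["genotype"].map({"ref/ref": 0, "ref/alt": 1, "alt/alt": 2})
        rs = (
            merged.assign(dosage=dosage)
            .groupby("snp_id")
            .apply(
                lambda g: np.corrcoef(g["dosage"], g["activity"])[0, 1],
                include_groups=False,
            )
        )
        assert abs(rs.mean()) < 0.05

    def test_at_least_two_genotype_groups_per_locus(self):
        cohort = gen_genotyped_cohort(CohortConfig(n_loci=50, seed=1))
        counts = cohort.genotypes.groupby("snp_id")["genotype"].nunique()
        assert (counts >= 2).all()

    def test_fragment_depth_tracks_planted_direction(self):
        cohort = gen_genotyped_cohort(
            CohortConfig(n_samples=12, n_loci=6, seed=3)
        )
        frag_sets = cohort_fragments(cohort, base_depth=80, depth_shift=0.4)
        truth = cohort.truth.set_index("snp_id")
        # pooled over loci: hom-alt depth minus hom-ref depth has the planted sign
        diffs = []
        for snp_id, grp in cohort.genotypes.groupby("snp_id"):
            locus = truth.loc[snp_id]
            direction = 1 if locus["direction"] == "gain" else -1
            depths = {}
            for _, row in grp.iterrows():
                frs = [
                    f
                    for f in frag_sets[row["sample"]]
                    if f.interval.chrom == locus["chrom"]
                    and f.interval.start < locus["end"] + 600
                    and f.interval.end > locus["start"] - 600
                ]
                depths.setdefault(row["genotype"], []).append(len(frs))
            if "ref/ref" in depths and "alt/alt" in depths:
                diffs.append(
                    direction
                    * (np.mean(depths["alt/alt"]) - np.mean(depths["ref/ref"]))
                )
        assert diffs and np.mean(diffs) > 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_samples=1)
        with pytest.raises(ValueError):
            CohortConfig(allele_freq=0.0)


class TestStudyDeterminism:
    def test_same_seed_same_study(self, tmp_path):
        a = simulate.simulate_study(str(tmp_path / "a"), 8, 4, 4, seed=21)
        b = simulate.simulate_study(str(tmp_path / "b"), 8, 4, 4, seed=21)
        assert [p.name for p in a.peaks] == [p.name for p in b.peaks]
        assert [p.interval.start for p in a.peaks] == [p.interval.start for p in b.peaks]
        assert a.classes == b.classes
        assert len(a.fragments) == len(b.fragments)
        with open(a.reference_path) as fa, open(b.reference_path) as fb:
            assert fa.read() == fb.read()

    def test_written_artifacts(self, tmp_path, tiny_study):
        paths = simulate.write_study(tiny_study, str(tmp_path / "out"))
        from atacre.genomic_io import read_peaks, read_segmentation

        peaks = read_peaks(paths["peaks"], "narrowPeak")
        assert len(peaks) == len(tiny_study.peaks)
        seg = read_segmentation(paths["segmentation"])
        assert len(seg) == len(tiny_study.segmentation)
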