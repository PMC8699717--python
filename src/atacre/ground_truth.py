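"""Ground-truth labels for ATAC-seq peaks from chromatin-state segmentations.

ChromHMM-style state labels are merged into 4 functional classes (promoter,
enhancer, insulator, other); a peak is retained only if states of a single
class cover at least 90% of its length (the unanimity filter).  Retained
autosomal peaks are partitioned into train / validation / test by chromosome
(validation: chr2, chr10; test: chr3, chr11), and the "other" class can be
augmented with consensus regions that were not called as peaks in the sample
itself, capped at 25% of that sample's "other" examples.

Built-in label schemes:

``roadmap18``
    The 18-state Roadmap expanded model.  Promoter <- 1_TssA, 2_TssFlnk;
    Enhancer <- 7_EnhG1, 8_EnhG2, 9_EnhA1, 10_EnhA2, 11_EnhWk; Other <-
    5_Tx, 6_TxWk, 12_ZNF/Rpts, 13_Het, 16_ReprPC, 17_ReprPCW, 18_Quies.
    Remaining states are unmapped (peaks covered by them are excluded).
``endoc``
    The EndoC beta-cell study's state names.  Promoter <- 1_Active_TSS,
    2_Weak_TSS, 14_Bivalent_poised_TSS; Enhancer <- 8_Genic_enhancer,
    9_Active_enhancer_1, 10_Active_enhancer_2, 11_Weak_enhancer; Other <-
    5_Strong_transcription, 6_Weak_transcription, 16_Repressed_polycomb,
    17_Weak_repressed_polycomb, 18_Quiescent_low_signal.

Neither built-in scheme carries CTCF-insulator states (a known labeling
limitation of those references); a ``custom`` scheme loaded from a
two-column TSV covers in-house models that do.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .genomic_io import GenomicInterval, Peak, SegmentationRecord


class FunctionalClass(str, Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"
    INSULATOR = "insulator"
    OTHER = "other"


ROADMAP18_MAP = {
    "1_TssA": FunctionalClass.PROMOTER,
    "2_TssFlnk": FunctionalClass.PROMOTER,
    "7_EnhG1": FunctionalClass.ENHANCER,
    "8_EnhG2": FunctionalClass.ENHANCER,
    "9_EnhA1": FunctionalClass.ENHANCER,
    "10_EnhA2": FunctionalClass.ENHANCER,
    "11_EnhWk": FunctionalClass.ENHANCER,
    "5_Tx": FunctionalClass.OTHER,
    "6_TxWk": FunctionalClass.OTHER,
    "12_ZNF/Rpts": FunctionalClass.OTHER,
    "13_Het": FunctionalClass.OTHER,
    "16_ReprPC": FunctionalClass.OTHER,
    "17_ReprPCW": FunctionalClass.OTHER,
    "18_Quies": FunctionalClass.OTHER,
}

ENDOC_MAP = {
    "1_Active_TSS": FunctionalClass.PROMOTER,
    "2_Weak_TSS": FunctionalClass.PROMOTER,
    "14_Bivalent_poised_TSS": FunctionalClass.PROMOTER,
    "8_Genic_enhancer": FunctionalClass.ENHANCER,
    "9_Active_enhancer_1": FunctionalClass.ENHANCER,
    "10_Active_enhancer_2": FunctionalClass.ENHANCER,
    "11_Weak_enhancer": FunctionalClass.ENHANCER,
    "5_Strong_transcription": FunctionalClass.OTHER,
    "6_Weak_transcription": FunctionalClass.OTHER,
    "16_Repressed_polycomb": FunctionalClass.OTHER,
    "17_Weak_repressed_polycomb": FunctionalClass.OTHER,
    "18_Quiescent_low_signal": FunctionalClass.OTHER,
}

TRAIN_CHROMS = {
    "1", "4", "5", "6", "7", "8", "9", "12", "13", "14",
    "15", "16", "17", "18", "19", "20", "21", "22",
}
VALIDATION_CHROMS = {"2", "10"}
TEST_CHROMS = {"3", "11"}

UNANIMITY_THRESHOLD = 0.9
NONPEAK_OTHER_CAP = 0.25


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from segmentation state labels to functional classes.

    Unmapped states are excluded: a peak covered by them cannot reach the
    unanimity threshold for any class.
    """

    name: str
    state_to_class: dict

    def relabel(self, state_label: str) -> Optional[FunctionalClass]:
        return self.state_to_class.get(state_label)


def get_scheme(scheme: str, custom_map: Optional[dict] = None) -> LabelScheme:
    if scheme == "roadmap18":
        return LabelScheme("roadmap18", dict(ROADMAP18_MAP))
    if scheme == "endoc":
        return LabelScheme("endoc", dict(ENDOC_MAP))
    if scheme == "custom":
        if not custom_map:
            raise ValueError("custom scheme requires a state -> class map")
        mapped = {
            state: FunctionalClass(cls) if not isinstance(cls, FunctionalClass) else cls
            for state, cls in custom_map.items()
        }
        return LabelScheme("custom", mapped)
    raise ValueError(f"unknown label scheme: {scheme!r}")


def load_scheme_tsv(path: str, name: str = "custom") -> LabelScheme:
    """Two-column TSV: state_label <tab> class (promoter/enhancer/insulator/other)."""
    mapping: dict[str, FunctionalClass] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            state, cls = line.split("\t")[:2]
            mapping[state] = FunctionalClass(cls.strip().lower())
    return LabelScheme(name, mapping)


def relabel_state(state_label: str, scheme) -> Optional[FunctionalClass]:
    """Map one state label to a functional class, or None (excluded)."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    return scheme.relabel(state_label)


@dataclass(frozen=True)
class LabeledPeak:
    peak: Peak
    label: FunctionalClass
    overlap_fraction: float
    split: Optional[str] = None
    is_nonpeak_augmented: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.is_nonpeak_augmented and self.label is not FunctionalClass.OTHER:
            raise ValueError("augmented non-peak examples must be labeled other")


def annotate_peak(
    peak: Peak,
    segmentation: Sequence[SegmentationRecord],
    scheme,
    threshold: float = UNANIMITY_THRESHOLD,
) -> Optional[LabeledPeak]:
    """Label a peak by the class whose states cover >= ``threshold`` of the
    peak's length; None when no class reaches the threshold (excluded).

    Coverage is an exact interval-intersection sum, so splitting a
    segmentation record into adjacent same-state pieces changes nothing.
    The boundary is inclusive (exactly 90% is retained).
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    covered: dict[FunctionalClass, int] = {}
    for rec in segmentation:
        cls = scheme.relabel(rec.state_label)
        if cls is None:
            continue
        bp = peak.interval.overlap(rec.interval)
        if bp:
            covered[cls] = covered.get(cls, 0) + bp
    if not covered:
        return None
    best_cls, best_bp = max(covered.items(), key=lambda kv: kv[1])
    fraction = best_bp / len(peak.interval)
    if fraction < threshold:
        return None
    return LabeledPeak(peak, best_cls, fraction, assign_split(peak.interval.chrom))


def assign_split(chrom: str) -> Optional[str]:
    """Chromosome-level split: validation {2, 10}, test {3, 11}, train for the
    remaining 18 autosomes; anything else (X, Y, M, scaffolds) excluded."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name in VALIDATION_CHROMS:
        return "validation"
    if name in TEST_CHROMS:
        return "test"
    if name in TRAIN_CHROMS:
        return "train"
    return None


def label_dataset(
    peaks: Sequence[Peak],
    segmentation: Sequence[SegmentationRecord],
    scheme,
    threshold: float = UNANIMITY_THRESHOLD,
    keep_unsplit: bool = False,
) -> list[LabeledPeak]:
    """Annotate every peak; drop peaks failing the unanimity filter and (by
    default) peaks on chromosomes outside the split tables."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    out = []
    for peak in peaks:
        lp = annotate_peak(peak, segmentation, scheme, threshold)
        if lp is None:
            continue
        if lp.split is None and not keep_unsplit:
            continue
        out.append(lp)
    return out


def augment_nonpeak_other(
    sample_other_peaks: Sequence[LabeledPeak],
    consensus_peaks: Sequence[Peak],
    sample_peak_set: Sequence[Peak],
    cap: float = NONPEAK_OTHER_CAP,
    seed: int = 0,
) -> list[LabeledPeak]:
    """Additional "other" examples from consensus regions absent from the
    sample's own peak calls.

    The number of augmented examples n is capped so that
    n / (len(sample_other_peaks) + n) <= cap, i.e. n <= P*cap/(1-cap) for P
    peak-derived examples.  Selection is a seeded uniform subsample.
    """
    if not (0.0 < cap <= 1.0):
        raise ValueError("cap must lie in (0, 1]")
    own = {
        (p.interval.chrom, p.interval.start, p.interval.end) for p in sample_peak_set
    }
    candidates = [
        p
        for p in consensus_peaks
        if (p.interval.chrom, p.interval.start, p.interval.end) not in own
    ]
    n_peak_derived = len(sample_other_peaks)
    if cap >= 1.0:
        n_max = len(candidates)
    else:
        n_max = int(np.floor(n_peak_derived * cap / (1.0 - cap)))
    n_take = min(n_max, len(candidates))
    if n_take <= 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_take, replace=False)
    return [
        LabeledPeak(
            candidates[i],
            FunctionalClass.OTHER,
            1.0,
            assign_split(candidates[i].interval.chrom),
            is_nonpeak_augmented=True,
        )
        for i in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# persistence: labeled datasets as BED6+
# ---------------------------------------------------------------------------

def write_labeled_bed(labeled: Sequence[LabeledPeak], path: str) -> None:
    """BED6+: chrom, start, end, name, overlap_fraction, strand ".", class, split."""
    with open(path, "w") as fh:
        for lp in labeled:
            iv = lp.peak.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lp.peak.name}\t"
                f"{lp.overlap_fraction:.4f}\t.\t{lp.label.value}\t{lp.split or '.'}\n"
            )


def read_labeled_bed(path: str) -> list[LabeledPeak]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}: labeled BED requires 8 columns")
            out.append(
                LabeledPeak(
                    Peak(GenomicInterval(f[0], int(f[1]), int(f[2])), f[3]),
                    FunctionalClass(f[6]),
                    float(f[4]),
                    None if f[7] == "." else f[7],
                )
            )
    return out
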