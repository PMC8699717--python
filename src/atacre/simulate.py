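"""Synthetic ATAC-seq study generator.

Emulates the qualitative structure a functional-annotation classifier
exploits: each cis-RE class has its own fragment-size mixture (sub- versus
mono-nucleosomal modes), positional focus (nucleosome-free-region width) and
accessibility amplitude; insulator loci carry a planted CTCF consensus in
the reference sequence; promoter loci register a TSS at their center; and a
chromatin-state segmentation consistent with the planted labels is emitted
alongside.  A genotyped-cohort generator plants allele-dosage effects on
accessibility for gain/loss recovery experiments.

All generators are pure functions of (config, seed).  Not modeled: GC bias,
mappability, chimeric fragments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    GenomicInterval,
    PairedFragment,
    Peak,
    ReferenceGenome,
    SegmentationRecord,
)
from .ground_truth import FunctionalClass, LabelScheme, get_scheme

# concrete CTCF consensus instance planted at insulator loci (an IUPAC-N-free
# instance of the CCGCGNGGNGGCAG consensus)
CTCF_INSTANCE = "CCGCGAGGTGGCAG"
TATA_INSTANCE = "TATAAA"

SEGMENT_GRID = 200  # chromatin-state segment granularity (bp)

# state vocabulary for synthetic segmentations; the custom scheme below adds
# a CTCF-insulator state that public 18-state references lack
SYNTH_STATE_MAP = {
    "1_TssA": FunctionalClass.PROMOTER,
    "9_EnhA1": FunctionalClass.ENHANCER,
    "Ins_CTCF": FunctionalClass.INSULATOR,
    "18_Quies": FunctionalClass.OTHER,
}
_CLASS_TO_STATE = {v: k for k, v in SYNTH_STATE_MAP.items()}


def synthetic_scheme() -> LabelScheme:
    return get_scheme("custom", SYNTH_STATE_MAP)


@dataclass(frozen=True)
class ArchetypeConfig:
    """Per-class simulation parameters.

    ``amplitude`` scales fragment depth; ``nfr_width`` is the SD (bp) of
    fragment centers around the locus center; the fragment-size mixture is a
    two-component lognormal (sub-nucleosomal mode near 85 bp, mono-nucleosomal
    near 205 bp) with ``sub_weight`` on the sub-nucleosomal mode.
    """

    amplitude: float
    nfr_width: float
    sub_weight: float
    sub_mean: float = 85.0
    sub_sigma: float = 0.25
    mono_mean: float = 205.0
    mono_sigma: float = 0.18
    peak_half_width: int = 250
    motif: Optional[str] = None
    has_tss: bool = False
    qval_range: tuple = (2.0, 8.0)  # -log10 q

    def __post_init__(self) -> None:
        if not (0.0 <= self.sub_weight <= 1.0):
            raise ValueError("sub_weight must lie in [0, 1]")
        if self.nfr_width <= 0 or self.amplitude <= 0:
            raise ValueError("widths and amplitudes must be positive")


DEFAULT_ARCHETYPES = {
    FunctionalClass.PROMOTER: ArchetypeConfig(
        amplitude=1.0, nfr_width=80.0, sub_weight=0.75,
        motif=TATA_INSTANCE, has_tss=True, qval_range=(20.0, 50.0),
    ),
    FunctionalClass.ENHANCER: ArchetypeConfig(
        amplitude=0.7, nfr_width=130.0, sub_weight=0.55, qval_range=(10.0, 30.0),
    ),
    FunctionalClass.INSULATOR: ArchetypeConfig(
        amplitude=0.55, nfr_width=100.0, sub_weight=0.62,
        motif=CTCF_INSTANCE, qval_range=(5.0, 20.0),
    ),
    FunctionalClass.OTHER: ArchetypeConfig(
        amplitude=0.3, nfr_width=260.0, sub_weight=0.25, qval_range=(2.0, 6.0),
    ),
}


# ---------------------------------------------------------------------------
# reference sequences
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must lie in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def write_fasta(sequences: dict, path: str, width: int = 60) -> str:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def gen_reference(
    seed: int, contig_lengths: dict, gc: float = 0.41, path: Optional[str] = None
) -> dict:
    """Seeded i.i.d. reference sequences with target GC; written to ``path``
    as FASTA when given."""
    rng = np.random.default_rng(seed)
    seqs = {
        name: random_sequence(rng, length, gc)
        for name, length in contig_lengths.items()
    }
    if path is not None:
        write_fasta(seqs, path)
    return seqs


# ---------------------------------------------------------------------------
# per-peak fragment sampling
# ---------------------------------------------------------------------------

def _sample_lengths(
    archetype: ArchetypeConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    sub = rng.random(n) < archetype.sub_weight
    mean = np.where(sub, archetype.sub_mean, archetype.mono_mean)
    sigma = np.where(sub, archetype.sub_sigma, archetype.mono_sigma)
    lengths = np.exp(rng.normal(np.log(mean), sigma))
    return np.clip(np.round(lengths), 25, 500).astype(int)


def gen_peak_fragments(
    archetype: ArchetypeConfig,
    locus: GenomicInterval,
    n_fragments: int,
    seed_or_rng,
) -> list[PairedFragment]:
    """Sample ``n_fragments`` fragments around the locus center from the
    archetype's positional and size distributions."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    center = (locus.start + locus.end) // 2
    centers = rng.normal(center, archetype.nfr_width, size=n_fragments)
    lengths = _sample_lengths(archetype, n_fragments, rng)
    starts = np.round(centers - lengths / 2).astype(int)
    starts = np.maximum(starts, 0)
    return [
        PairedFragment(GenomicInterval(locus.chrom, int(s), int(s + l)))
        for s, l in zip(starts, lengths)
    ]


# ---------------------------------------------------------------------------
# segmentations consistent with planted labels
# ---------------------------------------------------------------------------

def gen_segmentation(
    labeled_loci: Sequence[tuple],
    contig_lengths: dict,
    scheme_states: Optional[dict] = None,
) -> list[SegmentationRecord]:
    """Segmentation covering each (Peak, FunctionalClass) locus fully with a
    state mapping to its class, background filled with the quiescent state.
    Loci must be non-overlapping.  Segments snap to the 200 bp grid."""
    states = dict(scheme_states or _CLASS_TO_STATE)
    quies = states[FunctionalClass.OTHER]
    by_chrom: dict[str, list] = {}
    for peak, cls in labeled_loci:
        if cls not in states:
            raise ValueError(f"no segmentation state maps to class {cls}")
        by_chrom.setdefault(peak.interval.chrom, []).append((peak, cls))
    records: list[SegmentationRecord] = []
    for chrom, loci in sorted(by_chrom.items()):
        loci.sort(key=lambda pc: pc[0].interval.start)
        clen = contig_lengths[chrom]
        cursor = 0
        for peak, cls in loci:
            lo = (peak.interval.start // SEGMENT_GRID) * SEGMENT_GRID
            hi = -(-peak.interval.end // SEGMENT_GRID) * SEGMENT_GRID
            hi = min(hi, clen)
            if lo < cursor:
                raise ValueError(
                    f"overlapping loci on {chrom} near position {peak.interval.start}"
                )
            if lo > cursor:
                records.append(
                    SegmentationRecord(GenomicInterval(chrom, cursor, lo), quies)
                )
            records.append(
                SegmentationRecord(GenomicInterval(chrom, lo, hi), states[cls])
            )
            cursor = hi
        if cursor < clen:
            records.append(
                SegmentationRecord(GenomicInterval(chrom, cursor, clen), quies)
            )
    return records


def write_segmentation_bed(records: Sequence[SegmentationRecord], path: str) -> str:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.state_label}\n")
    return path


# ---------------------------------------------------------------------------
# the full 4-class study
# ---------------------------------------------------------------------------

TRAIN_CHROM_CYCLE = ("chr1", "chr4", "chr5", "chr6")
VAL_CHROM_CYCLE = ("chr2", "chr10")
TEST_CHROM_CYCLE = ("chr3", "chr11")

LOCUS_SPACING = 2000  # bp between planted locus centers


@dataclass
class SimulatedStudy:
    reference_path: str
    contig_lengths: dict
    peaks: list            # Peak, in generation order
    classes: list          # FunctionalClass per peak
    splits: list           # train/validation/test per peak
    fragments: list        # all PairedFragment
    tss_positions: dict    # chrom -> sorted np.array
    segmentation: list     # SegmentationRecord
    scheme: LabelScheme

    def reference(self) -> ReferenceGenome:
        return ReferenceGenome(self.reference_path)


def _plant(seq_list: list, pos: int, motif: str) -> None:
    for i, base in enumerate(motif):
        if 0 <= pos + i < len(seq_list):
            seq_list[pos + i] = base


def simulate_study(
    outdir: str,
    n_train: int = 2000,
    n_val: int = 400,
    n_test: int = 400,
    seed: int = 17,
    fragments_per_peak: float = 220.0,
    gc: float = 0.41,
    archetypes: Optional[dict] = None,
) -> SimulatedStudy:
    """Generate a full labeled 4-class study: reference FASTA, peaks with
    class-archetype fragments, TSS annotation, and a consistent
    segmentation.  Classes cycle evenly within each split."""
    archetypes = archetypes or DEFAULT_ARCHETYPES
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    classes_cycle = list(DEFAULT_ARCHETYPES.keys())

    plan: list[tuple] = []  # (split, chrom, class)
    for split, n, cycle in (
        ("train", n_train, TRAIN_CHROM_CYCLE),
        ("validation", n_val, VAL_CHROM_CYCLE),
        ("test", n_test, TEST_CHROM_CYCLE),
    ):
        for i in range(n):
            plan.append((split, cycle[i % len(cycle)], classes_cycle[i % 4]))

    # lay loci on each chromosome at fixed spacing
    per_chrom_count: dict[str, int] = {}
    placements = []
    for split, chrom, cls in plan:
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        center = 1500 + k * LOCUS_SPACING
        placements.append((split, chrom, cls, center))
    contig_lengths = {
        chrom: 1500 + count * LOCUS_SPACING + 1500
        for chrom, count in per_chrom_count.items()
    }

    sequences = {
        chrom: list(random_sequence(rng, length, gc))
        for chrom, length in contig_lengths.items()
    }

    peaks: list[Peak] = []
    classes: list[FunctionalClass] = []
    splits: list[str] = []
    fragments: list[PairedFragment] = []
    tss: dict[str, list] = {}

    for i, (split, chrom, cls, center) in enumerate(placements):
        arch = archetypes[cls]
        if arch.motif:
            _plant(sequences[chrom], center - len(arch.motif) // 2, arch.motif)
        if arch.has_tss:
            tss.setdefault(chrom, []).append(center)
        half = arch.peak_half_width + int(rng.integers(-40, 41))
        qlo, qhi = arch.qval_range
        peak = Peak(
            GenomicInterval(chrom, center - half, center + half),
            name=f"pk{i:05d}",
            neglog10_qval=float(rng.uniform(qlo, qhi)),
            summit_offset=half,
        )
        n_frags = int(rng.poisson(fragments_per_peak * arch.amplitude))
        fragments.extend(
            gen_peak_fragments(arch, peak.interval, n_frags, rng)
        )
        peaks.append(peak)
        classes.append(cls)
        splits.append(split)

    reference_path = os.path.join(outdir, "reference.fa")
    write_fasta({c: "".join(s) for c, s in sequences.items()}, reference_path)

    segmentation = gen_segmentation(
        list(zip(peaks, classes)), contig_lengths
    )
    return SimulatedStudy(
        reference_path=reference_path,
        contig_lengths=contig_lengths,
        peaks=peaks,
        classes=classes,
        splits=splits,
        fragments=fragments,
        tss_positions={c: np.array(sorted(v)) for c, v in tss.items()},
        segmentation=segmentation,
        scheme=synthetic_scheme(),
    )


def write_study(study: SimulatedStudy, outdir: str) -> dict:
    """Write a simulated study's plain-text artifacts; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": study.reference_path,
        "peaks": os.path.join(outdir, "peaks.narrowPeak"),
        "fragments": os.path.join(outdir, "fragments.bed"),
        "segmentation": os.path.join(outdir, "segmentation.bed"),
        "tss": os.path.join(outdir, "tss.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["peaks"], "w") as fh:
        for p in study.peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\t0\t0\t"
                f"{p.neglog10_qval:.3f}\t{p.summit_offset}\n"
            )
    with open(paths["fragments"], "w") as fh:
        for fr in study.fragments:
            iv = fr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\n")
    write_segmentation_bed(study.segmentation, paths["segmentation"])
    with open(paths["tss"], "w") as fh:
        for chrom in sorted(study.tss_positions):
            for pos in study.tss_positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("name\tclass\tsplit\n")
        for p, c, s in zip(study.peaks, study.classes, study.splits):
            fh.write(f"{p.name}\t{c.value}\t{s}\n")
    return paths


# ---------------------------------------------------------------------------
# SAM export (for alignment-mode round trips)
# ---------------------------------------------------------------------------

def fragments_to_sam(
    fragments: Sequence[PairedFragment],
    sequences: dict,
    path: str,
    snp: Optional[tuple] = None,
    alt_read_ids: Optional[set] = None,
) -> str:
    """Write fragments as properly-paired SAM records whose two mates tile
    each fragment exactly with reference bases (so alignment-mode encoding
    reproduces fragments-BED-mode encoding bit for bit).

    ``snp`` = (chrom, pos, alt_base) substitutes the alternative base into
    reads of fragments listed in ``alt_read_ids`` that cover the position.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)} for chrom, seq in sorted(sequences.items())
        ],
    }
    order = sorted(
        range(len(fragments)),
        key=lambda i: (fragments[i].interval.chrom, fragments[i].interval.start),
    )
    chrom_index = {c: k for k, c in enumerate(sorted(sequences))}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in order:
            fr = fragments[i]
            iv = fr.interval
            seq = sequences[iv.chrom]
            frag_seq = list(seq[iv.start : iv.end])
            if (
                snp is not None
                and alt_read_ids is not None
                and i in alt_read_ids
                and snp[0] == iv.chrom
                and iv.start <= snp[1] < iv.end
            ):
                frag_seq[snp[1] - iv.start] = snp[2]
            L = len(frag_seq)
            half = L // 2
            mates = (
                (iv.start, "".join(frag_seq[:half]), False),
                (iv.start + half, "".join(frag_seq[half:]), True),
            )
            for mate_no, (pos, mseq, is_r2) in enumerate(mates):
                if not mseq:
                    continue
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i:07d}"
                a.query_sequence = mseq
                # FR pair: read1 forward with reverse mate, read2 reverse
                a.flag = 0x1 | 0x2 | (0x80 | 0x10 if is_r2 else 0x40 | 0x20)
                a.reference_id = chrom_index[iv.chrom]
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{len(mseq)}M"
                a.next_reference_id = chrom_index[iv.chrom]
                a.next_reference_start = mates[1 - mate_no][0]
                a.template_length = L if not is_r2 else -L
                a.query_qualities = pysam.qualitystring_to_array("I" * len(mseq))
                if fr.is_duplicate:
                    a.flag |= 0x400
                out.write(a)
    return path


# ---------------------------------------------------------------------------
# genotyped cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort emulating a multi-sample caQTL study (defaults match
    a 19-sample islet-sized cohort): per-locus SNPs with the given allele
    frequency, an accessibility shift of ``effect_size`` population SDs per
    alternative allele in a planted direction, and Gaussian sample noise."""

    n_samples: int = 19
    n_loci: int = 100
    allele_freq: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 0.1
    baseline: float = 0.5
    mpra_effect: float = 1.0
    mpra_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not (0.0 < self.allele_freq < 1.0):
            raise ValueError("allele_freq must lie in (0, 1)")


@dataclass
class SimulatedCohort:
    genotypes: pd.DataFrame   # snp_id chrom start end sample genotype
    activity: pd.DataFrame    # snp_id sample activity
    truth: pd.DataFrame       # snp_id chrom start end direction mpra_logfc
    config: CohortConfig


_GT_NAMES = ("ref/ref", "ref/alt", "alt/alt")


def gen_genotyped_cohort(
    config: CohortConfig = CohortConfig(),
    loci: Optional[Sequence[GenomicInterval]] = None,
) -> SimulatedCohort:
    """Cohort with planted per-locus gain/loss directions.

    Per sample and locus, genotype dosage g ~ Binomial(2, allele_freq) and
    activity = baseline + direction * effect_size * noise_sd * g + noise,
    i.e. each alternative allele shifts activity by ``effect_size``
    population SDs in the planted direction.  A matched reporter-assay log
    fold change per locus is drawn around ``±mpra_effect``.
    """
    rng = np.random.default_rng(config.seed)
    if loci is None:
        loci = [
            GenomicInterval("chr1", 1000 + 2000 * i, 1600 + 2000 * i)
            for i in range(config.n_loci)
        ]
    samples = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    geno_rows, act_rows, truth_rows = [], [], []
    for i, locus in enumerate(loci):
        snp_id = f"snp{i:04d}"
        direction = 1 if rng.random() < 0.5 else -1
        # resample until at least two genotype groups are present
        while True:
            dosages = rng.binomial(2, config.allele_freq, size=config.n_samples)
            if len(np.unique(dosages)) >= 2:
                break
        noise = rng.normal(0.0, config.noise_sd, size=config.n_samples)
        activity = (
            config.baseline
            + direction * config.effect_size * config.noise_sd * dosages
            + noise
        )
        mpra = direction * config.mpra_effect + rng.normal(0.0, config.mpra_sd)
        for s, g, a in zip(samples, dosages, activity):
            geno_rows.append(
                (snp_id, locus.chrom, locus.start, locus.end, s, _GT_NAMES[g])
            )
            act_rows.append((snp_id, s, a))
        truth_rows.append(
            (snp_id, locus.chrom, locus.start, locus.end,
             "gain" if direction > 0 else "loss", mpra)
        )
    return SimulatedCohort(
        genotypes=pd.DataFrame(
            geno_rows,
            columns=["snp_id", "chrom", "start", "end", "sample", "genotype"],
        ),
        activity=pd.DataFrame(act_rows, columns=["snp_id", "sample", "activity"]),
        truth=pd.DataFrame(
            truth_rows,
            columns=["snp_id", "chrom", "start", "end", "direction", "mpra_logfc"],
        ),
        config=config,
    )


def cohort_fragments(
    cohort: SimulatedCohort,
    base_depth: int = 60,
    depth_shift: float = 0.25,
    archetype: Optional[ArchetypeConfig] = None,
) -> dict:
    """Per-sample fragment sets whose depth at each locus is shifted by
    genotype dosage in the planted direction (depth factor
    1 + depth_shift * direction * dosage)."""
    archetype = archetype or DEFAULT_ARCHETYPES[FunctionalClass.ENHANCER]
    rng = np.random.default_rng(cohort.config.seed + 1)
    truth = cohort.truth.set_index("snp_id")
    out: dict[str, list] = {s: [] for s in cohort.genotypes["sample"].unique()}
    for (snp_id, sample), grp in cohort.genotypes.groupby(["snp_id", "sample"]):
        row = grp.iloc[0]
        dosage = _GT_NAMES.index(row["genotype"])
        direction = 1 if truth.loc[snp_id, "direction"] == "gain" else -1
        factor = max(0.05, 1.0 + depth_shift * direction * dosage)
        n = int(rng.poisson(base_depth * factor))
        locus = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        out[sample].extend(gen_peak_fragments(archetype, locus, n, rng))
    return out


def write_cohort(cohort: SimulatedCohort, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.tsv"),
        "activity": os.path.join(outdir, "activity.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    cohort.genotypes.to_csv(paths["genotypes"], sep="\t", index=False)
    cohort.activity.to_csv(paths["activity"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
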