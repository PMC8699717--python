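"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention) everywhere inside the
package; 1-based formats (SAM POS) are converted at the boundary.  Supported
inputs: narrowPeak / BED peak calls, coordinate-sorted SAM/BAM paired-end
alignments or a plain fragments-BED dialect, indexed FASTA references, and
BED4 chromatin-state segmentations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam
from pyfaidx import Fasta

CLASS_NAMES = ("promoter", "enhancer", "insulator", "other")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class PairedFragment:
    """Full sequenced insert, 5'-most to 3'-most base."""

    interval: GenomicInterval
    is_duplicate: bool = False
    barcode: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    name: str = "."
    neglog10_qval: Optional[float] = None
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.neglog10_qval is not None and self.neglog10_qval < 0:
            raise ValueError("neglog10_qval must be >= 0 when present")


@dataclass(frozen=True)
class SegmentationRecord:
    interval: GenomicInterval
    state_label: str
    scheme: str = ""

    def __post_init__(self) -> None:
        if not self.state_label:
            raise ValueError("state_label must be non-empty")


@dataclass(frozen=True)
class PredictionRecord:
    """A peak plus its 4-class probability vector (promoter, enhancer,
    insulator, other) and the argmax label."""

    peak: Peak
    probs: tuple
    label: str = field(default="")

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if len(probs) != 4:
            raise ValueError("probs must have exactly 4 entries")
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1 +- 1e-6, got {sum(probs)}")
        if not self.label:
            object.__setattr__(
                self, "label", CLASS_NAMES[max(range(4), key=lambda i: probs[i])]
            )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def read_peaks(path: str, dialect: str = "narrowPeak") -> list[Peak]:
    """Read peak calls from ``path``.

    ``dialect`` is ``narrowPeak`` (10 columns; column 9 is the -log10 FDR
    q-value, column 10 the summit offset) or ``bed3+`` (q-value absent).
    Header/track/comment lines are skipped.
    """
    if dialect not in ("narrowPeak", "bed3+"):
        raise ValueError(f"unknown peak dialect: {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed peak line") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            qval = None
            summit = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns"
                    )
                qval = float(fields[8])
                s = int(fields[9])
                summit = s if s >= 0 else None
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), name, qval, summit)
            )
    return peaks


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def _fragments_from_alignments(
    path: str,
    region: Optional[GenomicInterval],
    keep_duplicates: bool,
) -> list[PairedFragment]:
    mode = "rb" if path.endswith(".bam") else "r"
    frags: list[PairedFragment] = []
    saw_read = False
    saw_paired = False
    with pysam.AlignmentFile(path, mode) as af:
        indexed = af.has_index()
        if region is not None and indexed:
            it = af.fetch(region.chrom, region.start, region.end)
        else:
            it = af.fetch() if indexed else af
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            saw_read = True
            if not read.is_paired or not read.is_proper_pair:
                continue
            saw_paired = True
            # count each pair once, from its leftmost (template-length > 0) mate
            if read.template_length <= 0:
                continue
            if read.is_duplicate and not keep_duplicates:
                continue
            start = read.reference_start
            end = start + read.template_length
            if region is not None and (
                read.reference_name != region.chrom
                or end <= region.start
                or start >= region.end
            ):
                continue
            bc = read.get_tag("CB") if read.has_tag("CB") else None
            frags.append(
                PairedFragment(
                    GenomicInterval(read.reference_name, start, end),
                    is_duplicate=read.is_duplicate,
                    barcode=bc,
                )
            )
    if saw_read and not saw_paired:
        raise ValueError(
            f"{path}: no properly-paired reads found; for single-end or "
            "pre-computed inserts supply a fragments BED instead"
        )
    return frags


def _fragments_from_bed(
    path: str,
    region: Optional[GenomicInterval],
    keep_duplicates: bool,
) -> list[PairedFragment]:
    frags: list[PairedFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed fragment line") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            barcode = fields[3] if len(fields) > 3 and fields[3] != "." else None
            dup = len(fields) > 4 and fields[4] in ("1", "dup", "True", "true")
            if dup and not keep_duplicates:
                continue
            if region is not None and (
                chrom != region.chrom or end <= region.start or start >= region.end
            ):
                continue
            frags.append(
                PairedFragment(GenomicInterval(chrom, start, end), dup, barcode)
            )
    return frags


def read_fragments(
    path: str,
    region: Optional[GenomicInterval] = None,
    keep_duplicates: bool = False,
) -> list[PairedFragment]:
    """Read paired-end fragments from SAM/BAM or a fragments-BED file.

    One fragment per properly-paired read pair, spanning leftmost mate start
    to rightmost mate end.  Secondary/supplementary/unmapped records are
    excluded; duplicates are excluded unless ``keep_duplicates`` (duplicates
    are kept only for pseudo-bulk single-nucleus analyses).
    """
    if path.endswith((".bam", ".sam", ".cram")):
        if path.endswith(".bam") and region is not None:
            if not (os.path.exists(path + ".bai") or os.path.exists(path + ".csi")):
                raise FileNotFoundError(
                    f"{path}: BAM index (.bai) required for region queries"
                )
        return _fragments_from_alignments(path, region, keep_duplicates)
    return _fragments_from_bed(path, region, keep_duplicates)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Thin uppercase window accessor over an indexed FASTA.

    A personalized (consensus) genome is supported by simply pointing this at
    the individual-specific FASTA.
    """

    def __init__(self, path: str):
        self._fasta = Fasta(path, sequence_always_upper=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def window(self, interval: GenomicInterval) -> str:
        return read_reference_window(self._fasta, interval)

    def close(self) -> None:
        self._fasta.close()


def read_reference_window(fasta, interval: GenomicInterval) -> str:
    """Uppercase sequence of exactly ``len(interval)`` bases; positions beyond
    the contig are padded with ``N``."""
    if isinstance(fasta, str):
        fasta = Fasta(fasta, sequence_always_upper=True)
    if interval.chrom not in fasta:
        raise KeyError(f"contig {interval.chrom!r} not in reference")
    contig = fasta[interval.chrom]
    clen = len(contig)
    lo = max(0, interval.start)
    hi = min(clen, interval.end)
    core = str(contig[lo:hi]).upper() if hi > lo else ""
    left = "N" * (lo - interval.start)
    right = "N" * (interval.end - max(hi, interval.start))
    seq = left + core + right
    assert len(seq) == len(interval)
    return seq


# ---------------------------------------------------------------------------
# segmentations
# ---------------------------------------------------------------------------

def read_segmentation(path: str, scheme: str = "") -> list[SegmentationRecord]:
    """Read a BED4+ chromatin-state segmentation (state label in column 4).

    Output is sorted by (chrom, start); overlapping records within a
    chromosome are an error because a segmentation assigns one state per
    genomic position.
    """
    records: list[SegmentationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 requires 4 columns")
            chrom, start, end, state = fields[0], int(fields[1]), int(fields[2]), fields[3]
            records.append(
                SegmentationRecord(GenomicInterval(chrom, start, end), state, scheme)
            )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    prev: Optional[SegmentationRecord] = None
    for rec in records:
        if (
            prev is not None
            and rec.interval.chrom == prev.interval.chrom
            and rec.interval.start < prev.interval.end
        ):
            raise ValueError(
                f"{path}: overlapping segmentation records at "
                f"{rec.interval.chrom}:{rec.interval.start}"
            )
        prev = rec
    return records


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

_PRED_HEADER = [
    "chrom", "start", "end", "name",
    "prob_promoter", "prob_enhancer", "prob_insulator", "prob_other", "label",
]


def write_predictions(records: Sequence[PredictionRecord], path: str) -> None:
    """Write prediction records as a TSV (probabilities with 6 decimals)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PRED_HEADER) + "\n")
        for rec in records:
            iv = rec.peak.interval
            probs = "\t".join(f"{p:.6f}" for p in rec.probs)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.peak.name}\t{probs}\t{rec.label}\n")


def read_predictions(path: str) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PRED_HEADER:
            raise ValueError(f"{path}: unexpected predictions header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            probs = tuple(float(x) for x in f[4:8])
            total = sum(probs)
            # renormalize print-precision rounding only; larger drift is an error
            if abs(total - 1.0) > 1e-4:
                raise ValueError(f"{path}: probabilities sum to {total}")
            probs = tuple(p / total for p in probs)
            records.append(
                PredictionRecord(
                    Peak(GenomicInterval(f[0], int(f[1]), int(f[2])), f[3]),
                    probs,
                    f[8],
                )
            )
    return records
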