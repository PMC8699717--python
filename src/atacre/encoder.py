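"""Per-peak 10x600 signal/sequence encoding.

Each ATAC-seq peak is summarized over a fixed window centered on the peak
(300 bp up/downstream of the peak center) as a 10-row matrix:

  rows 1-4   frequency of A/C/G/T among aligned read base calls, falling back
             to a one-hot encoding of the reference base where read coverage
             is below ``min_depth`` (this makes the encoding genotype-aware:
             a SNP carried by the reads shifts the base frequencies away from
             the reference)
  row 5      insert (fragment-span) pileup
  rows 6-7   number of 5' / 3' transposase cuts per position, Savitzky-Golay
             smoothed (window 15)
  rows 8-9   median fragment length at each 5' / 3' cut position, smoothed
             the same way
  row 10     binary indicator of the original peak region

Rows 5-9 are z-standardized per column across all peaks of a dataset
(two-pass: raw tracks first, then dataset-level standardization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .genomic_io import (
    GenomicInterval,
    PairedFragment,
    Peak,
    ReferenceGenome,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SIGNAL_TRACKS = ("insert", "cut5", "cut3", "len5", "len3")


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable encoder parameters.

    ``tn5_shift`` is the (+forward, -reverse) cut-site offset; the default
    (0, 0) applies no shift, so cut positions are the raw fragment ends.
    """

    window_len: int = 600
    half_window: int = 300
    min_depth: int = 10
    smooth_window: int = 15
    smooth_polyorder: int = 3
    tn5_shift: tuple = (0, 0)
    zero_variance_value: float = 0.0

    def __post_init__(self) -> None:
        if self.window_len != 2 * self.half_window:
            raise ValueError("window_len must equal 2 * half_window")
        if self.smooth_window % 2 != 1:
            raise ValueError("smooth_window must be odd")
        if self.smooth_polyorder >= self.smooth_window:
            raise ValueError("smooth_polyorder must be < smooth_window")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class RawPeakTracks:
    """Pre-standardization tracks for one peak."""

    seq_freq: np.ndarray      # (4, L)
    insert_raw: np.ndarray    # (L,)
    cut5_raw: np.ndarray      # (L,) smoothed
    cut3_raw: np.ndarray      # (L,) smoothed
    len5_raw: np.ndarray      # (L,) smoothed
    len3_raw: np.ndarray      # (L,) smoothed
    indicator: np.ndarray     # (L,)

    def signal_stack(self) -> np.ndarray:
        return np.stack(
            [self.insert_raw, self.cut5_raw, self.cut3_raw, self.len5_raw, self.len3_raw]
        )


@dataclass
class EncodingStats:
    """Per-track per-column moments fitted across all peaks of a dataset."""

    mean: np.ndarray  # (5, L)
    std: np.ndarray   # (5, L), population std
    zero_variance_value: float = 0.0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "zero_variance_value": self.zero_variance_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingStats":
        return cls(
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["std"], dtype=float),
            float(d.get("zero_variance_value", 0.0)),
        )


@dataclass
class PeakEncoding:
    matrix: np.ndarray  # (10, L)
    peak: Peak


# ---------------------------------------------------------------------------
# fragment sources
# ---------------------------------------------------------------------------

class FragmentSource(Protocol):
    def fragments(self, interval: GenomicInterval) -> list[PairedFragment]: ...
    def base_call_counts(
        self, interval: GenomicInterval, reference_window: str
    ) -> np.ndarray: ...


class ListFragmentSource:
    """Fragments held in memory (e.g. loaded from a fragments BED).

    Without read sequences, base calls are taken as the reference base under
    each fragment span, so the base-call pileup equals span coverage split by
    the reference sequence.
    """

    def __init__(self, fragments: Sequence[PairedFragment]):
        self._by_chrom: dict[str, list[PairedFragment]] = {}
        for fr in fragments:
            self._by_chrom.setdefault(fr.interval.chrom, []).append(fr)
        for frs in self._by_chrom.values():
            frs.sort(key=lambda f: f.interval.start)

    def fragments(self, interval: GenomicInterval) -> list[PairedFragment]:
        out = []
        for fr in self._by_chrom.get(interval.chrom, []):
            if fr.interval.start < interval.end and fr.interval.end > interval.start:
                out.append(fr)
        return out

    def base_call_counts(
        self, interval: GenomicInterval, reference_window: str
    ) -> np.ndarray:
        cov = insert_pileup_row(self.fragments(interval), interval)
        counts = np.zeros((4, len(interval)), dtype=float)
        for p, base in enumerate(reference_window):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[idx, p] = cov[p]
        return counts


class AlignmentFragmentSource:
    """Fragments and base calls drawn from a SAM/BAM alignment file.

    Base calls are read bases at aligned match positions (A/C/G/T only;
    indels, skips and N calls are excluded from the depth used for the
    ``min_depth`` test).
    """

    def __init__(self, path: str, keep_duplicates: bool = False):
        self.path = path
        self.keep_duplicates = keep_duplicates

    def _open(self):
        import pysam

        mode = "rb" if self.path.endswith(".bam") else "r"
        return pysam.AlignmentFile(self.path, mode)

    def _reads(self, af, interval: GenomicInterval):
        if af.has_index():
            it = af.fetch(interval.chrom, max(0, interval.start), interval.end)
        else:
            it = af  # plain SAM: stream the whole (small) file
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or not read.is_proper_pair:
                continue
            if read.is_duplicate and not self.keep_duplicates:
                continue
            yield read

    def fragments(self, interval: GenomicInterval) -> list[PairedFragment]:
        from .genomic_io import read_fragments

        # fetch a widened region so fragments whose leftmost mate lies outside
        # the window but whose span overlaps it are not missed
        pad = 2000
        wide = GenomicInterval(
            interval.chrom, max(0, interval.start - pad), interval.end + pad
        )
        frs = read_fragments(self.path, wide, self.keep_duplicates)
        return [
            fr
            for fr in frs
            if fr.interval.start < interval.end and fr.interval.end > interval.start
        ]

    def base_call_counts(
        self, interval: GenomicInterval, reference_window: str
    ) -> np.ndarray:
        counts = np.zeros((4, len(interval)), dtype=float)
        with self._open() as af:
            for read in self._reads(af, interval):
                if read.reference_name != interval.chrom:
                    continue
                seq = read.query_sequence
                if seq is None:
                    continue
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos < interval.start or rpos >= interval.end:
                        continue
                    idx = _BASE_INDEX.get(seq[qpos].upper())
                    if idx is not None:
                        counts[idx, rpos - interval.start] += 1
        return counts


# ---------------------------------------------------------------------------
# per-peak track construction
# ---------------------------------------------------------------------------

def peak_window(peak: Peak, config: EncoderConfig = EncoderConfig()) -> GenomicInterval:
    """Fixed-length window centered on the peak center c = floor((start+end)/2)."""
    c = (peak.interval.start + peak.interval.end) // 2
    start = c - config.half_window
    end = c + config.half_window
    # negative starts are representable downstream via N-padding; clamp the
    # interval to 0 is wrong (length must stay window_len), so we allow the
    # raw coordinates and handle padding in the reference accessor
    if start < 0:
        # shift bookkeeping: we keep a virtual interval via offset handling
        return _VirtualInterval(peak.interval.chrom, start, end)
    return GenomicInterval(peak.interval.chrom, start, end)


class _VirtualInterval(GenomicInterval):
    """Interval allowed to start before the contig (start < 0)."""

    def __init__(self, chrom: str, start: int, end: int):
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    def __post_init__(self) -> None:  # pragma: no cover
        pass


def sequence_frequency_rows(
    base_call_counts: np.ndarray,
    reference_window: str,
    config: EncoderConfig = EncoderConfig(),
) -> np.ndarray:
    """Rows 1-4: per-position A/C/G/T frequency among base calls where depth
    >= ``min_depth``; one-hot of the reference base otherwise (all-zero
    column when the reference base is N)."""
    L = len(reference_window)
    if base_call_counts.shape != (4, L):
        raise ValueError("base_call_counts must be 4 x window length")
    out = np.zeros((4, L), dtype=float)
    depth = base_call_counts.sum(axis=0)
    deep = depth >= config.min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, base_call_counts / np.maximum(depth, 1), 0.0)
    out[:, deep] = freq[:, deep]
    for p in np.nonzero(~deep)[0]:
        idx = _BASE_INDEX.get(reference_window[p])
        if idx is not None:
            out[idx, p] = 1.0
    return out


def insert_pileup_row(
    fragments: Sequence[PairedFragment], window: GenomicInterval
) -> np.ndarray:
    """Row 5 (raw): number of fragments spanning each window position."""
    L = len(window)
    delta = np.zeros(L + 1, dtype=float)
    for fr in fragments:
        s = max(fr.interval.start, window.start) - window.start
        e = min(fr.interval.end, window.end) - window.start
        if e > s:
            delta[s] += 1
            delta[e] -= 1
    return np.cumsum(delta[:-1])


def _cut_positions(
    fragments: Sequence[PairedFragment], config: EncoderConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts = np.array([fr.interval.start for fr in fragments], dtype=int)
    ends = np.array([fr.interval.end for fr in fragments], dtype=int)
    lengths = ends - starts
    cut5 = starts + config.tn5_shift[0]
    cut3 = ends - 1 + config.tn5_shift[1]
    return cut5, cut3, lengths


def cut_count_rows(
    fragments: Sequence[PairedFragment],
    window: GenomicInterval,
    config: EncoderConfig = EncoderConfig(),
    smooth: bool = True,
) -> np.ndarray:
    """Rows 6-7: 5' and 3' cut counts per position (smoothed by default)."""
    L = len(window)
    rows = np.zeros((2, L), dtype=float)
    if fragments:
        cut5, cut3, _ = _cut_positions(fragments, config)
        for row, cuts in zip(rows, (cut5, cut3)):
            rel = cuts - window.start
            rel = rel[(rel >= 0) & (rel < L)]
            np.add.at(row, rel, 1.0)
    if smooth:
        rows = np.stack([smooth_track(r, config) for r in rows])
    return rows


def fragment_length_rows(
    fragments: Sequence[PairedFragment],
    window: GenomicInterval,
    config: EncoderConfig = EncoderConfig(),
    smooth: bool = True,
) -> np.ndarray:
    """Rows 8-9: median fragment length at each 5' / 3' cut position
    (0 where no cuts), smoothed by default."""
    L = len(window)
    rows = np.zeros((2, L), dtype=float)
    if fragments:
        cut5, cut3, lengths = _cut_positions(fragments, config)
        for row, cuts in zip(rows, (cut5, cut3)):
            rel = cuts - window.start
            keep = (rel >= 0) & (rel < L)
            rel_k, len_k = rel[keep], lengths[keep]
            order = np.argsort(rel_k, kind="stable")
            rel_k, len_k = rel_k[order], len_k[order]
            starts = np.flatnonzero(np.r_[True, np.diff(rel_k) > 0])
            bounds = np.r_[starts, len(rel_k)]
            for i, s in enumerate(starts):
                p = rel_k[s]
                row[p] = np.median(len_k[s : bounds[i + 1]])
    if smooth:
        rows = np.stack([smooth_track(r, config) for r in rows])
    return rows


def smooth_track(track: np.ndarray, config: EncoderConfig = EncoderConfig()) -> np.ndarray:
    """Savitzky-Golay smoothing (least-squares local polynomial fit); edges
    are evaluated from the polynomial fitted to the terminal window."""
    track = np.asarray(track, dtype=float)
    if track.shape[-1] < config.smooth_window:
        raise ValueError(
            f"track length {track.shape[-1]} shorter than smoothing window "
            f"{config.smooth_window}"
        )
    return savgol_filter(
        track, config.smooth_window, config.smooth_polyorder, mode="interp"
    )


def peak_indicator_row(peak: Peak, window: GenomicInterval) -> np.ndarray:
    """Row 10: 1 where the window position falls inside the original peak."""
    L = len(window)
    pos = np.arange(window.start, window.end)
    return ((pos >= peak.interval.start) & (pos < peak.interval.end)).astype(float)


def encode_peak_raw(
    peak: Peak,
    source: FragmentSource,
    reference: ReferenceGenome,
    config: EncoderConfig = EncoderConfig(),
) -> RawPeakTracks:
    window = peak_window(peak, config)
    ref_window = reference.window(window)
    frags = source.fragments(window)
    counts = source.base_call_counts(window, ref_window)
    return RawPeakTracks(
        seq_freq=sequence_frequency_rows(counts, ref_window, config),
        insert_raw=insert_pileup_row(frags, window),
        cut5_raw=cut_count_rows(frags, window, config)[0],
        cut3_raw=cut_count_rows(frags, window, config)[1],
        len5_raw=fragment_length_rows(frags, window, config)[0],
        len3_raw=fragment_length_rows(frags, window, config)[1],
        indicator=peak_indicator_row(peak, window),
    )


# ---------------------------------------------------------------------------
# dataset-level standardization (second pass)
# ---------------------------------------------------------------------------

def fit_stats(
    raw_tracks: Sequence[RawPeakTracks], config: EncoderConfig = EncoderConfig()
) -> EncodingStats:
    if not raw_tracks:
        raise ValueError("at least one peak required to fit standardization stats")
    stack = np.stack([rt.signal_stack() for rt in raw_tracks])  # (n, 5, L)
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)  # population std
    return EncodingStats(mean, std, config.zero_variance_value)


def apply_stats(raw: RawPeakTracks, stats: EncodingStats) -> np.ndarray:
    """Assemble the standardized 10 x L matrix for one peak."""
    signal = raw.signal_stack()
    std = stats.std
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (signal - stats.mean) / np.where(std > 0, std, 1.0)
    z = np.where(std > 0, z, stats.zero_variance_value)
    return np.vstack([raw.seq_freq, z, raw.indicator[None, :]])


def standardize_dataset(
    raw_tracks: Sequence[RawPeakTracks], config: EncoderConfig = EncoderConfig()
) -> tuple[EncodingStats, list[np.ndarray]]:
    stats = fit_stats(raw_tracks, config)
    return stats, [apply_stats(rt, stats) for rt in raw_tracks]


def encode_dataset(
    peaks: Sequence[Peak],
    source: FragmentSource,
    reference: ReferenceGenome,
    config: EncoderConfig = EncoderConfig(),
    stats: Optional[EncodingStats] = None,
) -> tuple[list[PeakEncoding], EncodingStats]:
    """Two-pass encoding: per-peak raw tracks, then column standardization
    across all peaks.  Pass ``stats`` to reuse moments fitted on another
    dataset (e.g. at predict time with a trained model's stored stats)."""
    raw = [encode_peak_raw(p, source, reference, config) for p in peaks]
    if stats is None:
        stats = fit_stats(raw, config)
    encodings = [PeakEncoding(apply_stats(rt, stats), p) for rt, p in zip(raw, peaks)]
    return encodings, stats


# ---------------------------------------------------------------------------
# persistence: binary array container + sidecar JSON manifest
# ---------------------------------------------------------------------------

def save_encoded_dataset(
    path_prefix: str,
    encodings: Sequence[PeakEncoding],
    stats: EncodingStats,
    config: EncoderConfig,
) -> None:
    mats = np.stack([e.matrix for e in encodings])
    np.savez_compressed(path_prefix + ".npz", matrices=mats)
    manifest = {
        "peaks": [
            {
                "chrom": e.peak.interval.chrom,
                "start": e.peak.interval.start,
                "end": e.peak.interval.end,
                "name": e.peak.name,
                "neglog10_qval": e.peak.neglog10_qval,
            }
            for e in encodings
        ],
        "config": asdict(config),
        "stats": stats.to_dict(),
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(manifest, fh)


def load_encoded_dataset(
    path_prefix: str,
) -> tuple[list[PeakEncoding], EncodingStats, EncoderConfig]:
    mats = np.load(path_prefix + ".npz")["matrices"]
    with open(path_prefix + ".json") as fh:
        manifest = json.load(fh)
    cfg_d = manifest["config"]
    cfg_d["tn5_shift"] = tuple(cfg_d["tn5_shift"])
    config = EncoderConfig(**cfg_d)
    stats = EncodingStats.from_dict(manifest["stats"])
    encodings = []
    for mat, pd in zip(mats, manifest["peaks"]):
        peak = Peak(
            GenomicInterval(pd["chrom"], pd["start"], pd["end"]),
            pd["name"],
            pd["neglog10_qval"],
        )
        encodings.append(PeakEncoding(mat, peak))
    return encodings, stats, config


def dump_tsv(encodings: Sequence[PeakEncoding], path: str) -> None:
    """Plain-text dump: one 10-row block per peak, for inspection."""
    with open(path, "w") as fh:
        for e in encodings:
            fh.write(f"# {e.peak.name}\t{e.peak.interval.chrom}:"
                     f"{e.peak.interval.start}-{e.peak.interval.end}\n")
            for row in e.matrix:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
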