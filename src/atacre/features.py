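"""Auxiliary per-peak feature vector for the second classifier branch.

Nineteen summary features per peak, drawn from the families that naive
annotation also relies on (distance to nearest TSS, peak-caller FDR, CTCF
motif content) plus insert-size, cut-site, sequence-composition and
conservation statistics.  The length-19 contract is fixed; membership is
configurable through :class:`FeatureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genomic_io import GenomicInterval, PairedFragment, Peak

# JASPAR-style CTCF core consensus as an IUPAC string (configurable)
CTCF_CONSENSUS = "CCGCGNGGNGGCAG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FEATURE_NAMES = (
    "tss_distance",
    "peak_length",
    "neglog10_qval",
    "fragment_count",
    "mean_insert_size",
    "sd_insert_size",
    "frac_subnucleosomal",
    "frac_mononucleosomal",
    "cut_asymmetry",
    "gc_fraction",
    "cpg_count",
    "ctcf_motif_count",
    "motif_count_1",
    "motif_count_2",
    "motif_count_3",
    "motif_count_4",
    "mean_conservation",
    "summit_offset_fraction",
    "duplicate_fraction",
)

# sub-nucleosomal / mono-nucleosomal fragment-length boundaries (bp)
NUCLEOSOME_BP = 147

_DEFAULT_EXTRA_MOTIFS = ("TATAWAW", "GGGCGG", "CACGTG", "TGASTCA")


@dataclass
class FeatureConfig:
    """Annotation inputs for feature extraction.

    ``tss_positions`` maps chrom -> sorted array of TSS coordinates;
    ``conservation`` (optional) maps chrom -> per-base score array.
    """

    tss_positions: dict = field(default_factory=dict)
    ctcf_motif: str = CTCF_CONSENSUS
    extra_motifs: tuple = _DEFAULT_EXTRA_MOTIFS
    conservation: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.ctcf_motif:
            raise ValueError("a CTCF motif is required")
        if len(self.extra_motifs) != 4:
            raise ValueError("exactly 4 additional motifs are required")


def load_tss_bed(path: str) -> dict:
    """Read TSS positions from a BED file (the start of each record)."""
    tss: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            tss.setdefault(f[0], []).append(int(f[1]))
    return {c: np.array(sorted(v)) for c, v in tss.items()}


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _matches_at(sequence: str, pos: int, motif: str) -> bool:
    for j, code in enumerate(motif):
        base = sequence[pos + j]
        if base == "N" or base not in IUPAC.get(code, ""):
            return False
    return True


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def count_motif_occurrences(sequence: str, motif: str) -> int:
    """Number of IUPAC-consensus match positions on the forward plus
    reverse-complement strands.  Overlapping matches count; sequence ``N``
    never matches.  Palindromic motifs are counted once per position."""
    sequence = sequence.upper()
    motif = motif.upper()
    m = len(motif)
    if m == 0 or len(sequence) < m:
        return 0
    rc = reverse_complement(motif)
    count = 0
    for p in range(len(sequence) - m + 1):
        if _matches_at(sequence, p, motif):
            count += 1
        elif rc != motif and _matches_at(sequence, p, rc):
            count += 1
    return count


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _signed_tss_distance(center: int, chrom: str, config: FeatureConfig) -> float:
    positions = config.tss_positions.get(chrom)
    if positions is None or len(positions) == 0:
        return 1e6  # documented neutral value: "far from any TSS"
    i = int(np.searchsorted(positions, center))
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            d = center - int(positions[j])
            if best is None or abs(d) < abs(best):
                best = d
    return float(best)


def extract_features(
    peak: Peak,
    fragments: Sequence[PairedFragment],
    reference_window: str,
    config: FeatureConfig,
) -> np.ndarray:
    """Deterministic 19-vector for one peak.

    ``fragments`` are the fragments overlapping the peak's encoding window and
    ``reference_window`` is the window sequence.  Missing optional annotations
    map to neutral values (conservation 0, q-value 0), never to a shorter
    vector.
    """
    iv = peak.interval
    center = (iv.start + iv.end) // 2
    lengths = np.array([fr.length for fr in fragments], dtype=float)
    n = len(lengths)

    cut5_in = sum(1 for fr in fragments if iv.start <= fr.interval.start < iv.end)
    cut3_in = sum(1 for fr in fragments if iv.start <= fr.interval.end - 1 < iv.end)
    asym = (cut5_in - cut3_in) / (cut5_in + cut3_in) if (cut5_in + cut3_in) else 0.0

    seq = reference_window.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
    cpg = seq.count("CG")

    if config.conservation is not None and iv.chrom in config.conservation:
        track = config.conservation[iv.chrom]
        lo, hi = max(0, iv.start), min(len(track), iv.end)
        cons = float(np.mean(track[lo:hi])) if hi > lo else 0.0
    else:
        cons = 0.0

    if peak.summit_offset is not None and len(iv) > 0:
        summit_frac = peak.summit_offset / len(iv)
    else:
        summit_frac = 0.5  # neutral: summit assumed central

    dup = sum(1 for fr in fragments if fr.is_duplicate)

    values = np.array(
        [
            _signed_tss_distance(center, iv.chrom, config),
            float(len(iv)),
            float(peak.neglog10_qval) if peak.neglog10_qval is not None else 0.0,
            float(n),
            float(np.mean(lengths)) if n else 0.0,
            float(np.std(lengths)) if n else 0.0,
            float(np.mean(lengths < NUCLEOSOME_BP)) if n else 0.0,
            float(np.mean((lengths >= NUCLEOSOME_BP) & (lengths < 2 * NUCLEOSOME_BP)))
            if n
            else 0.0,
            float(asym),
            float(gc),
            float(cpg),
            float(count_motif_occurrences(seq, config.ctcf_motif)),
            *(
                float(count_motif_occurrences(seq, m))
                for m in config.extra_motifs
            ),
            cons,
            float(summit_frac),
            dup / n if n else 0.0,
        ],
        dtype=float,
    )
    assert values.shape == (19,)
    return values


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class FeatureStats:
    mean: np.ndarray
    std: np.ndarray

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        z = (matrix - self.mean) / np.where(self.std > 0, self.std, 1.0)
        return np.where(self.std > 0, z, 0.0)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStats":
        return cls(np.asarray(d["mean"], dtype=float), np.asarray(d["std"], dtype=float))


def standardize_features(matrix: np.ndarray) -> tuple[FeatureStats, np.ndarray]:
    """Per-feature z-scoring (population std); zero-variance features map to
    0.  The fitted stats are reused verbatim at predict time."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("feature matrix must be 2-D with >= 1 row")
    stats = FeatureStats(matrix.mean(axis=0), matrix.std(axis=0))
    return stats, stats.apply(matrix)


def write_feature_tsv(matrix: np.ndarray, names: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for row in np.asarray(matrix):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
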