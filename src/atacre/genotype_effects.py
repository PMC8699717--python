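"""Genotype-modulated gain/loss of cis-regulatory activity.

For each locus with per-sample genotypes (ref/ref, ref/alt, alt/alt) and a
per-sample activity score — the sum of promoter and enhancer prediction
probabilities — a one-tailed point-biserial correlation screens for activity
that tracks alternative-allele dosage.  All present genotype-group pairs are
compared (the higher-dosage group coded 1) and the pairing with the maximum
|r| is kept; significant loci (p < 0.01) split into loss (r < 0) and gain
(r > 0) of activity in the alternative allele.  Reporter-assay (MPRA)
concordance is assessed with one-sided one-sample t-tests per group (loss:
mean log fold change < 0; gain: > 0) and a two-sided Mann-Whitney U between
the groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval

GENOTYPES = ("ref/ref", "ref/alt", "alt/alt")
_DOSAGE = {"ref/ref": 0, "ref/alt": 1, "alt/alt": 2}

DEFAULT_ALPHA = 0.01


@dataclass
class GenotypeSeries:
    """Per-sample genotypes and activity scores at one locus."""

    locus: GenomicInterval
    snp_id: str
    genotypes: Sequence[str]
    scores: Sequence[float]

    def __post_init__(self) -> None:
        self.genotypes = list(self.genotypes)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genotypes) != len(self.scores):
            raise ValueError("genotypes and scores must be aligned")
        bad = set(self.genotypes) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class EffectCall:
    locus: GenomicInterval
    snp_id: str
    r: float
    p: float
    direction: str  # loss / gain / none
    pairing: tuple  # (low-dosage group, high-dosage group)


def activity_score(probs: Sequence[float]) -> float:
    """Sum of promoter and enhancer probabilities from a 4-class vector."""
    return float(probs[0]) + float(probs[1])


def point_biserial(grouping: Sequence[int], scores: Sequence[float]) -> tuple[float, float]:
    """Point-biserial correlation of scores against a 0/1 grouping.

    r is the Pearson correlation with the dummy coding; the one-tailed p
    tests the group-1 mean being larger (upper tail of the t transform
    t = r*sqrt((n-2)/(1-r^2)) with n-2 df).  Swapping the coding flips the
    sign of r and mirrors p -> 1-p.  Constant scores give r = 0, p = 0.5.
    """
    g = np.asarray(grouping, dtype=float)
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n != len(g):
        raise ValueError("grouping and scores must be aligned")
    if n < 3:
        raise ValueError("at least 3 samples required")
    if not (g == 0).any() or not (g == 1).any():
        raise ValueError("both groups must be non-empty")
    sx = x.std()
    sg = g.std()
    if sx == 0 or sg == 0:
        return 0.0, 0.5
    r = float(np.mean((x - x.mean()) * (g - g.mean())) / (sx * sg))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(stats.t.sf(t, df=n - 2))
    return r, p


def max_genotype_correlation(
    series: GenotypeSeries,
) -> tuple[float, float, tuple]:
    """Point-biserial over every present genotype-group pair, coding the
    higher-alt-dosage group 1; returns (r, one-tailed p in the direction of
    r, pairing) for the pairing with maximum |r| (ties broken by larger
    combined n)."""
    present = [gt for gt in GENOTYPES if gt in series.genotypes]
    if len(present) < 2:
        raise ValueError("at least 2 genotype groups required")
    scores = np.asarray(series.scores)
    gts = np.asarray(series.genotypes)
    best = None
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            low, high = present[i], present[j]  # GENOTYPES is dosage-ordered
            mask = (gts == low) | (gts == high)
            if mask.sum() < 3:  # pairing too small for the t transform
                continue
            coding = (gts[mask] == high).astype(int)
            r, p_upper = point_biserial(coding, scores[mask])
            p_directional = min(p_upper, 1.0 - p_upper)
            n_pair = int(mask.sum())
            key = (abs(r), n_pair)
            if best is None or key > best[0]:
                best = (key, (r, p_directional, (low, high)))
    if best is None:
        raise ValueError("no genotype pairing has enough samples to test")
    return best[1]


def classify_gain_loss(r: float, p: float, alpha: float = DEFAULT_ALPHA) -> str:
    """loss if p < alpha and r < 0; gain if p < alpha and r > 0; else none."""
    if p < alpha and r < 0:
        return "loss"
    if p < alpha and r > 0:
        return "gain"
    return "none"


def call_effects(
    series_list: Sequence[GenotypeSeries], alpha: float = DEFAULT_ALPHA
) -> list[EffectCall]:
    """Effect calls for every testable locus; loci with no genotype pairing
    large enough to test are skipped."""
    calls = []
    for series in series_list:
        try:
            r, p, pairing = max_genotype_correlation(series)
        except ValueError:
            continue
        calls.append(
            EffectCall(
                series.locus,
                series.snp_id,
                r,
                p,
                classify_gain_loss(r, p, alpha),
                pairing,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# MPRA concordance
# ---------------------------------------------------------------------------

def mpra_concordance(
    loss_logfc: Sequence[float], gain_logfc: Sequence[float]
) -> dict:
    """Concordance of predicted direction with reporter-assay activity.

    One-sided one-sample t-tests per group (loss: mean logFC < 0, gain:
    mean logFC > 0) and a two-sided Mann-Whitney U between the groups.
    Tests on groups with fewer than 2 members are reported as None.
    """
    loss = np.asarray(loss_logfc, dtype=float)
    gain = np.asarray(gain_logfc, dtype=float)
    out: dict[str, Optional[float]] = {
        "loss_t_p": None,
        "gain_t_p": None,
        "between_mwu_p": None,
    }
    if len(loss) >= 2:
        out["loss_t_p"] = float(
            stats.ttest_1samp(loss, 0.0, alternative="less").pvalue
        )
    if len(gain) >= 2:
        out["gain_t_p"] = float(
            stats.ttest_1samp(gain, 0.0, alternative="greater").pvalue
        )
    if len(loss) >= 1 and len(gain) >= 1:
        out["between_mwu_p"] = float(
            stats.mannwhitneyu(loss, gain, alternative="two-sided").pvalue
        )
    return out


# ---------------------------------------------------------------------------
# TSV plumbing for the effects workflow
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str) -> pd.DataFrame:
    """Genotype table: columns snp_id, chrom, start, end, sample, genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "start", "end", "sample", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def series_from_tables(
    genotypes: pd.DataFrame, activity: pd.DataFrame
) -> list[GenotypeSeries]:
    """Join a genotype table with a per-(snp_id, sample) activity table
    (columns snp_id, sample, activity) into per-locus series."""
    merged = genotypes.merge(activity, on=["snp_id", "sample"], how="inner")
    out = []
    for snp_id, grp in merged.groupby("snp_id", sort=True):
        row = grp.iloc[0]
        out.append(
            GenotypeSeries(
                GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
                str(snp_id),
                grp["genotype"].tolist(),
                grp["activity"].to_numpy(dtype=float),
            )
        )
    return out


def write_effect_calls(calls: Sequence[EffectCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tstart\tend\tr\tp\tdirection\tpairing\n")
        for c in calls:
            fh.write(
                f"{c.snp_id}\t{c.locus.chrom}\t{c.locus.start}\t{c.locus.end}\t"
                f"{c.r:.6f}\t{c.p:.6g}\t{c.direction}\t{c.pairing[0]}|{c.pairing[1]}\n"
            )
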