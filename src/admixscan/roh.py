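"""Runs-of-homozygosity detection with the PLINK sliding-window algorithm.

A scanning window of 50 consecutive SNPs — truncated so it never spans
more than 5,000 kb — is anchored at every SNP; a window passes for an
individual when it contains at most one heterozygous and at most five
missing calls. Each SNP's hit rate is the fraction of passing windows
among those containing it; SNPs at or above the hit fraction (0.05, the
PLINK default) are ROH-eligible, and maximal eligible runs are reported
when they are at least 500 kb long, no sparser than 50 kb/SNP, and free of
internal gaps above 1,000 kb. Segment bounds sit at the outermost eligible
SNPs. The window SNP count, hit fraction and maximum gap are PLINK
defaults; window span, het/missing allowances, minimum length and density
are the tuned study parameters — all affect reproduction on external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, VariantTable

CATEGORY_EDGES_MB = [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
CATEGORY_LABELS = ["0.5-1", "1-2", "2-4", "4-8", "8-16", ">16"]
SIZE_SPLIT_MB = 1.6


@dataclass
class ROHConfig:
    window_snps: int = 50
    window_kb: float = 5_000.0
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_roh_kb: float = 500.0
    min_density_kb_per_snp: float = 50.0
    hit_fraction: float = 0.05
    max_gap_kb: float = 1_000.0

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0 or (name not in ("max_het_per_window",
                                      "max_missing_per_window") and v <= 0):
                raise ValueError(f"{name} must be positive")


def length_category(length_mb: float) -> str:
    idx = np.searchsorted(CATEGORY_EDGES_MB, length_mb, side="right") - 1
    return CATEGORY_LABELS[max(idx, 0)]


def _eligible_snps(pos: np.ndarray, het: np.ndarray, miss: np.ndarray,
                   cfg: ROHConfig) -> np.ndarray:
    """Hit-rate eligibility for one individual on one chromosome."""
    m = len(pos)
    W = cfg.window_kb * 1000.0
    idx = np.arange(m)
    # window anchored at SNP i: the next window_snps SNPs, truncated to
    # a bp span of at most window_kb
    end_idx = np.minimum(idx + cfg.window_snps,
                         np.searchsorted(pos, pos + W, side="left"))
    end_idx = np.maximum(end_idx, idx + 1)  # a window always holds its anchor
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(miss)])
    passes = ((chet[end_idx] - chet[idx]) <= cfg.max_het_per_window) & \
             ((cmis[end_idx] - cmis[idx]) <= cfg.max_missing_per_window)
    cpass = np.concatenate([[0], np.cumsum(passes)])
    # anchors whose window contains SNP j: i <= j with end_idx[i] > j
    lo = np.searchsorted(end_idx, idx, side="right")
    total = idx - lo + 1
    passing = cpass[idx + 1] - cpass[lo]
    return passing / total >= cfg.hit_fraction


def call_roh(vt: VariantTable, cfg: ROHConfig | None = None) -> pd.DataFrame:
    """ROH segments for every individual.

    Columns: individual, chrom, start, end (0-based half-open), length_kb,
    n_snps, category, size_class.
    """
    cfg = cfg or ROHConfig()
    chrom_arr = vt.variants["chrom"].to_numpy()
    pos_arr = vt.variants["pos"].to_numpy()
    out = []
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        if len(sel) < 2:
            continue
        pos = pos_arr[sel].astype(float)
        for i, ind in enumerate(vt.samples["id"]):
            g = vt.calls[i, sel]
            het = (g == 1).astype(np.int64)
            miss = (g == MISSING).astype(np.int64)
            elig = _eligible_snps(pos, het, miss, cfg)
            out.extend(_segments_from_eligible(
                str(ind), str(chrom), pos, elig, cfg))
    df = pd.DataFrame(out, columns=["individual", "chrom", "start", "end",
                                    "length_kb", "n_snps"])
    if len(df):
        mb = df["length_kb"] / 1000.0
        df["category"] = [length_category(x) for x in mb]
        df["size_class"] = np.where(mb > SIZE_SPLIT_MB,
                                    f">{SIZE_SPLIT_MB}", f"<={SIZE_SPLIT_MB}")
    else:
        df["category"] = pd.Series(dtype=str)
        df["size_class"] = pd.Series(dtype=str)
    return df


def _segments_from_eligible(ind: str, chrom: str, pos: np.ndarray,
                            elig: np.ndarray, cfg: ROHConfig) -> list[tuple]:
    segs = []
    idx = np.flatnonzero(elig)
    if len(idx) == 0:
        return segs
    # runs are consecutive eligible SNPs; an ineligible SNP or a bp gap
    # above max_gap_kb ends the run
    cut = np.flatnonzero((np.diff(idx) > 1)
                         | (np.diff(pos[idx]) > cfg.max_gap_kb * 1000.0))
    starts = np.concatenate([[0], cut + 1])
    ends = np.concatenate([cut, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        first, last = idx[s], idx[e]
        length_bp = pos[last] - pos[first] + 1
        n_snps = last - first + 1  # every SNP between the bounds
        length_kb = length_bp / 1000.0
        if length_kb < cfg.min_roh_kb:
            continue
        if length_kb / n_snps > cfg.min_density_kb_per_snp:
            continue
        segs.append((ind, chrom, int(pos[first] - 1), int(pos[last]),
                     float(length_kb), int(n_snps)))
    return segs


def summarize_roh(segments: pd.DataFrame, samples: pd.DataFrame
                  ) -> pd.DataFrame:
    """Per-group means of total ROH length (Mb), segment count, per-category
    totals and the ≤1.6 / >1.6 Mb split."""
    per_ind = []
    for ind in samples["id"]:
        sub = segments[segments["individual"] == ind]
        mb = sub["length_kb"].to_numpy(float) / 1000.0
        row = {"individual": ind,
               "total_mb": mb.sum(), "n_segments": len(sub)}
        for lab in CATEGORY_LABELS:
            row[f"cat_{lab}_mb"] = mb[(sub["category"] == lab).to_numpy()].sum() \
                if len(sub) else 0.0
        row["le1.6_mb"] = mb[mb <= SIZE_SPLIT_MB].sum()
        row["gt1.6_mb"] = mb[mb > SIZE_SPLIT_MB].sum()
        per_ind.append(row)
    per_ind = pd.DataFrame(per_ind)
    per_ind["group"] = samples["group"].to_numpy()
    return per_ind.groupby("group").mean(numeric_only=True).reset_index()


def per_individual_totals(segments: pd.DataFrame, samples: pd.DataFrame
                          ) -> pd.Series:
    """Total ROH Mb per individual, indexed by sample id (zeros included)."""
    mb = segments.assign(mb=segments["length_kb"] / 1000.0)
    tot = mb.groupby("individual")["mb"].sum()
    return tot.reindex(samples["id"], fill_value=0.0)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test: exact enumeration for small tie-free
    samples, otherwise normal approximation with tie and continuity
    corrections. Fully tied data returns p = 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance threshold after Bonferroni correction."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
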