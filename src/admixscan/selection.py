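"""Windowed selection statistics: Tajima's D, Hudson FST and PBS.

Statistics are computed in non-overlapping 10-kb tiles anchored at the
region start. Diversity uses allele frequencies from unphased genotypes
under random union of gametes; the effective haplotype count is twice the
number of genotyped samples (per site for pi, globally for D). Hudson's
ratio-of-averages FST feeds the population branch statistic
PBS_A = (T_AB + T_AC - T_BC) / 2 with T = -log(1 - FST). Significance
comes from empirical tail probabilities against a coalescent null
ensemble, Bonferroni-corrected per statistic family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import NullEnsemble, empirical_p, tajimas_d
from .genotype_io import MISSING, VariantTable

WINDOW_BP_DEFAULT = 10_000


def window_stats(vt: VariantTable, chrom: str, start: int, end: int,
                 window_bp: int = WINDOW_BP_DEFAULT) -> pd.DataFrame:
    """Per-window S, pi and Tajima's D over [start, end) (0-based).

    Windows tile the region from ``start``; a window without genotyped
    polymorphic sites has S=0 and undefined (NaN) D.
    """
    sel = np.flatnonzero((vt.variants["chrom"].to_numpy() == str(chrom))
                         & (vt.variants["pos"].to_numpy() - 1 >= start)
                         & (vt.variants["pos"].to_numpy() - 1 < end))
    pos0 = vt.variants["pos"].to_numpy()[sel] - 1
    calls = vt.calls[:, sel]
    rows = []
    for ws in range(start, end, window_bp):
        we = min(ws + window_bp, end)
        inw = (pos0 >= ws) & (pos0 < we)
        g = calls[:, inw]
        S, pi = _diversity_from_genotypes(g)
        n_hap = 2 * vt.n_samples
        D = tajimas_d(S, pi, n_hap) if S > 0 else float("nan")
        rows.append((str(chrom), ws, we, int(inw.sum()), S, pi, D))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_snps", "S", "pi", "D"])


def _diversity_from_genotypes(g: np.ndarray) -> tuple[int, float]:
    """(S, pi) from a samples x sites genotype slice; per-site haplotype
    counts exclude missing genotypes."""
    if g.shape[1] == 0:
        return 0, 0.0
    ok = g != MISSING
    n_hap = 2.0 * ok.sum(axis=0)
    alt = np.where(ok, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_hap > 0, alt / n_hap, np.nan)
    seg = np.isfinite(p) & (p > 0) & (p < 1) & (n_hap > 1)
    S = int(seg.sum())
    if S == 0:
        return 0, 0.0
    m = n_hap[seg]
    ps = p[seg]
    pi = float((2.0 * ps * (1.0 - ps) * m / (m - 1.0)).sum())
    return S, pi


def genotype_allele_counts(vt: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, haplotype count) per site, missing excluded."""
    ok = vt.calls != MISSING
    return (np.where(ok, vt.calls, 0).sum(axis=0).astype(float),
            2.0 * ok.sum(axis=0))


def hudson_fst_counts(alt1: np.ndarray, n1: np.ndarray,
                      alt2: np.ndarray, n2: np.ndarray) -> float:
    """Hudson FST, ratio of averages over sites.

    Per site: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1); FST = sum(N)/sum(D). Sites with fewer than two
    observed haplotypes in either population are dropped; NaN when no
    informative site remains.
    """
    alt1 = np.asarray(alt1, float)
    alt2 = np.asarray(alt2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    ok = (n1 > 1) & (n2 > 1)
    if not ok.any():
        return float("nan")
    p1 = alt1[ok] / n1[ok]
    p2 = alt2[ok] / n2[ok]
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1[ok] - 1)
           - p2 * (1 - p2) / (n2[ok] - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    informative = den > 0
    if not informative.any():
        return float("nan")
    return float(num[informative].sum() / den[informative].sum())


def hudson_fst(vt1: VariantTable, vt2: VariantTable) -> float:
    """Hudson FST between two tables sharing the same variant panel."""
    a1, n1 = genotype_allele_counts(vt1)
    a2, n2 = genotype_allele_counts(vt2)
    return hudson_fst_counts(a1, n1, a2, n2)


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Population branch statistic for population A; NaN propagates."""
    vals = [fst_ab, fst_ac, fst_bc]
    if any(v is None or not np.isfinite(v) for v in vals):
        return float("nan")
    t = [-math.log(1.0 - min(v, 1.0 - 1e-9)) for v in vals]
    return (t[0] + t[1] - t[2]) / 2.0


def selection_scan(windows: pd.DataFrame, null: NullEnsemble,
                   m_d: int, m_pbs: int | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Attach empirical p-values and Bonferroni flags to window statistics.

    ``p_D`` is the lower-tail probability of each window's D under the
    null; ``p_PBS`` (when a PBS column and null are present) the upper
    tail. Zero tail counts are floored at 1/N and flagged in ``*_floored``.
    """
    out = windows.copy()
    thr_d = alpha / m_d
    pd_vals, pd_floor = [], []
    for d in out["D"]:
        if not np.isfinite(d):
            pd_vals.append(np.nan)
            pd_floor.append(False)
            continue
        ep = empirical_p(d, null.values["D"], tail="lower")
        pd_vals.append(ep.p)
        pd_floor.append(ep.floored)
    out["p_D"] = pd_vals
    out["p_D_floored"] = pd_floor
    out["sig_D"] = out["p_D"] < thr_d
    if "PBS" in out.columns and "PBS" in null.values:
        if m_pbs is None:
            raise ValueError("m_pbs required when PBS is scanned")
        thr_p = alpha / m_pbs
        pp_vals, pp_floor = [], []
        for v in out["PBS"]:
            if not np.isfinite(v):
                pp_vals.append(np.nan)
                pp_floor.append(False)
                continue
            ep = empirical_p(v, null.values["PBS"], tail="upper")
            pp_vals.append(ep.p)
            pp_floor.append(ep.floored)
        out["p_PBS"] = pp_vals
        out["p_PBS_floored"] = pp_floor
        out["sig_PBS"] = out["p_PBS"] < thr_p
    return out
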