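"""Genome-wide local-ancestry deviation scan and region diversity follow-up.

For each ancestry k the per-locus cohort-mean ancestry fraction (mean
dosage / 2 over non-missing individuals) is standardized against its
genome-wide mean and empirical SD across loci, giving a Z score per SNP.
|Z| > 3 corresponds to a two-sided normal tail of 2.7e-3; regions are
maximal runs of significant SNPs. The empirical (across-locus) SD is used
rather than a binomial standard error so that ancestry autocorrelation and
inference noise are absorbed into the null scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, DosageTensor, VariantTable
from .roh import wilcoxon_rank_sum

Z_THRESHOLD_DEFAULT = 3.0


@dataclass
class ZScanResult:
    loci: pd.DataFrame          # chrom, pos
    labels: list
    frac: np.ndarray            # loci x K mean ancestry fractions
    mu: np.ndarray              # K genome means
    sd: np.ndarray              # K genome SDs (ddof=0)
    z: np.ndarray               # loci x K


def zscore_scan(dt: DosageTensor) -> ZScanResult:
    """Standardized per-locus ancestry deviation for each ancestry."""
    if dt.dose.shape[1] < 2 or dt.dose.shape[0] < 2:
        raise ValueError("need >= 2 loci and >= 2 individuals")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        frac = np.nanmean(dt.dose, axis=0) / 2.0   # loci x K
    mu = frac.mean(axis=0)
    sd = frac.std(axis=0, ddof=0)
    z = np.zeros_like(frac)
    for k in range(dt.K):
        if sd[k] == 0:
            warnings.warn(f"ancestry {dt.labels[k]} constant across loci; "
                          "Z set to 0")
        else:
            z[:, k] = (frac[:, k] - mu[k]) / sd[k]
    return ZScanResult(loci=dt.loci.reset_index(drop=True),
                       labels=list(dt.labels), frac=frac, mu=mu, sd=sd, z=z)


def call_regions(zs: ZScanResult, threshold: float = Z_THRESHOLD_DEFAULT,
                 max_gap_snps: int = 0) -> pd.DataFrame:
    """Maximal runs of loci with |Z| > threshold, per ancestry.

    Runs tolerate up to ``max_gap_snps`` consecutive sub-threshold loci.
    Columns: ancestry, chrom, start, end (0-based half-open at outermost
    qualifying SNPs), n_snps, lead_pos, lead_z, lead_mean_pct.
    """
    out = []
    chrom_arr = zs.loci["chrom"].to_numpy()
    pos_arr = zs.loci["pos"].to_numpy()
    for k, anc in enumerate(zs.labels):
        zcol = zs.z[:, k]
        for chrom in dict.fromkeys(chrom_arr):
            sel = np.flatnonzero(chrom_arr == chrom)
            sig = np.abs(zcol[sel]) > threshold
            hits = np.flatnonzero(sig)
            if len(hits) == 0:
                continue
            # group hits separated by more than max_gap_snps non-hits
            cuts = np.flatnonzero(np.diff(hits) > max_gap_snps + 1)
            run_starts = np.concatenate([[0], cuts + 1])
            run_ends = np.concatenate([cuts, [len(hits) - 1]])
            for rs, re in zip(run_starts, run_ends):
                lo, hi = hits[rs], hits[re]
                idx = sel[lo:hi + 1]
                zr = zcol[idx]
                lead_local = int(np.argmax(np.abs(zr)))  # ties -> lowest pos
                lead = idx[lead_local]
                out.append((anc, str(chrom),
                            int(pos_arr[sel[lo]] - 1), int(pos_arr[sel[hi]]),
                            hi - lo + 1, int(pos_arr[lead]),
                            float(zcol[lead]),
                            float(zs.frac[lead, k] * 100.0)))
    return pd.DataFrame(out, columns=["ancestry", "chrom", "start", "end",
                                      "n_snps", "lead_pos", "lead_z",
                                      "lead_mean_pct"])


def _roh_carrier_counts(vt: VariantTable, roh: pd.DataFrame) -> np.ndarray:
    """Per-SNP count of individuals whose ROH covers the SNP."""
    counts = np.zeros(vt.n_variants, dtype=np.int64)
    chrom_arr = vt.variants["chrom"].to_numpy()
    pos0 = vt.variants["pos"].to_numpy() - 1
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        p = pos0[sel]
        sub = roh[roh["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            lo = np.searchsorted(p, s, side="left")
            hi = np.searchsorted(p, e, side="left")
            counts[sel[lo:hi]] += 1
    return counts


def region_diversity(vt: VariantTable, roh: pd.DataFrame,
                     regions: pd.DataFrame, m_tests: int,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Mean SNP heterozygosity and ROH-carrier counts inside called regions,
    compared with the genome-wide per-SNP distributions by rank-sum tests.

    ``m_tests`` sets the Bonferroni threshold alpha/m for the significance
    flags. Regions with no SNPs get NaN statistics.
    """
    het = vt.het_rate()
    carriers = _roh_carrier_counts(vt, roh)
    chrom_arr = vt.variants["chrom"].to_numpy()
    pos0 = vt.variants["pos"].to_numpy() - 1
    thr = alpha / m_tests
    rows = []
    for r in regions.itertuples():
        inside = (chrom_arr == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
        if not inside.any():
            rows.append((r.chrom, r.start, r.end, np.nan, np.nan,
                         np.nan, np.nan, False, False))
            continue
        het_in = het[inside & np.isfinite(het)]
        car_in = carriers[inside]
        het_all = het[np.isfinite(het)]
        p_het = wilcoxon_rank_sum(het_in, het_all)[1] if len(het_in) else np.nan
        p_car = wilcoxon_rank_sum(car_in, carriers)[1]
        rows.append((r.chrom, r.start, r.end,
                     float(het_in.mean()) if len(het_in) else np.nan,
                     float(car_in.mean()),
                     p_het, p_car,
                     bool(p_het < thr) if np.isfinite(p_het) else False,
                     bool(p_car < thr)))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "mean_het", "mean_roh_carriers",
        "p_het", "p_carriers", "sig_het", "sig_carriers"])
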