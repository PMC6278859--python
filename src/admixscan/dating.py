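"""Weighted two-locus admixture-LD decay and dating of the admixture pulse.

For an admixed cohort and two reference panels, each SNP gets a weight
w_i = f_ref1(i) - f_ref2(i). Every intra-chromosomal SNP pair (i, j)
within the genetic-distance range contributes cov(g_i, g_j) * w_i * w_j,
where the covariance is taken over admixed individuals' genotypes; the
contributions are averaged in genetic-distance bins. A single admixture
pulse n generations ago makes the curve decay as A*exp(-n*d) + c in the
distance d (Morgans), so a bounded nonlinear least-squares fit of that
form estimates the number of generations. Standard errors come from a
leave-one-chromosome-out jackknife, and years before present are obtained
at 33 years per generation. Pairs closer than 0.5 cM are excluded
(short-range LD contamination); the bin width defaults to 0.05 cM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genotype_io import MISSING, GeneticMap, VariantTable

YEARS_PER_GENERATION = 33.0
MIN_CM_DEFAULT = 0.5
MAX_CM_DEFAULT = 30.0
BIN_CM_DEFAULT = 0.05


@dataclass
class DecayCurve:
    """Binned weighted-LD decay with per-chromosome partial sums
    (enabling cheap jackknife re-binning)."""
    bin_edges_cm: np.ndarray        # B+1 edges
    chroms: list                    # C chromosome labels
    sums: np.ndarray                # C x B weighted-LD sums
    counts: np.ndarray              # C x B pair counts

    @property
    def d_morgans(self) -> np.ndarray:
        centers = 0.5 * (self.bin_edges_cm[:-1] + self.bin_edges_cm[1:])
        return centers / 100.0

    def values(self, leave_out: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(bin values, pair counts), optionally excluding one chromosome."""
        keep = np.ones(len(self.chroms), dtype=bool)
        if leave_out is not None:
            keep = np.array([c != leave_out for c in self.chroms])
        s = self.sums[keep].sum(axis=0)
        n = self.counts[keep].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / n, np.nan), n

    def to_frame(self) -> pd.DataFrame:
        v, n = self.values()
        return pd.DataFrame({"d_cm": self.d_morgans * 100.0,
                             "weighted_ld": v, "n_pairs": n})


@dataclass
class FitResult:
    n_generations: float
    amplitude: float
    affine: float
    residual: float
    detected: bool


@dataclass
class DatingResult:
    n_generations: float
    amplitude: float
    affine: float
    se_n: float | None
    se_amplitude: float | None
    z_amplitude: float | None
    years_bp: tuple | None
    detected: bool


def _centered_genotypes(vt: VariantTable) -> np.ndarray:
    """Float genotype matrix with missing entries replaced by the variant
    mean (pairwise-complete covariance approximation)."""
    g = vt.calls.astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = mu[idx[1]]
    return g - np.nanmean(g, axis=0)


def weighted_ld_curve(admixed: VariantTable, ref1: VariantTable,
                      ref2: VariantTable, gmap: GeneticMap,
                      bin_cm: float = BIN_CM_DEFAULT,
                      min_cm: float = MIN_CM_DEFAULT,
                      max_cm: float = MAX_CM_DEFAULT,
                      block_size: int = 1024) -> DecayCurve:
    """Binned weighted admixture-LD decay across all chromosomes.

    The three tables must share the same variant panel (same order).
    Chromosomes with fewer than two shared loci are skipped with a warning.
    """
    if not (len(admixed.variants) == len(ref1.variants) == len(ref2.variants)):
        raise ValueError("tables must share one variant panel")
    w_all = ref1.alt_freq() - ref2.alt_freq()
    g_all = _centered_genotypes(admixed)
    n_ind = admixed.n_samples

    edges = np.arange(min_cm, max_cm + bin_cm * 0.5, bin_cm)
    B = len(edges) - 1
    chrom_arr = admixed.variants["chrom"].to_numpy()
    chroms = list(dict.fromkeys(chrom_arr))
    sums = np.zeros((len(chroms), B))
    counts = np.zeros((len(chroms), B), dtype=np.int64)

    for ci, chrom in enumerate(chroms):
        sel = np.flatnonzero(chrom_arr == chrom)
        if len(sel) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 shared loci; skipped")
            continue
        cm = gmap.cm_at(chrom, admixed.variants["pos"].to_numpy()[sel].astype(float))
        g = g_all[:, sel]
        w = w_all[sel]
        m = len(sel)
        for lo in range(0, m, block_size):
            hi = min(lo + block_size, m)
            # pairs (i in block, j > i) with distance within [min_cm, max_cm]
            jmax = np.searchsorted(cm, cm[hi - 1] + max_cm, side="right")
            cov = g[:, lo:hi].T @ g[:, lo:jmax] / (n_ind - 1)
            prod = cov * np.outer(w[lo:hi], w[lo:jmax])
            d = np.abs(cm[lo:jmax][None, :] - cm[lo:hi][:, None])
            upper = np.arange(lo, hi)[:, None] < np.arange(lo, jmax)[None, :]
            ok = upper & (d >= min_cm) & (d < max_cm)
            if not ok.any():
                continue
            bins = np.minimum(((d[ok] - min_cm) / bin_cm).astype(np.int64), B - 1)
            sums[ci] += np.bincount(bins, weights=prod[ok], minlength=B)
            counts[ci] += np.bincount(bins, minlength=B)
    return DecayCurve(bin_edges_cm=edges, chroms=chroms,
                      sums=sums, counts=counts)


def fit_decay(d_morgans: np.ndarray, values: np.ndarray,
              counts: np.ndarray | None = None) -> FitResult:
    """Bounded least squares of value(d) = A*exp(-n*d) + c with A, n >= 0.

    Bins with no pairs are dropped; bins are weighted by sqrt(pair count).
    A fit collapsing to zero amplitude is reported as "no admixture
    signal" (``detected=False``).
    """
    v = np.asarray(values, float)
    d = np.asarray(d_morgans, float)
    ok = np.isfinite(v)
    if counts is not None:
        ok &= np.asarray(counts) > 0
    d, v = d[ok], v[ok]
    if len(d) < 5:
        raise ValueError("need >= 5 informative bins")
    sigma = None
    if counts is not None:
        c = np.asarray(counts, float)[ok]
        sigma = 1.0 / np.sqrt(c)

    tail = v[d > d.mean()].mean()
    a0 = max(v[0] - tail, 1e-12)
    # crude rate from the log-linear slope of the positive early part
    pos = v - tail > a0 * 1e-3
    n0 = 50.0
    if pos.sum() >= 2:
        slope = np.polyfit(d[pos], np.log(v[pos] - tail + 1e-300), 1)[0]
        if slope < 0:
            n0 = -slope
    n0 = float(np.clip(n0, 1.0, 500.0))

    def model(x, A, n, c):
        return A * np.exp(-n * x) + c

    try:
        popt, _ = curve_fit(model, d, v, p0=[a0, n0, tail], sigma=sigma,
                            bounds=([0.0, 0.0, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20_000)
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    A, n, c = popt
    resid = float(np.sqrt(np.mean((model(d, *popt) - v) ** 2)))
    detected = A > 0 and n > 0
    return FitResult(n_generations=float(n), amplitude=float(A),
                     affine=float(c), residual=resid, detected=detected)


def fit_with_jackknife(curve: DecayCurve) -> DatingResult:
    """Full fit plus leave-one-chromosome-out jackknife SEs.

    With a single chromosome the jackknife is undefined and SEs are None.
    """
    v, n_pairs = curve.values()
    full = fit_decay(curve.d_morgans, v, n_pairs)
    used = [c for i, c in enumerate(curve.chroms) if curve.counts[i].sum() > 0]
    if len(used) < 2:
        warnings.warn("jackknife undefined with a single chromosome")
        return DatingResult(full.n_generations, full.amplitude, full.affine,
                            None, None, None, None, full.detected)
    reps_n, reps_a = [], []
    for c in used:
        vj, nj = curve.values(leave_out=c)
        fj = fit_decay(curve.d_morgans, vj, nj)
        reps_n.append(fj.n_generations)
        reps_a.append(fj.amplitude)
    C = len(used)
    fac = (C - 1) / C
    se_n = math.sqrt(fac * np.sum((np.array(reps_n) - np.mean(reps_n)) ** 2))
    se_a = math.sqrt(fac * np.sum((np.array(reps_a) - np.mean(reps_a)) ** 2))
    z_amp = full.amplitude / se_a if se_a > 0 else float("inf")
    years = years_interval(full.n_generations, se_n)
    return DatingResult(full.n_generations, full.amplitude, full.affine,
                        se_n, se_a, z_amp, years, full.detected)


def years_interval(n_generations: float, se: float) -> tuple[int, int]:
    """(low, high) years BP from the +-1 SE generation interval at 33
    years per generation."""
    lo = math.floor(n_generations - se)
    hi = math.ceil(n_generations + se)
    return (int(lo * YEARS_PER_GENERATION), int(hi * YEARS_PER_GENERATION))


def date_admixture(admixed: VariantTable, ref_pairs: list[tuple],
                   gmap: GeneticMap, min_z: float = 2.0,
                   **curve_kwargs) -> dict:
    """Date the admixture pulse against one or more reference pairs.

    Each pair yields a curve, fit and jackknife; pairs whose amplitude
    z-score falls below ``min_z`` fail the detection pretest. The combined
    estimate is the inverse-variance weighted mean over passing pairs.
    """
    per_pair = []
    for ref1, ref2 in ref_pairs:
        curve = weighted_ld_curve(admixed, ref1, ref2, gmap, **curve_kwargs)
        res = fit_with_jackknife(curve)
        passed = (res.detected and res.z_amplitude is not None
                  and res.z_amplitude >= min_z)
        per_pair.append({"result": res, "curve": curve, "passed": passed})
    passing = [p["result"] for p in per_pair if p["passed"]]
    if not passing:
        return {"per_pair": per_pair, "combined": None,
                "message": "no admixture detected"}
    ws = np.array([1.0 / r.se_n ** 2 if r.se_n else 1.0 for r in passing])
    ns = np.array([r.n_generations for r in passing])
    n_comb = float((ws * ns).sum() / ws.sum())
    se_comb = float(1.0 / math.sqrt(ws.sum()))
    combined = DatingResult(n_comb, np.nan, np.nan, se_comb, None, None,
                            years_interval(n_comb, se_comb), True)
    return {"per_pair": per_pair, "combined": combined, "message": "ok"}
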