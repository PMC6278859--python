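"""Genotype quality control: call-rate, MAF and HWE filters, windowed LD
pruning and exclusion of canonical long-range-LD regions.

Filter order is fixed: samples by call rate first, then variants by call
rate, MAF and the Hardy-Weinberg exact test. Missing genotypes are excluded
from every denominator, matching PLINK conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, VariantTable, interval_to_internal

#: hg19 long-range-LD regions commonly excluded before structure analyses
#: (0-based half-open): chr5/chr6(MHC)/chr8(inversion)/chr11.
LONG_RANGE_LD_HG19 = [
    ("5", *interval_to_internal(43_964_243, 51_464_244)),
    ("6", *interval_to_internal(24_892_021, 33_392_022)),
    ("8", *interval_to_internal(7_962_590, 11_962_591)),
    ("11", *interval_to_internal(45_043_424, 57_243_424)),
]


@dataclass
class QCConfig:
    sample_call_rate_min: float = 0.95
    variant_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-6
    prune_window: int = 50
    prune_step: int = 10
    prune_r2_max: float = 0.5
    excluded_regions: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("sample_call_rate_min", "variant_call_rate_min",
                     "maf_min", "hwe_p_min", "prune_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.prune_window > self.prune_step > 0:
            raise ValueError("require prune_window > prune_step > 0")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one. Monomorphic
    sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = n_Aa + 2 * n_aa           # minor-or-not does not matter: symmetric
    n_A = n_Aa + 2 * n_AA
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # feasible het counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    lg = math.lgamma
    logp = np.array([
        h * math.log(2)
        - lg((rare - h) // 2 + 1) - lg(h + 1) - lg((2 * n - rare - h) // 2 + 1)
        for h in hets
    ])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_Aa]
    if obs.size == 0:  # inconsistent parity cannot occur with valid counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return ((calls == 0).sum(axis=0), (calls == 1).sum(axis=0),
            (calls == 2).sum(axis=0))


def filter_genotypes(vt: VariantTable, cfg: QCConfig) -> tuple[VariantTable, dict]:
    """Apply the QC cascade; returns the surviving table and a removal report
    keyed by reason."""
    report = {}

    ok = vt.calls != MISSING
    sample_cr = ok.mean(axis=1) if vt.n_variants else np.ones(vt.n_samples)
    keep_s = sample_cr >= cfg.sample_call_rate_min
    report["samples_call_rate"] = int((~keep_s).sum())
    vt = vt.take_samples(np.flatnonzero(keep_s))

    ok = vt.calls != MISSING
    var_cr = ok.mean(axis=0) if vt.n_samples else np.zeros(vt.n_variants)
    keep = var_cr >= cfg.variant_call_rate_min
    report["variants_call_rate"] = int((~keep).sum())
    vt = vt.take_variants(np.flatnonzero(keep))

    maf = vt.maf()
    keep = ~(maf < cfg.maf_min)  # NaN (all-missing) already removed above
    report["variants_maf"] = int((~keep).sum())
    vt = vt.take_variants(np.flatnonzero(keep))

    n_hom_ref, n_het, n_hom_alt = _genotype_counts(vt.calls)
    hwe_p = np.array([
        hwe_exact_test(int(a), int(h), int(b))
        for a, h, b in zip(n_hom_ref, n_het, n_hom_alt)
    ]) if vt.n_variants else np.array([])
    keep = ~(hwe_p < cfg.hwe_p_min)
    report["variants_hwe"] = int((~keep).sum())
    vt = vt.take_variants(np.flatnonzero(keep))

    return vt, report


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete observations; NaN when undefined."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def remove_regions(vt: VariantTable, regions) -> VariantTable:
    """Drop variants falling inside any (chrom, start, end) 0-based
    half-open interval."""
    drop = np.zeros(vt.n_variants, dtype=bool)
    chrom = vt.variants["chrom"].to_numpy()
    pos0 = vt.variants["pos"].to_numpy() - 1
    for c, s, e in regions:
        drop |= (chrom == c) & (pos0 >= s) & (pos0 < e)
    return vt.take_variants(np.flatnonzero(~drop))


def ld_prune(vt: VariantTable, cfg: QCConfig) -> VariantTable:
    """Greedy windowed LD pruning (PLINK --indep-pairwise analogue).

    Variants inside ``cfg.excluded_regions`` are removed first. Within each
    ``prune_window``-SNP window, while any kept pair has r^2 above the
    threshold, the member with the lower MAF is dropped (tie: the later
    variant); the window then slides by ``prune_step`` SNPs.
    """
    if cfg.excluded_regions:
        vt = remove_regions(vt, cfg.excluded_regions)

    maf = vt.maf()
    keep = np.ones(vt.n_variants, dtype=bool)
    chrom = vt.variants["chrom"].to_numpy()
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start:start + cfg.prune_window]
            live = [j for j in window if keep[j]]
            changed = True
            while changed:
                changed = False
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        i, j = live[a], live[b]
                        if not (keep[i] and keep[j]):
                            continue
                        r2 = genotype_r2(vt.calls[:, i], vt.calls[:, j])
                        if np.isfinite(r2) and r2 > cfg.prune_r2_max:
                            victim = j if maf[j] <= maf[i] else i
                            keep[victim] = False
                            changed = True
                live = [j for j in live if keep[j]]
            if start + cfg.prune_window >= len(idx):
                break
            start += cfg.prune_step
    return vt.take_variants(np.flatnonzero(keep))
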