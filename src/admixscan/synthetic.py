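"""Synthetic three-way admixed cohorts with known truth.

Individuals are diploid mosaics of K ancestral populations. Each haplotype
is a Markov path along the genetic map: ancestry is drawn from the admixture
proportions at the chromosome start, switch events arrive as a Poisson
process at rate g per Morgan (g = generations since the admixture pulse),
and at every switch the new ancestry is redrawn from the proportions. After
merging same-ancestry neighbours the tract length of ancestry k is
exponential with mean 100 / (g (1 - p_k)) cM, and the indicator covariance
between two points d Morgans apart decays exactly as exp(-g d) — the model
the weighted admixture-LD dating estimator assumes.

Ancestry-specific allele frequencies follow the Balding-Nichols model:
frequency_k ~ Beta(p (1-F_k)/F_k, (1-p) (1-F_k)/F_k) around an ancestral
frequency p, so differentiation is controlled per ancestry by F_k (defaults
keep EUR-NAF differentiation small and both far from SSA).

Deviant-region injection reassigns whole haplotype tracts (preserving
contiguity) until the cohort-mean ancestry fraction in the interval matches
a target; ROH injection copies one haplotype onto the other within an
interval, producing fully autozygous stretches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import DosageTensor, GeneticMap, VariantTable

#: relative autosome lengths (approximate human karyotype, arbitrary units)
_AUTOSOME_REL = np.array([249, 243, 198, 191, 181, 171, 159, 146, 141, 135,
                          135, 133, 115, 107, 102, 90, 81, 78, 59, 63, 48, 51],
                         dtype=float)


@dataclass
class AncestryModel:
    """Admixture pulse model: proportions, time, and per-ancestry divergence."""
    labels: tuple = ("EUR", "NAF", "SSA")
    proportions: tuple = (0.75, 0.22, 0.03)
    generations: int = 15
    F: tuple = (0.02, 0.03, 0.12)

    def __post_init__(self):
        p = np.asarray(self.proportions, float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if any(not 0.0 <= f < 1.0 for f in self.F):
            raise ValueError("F parameters must lie in [0, 1)")

    @property
    def K(self) -> int:
        return len(self.labels)


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a synthetic cohort."""
    blocks: list            # per haplotype: {chrom: (ends_bp, ancestries)}
    deviant_regions: list   # (chrom, start0, end, ancestry_idx, achieved_mean)
    roh: list               # (individual_idx, chrom, start0, end)
    seed: int | None = None


def default_genome(total_mb: float = 3000.0, n_chrom: int = 22) -> dict[str, int]:
    """Chromosome name -> length (bp), human-like relative sizes scaled to
    ``total_mb``."""
    rel = _AUTOSOME_REL[:n_chrom]
    lengths = rel / rel.sum() * total_mb * 1e6
    return {str(i + 1): int(round(l)) for i, l in enumerate(lengths)}


def uniform_loci(genome: dict[str, int], spacing_bp: int) -> pd.DataFrame:
    """Evenly spaced loci (1-based positions) across a genome dict."""
    rows = []
    for chrom, L in genome.items():
        pos = np.arange(spacing_bp, L + 1, spacing_bp, dtype=np.int64)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def draw_ancestral_freqs(m: int, model: AncestryModel, rng: np.random.Generator,
                         base_low: float = 0.05, base_high: float = 0.95
                         ) -> np.ndarray:
    """m x K ancestry-specific frequencies under Balding-Nichols drift."""
    if m <= 0:
        raise ValueError("m must be positive")
    p = rng.uniform(base_low, base_high, size=m)
    out = np.empty((m, model.K))
    for k, F in enumerate(model.F):
        if F == 0.0:
            out[:, k] = p
        else:
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            out[:, k] = rng.beta(a, b)
    return out


# ---------------------------------------------------------------------------
# Mosaic simulation
# ---------------------------------------------------------------------------

def _simulate_haplotype(model: AncestryModel, gmap: GeneticMap,
                        rng: np.random.Generator) -> dict:
    """One haplotype: per chromosome (block_ends_bp, block_ancestries),
    same-ancestry neighbours merged."""
    g = float(model.generations)
    p = np.asarray(model.proportions)
    hap = {}
    for chrom in gmap.chroms():
        total_m = gmap.length_cm(chrom) / 100.0
        # switch points: Poisson process at rate g per Morgan
        n_sw = rng.poisson(g * total_m)
        cuts_m = np.sort(rng.uniform(0.0, total_m, size=n_sw))
        anc = rng.choice(model.K, size=n_sw + 1, p=p)
        ends_m = np.append(cuts_m, total_m)
        # merge consecutive identical ancestries
        keep = np.append(anc[:-1] != anc[1:], True)
        ends_m = ends_m[keep]
        anc = anc[keep]
        ends_bp = gmap.bp_at(chrom, ends_m * 100.0).astype(np.int64)
        ends_bp[-1] = int(gmap.tables[chrom][0][-1])
        hap[chrom] = (ends_bp, anc.astype(np.int8))
    return hap


def simulate_mosaic(n_individuals: int, model: AncestryModel, gmap: GeneticMap,
                    rng: np.random.Generator) -> list[dict]:
    """2 n haplotype mosaics (haplotypes 2i and 2i+1 form individual i)."""
    return [_simulate_haplotype(model, gmap, rng)
            for _ in range(2 * n_individuals)]


def ancestry_at(hap: dict, chrom: str, pos: np.ndarray) -> np.ndarray:
    """Ancestry index of a haplotype at 1-based positions."""
    ends, anc = hap[chrom]
    idx = np.searchsorted(ends, pos, side="left")
    idx = np.minimum(idx, len(anc) - 1)
    return anc[idx]


def haplotype_proportions(paths: list[dict], gmap: GeneticMap, K: int) -> np.ndarray:
    """Genome-wide length-weighted ancestry proportions across haplotypes."""
    tot = np.zeros(K)
    for hap in paths:
        for chrom, (ends, anc) in hap.items():
            starts = np.concatenate([[0], ends[:-1]])
            lengths = ends - starts
            for k in range(K):
                tot[k] += lengths[anc == k].sum()
    return tot / tot.sum()


def block_lengths_cm(paths: list[dict], gmap: GeneticMap, K: int) -> list[np.ndarray]:
    """Per-ancestry tract lengths in cM (interior blocks only, so chromosome
    edges do not truncate the exponential)."""
    out = [[] for _ in range(K)]
    for hap in paths:
        for chrom, (ends, anc) in hap.items():
            cm = gmap.cm_at(chrom, ends.astype(float))
            starts = np.concatenate([[0.0], cm[:-1]])
            lens = cm - starts
            for i in range(1, len(anc) - 1):
                out[anc[i]].append(lens[i])
    return [np.asarray(v) for v in out]


# ---------------------------------------------------------------------------
# Signal injection
# ---------------------------------------------------------------------------

def _set_interval_ancestry(hap: dict, chrom: str, start0: int, end: int,
                           anc_new: int) -> None:
    """Overwrite haplotype ancestry with ``anc_new`` on [start0, end)."""
    ends, anc = hap[chrom]
    starts = np.concatenate([[0], ends[:-1]])
    new_ends, new_anc = [], []
    inserted = False
    for s, e, a in zip(starts, ends, anc):
        if e <= start0 or s >= end:          # untouched
            new_ends.append(e)
            new_anc.append(a)
            continue
        if s < start0:                       # left remnant
            new_ends.append(start0)
            new_anc.append(a)
        if not inserted:
            new_ends.append(min(end, ends[-1]))
            new_anc.append(anc_new)
            inserted = True
        if e > end:                          # right remnant
            new_ends.append(e)
            new_anc.append(a)
    ends = np.asarray(new_ends, dtype=np.int64)
    anc = np.asarray(new_anc, dtype=np.int8)
    keep = np.append(anc[:-1] != anc[1:], True)
    hap[chrom] = (ends[keep], anc[keep])


def _interval_fraction(hap: dict, chrom: str, start0: int, end: int,
                       anc_k: int) -> float:
    ends, anc = hap[chrom]
    starts = np.concatenate([[0], ends[:-1]])
    ov = np.minimum(ends, end) - np.maximum(starts, start0)
    ov = np.clip(ov, 0, None)
    tot = ov.sum()
    return float(ov[anc == anc_k].sum() / tot) if tot > 0 else 0.0


def inject_deviant_region(paths: list[dict], chrom: str, start0: int, end: int,
                          anc_k: int, target_mean: float,
                          rng: np.random.Generator, n_ancestries: int = 3) -> float:
    """Raise (or lower) the cohort-mean fraction of ancestry ``anc_k`` inside
    an interval to ``target_mean`` by reassigning whole haplotype tracts.

    Haplotypes are converted greedily (those furthest from the target first,
    in shuffled order among ties) until the achieved mean crosses the target;
    granularity is 1 / n_haplotypes. Returns the achieved mean.
    """
    if not 0.0 <= target_mean <= 1.0:
        raise ValueError("target mean must be an ancestry fraction in [0, 1]")
    H = len(paths)
    fracs = np.array([_interval_fraction(h, chrom, start0, end, anc_k)
                      for h in paths])
    order = rng.permutation(H)
    raising = fracs.mean() < target_mean
    # convert haplotypes with least (most) current ancestry-k content first
    order = order[np.argsort(fracs[order], kind="stable")]
    if not raising:
        order = order[::-1]
    mean = fracs.mean()
    for h_idx in order:
        if (raising and mean >= target_mean) or \
           (not raising and mean <= target_mean):
            break
        if raising:
            delta = (1.0 - fracs[h_idx]) / H
            _set_interval_ancestry(paths[h_idx], chrom, start0, end, anc_k)
            fracs[h_idx] = 1.0
        else:
            delta = -fracs[h_idx] / H
            others = [k for k in range(n_ancestries) if k != anc_k]
            repl = int(rng.choice(others))
            _set_interval_ancestry(paths[h_idx], chrom, start0, end, repl)
            fracs[h_idx] = 0.0
        mean += delta
    return float(fracs.mean())


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emit_cohort(paths: list[dict], freqs: np.ndarray, loci: pd.DataFrame,
                rng: np.random.Generator, labels=("EUR", "NAF", "SSA"),
                roh: list | None = None, groups=None
                ) -> tuple[VariantTable, DosageTensor]:
    """Draw genotypes from haplotype-local ancestry frequencies.

    Each haplotype allele is Bernoulli(freq of its local ancestry); the
    genotype is the sum of the two haplotypes and the truth dosage counts
    haplotypes of each ancestry (integers summing to 2). ROH intervals copy
    haplotype A onto haplotype B (ancestry and alleles alike).
    """
    n = len(paths) // 2
    m = len(loci)
    K = freqs.shape[1]
    calls = np.zeros((n, m), dtype=np.int8)
    dose = np.zeros((n, m, K), dtype=np.float64)
    roh = roh or []

    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    chrom_slices = {}
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        chrom_slices[chrom] = (idx, pos_arr[idx])

    for i in range(n):
        hapA, hapB = paths[2 * i], paths[2 * i + 1]
        for chrom, (idx, pos) in chrom_slices.items():
            ancA = ancestry_at(hapA, chrom, pos)
            ancB = ancestry_at(hapB, chrom, pos).copy()
            fA = freqs[idx, ancA]
            fB = freqs[idx, ancB]
            aA = (rng.random(len(idx)) < fA).astype(np.int8)
            aB = (rng.random(len(idx)) < fB).astype(np.int8)
            for (ind, rchrom, s0, e) in roh:
                if ind == i and rchrom == chrom:
                    mask = (pos - 1 >= s0) & (pos - 1 < e)
                    ancB[mask] = ancA[mask]
                    aB[mask] = aA[mask]
            calls[i, idx] = aA + aB
            np.add.at(dose[i], (idx, ancA), 1.0)
            np.add.at(dose[i], (idx, ancB), 1.0)

    ids = [f"ind{i:04d}" for i in range(n)]
    grp = groups if groups is not None else [""] * n
    variants = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_arr,
        "id": [f"snp{j}" for j in range(m)],
        "ref": "A", "alt": "G",
    })
    vt = VariantTable(variants, pd.DataFrame({"id": ids, "group": grp}), calls)
    dt = DosageTensor(ids, loci[["chrom", "pos"]].reset_index(drop=True),
                      list(labels), dose)
    return vt, dt


def reference_panel(freqs: np.ndarray, ancestry_idx: int, n_individuals: int,
                    loci: pd.DataFrame, rng: np.random.Generator,
                    group: str = "") -> VariantTable:
    """Unadmixed panel drawn in Hardy-Weinberg proportions from one
    ancestry's allele frequencies (a stand-in for a reference population)."""
    f = freqs[:, ancestry_idx]
    calls = (rng.random((n_individuals, len(f))) < f).astype(np.int8)
    calls += (rng.random((n_individuals, len(f))) < f).astype(np.int8)
    variants = pd.DataFrame({
        "chrom": loci["chrom"].to_numpy(), "pos": loci["pos"].to_numpy(),
        "id": [f"snp{j}" for j in range(len(f))], "ref": "A", "alt": "G"})
    samples = pd.DataFrame(
        {"id": [f"ref{ancestry_idx}_{i:03d}" for i in range(n_individuals)],
         "group": group})
    return VariantTable(variants, samples, calls)


def simulate_cohort(n_individuals: int, model: AncestryModel | None = None,
                    genome: dict[str, int] | None = None,
                    cm_per_mb: float = 1.0, spacing_bp: int = 20_000,
                    deviant_regions: list | None = None,
                    roh: list | None = None, seed: int = 0, groups=None
                    ) -> tuple[VariantTable, DosageTensor, SyntheticTruth]:
    """End-to-end cohort generation with truth.

    ``deviant_regions``: list of (chrom, start0, end, ancestry_idx, target
    mean fraction). ``roh``: list of (individual_idx, chrom, start0, end).
    """
    model = model or AncestryModel()
    genome = genome or default_genome()
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.uniform(genome, cm_per_mb)
    loci = uniform_loci(genome, spacing_bp)
    freqs = draw_ancestral_freqs(len(loci), model, rng)
    paths = simulate_mosaic(n_individuals, model, gmap, rng)
    achieved = []
    for (chrom, s0, e, k, target) in (deviant_regions or []):
        got = inject_deviant_region(paths, str(chrom), s0, e, k, target, rng)
        achieved.append((str(chrom), s0, e, k, got))
    vt, dt = emit_cohort(paths, freqs, loci, rng, labels=model.labels,
                         roh=roh, groups=groups)
    truth = SyntheticTruth(blocks=paths, deviant_regions=achieved,
                           roh=list(roh or []), seed=seed)
    return vt, dt, truth
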