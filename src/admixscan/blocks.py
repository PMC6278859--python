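"""Ancestry-block segmentation and block-length statistics.

Continuous ancestry dosages are rounded to integer copy numbers with
thresholds at 0.6 and 1.4; loci whose rounded copies do not sum to 2 are
flagged ambiguous and excluded. Blocks are maximal runs of a constant
positive copy number per ancestry, split at centromeres and chromosome
ends. Dosage level 2 is treated as one homozygous block covering both
haplotypes; haploid summaries weight blocks by their level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import DosageTensor

#: genome length (Mb) placed behind the canonical expected-count example
GENOME_LENGTH_MB = 3150.0


def round_dosages(dt: DosageTensor, low: float = 0.6, high: float = 1.4
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Round dosages to {0,1,2}: value < low -> 0, low..high -> 1,
    > high -> 2. Returns (calls, ambiguous mask) where ambiguous marks
    individual x locus entries whose rounded copies do not sum to 2."""
    d = dt.dose
    calls = np.where(d < low, 0, np.where(d > high, 2, 1)).astype(np.int8)
    calls[~np.isfinite(d)] = 0
    ambiguous = calls.sum(axis=2) != 2
    ambiguous |= ~np.isfinite(d).all(axis=2)
    return calls, ambiguous


def segment_blocks(calls: np.ndarray, loci: pd.DataFrame,
                   ambiguous: np.ndarray | None = None,
                   centromeres: list | None = None,
                   individuals: list | None = None,
                   labels: list | None = None) -> pd.DataFrame:
    """Maximal constant-level (>=1) runs per individual and ancestry.

    Output columns: individual, ancestry, level, chrom, start, end (0-based
    half-open at the outermost SNPs), n_snps. Runs break at chromosome ends,
    ambiguous loci, and any centromere interval they would span.
    """
    n, m, K = calls.shape
    individuals = individuals or [f"ind{i:04d}" for i in range(n)]
    labels = labels or [f"anc{k}" for k in range(K)]
    cen_by_chrom: dict[str, list] = {}
    for (c, s, e) in (centromeres or []):
        cen_by_chrom.setdefault(str(c), []).append((s, e))

    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    out = []
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[sel]
        cens = cen_by_chrom.get(str(chrom), [])
        # break between consecutive SNPs whose gap intersects a centromere;
        # SNPs inside a centromere are excluded from blocks entirely
        brk = np.zeros(len(sel), dtype=bool)  # break BEFORE snp t
        in_cen = np.zeros(len(sel), dtype=bool)
        pos0 = pos - 1
        for (cs, ce) in cens:
            brk[1:] |= (pos0[:-1] < ce) & (pos0[1:] >= cs)
            in_cen |= (pos0 >= cs) & (pos0 < ce)
        for i in range(n):
            amb = ambiguous[i, sel] if ambiguous is not None else \
                np.zeros(len(sel), dtype=bool)
            for k in range(K):
                lvl = calls[i, sel, k].astype(int)
                lvl = np.where(amb | in_cen, -9, lvl)
                t = 0
                while t < len(sel):
                    if lvl[t] < 1:
                        t += 1
                        continue
                    u = t
                    while (u + 1 < len(sel) and lvl[u + 1] == lvl[t]
                           and not brk[u + 1]):
                        u += 1
                    out.append((individuals[i], labels[k], int(lvl[t]),
                                str(chrom), int(pos[t] - 1), int(pos[u]),
                                u - t + 1))
                    t = u + 1
    return pd.DataFrame(out, columns=["individual", "ancestry", "level",
                                      "chrom", "start", "end", "n_snps"])


@dataclass
class BlockStats:
    per_ancestry: pd.DataFrame   # ancestry, count, mean_mb, lognorm_mu, lognorm_sigma, expected_n
    total_expected: int
    pairwise_p: dict             # (anc_a, anc_b) -> rank-sum p on lengths


def expected_block_counts(proportions, mean_lengths_mb, genome_length_mb
                          ) -> list[int]:
    """Expected blocks per haploid genome: N_k = round(p_k * L / mean_k)."""
    return [int(round(p * genome_length_mb / m))
            for p, m in zip(proportions, mean_lengths_mb)]


def block_stats(blocks: pd.DataFrame, proportions: dict[str, float],
                genome_length_mb: float) -> BlockStats:
    """Length means, lognormal MLE fits and expected haploid block counts.

    Lengths are level-weighted (a level-2 block counts as two haploid
    blocks of its length). Ancestries with no blocks get count 0 and
    undefined statistics.
    """
    rows = []
    lengths = {}
    for anc in proportions:
        sub = blocks[blocks["ancestry"] == anc]
        if len(sub) == 0:
            rows.append((anc, 0, np.nan, np.nan, np.nan, 0))
            lengths[anc] = np.array([])
            continue
        mb = (sub["end"] - sub["start"]).to_numpy(float) / 1e6
        w = sub["level"].to_numpy(float)
        mb_rep = np.repeat(mb, w.astype(int))
        lengths[anc] = mb_rep
        mean = float(mb_rep.mean())
        logs = np.log(mb_rep[mb_rep > 0])
        mu = float(logs.mean()) if len(logs) else np.nan
        sigma = float(logs.std(ddof=0)) if len(logs) > 1 else 0.0
        n_exp = int(round(proportions[anc] * genome_length_mb / mean))
        rows.append((anc, len(mb_rep), mean, mu, sigma, n_exp))
    per = pd.DataFrame(rows, columns=["ancestry", "count", "mean_mb",
                                      "lognorm_mu", "lognorm_sigma",
                                      "expected_n"])
    pairwise = {}
    ancs = list(proportions)
    for a in range(len(ancs)):
        for b in range(a + 1, len(ancs)):
            x, y = lengths[ancs[a]], lengths[ancs[b]]
            if len(x) and len(y):
                pairwise[(ancs[a], ancs[b])] = float(
                    stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return BlockStats(per_ancestry=per,
                      total_expected=int(per["expected_n"].sum()),
                      pairwise_p=pairwise)


def fit_lognormal(lengths: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood lognormal (mu, sigma) on positive lengths."""
    logs = np.log(np.asarray(lengths, float))
    return float(logs.mean()), float(logs.std(ddof=0))
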