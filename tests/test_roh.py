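"""ROH calling against a brute-force oracle, truth recovery, summaries and
the rank-sum test."""

import numpy as np
import pandas as pd
import pytest

from admixscan import roh, synthetic as syn
from admixscan.genotype_io import MISSING
from conftest import make_table


def brute_force_roh(pos, geno, cfg):
    """Direct window enumeration for one individual on one chromosome
    (independent of the production implementation)."""
    m = len(pos)
    het = geno == 1
    miss = geno == MISSING
    # window anchored at i: next window_snps SNPs, span capped at window_kb
    windows = []
    for i in range(m):
        members = [i]
        for j in range(i + 1, m):
            if len(members) >= cfg.window_snps:
                break
            if pos[j] >= pos[i] + cfg.window_kb * 1000.0:
                break
            members.append(j)
        ok = (sum(het[k] for k in members) <= cfg.max_het_per_window and
              sum(miss[k] for k in members) <= cfg.max_missing_per_window)
        windows.append((set(members), ok))
    eligible = []
    for j in range(m):
        containing = [ok for members, ok in windows if j in members]
        rate = sum(containing) / len(containing)
        eligible.append(rate >= cfg.hit_fraction)
    # maximal eligible runs with gap/length/density constraints
    segs = []
    run = []
    for j in range(m + 1):
        if j < m and eligible[j]:
            if run and pos[j] - pos[run[-1]] > cfg.max_gap_kb * 1000.0:
                segs.append(run)
                run = []
            run.append(j)
        else:
            if run:
                segs.append(run)
            run = []
    out = []
    for run in segs:
        first, last = run[0], run[-1]
        length_kb = (pos[last] - pos[first] + 1) / 1000.0
        n_snps = last - first + 1
        if length_kb < cfg.min_roh_kb:
            continue
        if length_kb / n_snps > cfg.min_density_kb_per_snp:
            continue
        out.append((int(pos[first] - 1), int(pos[last]), length_kb, n_snps))
    return out


class TestCallROH:
    def test_all_heterozygous_no_segments(self):
        vt = make_table(np.ones((1, 300), dtype=np.int8))
        assert len(roh.call_roh(vt)) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        m = 200
        # long homozygous stretches interrupted by occasional hets
        state = rng.random(m) < 0.07
        geno = np.where(state, 1, rng.choice([0, 2], size=m)).astype(np.int8)
        geno[rng.random(m) < 0.03] = MISSING
        # make part of the chromosome solidly homozygous
        a = int(rng.integers(0, m - 80))
        geno[a:a + 60] = np.where(rng.random(60) < 0.5, 0, 2)
        vt = make_table(geno[None, :], spacing=15_000)
        cfg = roh.ROHConfig()
        got = roh.call_roh(vt, cfg)
        pos = vt.variants["pos"].to_numpy().astype(float)
        want = brute_force_roh(pos, geno, cfg)
        assert len(got) == len(want)
        for (_, row), w in zip(got.iterrows(), want):
            assert (row["start"], row["end"]) == (w[0], w[1])
            assert row["length_kb"] == pytest.approx(w[2])
            assert row["n_snps"] == w[3]

    def test_injected_tract_recovered(self, small_cohort):
        vt, _, truth = small_cohort
        ind, chrom, s0, e = truth.roh[0]
        segs = roh.call_roh(vt)
        mine = segs[(segs["individual"] == vt.samples["id"][ind])
                    & (segs["chrom"] == chrom)]
        assert len(mine) == 1
        seg = mine.iloc[0]
        assert seg["category"] == "2-4"
        # boundaries within the hit-rate smoothing slack (a few SNP gaps)
        assert abs(seg["start"] - s0) <= 100_000
        assert abs(seg["end"] - e) <= 100_000

    def test_short_tract_rejected(self):
        vt, _, truth = syn.simulate_cohort(
            5, genome={"1": 40_000_000}, spacing_bp=20_000, seed=31,
            roh=[(0, "1", 20_000_000, 20_400_000)])
        segs = roh.call_roh(vt)
        ind0 = segs[segs["individual"] == vt.samples["id"][0]]
        for seg in ind0.itertuples():
            # any by-chance segment must not be the injected 400-kb tract
            assert not (abs(seg.start - 20_000_000) < 200_000)

    def test_relaxing_het_allowance_never_shrinks_total(self, small_cohort):
        vt, _, _ = small_cohort
        tight = roh.call_roh(vt, roh.ROHConfig(max_het_per_window=1))
        loose = roh.call_roh(vt, roh.ROHConfig(max_het_per_window=2))
        t1 = roh.per_individual_totals(tight, vt.samples)
        t2 = roh.per_individual_totals(loose, vt.samples)
        assert np.all(t2.to_numpy() >= t1.to_numpy() - 1e-9)

    def test_output_satisfies_constraints(self, small_cohort):
        vt, _, _ = small_cohort
        cfg = roh.ROHConfig()
        segs = roh.call_roh(vt, cfg)
        assert np.all(segs["length_kb"] >= cfg.min_roh_kb)
        density = segs["length_kb"] / segs["n_snps"]
        assert np.all(density <= cfg.min_density_kb_per_snp)


class TestSummaries:
    def test_worked_example_two_segments(self):
        segs = pd.DataFrame([
            ("i0", "1", 0, 800_000, 800.0, 40, "0.5-1", "<=1.6"),
            ("i0", "2", 0, 2_500_000, 2500.0, 120, "2-4", ">1.6"),
        ], columns=["individual", "chrom", "start", "end", "length_kb",
                    "n_snps", "category", "size_class"])
        samples = pd.DataFrame({"id": ["i0"], "group": ["G"]})
        out = roh.summarize_roh(segs, samples)
        row = out.iloc[0]
        assert row["total_mb"] == pytest.approx(3.3)
        assert row["n_segments"] == 2
        assert row["cat_0.5-1_mb"] == pytest.approx(0.8)
        assert row["cat_2-4_mb"] == pytest.approx(2.5)
        assert row["le1.6_mb"] == pytest.approx(0.8)
        assert row["gt1.6_mb"] == pytest.approx(2.5)

    def test_random_aggregation_matches_brute_force(self):
        rng = np.random.default_rng(33)
        rows = []
        inds = [f"i{k}" for k in range(6)]
        for _ in range(40):
            ind = rng.choice(inds)
            kb = float(rng.uniform(500, 20_000))
            rows.append((ind, "1", 0, int(kb * 1000), kb, 100,
                         roh.length_category(kb / 1000),
                         ">1.6" if kb / 1000 > 1.6 else "<=1.6"))
        segs = pd.DataFrame(rows, columns=[
            "individual", "chrom", "start", "end", "length_kb", "n_snps",
            "category", "size_class"])
        samples = pd.DataFrame({"id": inds,
                                "group": ["A"] * 3 + ["B"] * 3})
        out = roh.summarize_roh(segs, samples).set_index("group")
        for grp in ("A", "B"):
            members = [i for i, g in zip(inds, samples["group"]) if g == grp]
            tot = [segs[segs["individual"] == i]["length_kb"].sum() / 1000.0
                   for i in members]
            assert out.loc[grp, "total_mb"] == pytest.approx(np.mean(tot))

    def test_isolated_group_has_larger_mean_total(self):
        groups = ["isolated"] * 5 + ["open"] * 10
        injected = [(i, "1", 5_000_000 + 3_000_000 * i,
                     7_500_000 + 3_000_000 * i) for i in range(5)]
        vt, _, _ = syn.simulate_cohort(
            15, genome={"1": 60_000_000}, spacing_bp=20_000, seed=34,
            roh=injected, groups=groups)
        segs = roh.call_roh(vt)
        out = roh.summarize_roh(segs, vt.samples).set_index("group")
        assert out.loc["isolated", "total_mb"] > out.loc["open", "total_mb"]


class TestRankSum:
    def test_identical_samples_p_one(self):
        stat, p = roh.wilcoxon_rank_sum([3.0, 3.0], [3.0, 3.0])
        assert p == 1.0

    def test_exact_small_sample(self):
        # the most extreme of C(4,2)=6 orderings, two-sided
        _, p = roh.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(2.0 / 6.0)

    def test_bonferroni_for_island_pairs(self):
        # 7 islands -> 21 pairwise comparisons
        thr = roh.bonferroni_alpha(0.05, 21)
        assert thr == pytest.approx(2.4e-3, abs=0.05e-3)
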