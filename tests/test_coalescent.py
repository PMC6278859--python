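"""ms-dialect parsing, coalescent expectations, sample statistics and
empirical p-values."""

import math

import numpy as np
import pytest
from scipy import stats

from admixscan import coalescent as co
from admixscan.selection import hudson_fst_counts


class TestParser:
    def test_four_population_null_command(self):
        m = co.parse_ms_command(co.CANARIAN_NULL_COMMAND)
        assert (m.nsam, m.nreps, m.npop) == (28, 5000, 4)
        assert m.sample_config == [0, 0, 0, 28]
        assert m.theta == "tbs" and m.rho == "tbs"
        assert m.length_bp == 10_000
        times = sorted({e.time for e in m.events})
        assert times == [0.0005, 0.0135, 0.028985, 0.197963, 0.303501]
        joins = [e for e in m.events if e.kind == "ej"]
        assert len(joins) == 4
        splits = [e for e in m.events if e.kind == "es"]
        assert len(splits) == 1
        assert splits[0].params == (3, 0.1)   # pop 4, fraction kept 0.1
        assert m.total_pops == 5

    def test_minimal_command(self):
        m = co.parse_ms_command("ms 2 1 -t 1")
        assert (m.nsam, m.nreps, m.npop) == (2, 1, 1)
        assert m.theta == 1.0

    def test_unknown_flag_named_in_error(self):
        with pytest.raises(co.MsParseError, match="-G"):
            co.parse_ms_command("ms 4 1 -t 2 -G 5")

    def test_shell_redirections_ignored(self):
        m = co.parse_ms_command("./msHOT 4 2 -t 3 < thetas.txt > out.ms")
        assert m.nsam == 4 and m.theta == 3.0

    @pytest.mark.parametrize("seed", range(5))
    def test_serialize_parse_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            npop = int(rng.integers(1, 4))
            counts = rng.multinomial(12, np.ones(npop) / npop)
            cmd = f"ms 12 5 -t {rng.uniform(0.5, 9):.4f}"
            if npop > 1:
                cmd += " -I " + str(npop) + " " + " ".join(map(str, counts))
                for k in range(npop):
                    cmd += f" -n {k + 1} {rng.uniform(0.1, 3):.4f}"
                t = 0.0
                for _ in range(int(rng.integers(0, 3))):
                    t += rng.uniform(0.01, 0.2)
                    a, b = rng.choice(npop, 2, replace=False) + 1
                    cmd += f" -ej {t:.4f} {a} {b}"
            m1 = co.parse_ms_command(cmd)
            m2 = co.parse_ms_command(co.serialize_ms_command(m1))
            assert m1.model_hash() == m2.model_hash()


class TestCoalescentExpectations:
    def test_watterson_and_neutral_d(self):
        """Constant-size single population: E[S] = theta*a1 within 3 Monte
        Carlo SE; mean Tajima's D near 0."""
        theta, n, reps = 5.0, 10, 4000
        model = co.parse_ms_command(f"ms {n} {reps} -t {theta}")
        lp = co.LocusParams(theta=theta, rho=0.0, length_bp=100)
        S, D = [], []
        for haps, _ in co.simulate_replicates(model, lp, reps, seed=11):
            if haps.shape[1] == 0:
                S.append(0)
                continue
            s, pi, d = co.sample_stats(haps)
            S.append(s)
            if not math.isnan(d):
                D.append(d)
        a1 = sum(1.0 / i for i in range(1, n))
        se = np.std(S, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(S) - theta * a1) < 3 * se
        assert -0.1 < np.mean(D) < 0.1

    def test_high_migration_fst_vanishes(self):
        """4N0m = 100 between two demes drives Hudson FST below 0.01."""
        model = co.parse_ms_command("ms 40 1 -t 8 -I 2 20 20 100")
        fst = []
        lp = co.LocusParams(theta=8.0, rho=0.0, length_bp=100)
        for haps, _ in co.simulate_replicates(model, lp, 300, seed=12):
            if haps.shape[1] == 0:
                continue
            a, b = haps[:20], haps[20:]
            f = hudson_fst_counts(a.sum(0), np.full(haps.shape[1], 20),
                                  b.sum(0), np.full(haps.shape[1], 20))
            if math.isfinite(f):
                fst.append(f)
        assert abs(np.mean(fst)) < 0.01

    def test_recent_island_size_in_psmc_interval(self):
        """-en 0.0005 4 0.068 with N0=7310 puts the recent island deme at
        Ne ~ 497, inside the aboriginal 470-560 estimate."""
        m = co.parse_ms_command(co.CANARIAN_NULL_COMMAND)
        en = [e for e in m.events if e.kind == "en" and e.params[0] == 3][0]
        ne = en.params[1] * co.DEFAULT_N0
        assert 470 <= ne <= 560


class TestSampleStats:
    def test_no_variation(self):
        S, pi, D = co.sample_stats(np.zeros((2, 5), dtype=np.int8))
        assert S == 0 and pi == 0.0 and math.isnan(D)

    def test_pi_matches_pairwise_hamming(self):
        haps = np.array([[0, 0, 1, 1],
                         [1, 1, 0, 0],
                         [0, 0, 0, 0],
                         [1, 1, 1, 1]], dtype=np.int8)
        S, pi, D = co.sample_stats(haps)
        dists = []
        for a in range(4):
            for b in range(a + 1, 4):
                dists.append(np.sum(haps[a] != haps[b]))
        assert pi == pytest.approx(np.mean(dists))
        assert S == 4

    def test_random_pi_matches_brute_force(self):
        rng = np.random.default_rng(13)
        haps = (rng.random((12, 60)) < 0.35).astype(np.int8)
        _, pi, _ = co.sample_stats(haps)
        n = 12
        acc = 0
        for a in range(n):
            for b in range(a + 1, n):
                acc += np.sum(haps[a] != haps[b])
        assert pi == pytest.approx(acc / (n * (n - 1) / 2))

    def test_constants_for_28_haplotypes(self):
        k = co.tajima_constants(28)
        a1 = sum(1.0 / i for i in range(1, 28))
        assert k["a1"] == pytest.approx(a1, abs=1e-12)
        # independent check of the variance constants via Tajima's formulas
        n = 28
        a2 = sum(1.0 / i**2 for i in range(1, 28))
        b1 = (n + 1) / (3 * (n - 1))
        c1 = b1 - 1 / a1
        assert k["e1"] == pytest.approx(c1 / a1, abs=1e-12)

    def test_matches_tskit_oracle(self):
        """S, pi and D agree with tskit's branch-agnostic site statistics."""
        import msprime

        ts = msprime.sim_ancestry(10, sequence_length=1e4, ploidy=1,
                                  population_size=1e4, random_seed=5)
        mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=6,
                                    model=msprime.BinaryMutationModel(),
                                    discrete_genome=False)
        haps = (mts.genotype_matrix().T > 0).astype(np.int8)
        S, pi, D = co.sample_stats(haps)
        assert S == mts.num_sites
        assert pi == pytest.approx(
            mts.diversity(span_normalise=False), rel=1e-9)
        assert D == pytest.approx(mts.Tajimas_D(), rel=1e-9)


class TestNullEnsemble:
    def test_pbs_null_centered_under_neutrality(self):
        """Sampling the two reference demes alongside the focal sample
        yields a PBS null centered near zero."""
        model = co.parse_ms_command(co.CANARIAN_NULL_COMMAND)
        ens = co.simulate_null_ensemble(model, 7.3, 4.0, nreps=60, seed=16,
                                        pbs_pops=(1, 2),
                                        pbs_samples=(20, 20))
        assert set(ens.values) == {"D", "PBS"}
        assert abs(np.mean(ens.values["PBS"])) < 0.05

    def test_save_load_round_trip(self, tmp_path):
        ens = co.NullEnsemble(values={"D": np.arange(10.0)}, N=10,
                              model_hash="abc", seed=1)
        ens.save(tmp_path / "null.json")
        back = co.NullEnsemble.load(tmp_path / "null.json")
        np.testing.assert_array_equal(back.values["D"], ens.values["D"])
        assert back.model_hash == "abc"


class TestLocusParams:
    def test_randomized_theta_mean_and_variance(self):
        rng = np.random.default_rng(14)
        draws = [co.draw_locus_params(10.0, 0.0, rng).theta
                 for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(10.0, abs=0.3)
        assert np.var(draws) == pytest.approx(10.0, rel=0.15)

    def test_zero_theta_rejected(self):
        with pytest.raises(ValueError):
            co.draw_locus_params(0.0, 1.0, np.random.default_rng(0))

    def test_fixed_seed_reproducible(self):
        a = [co.draw_locus_params(5.0, 2.0, np.random.default_rng(99)).theta
             for _ in range(1)]
        b = [co.draw_locus_params(5.0, 2.0, np.random.default_rng(99)).theta
             for _ in range(1)]
        assert a == b


class TestEmpiricalP:
    def test_floored_below_all_nulls(self):
        null = np.linspace(-1, 1, 5000)
        ep = co.empirical_p(-2.0, null, tail="lower")
        assert ep.floored
        assert ep.p == pytest.approx(2.0e-4)
        assert str(ep).startswith("<")

    def test_median_gives_half(self):
        null = np.arange(1000, dtype=float)
        ep = co.empirical_p(499.5, null, tail="lower")
        assert ep.p == pytest.approx(0.5, abs=1.0 / 1000)

    def test_uniform_observations_give_uniform_p(self):
        rng = np.random.default_rng(15)
        null = rng.random(2000)
        obs = rng.random(500)
        ps = np.array([co.empirical_p(o, null, "lower").p for o in obs])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
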