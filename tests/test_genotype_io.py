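"""Format round-trips, coordinate policy and site extraction."""

import numpy as np
import pandas as pd
import pytest

from admixscan import genotype_io as gio
from conftest import make_table

TOY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr3>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr3\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1
chr3\t200\trs2\tC\tA,T\t.\tPASS\t.\tGT\t0/1\t1/1
chr3\t300\trs3\tT\tC\t.\tPASS\t.\tGT\t./.\t1/1
"""


class TestVCF:
    def test_multiallelic_records_dropped(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        vt = gio.read_vcf(p)
        assert vt.n_variants == 2
        assert list(vt.variants["id"]) == ["rs1", "rs3"]
        # chr prefix stripped
        assert list(vt.variants["chrom"].unique()) == ["3"]

    def test_missing_call_preserved(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        vt = gio.read_vcf(p)
        j = list(vt.variants["id"]).index("rs3")
        assert vt.calls[0, j] == gio.MISSING
        assert vt.calls[1, j] == 2

    def test_region_with_no_records_is_empty(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        vt = gio.read_vcf(p, region="3:1000-2000")
        assert vt.n_variants == 0

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        calls = rng.integers(-1, 3, size=(5, 20))
        vt = make_table(calls)
        p = tmp_path / "rt.vcf"
        gio.write_vcf(vt, p)
        back = gio.read_vcf(p)
        np.testing.assert_array_equal(back.calls, vt.calls)
        assert list(back.variants["pos"]) == list(vt.variants["pos"])

    def test_malformed_header_raises(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(gio.FormatError):
            gio.read_vcf(p)


class TestBED:
    def test_single_region_line_conversion(self, tmp_path):
        # a 1-based inclusive interval converts to 0-based half-open
        start0, end = gio.interval_to_internal(133_952_040, 144_266_489)
        assert (start0, end) == (133_952_039, 144_266_489)
        p = tmp_path / "one.bed"
        gio.write_bed_regions([("chr2", start0, end, "NAF_peak", 5.92)], p)
        lines = p.read_text().strip().split("\n")
        assert lines == ["2\t133952039\t144266489\tNAF_peak\t5.92"]

    def test_empty_list_gives_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        gio.write_bed_regions([], p)
        assert p.read_text() == ""

    def test_round_trip_random_regions(self, tmp_path):
        rng = np.random.default_rng(2)
        regions = []
        for i in range(100):
            s = int(rng.integers(0, 10**8))
            e = s + int(rng.integers(1, 10**6))
            regions.append((str(rng.integers(1, 23)), s, e, f"r{i}",
                            float(np.round(rng.random(), 4))))
        p = tmp_path / "many.bed"
        gio.write_bed_regions(regions, p)
        assert gio.read_bed_regions(p) == regions

    def test_invalid_interval_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            gio.write_bed_regions([("1", 100, 100, "x", 0)], tmp_path / "x.bed")


class TestDosage:
    def test_sum_tolerance_edges(self, tmp_path):
        loci = pd.DataFrame({"chrom": ["1", "1"], "pos": [100, 200]})
        good = np.array([[[1.2, 0.7, 0.1], [0.5, 0.5, 1.0]]])
        dt = gio.DosageTensor(["a"], loci, ["EUR", "NAF", "SSA"], good)
        gio.write_dosage(dt, tmp_path / "d.tsv", tmp_path / "l.tsv")
        back = gio.read_dosage(tmp_path / "d.tsv", 3, tmp_path / "l.tsv")
        assert back.n_rejected == 0
        np.testing.assert_allclose(back.dose, good, atol=1e-4)

        bad = np.array([[[1.2, 0.7, 0.4], [0.5, 0.5, 1.0]]])  # sums to 2.3
        dt = gio.DosageTensor(["a"], loci, ["EUR", "NAF", "SSA"], bad)
        gio.write_dosage(dt, tmp_path / "b.tsv", tmp_path / "l.tsv")
        with pytest.warns(UserWarning, match="rejected"):
            back = gio.read_dosage(tmp_path / "b.tsv", 3, tmp_path / "l.tsv")
        assert back.n_rejected == 1
        assert np.isnan(back.dose[0, 0]).all()

    def test_cohort_round_trip_equals_truth(self, tmp_path, small_cohort):
        _, dt, _ = small_cohort
        gio.write_dosage(dt, tmp_path / "d.tsv", tmp_path / "l.tsv")
        back = gio.read_dosage(tmp_path / "d.tsv", 3, tmp_path / "l.tsv")
        np.testing.assert_allclose(back.dose, dt.dose, atol=1e-4)
        assert back.labels == list(dt.labels)
        assert back.n_rejected == 0

    def test_k_mismatch_raises(self, tmp_path, small_cohort):
        _, dt, _ = small_cohort
        gio.write_dosage(dt, tmp_path / "d.tsv", tmp_path / "l.tsv")
        with pytest.raises(gio.FormatError):
            gio.read_dosage(tmp_path / "d.tsv", 4, tmp_path / "l.tsv")


class TestGenotypeTSV:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        vt = make_table(rng.integers(-1, 3, size=(8, 30)),
                        groups=["g1"] * 4 + ["g2"] * 4)
        gio.write_genotype_tsv(vt, tmp_path / "g.tsv")
        back = gio.read_genotype_tsv(tmp_path / "g.tsv")
        np.testing.assert_array_equal(back.calls, vt.calls)
        assert list(back.samples["group"]) == list(vt.samples["group"])


class TestGeneticMap:
    def test_uniform_interpolation_inverse(self):
        gmap = gio.GeneticMap.uniform({"1": 100_000_000}, cm_per_mb=1.2)
        bp = np.array([0, 25e6, 100e6])
        cm = gmap.cm_at("1", bp)
        np.testing.assert_allclose(cm, [0.0, 30.0, 120.0])
        np.testing.assert_allclose(gmap.bp_at("1", cm), bp)

    def test_tsv_round_trip(self, tmp_path):
        gmap = gio.GeneticMap.uniform({"1": 50_000_000, "2": 30_000_000})
        gmap.write_tsv(tmp_path / "map.tsv")
        back = gio.GeneticMap.read_tsv(tmp_path / "map.tsv")
        np.testing.assert_allclose(back.cm_at("2", 15e6), gmap.cm_at("2", 15e6))

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            gio.GeneticMap({"1": (np.array([0.0, 10.0, 5.0]),
                                  np.array([0.0, 1.0, 2.0]))})


class TestExtractSites:
    def test_known_frequency(self):
        vt = make_table(np.array([[0], [1], [1], [2]]))
        res = gio.extract_sites(vt, ["snp0"])
        assert res[0]["found"]
        assert res[0]["alt_freq"] == pytest.approx(0.5)

    def test_absent_target_not_detected(self):
        vt = make_table(np.zeros((2, 3)))
        res = gio.extract_sites(vt, [("1", 999_999), "rs_nowhere"])
        assert all(not r["found"] for r in res)

    def test_random_sites_match_brute_force(self):
        rng = np.random.default_rng(4)
        vt = make_table(rng.integers(-1, 3, size=(15, 40)))
        picks = rng.choice(40, size=10, replace=False)
        targets = [(vt.variants["chrom"][j], int(vt.variants["pos"][j]))
                   for j in picks]
        res = gio.extract_sites(vt, targets)
        for r, j in zip(res, picks):
            g = vt.calls[:, j]
            alt = hom = 0
            for c in g:
                if c != gio.MISSING:
                    alt += c
                    hom += 2
            assert r["alt_freq"] == pytest.approx(alt / hom)
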