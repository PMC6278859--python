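"""Genotype, dosage and interval I/O plus the in-memory data model.

Coordinate policy: VCF and reported positions are 1-based inclusive; every
internal interval (BED, ROH segments, ancestry blocks, region calls) is
0-based half-open. Chromosome labels are stored without a ``chr`` prefix.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: tolerance for the per-locus sum of ancestry dosages around 2.0
DOSAGE_SUM_TOL = 0.05


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


def normalize_chrom(label: str) -> str:
    """Canonical chromosome label: strip any leading ``chr`` prefix."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


# ---------------------------------------------------------------------------
# VariantTable
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Diploid genotype calls for a sample x variant panel.

    ``calls`` holds alt-allele counts {0,1,2} with ``MISSING`` (-1) for
    no-calls, shape (n_samples, n_variants). Only biallelic SNPs are stored;
    positions are 1-based and strictly increasing within a chromosome.
    """

    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt
    samples: pd.DataFrame   # columns: id, group
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"(n_samples={len(self.samples)}, n_variants={len(self.variants)})"
            )
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency; missing calls excluded."""
        ok = self.calls != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def het_rate(self) -> np.ndarray:
        """Per-variant observed heterozygosity over non-missing calls."""
        ok = self.calls != MISSING
        n = ok.sum(axis=0)
        het = (self.calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def take_variants(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.variants.iloc[idx], self.samples, self.calls[:, idx]
        )

    def take_samples(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.variants, self.samples.iloc[idx], self.calls[idx, :]
        )


# ---------------------------------------------------------------------------
# DosageTensor
# ---------------------------------------------------------------------------

@dataclass
class DosageTensor:
    """Per-individual local-ancestry dosages in [0, 2] for K ancestries.

    ``dose`` has shape (n_individuals, n_loci, K); for every individual and
    locus the K dosages sum to 2 within ``DOSAGE_SUM_TOL`` (entries rejected
    on read are NaN and counted in ``n_rejected``).
    """

    individuals: list[str]
    loci: pd.DataFrame      # columns: chrom, pos
    labels: list[str]
    dose: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        n, m, k = self.dose.shape
        if n != len(self.individuals) or m != len(self.loci) or k != len(self.labels):
            raise ValueError("dose shape inconsistent with labels/loci/individuals")

    @property
    def K(self) -> int:
        return len(self.labels)

    def validate(self, tol: float = DOSAGE_SUM_TOL) -> None:
        d = self.dose
        finite = np.isfinite(d).all(axis=2)
        if np.any((d[finite] < 0) | (d[finite] > 2)):
            raise ValueError("dosage entries outside [0, 2]")
        sums = d.sum(axis=2)[finite]
        if np.any(np.abs(sums - 2.0) > tol):
            raise ValueError("per-locus dosages do not sum to 2 within tolerance")


# ---------------------------------------------------------------------------
# GeneticMap
# ---------------------------------------------------------------------------

class GeneticMap:
    """Monotone bp <-> cM interpolation tables, one per chromosome."""

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in tables.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"map for {chrom} not monotone")
            self.tables[normalize_chrom(chrom)] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths_bp: dict[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls({
            c: (np.array([0.0, float(l)]),
                np.array([0.0, l / 1e6 * cm_per_mb]))
            for c, l in chrom_lengths_bp.items()
        })

    def chroms(self) -> list[str]:
        return list(self.tables)

    def cm_at(self, chrom: str, bp) -> np.ndarray:
        b, c = self.tables[normalize_chrom(chrom)]
        return np.interp(np.asarray(bp, dtype=float), b, c)

    def bp_at(self, chrom: str, cm) -> np.ndarray:
        b, c = self.tables[normalize_chrom(chrom)]
        return np.interp(np.asarray(cm, dtype=float), c, b)

    def length_cm(self, chrom: str) -> float:
        _, c = self.tables[normalize_chrom(chrom)]
        return float(c[-1] - c[0])

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", names=["chrom", "bp", "cm"], comment="#")
        return cls({
            str(ch): (g["bp"].to_numpy(float), g["cm"].to_numpy(float))
            for ch, g in df.groupby("chrom", sort=False)
        })

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (bp, cm) in self.tables.items():
                for b, c in zip(bp, cm):
                    fh.write(f"{chrom}\t{b:.0f}\t{c:.6f}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF 4.x file into a VariantTable.

    Multiallelic records and indels are dropped (not split). ``region`` is a
    ``chrom:start-end`` string with 1-based inclusive bounds; a region with
    no records yields an empty table.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    want_chrom = want_lo = want_hi = None
    if region is not None:
        chrom_part, _, span = region.partition(":")
        want_chrom = normalize_chrom(chrom_part)
        if span:
            lo, _, hi = span.partition("-")
            want_lo, want_hi = int(lo), int(hi)

    rows, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        chrom = normalize_chrom(v.CHROM)
        if want_chrom is not None:
            if chrom != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= v.POS <= want_hi):
                continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types
        call = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append((chrom, v.POS, v.ID or ".", v.REF, v.ALT[0]))
        cols.append(call.astype(np.int8))

    samples = pd.DataFrame({"id": list(vcf.samples), "group": ""})
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    if cols:
        calls = np.stack(cols, axis=1)
    else:
        calls = np.zeros((len(samples), 0), dtype=np.int8)
    return VariantTable(variants, samples, calls)


def write_vcf(vt: VariantTable, path) -> None:
    """Write a VariantTable as a minimal uncompressed VCF 4.2 file."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(vt.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples["id"]) + "\n")
        for j, row in vt.variants.iterrows():
            gts = "\t".join(gt_str[int(c)] for c in vt.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Plain-text genotype tables (sample x variant TSV, .ped/.map)
# ---------------------------------------------------------------------------

def write_genotype_tsv(vt: VariantTable, path) -> None:
    """TSV with one header row of variant ids and one row per sample."""
    with open(path, "w") as fh:
        fh.write("sample\tgroup\t" + "\t".join(
            f"{r.chrom}:{r.pos}:{r.id}" for r in vt.variants.itertuples()) + "\n")
        for i, s in vt.samples.iterrows():
            vals = "\t".join(str(int(c)) for c in vt.calls[i])
            fh.write(f"{s.id}\t{s.group}\t{vals}\n")


def read_genotype_tsv(path) -> VariantTable:
    df = pd.read_csv(path, sep="\t")
    meta = df.columns[2:]
    rows = []
    for col in meta:
        chrom, pos, vid = col.split(":", 2)
        rows.append((normalize_chrom(chrom), int(pos), vid, "A", "G"))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    samples = df[["sample", "group"]].rename(columns={"sample": "id"})
    samples["group"] = samples["group"].fillna("")
    calls = df[meta].to_numpy(dtype=np.int8)
    return VariantTable(variants, samples, calls)


def read_ped_map(ped_path, map_path) -> VariantTable:
    """Read PLINK-style text .ped/.map (alleles recoded to alt counts)."""
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "pos"])
    mp["chrom"] = mp["chrom"].map(normalize_chrom)
    sample_ids, groups, geno = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6 + 2 * len(mp):
                raise FormatError("short .ped line")
            groups.append(parts[0])
            sample_ids.append(parts[1])
            geno.append(parts[6:6 + 2 * len(mp)])
    geno = np.asarray(geno, dtype=object)
    a1 = geno[:, 0::2]
    a2 = geno[:, 1::2]
    calls = np.full((len(sample_ids), len(mp)), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(len(mp)):
        col = np.concatenate([a1[:, j], a2[:, j]])
        alleles = sorted(set(col) - {"0"})
        if len(alleles) > 2:
            raise FormatError(f"variant {mp['id'][j]} not biallelic")
        ref = alleles[0] if alleles else "A"
        alt = alleles[1] if len(alleles) > 1 else "G"
        refs.append(ref)
        alts.append(alt)
        ok = (a1[:, j] != "0") & (a2[:, j] != "0")
        calls[ok, j] = (a1[ok, j] == alt).astype(np.int8) + (a2[ok, j] == alt)
    variants = mp[["chrom", "pos", "id"]].copy()
    variants["ref"] = refs
    variants["alt"] = alts
    samples = pd.DataFrame({"id": sample_ids, "group": groups})
    return VariantTable(variants[["chrom", "pos", "id", "ref", "alt"]],
                        samples, calls)


# ---------------------------------------------------------------------------
# Ancestry dosage files (wide TSV + locus sidecar)
# ---------------------------------------------------------------------------

def write_dosage(dt: DosageTensor, path, loci_path) -> None:
    """Wide layout: one row per individual, K consecutive columns per locus."""
    dt.loci.assign(chrom=dt.loci["chrom"].map(normalize_chrom)).to_csv(
        loci_path, sep="\t", index=False, columns=["chrom", "pos"])
    n, m, k = dt.dose.shape
    flat = dt.dose.reshape(n, m * k)
    header = "individual\t" + "\t".join(
        f"L{j}_{lab}" for j in range(m) for lab in dt.labels)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, ind in enumerate(dt.individuals):
            fh.write(ind + "\t" + "\t".join(f"{x:.4f}" for x in flat[i]) + "\n")


def read_dosage(path, K: int, loci_path, labels: Sequence[str] | None = None,
                tol: float = DOSAGE_SUM_TOL) -> DosageTensor:
    """Read the wide dosage layout; entries violating the sum-to-2 tolerance
    (or the [0,2] range) are rejected (set NaN) and counted."""
    loci = pd.read_csv(loci_path, sep="\t")
    loci["chrom"] = loci["chrom"].map(normalize_chrom)
    df = pd.read_csv(path, sep="\t")
    individuals = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    n, total = vals.shape
    if total != len(loci) * K:
        raise FormatError(
            f"dosage file has {total} value columns, expected {len(loci)} loci x K={K}")
    dose = vals.reshape(n, len(loci), K)
    bad = (np.abs(dose.sum(axis=2) - 2.0) > tol) | \
          (dose < 0).any(axis=2) | (dose > 2).any(axis=2)
    n_rejected = int(bad.sum())
    if n_rejected:
        dose[bad] = np.nan
        warnings.warn(f"rejected {n_rejected} individual-locus dosage entries")
    if labels is None:
        first = [c.rsplit("_", 1)[-1] for c in df.columns[1:1 + K]]
        labels = first if len(set(first)) == K else [f"anc{k}" for k in range(K)]
    return DosageTensor(individuals, loci[["chrom", "pos"]], list(labels),
                        dose, n_rejected=n_rejected)


def long_to_wide_dosage(long_path, K: int) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Converter for the long dialect: one row per individual x locus:
    individual, chrom, pos, dose_1..dose_K. Returns (dose, loci, individuals)."""
    df = pd.read_csv(long_path, sep="\t")
    if df.shape[1] != 3 + K:
        raise FormatError(f"long dosage file must have 3+{K} columns")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    individuals = list(dict.fromkeys(df["individual"].astype(str)))
    loci = df[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    lkey = loci["chrom"].astype(str) + ":" + loci["pos"].astype(str)
    lidx = pd.Series(np.arange(len(loci)), index=lkey)
    iidx = pd.Series(np.arange(len(individuals)), index=individuals)
    dose = np.full((len(individuals), len(loci), K), np.nan)
    dose[iidx[df["individual"].astype(str)].to_numpy(),
         lidx[key].to_numpy(), :] = df.iloc[:, 3:].to_numpy(float)
    return dose, loci, individuals


# ---------------------------------------------------------------------------
# BED regions (0-based half-open)
# ---------------------------------------------------------------------------

def write_bed_regions(regions: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, name, score) tuples as BED5 lines."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in regions:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            fh.write(f"{normalize_chrom(chrom)}\t{int(start)}\t{int(end)}"
                     f"\t{name}\t{score}\n")


def read_bed_regions(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = normalize_chrom(parts[0]), int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            out.append((chrom, start, end, name, score))
    return out


def interval_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_1based


# ---------------------------------------------------------------------------
# Site extraction
# ---------------------------------------------------------------------------

def extract_sites(vt: VariantTable, targets: Sequence) -> list[dict]:
    """Look up target sites by (chrom, pos) tuple or by variant id.

    Absent targets are a result (``found=False``), not an error. Frequencies
    exclude missing calls from the denominator.
    """
    by_id = {vid: j for j, vid in enumerate(vt.variants["id"])}
    by_pos = {(c, p): j for j, (c, p) in
              enumerate(zip(vt.variants["chrom"], vt.variants["pos"]))}
    out = []
    for t in targets:
        if isinstance(t, tuple):
            j = by_pos.get((normalize_chrom(t[0]), int(t[1])))
        else:
            j = by_id.get(t)
        if j is None:
            out.append({"target": t, "found": False,
                        "genotypes": None, "alt_freq": np.nan})
            continue
        g = vt.calls[:, j]
        ok = g != MISSING
        freq = g[ok].sum() / (2.0 * ok.sum()) if ok.any() else np.nan
        out.append({"target": t, "found": True, "genotypes": g.copy(),
                    "alt_freq": float(freq)})
    return out
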