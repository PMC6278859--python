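"""End-to-end pipeline orchestration from a plain YAML config.

Stages: qc -> roh -> blocks -> zscan -> region_diversity -> selection ->
dating. Each enabled stage reads its inputs, writes TSV/JSON outputs under
the configured directory, and logs counts; a run manifest records the
package version, seeds and a config hash so mixed-run outputs are
detectable. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, blocks, coalescent, dating, genotype_io, qc, roh, scan, selection


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    # inputs
    genotypes_tsv: str | None = None
    vcf: str | None = None
    dosage_tsv: str | None = None
    dosage_loci: str | None = None
    dosage_k: int = 3
    genetic_map: str | None = None
    centromeres_bed: str | None = None
    # stage toggles
    stages: list = field(default_factory=lambda: ["qc", "roh", "blocks", "zscan"])
    # parameters
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    z_threshold: float = 3.0
    window_bp: int = 10_000
    null_replicates: int = 5_000
    ms_command: str | None = None
    theta_hat: float | None = None
    rho_hat: float | None = None
    selection_region: list | None = None  # [chrom, start, end]
    ancestry_proportions: dict = field(
        default_factory=lambda: {"EUR": 0.75, "NAF": 0.22, "SSA": 0.03})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_genotypes(cfg: PipelineConfig) -> genotype_io.VariantTable:
    if cfg.genotypes_tsv:
        return genotype_io.read_genotype_tsv(cfg.genotypes_tsv)
    if cfg.vcf:
        return genotype_io.read_vcf(cfg.vcf)
    raise ValueError("qc/roh stages need 'genotypes_tsv' or 'vcf' input")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    # validate inputs for enabled stages before executing anything
    needs_geno = {"qc", "roh", "region_diversity", "selection"}
    if needs_geno & set(cfg.stages) and not (cfg.genotypes_tsv or cfg.vcf):
        raise ValueError("enabled stages require genotype input")
    if {"blocks", "zscan"} & set(cfg.stages) and not cfg.dosage_tsv:
        raise ValueError("blocks/zscan stages require dosage input")

    vt = dt = None
    roh_segments = regions = None
    if needs_geno & set(cfg.stages):
        vt = _load_genotypes(cfg)
    if cfg.dosage_tsv:
        dt = genotype_io.read_dosage(cfg.dosage_tsv, cfg.dosage_k,
                                     cfg.dosage_loci)
    centromeres = []
    if cfg.centromeres_bed:
        centromeres = [(c, s, e) for c, s, e, *_ in
                       genotype_io.read_bed_regions(cfg.centromeres_bed)]

    for stage in cfg.stages:
        log: dict = {}
        if stage == "qc":
            qcfg = qc.QCConfig(**cfg.qc)
            vt, report = qc.filter_genotypes(vt, qcfg)
            log = {"removed": report, "variants_out": vt.n_variants,
                   "samples_out": vt.n_samples}
            pd.DataFrame(report.items(), columns=["reason", "count"]).to_csv(
                out / "qc_report.tsv", sep="\t", index=False)
        elif stage == "roh":
            rcfg = roh.ROHConfig(**cfg.roh)
            roh_segments = roh.call_roh(vt, rcfg)
            roh_segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
            summary = roh.summarize_roh(roh_segments, vt.samples)
            summary.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
            log = {"segments": len(roh_segments)}
        elif stage == "blocks":
            calls, amb = blocks.round_dosages(dt)
            blk = blocks.segment_blocks(calls, dt.loci, ambiguous=amb,
                                        centromeres=centromeres,
                                        individuals=dt.individuals,
                                        labels=dt.labels)
            blk.to_csv(out / "ancestry_blocks.tsv", sep="\t", index=False)
            span_mb = sum(
                (g["pos"].max() - g["pos"].min()) / 1e6
                for _, g in dt.loci.groupby("chrom"))
            st = blocks.block_stats(blk, cfg.ancestry_proportions, span_mb)
            st.per_ancestry.to_csv(out / "block_stats.tsv", sep="\t",
                                   index=False)
            log = {"blocks": len(blk), "ambiguous_entries": int(amb.sum())}
        elif stage == "zscan":
            zs = scan.zscore_scan(dt)
            track = zs.loci.copy()
            for k, lab in enumerate(zs.labels):
                track[f"Z_{lab}"] = zs.z[:, k]
            track.to_csv(out / "zscan_track.tsv", sep="\t", index=False)
            regions = scan.call_regions(zs, threshold=cfg.z_threshold)
            regions.to_csv(out / "zscan_regions.tsv", sep="\t", index=False)
            if len(regions):
                genotype_io.write_bed_regions(
                    [(r.chrom, r.start, r.end, f"{r.ancestry}_peak",
                      round(r.lead_z, 3)) for r in regions.itertuples()],
                    out / "zscan_regions.bed")
            log = {"regions": len(regions)}
        elif stage == "region_diversity":
            if regions is None or roh_segments is None:
                raise ValueError("region_diversity requires zscan and roh")
            div = scan.region_diversity(vt, roh_segments, regions,
                                        m_tests=max(len(regions), 1))
            div.to_csv(out / "region_diversity.tsv", sep="\t", index=False)
            log = {"regions": len(div)}
        elif stage == "selection":
            if not (cfg.ms_command and cfg.theta_hat and cfg.selection_region):
                raise ValueError("selection requires ms_command, theta_hat "
                                 "and selection_region")
            model = coalescent.parse_ms_command(cfg.ms_command)
            null = coalescent.simulate_null_ensemble(
                model, cfg.theta_hat, cfg.rho_hat or 0.0,
                nreps=cfg.null_replicates, seed=cfg.seed)
            chrom, s, e = cfg.selection_region
            win = selection.window_stats(vt, str(chrom), int(s), int(e),
                                         window_bp=cfg.window_bp)
            win = selection.selection_scan(win, null, m_d=len(win))
            win.to_csv(out / "selection_windows.tsv", sep="\t", index=False)
            log = {"windows": len(win)}
        elif stage == "dating":
            raise ValueError("dating stage requires reference panels; "
                             "use admixscan.dating directly or the CLI")
        else:
            raise ValueError(f"unknown stage: {stage}")
        manifest["stages"][stage] = log

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
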