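"""End-to-end orchestration: simulate -> QC -> LAI grid -> consensus -> nSL -> stats.

The demo pipeline reproduces the full analysis chain on the synthetic study
generator, where the true ancestry mosaic is known, and writes a summary
JSON with the quantities a study of adaptive introgression reports: the
global minor-ancestry fraction, window-level painting accuracy against the
truth, consensus-introgression regions with their truth support, sweep
intervals and their overlap with consensus regions, and per-population
diversity statistics. Every output directory carries the resolved
configuration and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import popstats
from .ciwi import ConsensusIntrogressionModel, annotate_regions
from .io import read_gene_intervals
from .lai import window_accuracy
from .qc import filter_markers
from .simulate import SimConfig, generate_study
from .sweep import NslScan

log = logging.getLogger("admixscan")

__all__ = ["PipelineConfig", "run_demo"]


@dataclass
class PipelineConfig:
    """Flat configuration for the demo pipeline (YAML-loadable)."""

    outdir: str = "demo_out"
    seed: int = 0
    # synthetic study; sweep is (center_cM, halfwidth_cM, carrier_fraction) or null
    sim: dict = field(default_factory=dict)
    sweep_tract: tuple | None = (50.2, 0.6, 0.9)
    # QC
    maf_min: float = 0.01
    callrate_min: float = 0.9
    # LAI / consensus
    window_snps: int = 20
    smoothing_g: float = 100.0
    top_pct_broad: float = 5.0
    top_pct_strict: float = 1.0
    max_gap_windows: int = 1
    # selection scan
    run_sweep_scan: bool = True
    nsl_maf_min: float = 0.05
    nsl_bins: int = 20
    call_threshold: float = 2.0
    spline_lam: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        if cfg.sweep_tract is not None:
            cfg.sweep_tract = tuple(cfg.sweep_tract)
        return cfg

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("sweep", self.sweep_tract)
        return SimConfig(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def _demo_genes(sim: SimConfig) -> list:
    """Deterministic synthetic gene intervals: a sparse backbone plus genes
    inside the injected tract (so annotation has something to find)."""
    genes = []
    length_bp = int(sim.chrom_length_cM * 1e6)
    for k in range(10):
        start = int((k + 0.5) * length_bp / 10)
        genes.append((sim.chrom, start, start + 60_000, f"GENE{k+1:02d}"))
    if sim.sweep is not None:
        center_bp = int(sim.sweep[0] * 1e6)
        genes.append((sim.chrom, center_bp - 40_000, center_bp + 20_000, "TRACTG1"))
        genes.append((sim.chrom, center_bp + 120_000, center_bp + 180_000, "TRACTG2"))
    return sorted(genes, key=lambda g: g[1])


def run_demo(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic study; returns the summary dict.

    Writes into ``config.outdir``: the simulated inputs, per-stage tables
    (QC report, consensus table, regions BED/JSON, scan TSV, diversity TSVs)
    and ``summary.json``. Fully reproducible per seed.
    """
    os.makedirs(config.outdir, exist_ok=True)
    config.to_json(os.path.join(config.outdir, "resolved_config.json"))
    summary: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        sim = config.sim_config()
        study = generate_study(sim, os.path.join(config.outdir, "sim"))
        log.info("stage=simulate samples=%d markers=%d", study.panel.n_samples, sim.n_markers)

        stage = "qc"
        panel, qc_report = filter_markers(study.panel, config.maf_min, config.callrate_min)
        with open(os.path.join(config.outdir, "qc_report.json"), "w") as fh:
            json.dump(qc_report.to_dict(), fh, indent=2)
        log.info("stage=qc in=%d retained=%d", qc_report.n_input_markers, qc_report.n_retained)
        orig_keys = pd.MultiIndex.from_arrays(
            [study.panel.markers.chrom, study.panel.markers.pos_bp]
        )
        kept_keys = pd.MultiIndex.from_arrays([panel.markers.chrom, panel.markers.pos_bp])
        truth_labels = study.truth.labels[:, orig_keys.isin(kept_keys)]

        stage = "ciwi"
        model = ConsensusIntrogressionModel(
            panel,
            sim.target_pop,
            sim.ref_pops_A,
            sim.ref_pops_B,
            window_snps=config.window_snps,
            smoothing_g=config.smoothing_g,
        )
        ciwi_res = model.fit()
        ciwi_res.to_tsv(os.path.join(config.outdir, "ciwi_table.tsv"))
        windows = ciwi_res.windows
        truth_win = (
            np.stack(
                [
                    truth_labels[:, s:e].mean(axis=1) >= 0.5
                    for s, e in zip(windows.m_start, windows.m_end)
                ],
                axis=1,
            ).astype(np.int8)
        )
        accs = {
            f"{a}x{b}": window_accuracy(res.labels, truth_win)
            for (a, b), res in ciwi_res.track_sets.items()
        }
        truth_win_freq = truth_win.mean(axis=0)
        first = next(iter(ciwi_res.track_sets.values()))
        summary["lai"] = {
            "window_accuracy_by_combination": accs,
            "window_accuracy_mean": float(np.mean(list(accs.values()))),
            "global_b_fraction_estimate": first.global_b_fraction(),
            "global_b_fraction_truth": float(truth_labels.mean()),
        }
        log.info("stage=ciwi combos=%d windows=%d", len(ciwi_res.combinations), windows.n_windows)

        genes_path = os.path.join(config.outdir, "genes.bed")
        with open(genes_path, "w") as fh:
            for chrom, start, end, name in _demo_genes(sim):
                fh.write(f"{chrom}\t{start-1}\t{end}\t{name}\n")
        genes = read_gene_intervals(genes_path)

        regions = {}
        for label, pct in (("broad", config.top_pct_broad), ("strict", config.top_pct_strict)):
            regs = annotate_regions(
                ciwi_res.call_regions(top_pct=pct, max_gap_windows=config.max_gap_windows),
                genes,
            )
            regions[label] = regs
            with open(os.path.join(config.outdir, f"regions_top{pct:g}pct.json"), "w") as fh:
                json.dump(
                    [
                        {
                            "chrom": str(r.chrom),
                            "start_bp": r.start_bp,
                            "end_bp": r.end_bp,
                            "n_windows": len(r.windows),
                            "peak_score": r.peak_s,
                            "min_consistency": r.min_c,
                            "genes": r.genes,
                            "truth_b_frequency": float(
                                np.mean(truth_win_freq[r.windows])
                            ),
                        }
                        for r in regs
                    ],
                    fh,
                    indent=2,
                )
        summary["ciwi"] = {
            "n_regions_broad": len(regions["broad"]),
            "n_regions_strict": len(regions["strict"]),
            "strict_regions": [
                {
                    "chrom": str(r.chrom),
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "peak_score": r.peak_s,
                    "min_consistency": r.min_c,
                    "genes": r.genes,
                    "truth_b_frequency": float(np.mean(truth_win_freq[r.windows])),
                }
                for r in regions["strict"]
            ],
        }

        stage = "sweep"
        if config.run_sweep_scan:
            scan = NslScan(
                panel, pop=sim.target_pop, maf_min=config.nsl_maf_min, n_bins=config.nsl_bins
            ).fit()
            scan.smooth(lam=config.spline_lam, call_threshold=config.call_threshold)
            scan.to_tsv(os.path.join(config.outdir, "nsl_scan.tsv"))
            overlap = scan.overlap_report(regions["strict"])
            overlap.to_csv(
                os.path.join(config.outdir, "sweep_ciwi_overlap.tsv"), sep="\t", index=False
            )
            summary["sweep"] = {
                "intervals": [
                    [str(c), s, e] for c, s, e in scan.sweep_intervals
                ],
                "ciwi_overlap_fractions": overlap["overlap_fraction"].tolist(),
            }
            log.info("stage=sweep intervals=%d", len(scan.sweep_intervals))
        else:
            summary["sweep"] = {"intervals": [], "ciwi_overlap_fractions": []}

        stage = "stats"
        genos = panel.to_genotypes()
        div = popstats.observed_het(genos)
        div.to_csv(os.path.join(config.outdir, "diversity.tsv"), sep="\t", index=False)
        rohs = popstats.roh_and_froh(genos)
        rohs.by_population.to_csv(
            os.path.join(config.outdir, "froh.tsv"), sep="\t", index=False
        )
        freqs = {p: panel.allele_frequencies(p) for p in panel.populations()}
        dmat = popstats.reynolds_matrix(freqs)
        popstats.write_phylip(dmat, os.path.join(config.outdir, "reynolds.phylip"))
        popstats.write_nexus_distances(dmat, os.path.join(config.outdir, "reynolds.nex"))
        summary["popstats"] = {
            "observed_het": {
                row["pop"]: round(row["ho_mean"], 6) for _, row in div.iterrows()
            },
            "froh_mean": {
                row["pop"]: round(row["froh_mean"], 6)
                for _, row in rohs.by_population.iterrows()
            },
            "reynolds_target_vs_refs": {
                p: round(float(dmat.loc[sim.target_pop, p]), 6)
                for p in sim.ref_pops_A + sim.ref_pops_B
            },
        }
        log.info("stage=stats populations=%d", len(div))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
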