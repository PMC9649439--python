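"""End-to-end orchestration: simulate -> reconstruct -> enrich -> phase -> methyl.

A run configuration (a YAML-able mapping) names the input files per stage
and surfaces every analysis threshold with its default.  Stages execute
independently: a failure is recorded on the report and only stages that
depend on the failed one are skipped.  Reports are reproducible — rerunning
the same configuration (same seed) yields an identical report hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import camper, enrichment, graph_model, methylation, phasing, synthdata

logger = logging.getLogger("ecdna_catch")

#: Analysis thresholds surfaced in every run configuration.
DEFAULT_THRESHOLDS = {
    "background_cn": 2.0,
    "edge_utilization_threshold": camper.DEFAULT_EDGE_UTILIZATION_THRESHOLD,
    "t_ec": phasing.T_ECDNA_VAF,
    "t_wgs_hi": phasing.T_WGS_NONHOM,
    "t_chr": phasing.T_CHROM_WGS,
    "t_hom": phasing.T_HOM_WGS,
    "min_depth": phasing.MIN_DEPTH,
    "window_bp": methylation.WINDOW_BP,
    "step_bp": methylation.STEP_BP,
    "categorize_threshold": methylation.CATEGORIZE_THRESHOLD,
    "peak_score_min": methylation.PEAK_SCORE_MIN,
    "min_site_coverage": methylation.MIN_SITE_COVERAGE,
    "significance_alpha": methylation.SIGNIFICANCE_ALPHA,
}

STAGES = ("simulate", "reconstruct", "enrich", "phase", "methyl")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: bool = False
    sim_options: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    band: tuple[float, float] | None = None
    cuts: list[tuple[str, int]] = field(default_factory=list)
    wgs_sample: str = synthdata.WGS_SAMPLE
    ecdna_samples: list[str] = field(default_factory=lambda: list(synthdata.ECDNA_SAMPLES))
    skip: list[str] = field(default_factory=list)
    thresholds: dict[str, Any] = field(default_factory=dict)

    def threshold(self, name: str):
        return self.thresholds.get(name, DEFAULT_THRESHOLDS[name])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["thresholds"] = {**DEFAULT_THRESHOLDS, **self.thresholds}
        d.pop("out_dir", None)  # run location does not change the analysis
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    stage_status: dict[str, str] = field(default_factory=dict)
    candidates: list[dict] = field(default_factory=list)
    truncated: bool = False
    compression_zone: bool = False
    enrichment: dict | None = None
    phasing_counts: dict[str, int] = field(default_factory=dict)
    differential_peaks: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_all(config: RunConfig) -> RunReport:
    """Execute all configured stages, isolating failures per stage."""
    report = RunReport(config_hash=config.config_hash)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.inputs)

    if config.simulate and "simulate" not in config.skip:
        try:
            sim_cfg = synthdata.SimConfig(seed=config.seed, **config.sim_options)
            manifest = synthdata.simulate_all(sim_cfg, out / "sim")
            inputs = {**manifest, **inputs}
            with open(manifest["band"]) as fh:
                band_info = json.load(fh)
            if config.band is None:
                config.band = (band_info["size_min_kb"], band_info["size_max_kb"])
            if not config.cuts:
                with open(manifest["cuts"]) as fh:
                    config.cuts = [
                        (ln.split("\t")[0], int(ln.split("\t")[1]))
                        for ln in fh if ln.strip()
                    ]
            report.stage_status["simulate"] = "ok"
        except Exception as err:  # noqa: BLE001 - stage isolation
            logger.exception("simulate stage failed")
            report.stage_status["simulate"] = f"failed: {err}"
            for stage in STAGES[1:]:
                report.stage_status[stage] = "skipped: simulate failed"
            return report
    else:
        report.stage_status["simulate"] = "skipped"

    _run_reconstruct(config, inputs, out, report)
    _run_enrich(config, inputs, out, report)
    _run_phase(config, inputs, report)
    _run_methyl(config, inputs, out, report)
    return report


def _run_reconstruct(config, inputs, out, report) -> None:
    if "reconstruct" in config.skip:
        report.stage_status["reconstruct"] = "skipped"
        return
    if "graph" not in inputs:
        report.stage_status["reconstruct"] = "skipped: no graph input"
        return
    if config.band is None:
        logger.warning("no band window configured; reconstruction skipped")
        report.stage_status["reconstruct"] = "skipped: no band window"
        return
    try:
        graph = graph_model.parse_graph_file(inputs["graph"])
        background = config.threshold("background_cn")
        mult = graph_model.estimate_multiplicities(graph, background_cn=background)
        band = graph_model.GelBand(size_min_kb=config.band[0], size_max_kb=config.band[1])
        cuts = [graph_model.CutSite(chrom=c, position=p, guide=f"g{i}")
                for i, (c, p) in enumerate(config.cuts)]
        options = camper.EnumerationOptions(
            band=band, cuts=cuts,
            edge_utilization_threshold=config.threshold("edge_utilization_threshold"),
        )
        logger.info("reconstruct: band=%s cuts=%d background_cn=%s",
                    config.band, len(cuts), background)
        result = camper.enumerate_candidates(graph, mult, options)
        report.truncated = result.truncated
        report.compression_zone = result.compression_zone
        report.candidates = [
            {
                "segments": camper.canonical_key_str(c.canonical),
                "length_bp": c.length_bp,
                "composite": c.scores.composite if c.scores else None,
                "pass_filter": c.pass_filter,
            }
            for c in result.candidates
        ]
        if result.candidates:
            camper.write_cycles(result.candidates, graph, out / "candidates.cycles")
            camper.write_bed(result.candidates, graph, out / "candidates.bed")
        camper.write_score_report(result, out / "candidates.json")
        report.stage_status["reconstruct"] = "ok"
    except Exception as err:  # noqa: BLE001
        logger.exception("reconstruct stage failed")
        report.stage_status["reconstruct"] = f"failed: {err}"


def _run_enrich(config, inputs, out, report) -> None:
    if "enrich" in config.skip:
        report.stage_status["enrich"] = "skipped"
        return
    if "coverage_enriched" not in inputs:
        report.stage_status["enrich"] = "skipped: no coverage input"
        return
    try:
        enriched = enrichment.read_bedgraph(inputs["coverage_enriched"])
        wgs = (enrichment.read_bedgraph(inputs["coverage_wgs"])
               if "coverage_wgs" in inputs else None)
        if "graph" in inputs:
            graph = graph_model.parse_graph_file(inputs["graph"])
            amplicon = [(s.chrom, s.start, s.end) for s in graph.segments]
        else:
            amp = enriched.bins[enriched.bins["chrom"] != "chrBg"]
            amplicon = [(str(c), int(g["start"].min()), int(g["end"].max()))
                        for c, g in amp.groupby("chrom")]
        band = (graph_model.GelBand(*config.band) if config.band else None)
        length = report.candidates[0]["length_bp"] if report.candidates else None
        rep = enrichment.enrichment_report(
            enriched, wgs, amplicon,
            length_bp=length, band=band if length else None,
        )
        rep.to_json(out / "enrichment.json")
        report.enrichment = {
            "on_amplicon_fraction": rep.on_amplicon_fraction,
            "wgs_fraction": rep.wgs_fraction,
            "fold_enrichment": rep.fold_enrichment,
            "enriched": rep.enriched,
        }
        report.stage_status["enrich"] = "ok"
    except Exception as err:  # noqa: BLE001
        logger.exception("enrich stage failed")
        report.stage_status["enrich"] = f"failed: {err}"


def _run_phase(config, inputs, report) -> None:
    if "phase" in config.skip:
        report.stage_status["phase"] = "skipped"
        return
    if "variants" not in inputs:
        report.stage_status["phase"] = "skipped: no variant table"
        return
    try:
        records = phasing.read_variant_table(inputs["variants"])
        phased = phasing.phase_variants(
            records, config.wgs_sample, config.ecdna_samples,
            min_depth=config.threshold("min_depth"),
            t_ec=config.threshold("t_ec"), t_wgs_hi=config.threshold("t_wgs_hi"),
            t_chr=config.threshold("t_chr"), t_hom=config.threshold("t_hom"),
        )
        report.phasing_counts = dict(phasing.class_counts(phased))
        report.stage_status["phase"] = "ok"
    except Exception as err:  # noqa: BLE001
        logger.exception("phase stage failed")
        report.stage_status["phase"] = f"failed: {err}"


def _run_methyl(config, inputs, out, report) -> None:
    if "methyl" in config.skip:
        report.stage_status["methyl"] = "skipped"
        return
    needed = {"methylation_ecdna", "methylation_chromosomal", "peaks"}
    if not needed <= set(inputs):
        report.stage_status["methyl"] = "skipped: missing methylation inputs"
        return
    try:
        thr = config.threshold("categorize_threshold")
        ec = methylation.site_frequencies(
            methylation.harmonize_strands(methylation.read_calls(inputs["methylation_ecdna"])), thr)
        ch = methylation.site_frequencies(
            methylation.harmonize_strands(methylation.read_calls(inputs["methylation_chromosomal"])), thr)
        peaks = methylation.filter_peaks(
            pd.read_csv(inputs["peaks"], sep="\t"),
            min_score=config.threshold("peak_score_min"),
        )
        results = methylation.differential_peak_test(
            ec, ch, peaks,
            min_coverage=config.threshold("min_site_coverage"),
            alpha=config.threshold("significance_alpha"),
        )
        methylation.write_diff_results(results, out / "differential_methylation.tsv")
        report.differential_peaks = [dataclasses.asdict(r) for r in results]
        report.stage_status["methyl"] = "ok"
    except Exception as err:  # noqa: BLE001
        logger.exception("methyl stage failed")
        report.stage_status["methyl"] = f"failed: {err}"


def summarize(report: RunReport, path) -> dict:
    """Write a JSON summary plus a short human-readable digest; returns the dict."""
    payload = report.to_dict()
    payload["report_hash"] = report.report_hash
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    text = path.with_suffix(".txt")
    lines = [f"run {report.config_hash} (report {report.report_hash})"]
    for stage in STAGES:
        lines.append(f"  {stage}: {report.stage_status.get(stage, 'not run')}")
    lines.append(f"  candidates: {len(report.candidates)}")
    if report.enrichment:
        fe = report.enrichment.get("fold_enrichment")
        lines.append(f"  fold enrichment: {fe if fe is None else f'{fe:.1f}'}")
    if report.phasing_counts:
        lines.append("  phasing: " + ", ".join(
            f"{k}={v}" for k, v in sorted(report.phasing_counts.items())))
    n_sig = sum(1 for r in report.differential_peaks if r.get("significant"))
    lines.append(f"  differential peaks: {len(report.differential_peaks)} tested, {n_sig} significant")
    text.write_text("\n".join(lines) + "\n")
    return payload


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
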