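"""End-to-end pipeline: peaks -> expression -> motif -> classification.

Stages run in a fixed order on either a simulated bundle or files loaded by
the CLI; any stage failure is re-raised with the stage name attached.  The
result bundle is written as TSV/BED/JSON reports plus a provenance record
(config hash, package version, input checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import glnreg
from glnreg.config import RunConfig
from glnreg.expression import dependence
from glnreg.motif import (BipartiteConsensus, annotate_regions_with_sites,
                          build_pwm, genome_background, promoter_windows)
from glnreg.peaks import (PeakCallParams, assign_targets, call_peaks_single,
                          count_binding_regions, merge_replicates,
                          regions_to_frame, union_binding_regions,
                          write_regions_bed)
from glnreg.regulon import classify, regulon_report
from glnreg.simulate import SimBundle, SimScenario, simulate_all


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    regions: list = field(default_factory=list)
    control_filtered: list = field(default_factory=list)
    regions_by_timepoint: dict = field(default_factory=dict)
    dependence_calls: pd.DataFrame | None = None
    motif_table: pd.DataFrame | None = None
    pwm: object | None = None
    records: list = field(default_factory=list)
    report: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def scenario_from_config(config: RunConfig) -> SimScenario:
    sc = config.scenario
    return SimScenario(seed=config.seed,
                       replicon_length=sc.replicon_length,
                       n_genes=sc.n_genes,
                       probe_spacing=sc.probe_spacing,
                       probe_length=sc.probe_length,
                       n_planted_sites=sc.n_planted_sites,
                       n_artefact_sites=sc.n_artefact_sites,
                       chip_noise_sd_log2=sc.chip_noise_sd_log2,
                       expr_noise_sd_log2=sc.expr_noise_sd_log2,
                       n_chip_replicates=sc.n_chip_replicates,
                       n_dependent=sc.n_dependent,
                       n_independent=sc.n_independent,
                       n_null=sc.n_null)


def call_binding_regions(bundle: SimBundle, params: PeakCallParams):
    """Per-timepoint peak calling + replicate merge + control subtraction."""
    regions_by_tp: dict[str, list] = {}
    filtered_all: list = []
    for tp, tracks in bundle.tracks.items():
        ip = {t.replicate_id: call_peaks_single(t, params)
              for t in tracks if not t.is_control}
        control_peaks = [p for t in tracks if t.is_control
                         for p in call_peaks_single(t, params)]
        reported, filtered = merge_replicates(ip, control_peaks, params)
        assign_targets(reported, bundle.annotation)
        regions_by_tp[tp] = reported
        filtered_all.extend(filtered)
    union = union_binding_regions(regions_by_tp.values())
    assign_targets(union, bundle.annotation)
    return regions_by_tp, union, filtered_all


def run_pipeline(config: RunConfig,
                 bundle: SimBundle | None = None,
                 write: bool = True) -> PipelineResult:
    """Execute every stage on a simulated (or supplied) dataset."""
    result = PipelineResult()
    outdir = Path(config.outdir)

    try:
        if bundle is None:
            bundle = simulate_all(scenario_from_config(config))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    try:
        params = PeakCallParams(**config.peaks.model_dump())
        regions_by_tp, union, filtered = call_binding_regions(bundle, params)
        result.regions_by_timepoint = regions_by_tp
        result.regions = union
        result.control_filtered = filtered
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("peaks", exc) from exc

    try:
        ex = config.expression
        result.dependence_calls = dependence(
            bundle.expression, ex.wt_strain, ex.mutant_strain,
            theta_wt=ex.theta,
            theta_responsive_mutant=ex.theta_responsive_mutant)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression", exc) from exc

    try:
        mo = config.motif
        consensus = BipartiteConsensus(half_site_a=mo.half_site_a,
                                       half_site_b=mo.half_site_b,
                                       spacer_min=mo.spacer_min,
                                       spacer_max=mo.spacer_max)
        windows = promoter_windows(result.regions, bundle.sequences,
                                   width=mo.window)
        result.motif_table = annotate_regions_with_sites(
            result.regions, windows, consensus)
        sites = [s for cell in result.motif_table["sites"]
                 if cell != "n/a" for s in cell.split(";")]
        if len(sites) >= 2 and len({len(s) for s in sites}) == 1:
            result.pwm = build_pwm(sites, pseudocount=mo.pseudocount,
                                   background=genome_background(
                                       bundle.sequences))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("motif", exc) from exc

    try:
        result.records = classify(result.dependence_calls, result.regions,
                                  result.motif_table)
        result.report, result.summary = regulon_report(
            result.records, regions=result.regions)
        n_total, per_tp = count_binding_regions(result.regions)
        result.summary["n_regions_per_timepoint"] = per_tp.to_dict()
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", exc) from exc

    if write:
        try:
            _write_outputs(config, bundle, result, outdir)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("report", exc) from exc
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_outputs(config: RunConfig, bundle: SimBundle,
                   result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    regions_to_frame(result.regions).to_csv(
        outdir / "regions.tsv", sep="\t", index=False)
    write_regions_bed(result.regions, outdir / "regions.bed")
    regions_to_frame(result.control_filtered).to_csv(
        outdir / "control_filtered.tsv", sep="\t", index=False)
    result.dependence_calls.to_csv(outdir / "dependence.tsv", sep="\t",
                                   index_label="gene_id")
    result.motif_table.to_csv(outdir / "motif_sites.tsv", sep="\t",
                              index=False)
    result.report.to_csv(outdir / "regulon.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, sort_keys=True))
    provenance = {
        "package_version": glnreg.__version__,
        "config_hash": config.config_hash(),
        "config": config.model_dump(exclude={"outdir"}),
        "output_checksums": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir())
            if p.name not in ("provenance.json",) and p.is_file()},
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True))
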