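"""One-command orchestration: simulate/load -> normalize -> analyses.

A :class:`RunConfig` names either input TSV paths or simulation
parameters (never both), the normalization options, and which analyses to
run. :func:`run_all` writes a deterministic output tree with both
normalization branches (with and without IgG subtraction, so the IHC
comparison never silently reuses the wrong matrix), per-analysis result
tables, Newick cluster trees, a structured log, and a manifest sufficient
to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import dilution_replicate_check, two_way_cluster
from .datatypes import Dataset, ValidationError
from .differential import (
    concordance_frame,
    difference_matrix,
    ihc_concordance,
    paired_protein_tests,
    paired_results_frame,
    phospho_nonphospho_correlation,
    size_association,
    surgery_comparison,
)
from .io import read_dataset, read_ihc, write_dataset, write_ihc, write_matrix
from .normalize import NormalizationOptions, run_normalization
from .simulate import SimParams, generate_cohort


@dataclass
class RunConfig:
    # exactly one of the two input sources
    input_paths: dict | None = None  # counts / probes / samples / [ihc]
    sim_params: SimParams | None = None
    normalization: NormalizationOptions = field(default_factory=NormalizationOptions)
    paired_tests: bool = True
    size_association: bool = True
    surgery_comparison: bool = True
    phospho_correlation: bool = True
    concordance: bool = True
    clustering: bool = True
    dilution_qc: bool = False
    ihc_mapping: dict[str, str] | None = None
    out_dir: str = "proteofix_run"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_paths is None) == (self.sim_params is None):
            raise ValidationError(
                "exactly one of input_paths or sim_params must be supplied"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim_params", None)
        norm = raw.pop("normalization", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim_params = SimParams(**sim)
        if norm is not None:
            cfg.normalization = NormalizationOptions(**norm)
        return cfg


def _config_manifest(config: RunConfig) -> dict:
    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    return {"version": __version__, "config": _plain(config)}


def run_all(config: RunConfig) -> Path:
    """Execute the configured pipeline; returns the output directory.

    Any stage failure raises with the stage name prefixed; partial outputs
    already written are retained alongside a ``FAILED`` marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def _log(msg: str) -> None:
        log.append(msg)

    try:
        _run_stages(config, out, _log)
    except Exception as exc:
        (out / "FAILED").write_text(f"{exc}\n")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise
    (out / "run.log").write_text("\n".join(log) + "\n")
    manifest = _config_manifest(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _run_stages(config: RunConfig, out: Path, _log) -> None:
    ihc_records = None
    if config.sim_params is not None:
        params = dataclasses.replace(config.sim_params, seed=config.seed)
        dataset, ihc_records, _truth = generate_cohort(params)
        write_dataset(dataset, out / "inputs")
        if ihc_records:
            write_ihc(ihc_records, out / "inputs" / "ihc.tsv")
        _log(
            f"[simulate] {len(dataset.probes)} probes x "
            f"{len(dataset.counts.lane_ids)} lanes, seed={config.seed}"
        )
    else:
        paths = config.input_paths
        dataset = read_dataset(paths["counts"], paths["probes"], paths["samples"])
        if paths.get("ihc"):
            ihc_records = read_ihc(paths["ihc"])
        _log(
            f"[load] {len(dataset.probes)} probes x "
            f"{len(dataset.counts.lane_ids)} lanes"
        )

    expr, report = run_normalization(dataset, config.normalization)
    write_matrix(expr, out / "normalized.tsv")
    report.housekeeping_cv_table.to_csv(out / "housekeeping_cv.tsv", sep="\t")
    (out / "normalization_report.txt").write_text(report.summary() + "\n")
    _log(
        f"[normalize] {len(expr.probe_ids)} proteins retained; "
        f"undetected: {report.undetected_probes or 'none'}; "
        f"zeros imputed: {len(report.zero_imputation_log)}"
    )

    expr_no_igg = None
    if config.concordance:
        opts = dataclasses.replace(config.normalization, subtract_igg=False)
        expr_no_igg, _ = run_normalization(dataset, opts)
        write_matrix(expr_no_igg, out / "normalized_no_igg.tsv")
        _log("[normalize] IgG-free branch written for IHC comparison")

    diff = None
    if config.paired_tests or config.size_association or config.surgery_comparison \
            or config.phospho_correlation:
        diff, dropped = difference_matrix(expr, dataset.samples)
        diff.to_csv(out / "difference_matrix.tsv", sep="\t")
        _log(f"[difference] {diff.shape[1]} complete pairs; dropped: {dropped or 'none'}")

    if config.paired_tests:
        results = paired_protein_tests(
            expr, dataset.samples, dataset.probes,
            skip_probes=report.undetected_probes,
        )
        paired_results_frame(results).to_csv(
            out / "paired_tests.tsv", sep="\t", index=False
        )
        _log(f"[paired] {len(results)} proteins tested")

    if config.size_association:
        assoc = size_association(diff, dataset.samples)
        rows = [
            {"protein": k, "rho": v.rho, "p_value": v.p_value, "n": v.n, "ok": v.ok}
            for k, v in assoc.items()
        ]
        pd.DataFrame(rows).to_csv(out / "size_association.tsv", sep="\t", index=False)
        _log(f"[size] {len(rows)} proteins")

    if config.surgery_comparison:
        comp = surgery_comparison(diff, dataset.samples)
        rows = [
            {"protein": k, "U": v.statistic, "p_value": v.p_value,
             "method": v.method}
            for k, v in comp.items()
        ]
        pd.DataFrame(rows).to_csv(out / "surgery_comparison.tsv", sep="\t", index=False)
        _log(f"[surgery] {len(rows)} proteins")

    if config.phospho_correlation:
        overall, per_protein, table = phospho_nonphospho_correlation(
            diff, dataset.probes
        )
        rows = [{"protein": "ALL_NONPHOSPHO", "rho": overall.rho,
                 "p_value": overall.p_value, "n": overall.n}]
        rows += [
            {"protein": k, "rho": v.rho, "p_value": v.p_value, "n": v.n}
            for k, v in per_protein.items()
        ]
        pd.DataFrame(rows).to_csv(
            out / "phospho_correlation.tsv", sep="\t", index=False
        )
        table.to_csv(out / "phospho_means.tsv", sep="\t")
        _log(f"[phospho] overall rho={overall.rho:.3f}")

    if config.concordance and ihc_records:
        results, skipped = ihc_concordance(
            expr_no_igg, ihc_records, dataset.samples, dataset.probes,
            mapping=config.ihc_mapping,
        )
        concordance_frame(results).to_csv(
            out / "concordance.tsv", sep="\t", index=False
        )
        _log(f"[concordance] {len(results)} proteins; skipped: {skipped or 'none'}")

    if config.clustering:
        rows_res, cols_res, scaled = two_way_cluster(expr)
        write_matrix(type(expr)(scaled, "log2"), out / "scaled_matrix.tsv")
        (out / "protein_tree.nwk").write_text(rows_res.newick() + "\n")
        (out / "lane_tree.nwk").write_text(cols_res.newick() + "\n")
        labels = pd.DataFrame(
            {"protein_cluster": rows_res.two_cut}
        )
        labels.to_csv(out / "protein_clusters.tsv", sep="\t")
        cols_res.two_cut.rename("lane_cluster").to_csv(
            out / "lane_clusters.tsv", sep="\t"
        )
        _log("[cluster] two-way trees and 2-cut labels written")

    if config.dilution_qc:
        passes, table = dilution_replicate_check(dataset)
        table.to_csv(out / "dilution_qc.tsv", sep="\t", index=False)
        _log(f"[dilution-qc] {sum(passes.values())}/{len(passes)} samples pass")
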