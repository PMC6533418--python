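"""Paired core-cut vs surgical-excision analyses.

Everything here works on the normalized log2 expression matrix. The
central quantity is the per-patient, per-protein *difference*

    difference = log2(excision) - log2(core)

so a protein losing immunoreactivity in the slowly fixed excision has a
negative difference. Built on top of it:

* per-protein paired Wilcoxon signed-rank tests with linear-scale percent
  changes and >50% / >75% reduction and >100% increase counts,
* Spearman association of the difference with tumour size,
* Mann–Whitney comparison of the difference between surgery types,
* correlation of the mean phospho difference with non-phospho differences,
* concordance of expression with IHC scores (pooled and per specimen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    IHCRecord,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)
from .stats import CorrelationResult, PairedTestResult, mann_whitney_u, spearman, wilcoxon_signed_rank

#: Dilution replicate kept for analysis when a (patient, specimen) has
#: several lanes; the assay's working dilution.
CANONICAL_DILUTION_TAG = "10x"


@dataclass
class PairedResult:
    protein: str
    is_phospho: bool
    n_pairs: int
    mean_percent_change: float
    n_over_50pct_reduction: int
    n_over_75pct_reduction: int
    n_over_100pct_increase: int
    wilcoxon: PairedTestResult
    #: alternative reporting convention: 100 * (mean excision / mean core - 1)
    percent_change_of_means: float = float("nan")


@dataclass
class ConcordanceResult:
    protein: str
    pooled: CorrelationResult
    core_only: CorrelationResult
    excision_only: CorrelationResult
    n_observations: int = 0


def _canonical_lanes(
    expr: ExpressionMatrix, samples: list[SampleMetadata]
) -> dict[tuple[str, str], str]:
    """Map (patient, specimen) -> single analysis lane present in ``expr``.

    Dilution replicates resolve to the untagged lane if present, else the
    canonical working-dilution tag.
    """
    lanes = set(expr.lane_ids)
    by_key: dict[tuple[str, str], list[SampleMetadata]] = {}
    for s in samples:
        if s.lane_id in lanes:
            by_key.setdefault((s.patient_id, s.specimen), []).append(s)
    out: dict[tuple[str, str], str] = {}
    for key, group in by_key.items():
        if len(group) == 1:
            out[key] = group[0].lane_id
            continue
        untagged = [s for s in group if s.dilution_tag is None]
        canonical = [s for s in group if s.dilution_tag == CANONICAL_DILUTION_TAG]
        if len(untagged) == 1:
            out[key] = untagged[0].lane_id
        elif len(canonical) == 1:
            out[key] = canonical[0].lane_id
        else:
            raise ValidationError(
                f"cannot resolve a canonical lane for {key}: "
                f"{[s.lane_id for s in group]}"
            )
    return out


def difference_matrix(
    expr: ExpressionMatrix, samples: list[SampleMetadata]
) -> tuple[pd.DataFrame, list[str]]:
    """log2(excision) - log2(core) per protein x patient.

    Only patients with both specimens enter; the second return value lists
    patients excluded for missing a specimen.
    """
    lanes = _canonical_lanes(expr, samples)
    patients = sorted({p for (p, _s) in lanes})
    complete = [
        p for p in patients if (p, "core") in lanes and (p, "excision") in lanes
    ]
    dropped = [p for p in patients if p not in complete]
    if not complete:
        raise ValidationError("no patient has both core and excision lanes")
    cols = {}
    for p in complete:
        core = expr.values[lanes[(p, "core")]]
        excision = expr.values[lanes[(p, "excision")]]
        cols[p] = excision - core
    return pd.DataFrame(cols), dropped


def paired_protein_tests(
    expr: ExpressionMatrix,
    samples: list[SampleMetadata],
    probes: list[ProbeAnnotation],
    skip_probes: list[str] | None = None,
) -> list[PairedResult]:
    """Per-protein paired Wilcoxon with linear-scale change summaries.

    Percent change is computed per pair on the linear scale,
    ``100 * (excision/core - 1)``, then averaged; the threshold counts use
    strict inequalities on the per-pair linear ratio (>50% reduction means
    ratio < 0.5, >75% means ratio < 0.25, >100% increase means ratio > 2).
    """
    skip = set(skip_probes or [])
    lanes = _canonical_lanes(expr, samples)
    complete = sorted(
        {
            p
            for (p, _s) in lanes
            if (p, "core") in lanes and (p, "excision") in lanes
        }
    )
    if len(complete) < 6:
        raise ValidationError(
            f"paired tests need at least 6 complete pairs (got {len(complete)})"
        )
    phospho = {a.probe_id: a.is_phospho for a in probes}
    results = []
    for probe in expr.probe_ids:
        if probe in skip:
            continue
        core = np.array(
            [expr.values.loc[probe, lanes[(p, "core")]] for p in complete]
        )
        excision = np.array(
            [expr.values.loc[probe, lanes[(p, "excision")]] for p in complete]
        )
        ratio = np.exp2(excision) / np.exp2(core)
        test = wilcoxon_signed_rank(core, excision)
        results.append(
            PairedResult(
                protein=probe,
                is_phospho=bool(phospho.get(probe, False)),
                n_pairs=len(complete),
                mean_percent_change=float(100.0 * (ratio - 1.0).mean()),
                n_over_50pct_reduction=int((ratio < 0.5).sum()),
                n_over_75pct_reduction=int((ratio < 0.25).sum()),
                n_over_100pct_increase=int((ratio > 2.0).sum()),
                wilcoxon=test,
                percent_change_of_means=float(
                    100.0 * (np.exp2(excision).mean() / np.exp2(core).mean() - 1.0)
                ),
            )
        )
    return results


def paired_results_frame(results: list[PairedResult]) -> pd.DataFrame:
    rows = [
        {
            "protein": r.protein,
            "is_phospho": r.is_phospho,
            "n_pairs": r.n_pairs,
            "mean_percent_change": r.mean_percent_change,
            "n_over_50pct_reduction": r.n_over_50pct_reduction,
            "n_over_75pct_reduction": r.n_over_75pct_reduction,
            "n_over_100pct_increase": r.n_over_100pct_increase,
            "wilcoxon_statistic": r.wilcoxon.statistic,
            "wilcoxon_p": r.wilcoxon.p_value,
            "wilcoxon_method": r.wilcoxon.method,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def size_association(
    diff: pd.DataFrame, samples: list[SampleMetadata]
) -> dict[str, CorrelationResult]:
    """Spearman correlation of each protein's difference with tumour size."""
    sizes = {}
    for s in samples:
        if s.tumour_size_mm is not None:
            sizes[s.patient_id] = s.tumour_size_mm
    patients = [p for p in diff.columns if p in sizes]
    if not patients:
        raise ValidationError("no patient in the difference matrix has a tumour size")
    x = np.array([sizes[p] for p in patients])
    out = {}
    for protein in diff.index:
        y = diff.loc[protein, patients].to_numpy(dtype=float)
        if len(patients) < 3:
            out[protein] = CorrelationResult(
                rho=float("nan"), p_value=float("nan"), n=len(patients),
                method="insufficient_n", ok=False,
                note="fewer than 3 patients with tumour size",
            )
        else:
            out[protein] = spearman(x, y)
    return out


def surgery_comparison(
    diff: pd.DataFrame, samples: list[SampleMetadata]
) -> dict[str, PairedTestResult]:
    """Mann–Whitney U on per-patient differences, mastectomy vs lumpectomy."""
    surgery = {s.patient_id: s.surgery for s in samples}
    mast = [p for p in diff.columns if surgery.get(p) == "mastectomy"]
    lump = [p for p in diff.columns if surgery.get(p) == "lumpectomy"]
    if not mast or not lump:
        raise ValidationError(
            f"need both surgery groups (mastectomy={len(mast)}, lumpectomy={len(lump)})"
        )
    out = {}
    for protein in diff.index:
        out[protein] = mann_whitney_u(
            diff.loc[protein, mast].to_numpy(dtype=float),
            diff.loc[protein, lump].to_numpy(dtype=float),
        )
    return out


def phospho_nonphospho_correlation(
    diff: pd.DataFrame, probes: list[ProbeAnnotation]
) -> tuple[CorrelationResult, dict[str, CorrelationResult], pd.DataFrame]:
    """Correlate mean phospho difference with non-phospho differences.

    Per patient, the difference is averaged over phospho proteins and over
    non-phospho proteins; the first return value is the Spearman between
    those patient vectors, the second maps each non-phospho protein to the
    Spearman of its own difference against the mean phospho difference,
    and the third is the patient-level table of the two means.
    """
    phospho = [
        a.probe_id
        for a in probes
        if a.probe_id in diff.index and a.probe_class == "endogenous" and a.is_phospho
    ]
    nonphospho = [
        a.probe_id
        for a in probes
        if a.probe_id in diff.index
        and a.probe_class == "endogenous"
        and not a.is_phospho
    ]
    if len(phospho) < 2 or len(nonphospho) < 2:
        raise ValidationError(
            "need >= 2 phospho and >= 2 non-phospho proteins "
            f"(got {len(phospho)}, {len(nonphospho)})"
        )
    mean_ph = diff.loc[phospho].mean(axis=0)
    mean_np = diff.loc[nonphospho].mean(axis=0)
    overall = spearman(mean_ph.to_numpy(), mean_np.to_numpy())
    per_protein = {
        protein: spearman(mean_ph.to_numpy(), diff.loc[protein].to_numpy())
        for protein in nonphospho
    }
    table = pd.DataFrame(
        {"mean_phospho_difference": mean_ph, "mean_nonphospho_difference": mean_np}
    )
    return overall, per_protein, table


def ihc_concordance(
    expr_no_igg: ExpressionMatrix,
    ihc: list[IHCRecord],
    samples: list[SampleMetadata],
    probes: list[ProbeAnnotation],
    mapping: dict[str, str] | None = None,
) -> tuple[list[ConcordanceResult], list[str]]:
    """Spearman concordance of expression with IHC, pooled and per specimen.

    ``expr_no_igg`` should come from the normalization branch that skips
    IgG subtraction. ``mapping`` sends IHC protein names to panel target
    names (identity by default); IHC proteins that resolve to no panel
    probe are returned in the skipped list. Ordinal scales (e.g. 0-3+)
    enter through mid-ranks, which Spearman handles natively.
    """
    mapping = mapping or {}
    target_to_probe = {a.target: a.probe_id for a in probes if a.probe_class == "endogenous"}
    lanes = _canonical_lanes(expr_no_igg, samples)
    by_protein: dict[str, list[IHCRecord]] = {}
    for rec in ihc:
        by_protein.setdefault(rec.protein, []).append(rec)

    results, skipped = [], []
    for protein in sorted(by_protein):
        target = mapping.get(protein, protein)
        probe = target_to_probe.get(target)
        if probe is None or probe not in expr_no_igg.probe_ids:
            skipped.append(protein)
            continue
        pairs = {"core": ([], []), "excision": ([], [])}
        for rec in by_protein[protein]:
            lane = lanes.get((rec.patient_id, rec.specimen))
            if lane is None:
                continue
            xs, ys = pairs[rec.specimen]
            xs.append(float(expr_no_igg.values.loc[probe, lane]))
            ys.append(rec.value)

        def _corr(xs, ys):
            if len(xs) < 3:
                return CorrelationResult(
                    rho=float("nan"), p_value=float("nan"), n=len(xs),
                    method="insufficient_n", ok=False,
                )
            return spearman(xs, ys)

        core_x, core_y = pairs["core"]
        exc_x, exc_y = pairs["excision"]
        pooled_x, pooled_y = core_x + exc_x, core_y + exc_y
        results.append(
            ConcordanceResult(
                protein=protein,
                pooled=_corr(pooled_x, pooled_y),
                core_only=_corr(core_x, core_y),
                excision_only=_corr(exc_x, exc_y),
                n_observations=len(pooled_x),
            )
        )
    return results, skipped


def concordance_frame(results: list[ConcordanceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "protein": r.protein,
                "pooled_rho": r.pooled.rho,
                "pooled_p": r.pooled.p_value,
                "pooled_n": r.pooled.n,
                "core_rho": r.core_only.rho,
                "core_p": r.core_only.p_value,
                "excision_rho": r.excision_only.rho,
                "excision_p": r.excision_only.p_value,
            }
        )
    return pd.DataFrame(rows)
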