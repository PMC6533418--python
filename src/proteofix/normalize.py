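"""Control-based normalization of barcode-antibody counts.

The chain runs, in fixed order:

1. **Positive-control normalization** — each lane is scaled so the
   geometric mean of its ERCC spike-in (positive) probes equals the
   across-lane reference; this removes hybridization-efficiency lane
   effects.
2. **Background correction** — the geometric mean of the ERCC negative
   probes, then (optionally) of the IgG non-specific probes, is subtracted
   per lane from endogenous and housekeeping counts, flooring at zero.
   For direct comparison with IHC the IgG subtraction is switched off.
3. **Housekeeping normalization** — counts are divided by the lane's
   housekeeping level (Histone H3 by default) relative to its across-lane
   geometric mean, correcting for sample input amount. The housekeeping
   probe is confirmed (or chosen) as the candidate with the lowest
   coefficient of variation of log2 counts.
4. **Undetected-probe exclusion** — endogenous probes whose counts sit
   below the lane's IgG geometric mean in *every* lane are flagged and
   dropped from downstream statistics.
5. **Half-minimum imputation and log2** — per protein, zeros become half
   the smallest detected value of that protein, then values are log2
   transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, Dataset, ExpressionMatrix, ValidationError

#: Zero counts on negative/IgG control probes are lifted to this value
#: before taking geometric means; background stays estimable without
#: discarding lanes.
CONTROL_ZERO_OFFSET = 0.5


@dataclass
class NormalizationOptions:
    subtract_igg: bool = True
    housekeeping_probe: str = "auto"
    #: per-lane scaling reference; only the documented mode exists.
    reference_mode: str = "geomean_of_lane_geomeans"
    floor_at_zero: bool = True


@dataclass
class NormalizationReport:
    lane_scaling_factors: pd.Series | None = None
    per_lane_negative_background: pd.Series | None = None
    per_lane_igg_background: pd.Series | None = None
    housekeeping_choice: str | None = None
    housekeeping_cv_table: pd.Series | None = None
    undetected_probes: list[str] = field(default_factory=list)
    zero_imputation_log: list[tuple[str, str, float]] = field(default_factory=list)
    options: NormalizationOptions | None = None

    def summary(self) -> str:
        lines = ["normalization report"]
        if self.lane_scaling_factors is not None:
            lines.append(f"  lanes scaled: {len(self.lane_scaling_factors)}")
        if self.housekeeping_choice:
            lines.append(f"  housekeeping: {self.housekeeping_choice}")
        lines.append(f"  undetected probes: {self.undetected_probes or 'none'}")
        lines.append(f"  zeros imputed: {len(self.zero_imputation_log)}")
        return "\n".join(lines)


def geometric_mean(values) -> float:
    """exp(mean(log x)) for strictly positive ``values``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of empty input")
    if (arr <= 0).any():
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _control_geomean(frame: pd.DataFrame) -> pd.Series:
    """Per-lane geometric mean of control counts, zeros lifted to 0.5."""
    arr = frame.to_numpy(dtype=float)
    arr = np.where(arr <= 0, CONTROL_ZERO_OFFSET, arr)
    return pd.Series(np.exp(np.mean(np.log(arr), axis=0)), index=frame.columns)


def positive_control_normalize(
    raw: CountMatrix, dataset: Dataset
) -> tuple[CountMatrix, pd.Series]:
    """Scale each lane so its spike-in geometric mean matches the reference.

    The reference is the geometric mean of the per-lane geometric means, so
    the lane factors multiply to one.
    """
    pos = dataset.probes_of_class("positive")
    if not pos:
        raise ValidationError("no positive-control probes")
    sub = raw.values.loc[pos]
    zero_lanes = sub.columns[(sub <= 0).any(axis=0)].tolist()
    if zero_lanes:
        raise ValidationError(
            f"zero positive-control count in lanes {zero_lanes}; "
            "spike-in failure, lane cannot be normalized"
        )
    lane_gm = pd.Series(
        np.exp(np.mean(np.log(sub.to_numpy(dtype=float)), axis=0)),
        index=sub.columns,
    )
    reference = geometric_mean(lane_gm)
    factors = reference / lane_gm
    out = raw.values.mul(factors, axis=1)
    return raw.advance(out, "positive_normalized"), factors


def background_correct(
    m: CountMatrix, dataset: Dataset, opts: NormalizationOptions | None = None
) -> tuple[CountMatrix, pd.Series, pd.Series]:
    """Subtract negative-probe then (optionally) IgG background per lane.

    Subtraction applies to endogenous and housekeeping probes, flooring at
    zero after each step; the IgG background is computed on the IgG probes
    *after* the negative subtraction has been applied to them. Control
    probes pass through unmodified for reporting.
    """
    opts = opts or NormalizationOptions()
    neg = dataset.probes_of_class("negative")
    if not neg:
        raise ValidationError("no negative-control probes")
    igg = dataset.probes_of_class("igg")
    if opts.subtract_igg and not igg:
        raise ValidationError("subtract_igg requested but no IgG probes")
    targets = dataset.probes_of_class("endogenous") + dataset.probes_of_class(
        "housekeeping"
    )
    targets = [p for p in m.probe_ids if p in set(targets)]

    b_neg = _control_geomean(m.values.loc[neg])
    out = m.values.copy()
    out.loc[targets] = (out.loc[targets] - b_neg).clip(lower=0.0)

    if opts.subtract_igg:
        igg_sub = (m.values.loc[igg] - b_neg).clip(lower=0.0)
        b_igg = _control_geomean(igg_sub)
        out.loc[targets] = (out.loc[targets] - b_igg).clip(lower=0.0)
    else:
        b_igg = pd.Series(0.0, index=m.lane_ids)
    return m.advance(out, "background_corrected"), b_neg, b_igg


def select_housekeeping(
    m: CountMatrix, dataset: Dataset
) -> tuple[str, pd.Series]:
    """Pick the housekeeping candidate with the lowest CV of log2 counts."""
    candidates = dataset.probes_of_class("housekeeping")
    if not candidates:
        raise ValidationError("no housekeeping probes")
    cvs = {}
    for probe in candidates:
        counts = m.values.loc[probe]
        if (counts <= 0).any():
            raise ValidationError(
                f"housekeeping candidate {probe!r} has a zero count"
            )
        logs = np.log2(counts.to_numpy(dtype=float))
        mean = logs.mean()
        if mean == 0:
            cvs[probe] = np.inf if logs.std(ddof=1 if logs.size > 1 else 0) else 0.0
        else:
            sd = logs.std(ddof=1) if logs.size > 1 else 0.0
            cvs[probe] = abs(sd / mean)
    table = pd.Series(cvs, name="cv_log2").sort_values(kind="stable")
    return str(table.index[0]), table


def housekeeping_normalize(
    m: CountMatrix, dataset: Dataset, hk: str
) -> CountMatrix:
    """Divide counts by the lane's housekeeping ratio to its geometric mean."""
    hk_counts = m.values.loc[hk]
    if (hk_counts <= 0).any():
        lanes = m.values.columns[(hk_counts <= 0)].tolist()
        raise ValidationError(f"housekeeping {hk!r} zero in lanes {lanes}")
    ratio = hk_counts / geometric_mean(hk_counts)
    targets = dataset.probes_of_class("endogenous") + dataset.probes_of_class(
        "housekeeping"
    )
    targets = [p for p in m.probe_ids if p in set(targets)]
    out = m.values.copy()
    out.loc[targets] = out.loc[targets].div(ratio, axis=1)
    return m.advance(out, "housekeeping_normalized")


def detect_above_background(m: CountMatrix, dataset: Dataset) -> list[str]:
    """Endogenous probes below the lane IgG geometric mean in every lane."""
    igg = dataset.probes_of_class("igg")
    if not igg:
        raise ValidationError("no IgG probes; cannot assess detection")
    igg_gm = _control_geomean(m.values.loc[igg])
    endo = [p for p in m.probe_ids if p in set(dataset.probes_of_class("endogenous"))]
    below = m.values.loc[endo].lt(igg_gm, axis=1)
    return [p for p in endo if bool(below.loc[p].all())]


def impute_and_log(
    m: CountMatrix, dataset: Dataset, probes: list[str] | None = None
) -> tuple[ExpressionMatrix, list[tuple[str, str, float]]]:
    """Half-minimum imputation of zeros per protein, then log2.

    ``probes`` restricts the output rows (endogenous probes by default);
    a probe with no detected value at all is an error — fully undetected
    probes must be excluded beforehand (see :func:`detect_above_background`).
    """
    if probes is None:
        probes = [
            p
            for p in m.probe_ids
            if p in set(dataset.probes_of_class("endogenous"))
        ]
    sub = m.values.loc[probes].copy()
    log: list[tuple[str, str, float]] = []
    for probe in probes:
        row = sub.loc[probe]
        positive = row[row > 0]
        if positive.empty:
            raise ValidationError(
                f"probe {probe!r} undetected in all lanes; exclude it before imputation"
            )
        fill = positive.min() / 2.0
        for lane in row.index[row <= 0]:
            sub.loc[probe, lane] = fill
            log.append((probe, lane, float(fill)))
    out = pd.DataFrame(
        np.log2(sub.to_numpy(dtype=float)), index=sub.index, columns=sub.columns
    )
    return m.advance(out, "log2"), log


def run_normalization(
    dataset: Dataset, opts: NormalizationOptions | None = None
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Full chain: lane scaling, background, housekeeping, exclusion, log2."""
    opts = opts or NormalizationOptions()
    report = NormalizationReport(options=opts)

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except ValidationError as exc:
            raise ValidationError(f"[{name}] {exc}") from exc

    m, factors = _stage("positive_control_normalize", positive_control_normalize,
                        dataset.counts, dataset)
    report.lane_scaling_factors = factors

    undetected = _stage("detect_above_background", detect_above_background, m, dataset)
    report.undetected_probes = undetected

    m, b_neg, b_igg = _stage("background_correct", background_correct, m, dataset, opts)
    report.per_lane_negative_background = b_neg
    report.per_lane_igg_background = b_igg

    if opts.housekeeping_probe == "auto":
        hk, cv_table = _stage("select_housekeeping", select_housekeeping, m, dataset)
    else:
        hk = opts.housekeeping_probe
        ann = dataset.probe_map().get(hk)
        if ann is None or ann.probe_class != "housekeeping":
            raise ValidationError(
                f"[select_housekeeping] {hk!r} is not a housekeeping probe"
            )
        _, cv_table = _stage("select_housekeeping", select_housekeeping, m, dataset)
    report.housekeeping_choice = hk
    report.housekeeping_cv_table = cv_table

    m = _stage("housekeeping_normalize", housekeeping_normalize, m, dataset, hk)

    keep = [
        p
        for p in m.probe_ids
        if p in set(dataset.probes_of_class("endogenous")) and p not in set(undetected)
    ]
    # a probe can clear the IgG comparison in a lane or two yet still carry
    # no signal after background subtraction; with nothing detected anywhere
    # it is excluded like any undetected probe rather than imputed
    all_zero = [p for p in keep if not (m.values.loc[p] > 0).any()]
    if all_zero:
        report.undetected_probes = undetected + all_zero
        keep = [p for p in keep if p not in set(all_zero)]
    if not keep:
        raise ValidationError("[impute_and_log] no detected endogenous probes")
    expr, imputation_log = _stage("impute_and_log", impute_and_log, m, dataset, keep)
    report.zero_imputation_log = imputation_log
    return expr, report
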