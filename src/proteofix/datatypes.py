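"""Core containers for barcode-antibody count data.

A dataset couples a probes × lanes count matrix with probe annotations
(which probes are endogenous targets, ERCC spike-ins, IgG non-specific
controls, or the housekeeping reference) and lane-level sample metadata
(patient, specimen type, surgery, tumour size, dilution replicate tag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "positive", "negative", "igg", "housekeeping")

#: Normalization stages in the only order transitions may occur.
STAGES = (
    "raw",
    "positive_normalized",
    "background_corrected",
    "housekeeping_normalized",
    "log2",
)

SPECIMENS = ("core", "excision")
SURGERIES = ("lumpectomy", "mastectomy", "unknown")

#: Inclusive value bounds per IHC score scale.
IHC_SCALE_BOUNDS = {
    "h_score": (0.0, 300.0),
    "percent_positive": (0.0, 100.0),
    "ordinal_0_to_3": (0.0, 3.0),
}


class ValidationError(ValueError):
    """Raised when input data violates a dataset invariant."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe of the panel.

    ``is_phospho`` is meaningful only for endogenous probes (phospho-epitope
    antibodies are the ones labile under delayed fixation).
    """

    probe_id: str
    target: str
    probe_class: str
    is_phospho: bool = False

    def __post_init__(self):
        if self.probe_class not in PROBE_CLASSES:
            raise ValidationError(
                f"probe {self.probe_id!r}: unknown probe_class {self.probe_class!r}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    """Lane-level sample annotation."""

    lane_id: str
    patient_id: str
    specimen: str
    surgery: str = "unknown"
    tumour_size_mm: float | None = None
    dilution_tag: str | None = None

    def __post_init__(self):
        if self.specimen not in SPECIMENS:
            raise ValidationError(
                f"lane {self.lane_id!r}: unknown specimen {self.specimen!r}"
            )
        if self.surgery not in SURGERIES:
            raise ValidationError(
                f"lane {self.lane_id!r}: unknown surgery {self.surgery!r}"
            )
        if self.tumour_size_mm is not None and not self.tumour_size_mm > 0:
            raise ValidationError(
                f"lane {self.lane_id!r}: tumour_size_mm must be positive"
            )


@dataclass(frozen=True)
class IHCRecord:
    """One immunohistochemistry read-out, validated against its scale."""

    patient_id: str
    specimen: str
    protein: str
    scale: str
    value: float

    def __post_init__(self):
        if self.specimen not in SPECIMENS:
            raise ValidationError(
                f"IHC {self.patient_id}/{self.protein}: unknown specimen {self.specimen!r}"
            )
        if self.scale not in IHC_SCALE_BOUNDS:
            raise ValidationError(
                f"IHC {self.patient_id}/{self.protein}: unknown scale {self.scale!r}"
            )
        lo, hi = IHC_SCALE_BOUNDS[self.scale]
        if not (lo <= self.value <= hi):
            raise ValidationError(
                f"IHC {self.patient_id}/{self.protein}: value {self.value} outside "
                f"{self.scale} bounds [{lo}, {hi}]"
            )


class CountMatrix:
    """Probes × lanes matrix with stage provenance.

    Values are non-negative reals at every stage except ``log2``, where
    negatives are legal. Stage transitions are enforced to follow
    :data:`STAGES` strictly in order (``advance``); this is how the
    normalization chain documents its provenance.
    """

    def __init__(self, values: pd.DataFrame, stage: str = "raw"):
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe_ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate lane_ids: {dupes}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("matrix contains non-finite values")
        if stage != "log2" and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at probe {values.index[i]!r}, lane "
                f"{values.columns[j]!r} (stage {stage})"
            )
        self.values = values.astype(float)
        self.stage = stage

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def lane_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def advance(self, new_values: pd.DataFrame, new_stage: str) -> "CountMatrix":
        """Return a new matrix at the next stage of the documented order."""
        if new_stage not in STAGES:
            raise ValidationError(f"unknown stage {new_stage!r}")
        if STAGES.index(new_stage) != STAGES.index(self.stage) + 1:
            raise ValidationError(
                f"illegal stage transition {self.stage} -> {new_stage}"
            )
        return CountMatrix(new_values, new_stage)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.stage)

    def __repr__(self):  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"<CountMatrix {n} probes x {m} lanes, stage={self.stage}>"


#: Normalized log2 matrices are the same container at stage "log2".
ExpressionMatrix = CountMatrix


@dataclass
class Dataset:
    """Validated bundle of counts, probe annotations and sample metadata."""

    counts: CountMatrix
    probes: list[ProbeAnnotation]
    samples: list[SampleMetadata]

    def __post_init__(self):
        self.validate()

    # -- lookups -------------------------------------------------------
    def probe_map(self) -> dict[str, ProbeAnnotation]:
        return {p.probe_id: p for p in self.probes}

    def probes_of_class(self, probe_class: str) -> list[str]:
        return [p.probe_id for p in self.probes if p.probe_class == probe_class]

    def sample_map(self) -> dict[str, SampleMetadata]:
        return {s.lane_id: s for s in self.samples}

    def sample_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lane_id": s.lane_id,
                "patient_id": s.patient_id,
                "specimen": s.specimen,
                "surgery": s.surgery,
                "tumour_size_mm": s.tumour_size_mm,
                "dilution_tag": s.dilution_tag,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("lane_id")

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        ann_ids = [p.probe_id for p in self.probes]
        if len(set(ann_ids)) != len(ann_ids):
            dupes = sorted({i for i in ann_ids if ann_ids.count(i) > 1})
            raise ValidationError(f"duplicate probe annotations: {dupes}")
        mat_ids = set(self.counts.probe_ids)
        missing_ann = sorted(mat_ids - set(ann_ids))
        if missing_ann:
            raise ValidationError(
                f"probes in counts without annotation: {missing_ann}"
            )
        missing_counts = sorted(set(ann_ids) - mat_ids)
        if missing_counts:
            raise ValidationError(
                f"annotated probes absent from counts: {missing_counts}"
            )
        for cls in ("positive", "negative", "housekeeping"):
            if not self.probes_of_class(cls):
                raise ValidationError(f"no probe of class {cls!r} in panel")

        lane_meta = [s.lane_id for s in self.samples]
        if len(set(lane_meta)) != len(lane_meta):
            dupes = sorted({i for i in lane_meta if lane_meta.count(i) > 1})
            raise ValidationError(f"duplicate lane metadata: {dupes}")
        missing_meta = sorted(set(self.counts.lane_ids) - set(lane_meta))
        if missing_meta:
            raise ValidationError(f"lanes without metadata: {missing_meta}")
        keys = [(s.patient_id, s.specimen, s.dilution_tag) for s in self.samples]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(
                f"multiple lanes share (patient, specimen, dilution_tag): {dupes}"
            )

    def canonical(self) -> "Dataset":
        """Dataset with probes and lanes sorted lexicographically."""
        vals = self.counts.values.sort_index(axis=0).sort_index(axis=1)
        probes = sorted(self.probes, key=lambda p: p.probe_id)
        samples = sorted(self.samples, key=lambda s: s.lane_id)
        return Dataset(CountMatrix(vals, self.counts.stage), probes, samples)
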