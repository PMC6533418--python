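"""Tab-delimited interchange for counts, probe annotations, metadata and IHC.

Dialect: UTF-8, tab separator, "." decimal point, no thousands separators.
``counts.tsv`` has a ``probe_id`` first column and one column per lane;
matrix files written by :func:`write_matrix` carry the stage in a leading
``# stage=...`` comment and round-trip values to 12 significant digits.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import pandas as pd

from .datatypes import (
    CountMatrix,
    Dataset,
    IHCRecord,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)

_PROBE_COLS = ["probe_id", "target", "probe_class", "is_phospho"]
_SAMPLE_COLS = [
    "lane_id",
    "patient_id",
    "specimen",
    "surgery",
    "tumour_size_mm",
    "dilution_tag",
]
_IHC_COLS = ["patient_id", "specimen", "protein", "scale", "value"]


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def read_counts(path) -> CountMatrix:
    df = _read_tsv(path)
    if df.columns[0] != "probe_id":
        raise ValidationError(f"{path}: first column must be 'probe_id'")
    df = df.set_index("probe_id")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for probe, cell in df[col].items():
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric count {cell!r} at probe {probe!r}, lane {col!r}"
                ) from None
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{path}: invalid count {cell!r} at probe {probe!r}, lane {col!r}"
                )
            values.loc[probe, col] = v
    return CountMatrix(values, "raw")


def read_probes(path) -> list[ProbeAnnotation]:
    df = _read_tsv(path)
    missing = [c for c in _PROBE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        flag = str(row["is_phospho"]).strip().lower()
        is_phospho = flag in ("true", "1", "yes")
        out.append(
            ProbeAnnotation(
                probe_id=row["probe_id"],
                target=row["target"],
                probe_class=row["probe_class"],
                is_phospho=is_phospho,
            )
        )
    return out


def _opt_float(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if not s:
        return None
    return float(s)


def _opt_str(cell) -> str | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    return s or None


def read_samples(path) -> list[SampleMetadata]:
    df = _read_tsv(path)
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                lane_id=row["lane_id"],
                patient_id=row["patient_id"],
                specimen=row["specimen"],
                surgery=_opt_str(row["surgery"]) or "unknown",
                tumour_size_mm=_opt_float(row["tumour_size_mm"]),
                dilution_tag=_opt_str(row["dilution_tag"]),
            )
        )
    return out


def read_dataset(counts_path, probes_path, samples_path) -> Dataset:
    """Read and cross-validate a full dataset (canonically ordered)."""
    counts = read_counts(counts_path)
    probes = read_probes(probes_path)
    samples = read_samples(samples_path)
    return Dataset(counts, probes, samples).canonical()


def read_ihc(path) -> list[IHCRecord]:
    df = _read_tsv(path)
    missing = [c for c in _IHC_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-numeric IHC value {row['value']!r} "
                f"({row['patient_id']}/{row['protein']})"
            ) from None
        out.append(
            IHCRecord(
                patient_id=row["patient_id"],
                specimen=row["specimen"],
                protein=row["protein"],
                scale=row["scale"],
                value=value,
            )
        )
    return out


# ---------------------------------------------------------------- writing

def write_matrix(matrix: CountMatrix, path) -> None:
    """Write a matrix with its stage in a header comment (12 sig. digits)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# stage={matrix.stage}\n")
    matrix.values.to_csv(
        buf, sep="\t", index_label="probe_id", float_format="%.12g"
    )
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_matrix(path) -> CountMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    stage = "raw"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# stage="):
        stage = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
    return CountMatrix(df.astype(float), stage)


def write_probes(probes: list[ProbeAnnotation], path) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "target": p.target,
            "probe_class": p.probe_class,
            "is_phospho": ("true" if p.is_phospho else "false")
            if p.probe_class == "endogenous"
            else "",
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=_PROBE_COLS).to_csv(path, sep="\t", index=False)


def write_samples(samples: list[SampleMetadata], path) -> None:
    rows = [
        {
            "lane_id": s.lane_id,
            "patient_id": s.patient_id,
            "specimen": s.specimen,
            "surgery": "" if s.surgery == "unknown" else s.surgery,
            "tumour_size_mm": "" if s.tumour_size_mm is None else f"{s.tumour_size_mm:.12g}",
            "dilution_tag": s.dilution_tag or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLS).to_csv(path, sep="\t", index=False)


def write_ihc(records: list[IHCRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "specimen": r.specimen,
            "protein": r.protein,
            "scale": r.scale,
            "value": f"{r.value:.12g}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_IHC_COLS).to_csv(path, sep="\t", index=False)


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write counts/probes/samples TSVs into ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "probes": out_dir / "probes.tsv",
        "samples": out_dir / "samples.tsv",
    }
    write_matrix(dataset.counts, paths["counts"])
    write_probes(dataset.probes, paths["probes"])
    write_samples(dataset.samples, paths["samples"])
    return paths
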