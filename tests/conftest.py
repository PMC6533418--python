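import numpy as np
import pandas as pd
import pytest

from proteofix.datatypes import CountMatrix, Dataset, ProbeAnnotation, SampleMetadata

# ---------------------------------------------------------------------
# Reference normalization fixture: 12 probes x 3 lanes worked by hand
# through every stage (lane factors 2.0 / 0.5 / 1.0; negative backgrounds
# 10 / 10 / 5; IgG backgrounds 6 / 8 / 4; housekeeping ratios 0.5 / 2 / 1;
# END3 sits below the IgG level in every lane and is excluded).

REFERENCE_RAW = {
    "POS1": (5, 20, 10),
    "POS2": (10, 40, 20),
    "POS3": (20, 80, 40),
    "NEG1": (2.5, 20, 5),
    "NEG2": (5, 20, 5),
    "NEG3": (10, 20, 5),
    "IGG1": (7, 28, 7),
    "IGG2": (9.5, 52, 13),
    "HK1": (12, 100, 25),
    "END1": (5, 76, 19),
    "END2": (28, 52, 25),
    "END3": (5, 24, 6),
}

#: Final log2 matrix: END1 -> log2(5, 10, 10), END2 -> log2(80, 4, 16).
REFERENCE_LOG2 = {
    "END1": (2.321928094887362, 3.321928094887362, 3.321928094887362),
    "END2": (6.321928094887363, 2.0, 4.0),
}

REFERENCE_UNDETECTED = ["END3"]


def _probe_class(pid: str) -> str:
    if pid.startswith("HK"):
        return "housekeeping"
    return {
        "POS": "positive",
        "NEG": "negative",
        "IGG": "igg",
        "END": "endogenous",
    }[pid[:3]]


def build_dataset(raw: dict, lanes=None, samples=None) -> Dataset:
    """Dataset from a {probe: per-lane counts} dict with inferred classes."""
    lanes = lanes or [f"L{i + 1}" for i in range(len(next(iter(raw.values()))))]
    values = pd.DataFrame(
        {lane: [raw[p][i] for p in raw] for i, lane in enumerate(lanes)},
        index=list(raw),
        dtype=float,
    )
    probes = [
        ProbeAnnotation(pid, pid, _probe_class(pid), pid.startswith("END"))
        for pid in raw
    ]
    if samples is None:
        samples = [
            SampleMetadata(
                lane_id=lane,
                patient_id=f"PAT{i // 2 + 1}",
                specimen="core" if i % 2 == 0 else "excision",
            )
            for i, lane in enumerate(lanes)
        ]
    return Dataset(CountMatrix(values, "raw"), probes, samples)


@pytest.fixture
def reference_dataset() -> Dataset:
    return build_dataset(REFERENCE_RAW)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
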