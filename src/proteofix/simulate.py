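"""Synthetic paired-cohort generator with fixation-delay artefacts.

The generator reproduces the statistical structure the analysis assumes,
not the biochemistry: each patient carries latent protein abundances; the
core-cut fixes almost immediately while the excision interior fixes only
after formalin (penetrating at about 1 mm/h) reaches it, so the excision
experiences a per-patient delay ``d`` driven by specimen half-thickness
and handling. During that delay a phospho-epitope with lability ``lam``
decays as ``exp(-lam * d)`` while stress-responsive proteins are induced
by a saturating factor ``1 + gamma * (1 - exp(-d / tau))``. Counts are
negative-binomial around ``count_scale * abundance`` with multiplicative
lane-efficiency and input-amount nuisance factors; ERCC spike-ins, IgG and
housekeeping probes follow their own models, and IHC read-outs are a
noisy saturating transform of the same latent abundances.

Delay modes
-----------
``surgery`` (default)
    lumpectomy: half tumour thickness / penetration rate plus an overnight
    offset (left unsliced until the next morning); mastectomy: half
    thickness capped by slicing at ~10 mm intervals plus a short grossing
    offset.
``size_proportional``
    delay = half thickness / penetration rate for every excision; the
    configuration that couples delay purely to tumour size.
``constant``
    a fixed excision delay; the matching no-coupling control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    Dataset,
    IHCRecord,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class ProteinSpec:
    """One endogenous panel protein and its artefact parameters.

    ``lability``: first-order decay rate of the epitope per hour of
    fixation delay. ``stress_gain``: maximal fractional induction of the
    protein by the pre-fixation stress response.
    """

    name: str
    is_phospho: bool
    base_abundance: float
    lability: float = 0.0
    stress_gain: float = 0.0
    #: probe-specific non-specific binding level; None = panel default
    #: (the IgG control level, so background subtraction is exact on average)
    nonspecific: float | None = None


@dataclass(frozen=True)
class IHCModel:
    """Saturating transform from latent abundance to an IHC score."""

    scale: str
    max_value: float
    half_saturation: float
    hill: float = 1.0
    noise_sd: float = 0.0
    #: ordinal scales bin the continuous score at these fractions of max
    ordinal_cutpoints: tuple[float, ...] = (0.25, 0.5, 0.75)


def default_panel() -> list[ProteinSpec]:
    """26-protein panel: 13 phospho targets, 13 non-phospho targets.

    Lability and stress defaults are ordered to mirror the qualitative
    field picture (pERK1/2 and pGSK3B most labile; cytokeratin and stress
    kinases induced); pEGFR is essentially absent, sitting below the IgG
    background in ER-positive tumours.
    """
    phospho = [  # (name, base abundance, lability per hour)
        ("pERK1/2", 40.0, 0.2),
        ("pAKT", 60.0, 0.11),
        ("p4EBP1", 80.0, 0.1),
        ("pGSK3B", 30.0, 0.2),
        ("pRPS6", 120.0, 0.065),
        ("pAMPKa", 25.0, 0.1),
        ("pMEK1/2", 35.0, 0.038),
        ("pPRAS40", 45.0, 0.052),
        ("pTSC2", 20.0, 0.012),
        ("pPDK1", 15.0, 0.01),
        ("pRAF1", 30.0, 0.02),
        ("pH3", 90.0, 0.0075),
    ]
    # Non-phospho targets combine a fast-saturating stress induction with a
    # mild epitope lability, so the net excision change is positive for the
    # stress responders yet still shrinks in the slowest-fixing specimens —
    # the structure that couples non-phospho differences to phospho loss.
    nonphospho = [  # (name, base abundance, stress gain, lability per hour)
        ("Ki67", 50.0, 0.5, 0.02),
        ("PgR", 70.0, 0.45, 0.02),
        ("HER2", 100.0, 0.45, 0.022),
        ("pan-KRT", 300.0, 2.5, 0.02),
        ("4EBP1", 110.0, 1.6, 0.025),
        ("ERK1/2", 90.0, 1.4, 0.025),
        ("MET", 45.0, 0.8, 0.02),
        ("GSK3B", 60.0, 0.5, 0.022),
        ("pan-AKT", 85.0, 0.5, 0.022),
        ("TSC2", 30.0, 0.5, 0.02),
        ("RPS6", 150.0, 0.45, 0.02),
        ("MEK1/2", 55.0, 0.45, 0.02),
        ("AMPKa", 25.0, 0.45, 0.022),
    ]
    panel = [
        ProteinSpec(name, True, base, lability=lam) for name, base, lam in phospho
    ]
    # pEGFR: essentially absent in ER-positive tumours and its antibody
    # binds less non-specifically than the IgG controls, so its counts sit
    # below the IgG level in every lane and it is flagged undetected.
    panel.append(
        ProteinSpec("pEGFR", True, 0.02, lability=0.05, nonspecific=12.0)
    )
    panel += [
        ProteinSpec(name, False, base, stress_gain=g, lability=lam)
        for name, base, g, lam in nonphospho
    ]
    return panel


def default_ihc_models() -> dict[str, IHCModel]:
    """IHC read-outs for the five proteins scored in both platforms."""
    return {
        "Ki67": IHCModel("percent_positive", 100.0, 50.0, noise_sd=6.0),
        "PgR": IHCModel("h_score", 300.0, 70.0, noise_sd=20.0),
        "HER2": IHCModel("ordinal_0_to_3", 300.0, 100.0, noise_sd=20.0),
        "pAKT": IHCModel("h_score", 300.0, 60.0, noise_sd=20.0),
        "pERK1/2": IHCModel("h_score", 300.0, 40.0, noise_sd=20.0),
    }


@dataclass
class SimParams:
    """Cohort-level generator parameters (defaults are the study design)."""

    n_patients: int = 16
    proteins: list[ProteinSpec] = field(default_factory=default_panel)
    # tumour size (mm): log-normal around the cohort median
    tumour_size_median_mm: float = 33.5
    tumour_size_sigma: float = 0.45
    mastectomy_size_threshold_mm: float = 30.0
    # fixation delay model
    delay_mode: str = "surgery"  # surgery | size_proportional | constant
    core_delay_h: float = 0.05
    penetration_rate_mm_per_h: float = 1.0
    lumpectomy_offset_h: float = 18.0
    mastectomy_offset_h: float = 12.0
    mastectomy_half_thickness_cap_mm: float = 5.0
    constant_excision_delay_h: float = 1.0
    stress_tau_h: float = 2.0
    # latent abundances
    abundance_sigma: float = 0.45
    housekeeping_base: float = 150.0
    housekeeping_sigma: float = 0.1
    # measurement layer
    lane_effect_sd: float = 0.15
    input_amount_sd: float = 0.25
    count_scale: float = 12.0
    count_dispersion: float = 0.01  # NB variance mu + disp * mu^2; 0 = noiseless
    negative_probe_mean: float = 12.0
    endogenous_nonspecific: float = 40.0
    igg_nonspecific: float = 40.0
    positive_ladder: tuple[float, ...] = (6400.0, 1600.0, 400.0, 100.0, 50.0, 25.0)
    n_negative_probes: int = 6
    n_igg_probes: int = 2
    ihc_models: dict[str, IHCModel] = field(default_factory=default_ihc_models)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not self.proteins:
            raise ValidationError("empty protein panel")
        names = [p.name for p in self.proteins]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate protein names in panel")
        for p in self.proteins:
            if p.lability < 0 or p.stress_gain < 0 or p.base_abundance < 0:
                raise ValidationError(f"negative rate/abundance for {p.name}")
            if p.nonspecific is not None and p.nonspecific < 0:
                raise ValidationError(f"negative nonspecific level for {p.name}")
        if self.penetration_rate_mm_per_h <= 0:
            raise ValidationError("penetration_rate_mm_per_h must be > 0")
        if self.delay_mode not in ("surgery", "size_proportional", "constant"):
            raise ValidationError(f"unknown delay_mode {self.delay_mode!r}")
        for name in (
            "tumour_size_sigma", "abundance_sigma", "housekeeping_sigma",
            "lane_effect_sd", "input_amount_sd", "count_dispersion",
            "core_delay_h", "lumpectomy_offset_h", "mastectomy_offset_h",
            "constant_excision_delay_h", "negative_probe_mean",
            "endogenous_nonspecific", "igg_nonspecific",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.stress_tau_h <= 0 or self.count_scale <= 0:
            raise ValidationError("stress_tau_h and count_scale must be > 0")
        if not self.positive_ladder or any(v <= 0 for v in self.positive_ladder):
            raise ValidationError("positive_ladder must be strictly positive")


@dataclass
class SimTruth:
    """Latent generator state for parameter-recovery tests."""

    sizes_mm: pd.Series
    surgery: pd.Series
    delays_h: pd.Series
    core_abundance: pd.DataFrame  # protein x patient
    excision_abundance: pd.DataFrame
    mean_linear_reduction: pd.Series  # per protein, mean over patients of 1 - exc/core
    lane_effects: pd.Series
    input_amounts: pd.Series


def _probe_id(name: str) -> str:
    return name.replace("/", "-")


def _panel_annotations(params: SimParams) -> list[ProbeAnnotation]:
    probes = [
        ProbeAnnotation(_probe_id(p.name), p.name, "endogenous", p.is_phospho)
        for p in params.proteins
    ]
    probes += [
        ProbeAnnotation(f"POS_{chr(65 + i)}", f"ERCC pos {chr(65 + i)}", "positive")
        for i in range(len(params.positive_ladder))
    ]
    probes += [
        ProbeAnnotation(f"NEG_{chr(65 + i)}", f"ERCC neg {chr(65 + i)}", "negative")
        for i in range(params.n_negative_probes)
    ]
    probes += [
        ProbeAnnotation(f"IGG_{i + 1}", f"IgG control {i + 1}", "igg")
        for i in range(params.n_igg_probes)
    ]
    probes.append(ProbeAnnotation("HK_HistoneH3", "Histone H3", "housekeeping"))
    return probes


def _delays(params: SimParams, sizes: np.ndarray, surgery: list[str]) -> np.ndarray:
    half = sizes / 2.0
    rate = params.penetration_rate_mm_per_h
    if params.delay_mode == "constant":
        return np.full(sizes.shape, params.constant_excision_delay_h)
    if params.delay_mode == "size_proportional":
        return half / rate
    out = np.empty(sizes.shape)
    for i, surg in enumerate(surgery):
        if surg == "mastectomy":
            thickness = min(half[i], params.mastectomy_half_thickness_cap_mm)
            out[i] = thickness / rate + params.mastectomy_offset_h
        else:
            out[i] = half[i] / rate + params.lumpectomy_offset_h
    return out


def _artefact_factor(params: SimParams, spec: ProteinSpec, delay: np.ndarray) -> np.ndarray:
    decay = np.exp(-spec.lability * delay)
    stress = 1.0 + spec.stress_gain * (1.0 - np.exp(-delay / params.stress_tau_h))
    return decay * stress


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + disp*mu^2); dispersion 0 is the noiseless limit."""
    if dispersion == 0:
        return mu.copy()
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _lane_means(
    params: SimParams,
    abundance: pd.DataFrame,  # protein x lane latent abundances
    hk_abundance: pd.Series,  # per lane
    lane_effects: pd.Series,
    input_amounts: pd.Series,
    probe_ids: list[str],
) -> pd.DataFrame:
    """Expected counts per probe x lane under the measurement model."""
    lanes = list(abundance.columns)
    mu = pd.DataFrame(0.0, index=probe_ids, columns=lanes)
    bg = params.negative_probe_mean
    for spec in params.proteins:
        pid = _probe_id(spec.name)
        ns = params.endogenous_nonspecific if spec.nonspecific is None else spec.nonspecific
        signal = params.count_scale * abundance.loc[spec.name] + ns
        mu.loc[pid] = lane_effects * (input_amounts * signal + bg)
    mu.loc["HK_HistoneH3"] = lane_effects * (
        input_amounts * (params.count_scale * hk_abundance) + bg
    )
    for i, level in enumerate(params.positive_ladder):
        mu.loc[f"POS_{chr(65 + i)}"] = lane_effects * level
    for i in range(params.n_negative_probes):
        mu.loc[f"NEG_{chr(65 + i)}"] = lane_effects * bg
    for i in range(params.n_igg_probes):
        mu.loc[f"IGG_{i + 1}"] = lane_effects * (
            input_amounts * params.igg_nonspecific + bg
        )
    return mu


def _ihc_score(
    rng: np.random.Generator, model: IHCModel, abundance: np.ndarray
) -> np.ndarray:
    a = np.asarray(abundance, dtype=float)
    sat = a**model.hill / (a**model.hill + model.half_saturation**model.hill)
    score = model.max_value * sat
    if model.noise_sd > 0:
        score = score + rng.normal(0.0, model.noise_sd, size=score.shape)
    if model.scale == "ordinal_0_to_3":
        cuts = np.array(model.ordinal_cutpoints) * model.max_value
        return np.digitize(score, cuts).astype(float)
    lo, hi = {"h_score": (0.0, 300.0), "percent_positive": (0.0, 100.0)}[model.scale]
    return np.clip(score, lo, hi)


def generate_cohort(
    params: SimParams | None = None,
) -> tuple[Dataset, list[IHCRecord], SimTruth]:
    """Simulate a paired core/excision cohort.

    Deterministic for a fixed ``params.seed``; the pseudo-random draw
    order is: tumour sizes, abundances, housekeeping abundances, lane
    effects, input amounts, counts, IHC noise.
    """
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    patients = [f"P{i + 1:02d}" for i in range(n)]
    protein_names = [p.name for p in params.proteins]

    sizes = params.tumour_size_median_mm * np.exp(
        rng.normal(0.0, params.tumour_size_sigma, size=n)
    )
    surgery = [
        "mastectomy" if s > params.mastectomy_size_threshold_mm else "lumpectomy"
        for s in sizes
    ]
    abundance = pd.DataFrame(
        {
            spec.name: spec.base_abundance
            * np.exp(rng.normal(0.0, params.abundance_sigma, size=n))
            for spec in params.proteins
        },
        index=patients,
    ).T  # protein x patient
    hk_abundance = pd.Series(
        params.housekeeping_base
        * np.exp(rng.normal(0.0, params.housekeeping_sigma, size=n)),
        index=patients,
    )
    delays = _delays(params, sizes, surgery)

    core_ab = pd.DataFrame(index=protein_names, columns=patients, dtype=float)
    exc_ab = pd.DataFrame(index=protein_names, columns=patients, dtype=float)
    core_delay = np.full(n, params.core_delay_h)
    for spec in params.proteins:
        core_ab.loc[spec.name] = abundance.loc[spec.name].to_numpy() * _artefact_factor(
            params, spec, core_delay
        )
        exc_ab.loc[spec.name] = abundance.loc[spec.name].to_numpy() * _artefact_factor(
            params, spec, delays
        )

    lane_ids = [f"{p}-core" for p in patients] + [f"{p}-excision" for p in patients]
    lane_effects = pd.Series(
        np.exp(rng.normal(0.0, params.lane_effect_sd, size=2 * n)), index=lane_ids
    )
    input_amounts = pd.Series(
        np.exp(rng.normal(0.0, params.input_amount_sd, size=2 * n)), index=lane_ids
    )

    lane_abundance = pd.concat(
        [
            core_ab.rename(columns={p: f"{p}-core" for p in patients}),
            exc_ab.rename(columns={p: f"{p}-excision" for p in patients}),
        ],
        axis=1,
    )
    lane_hk = pd.Series(
        {f"{p}-core": hk_abundance[p] for p in patients}
        | {f"{p}-excision": hk_abundance[p] for p in patients}
    )[lane_ids]

    probes = _panel_annotations(params)
    probe_ids = [p.probe_id for p in probes]
    mu = _lane_means(params, lane_abundance, lane_hk, lane_effects, input_amounts, probe_ids)
    counts = pd.DataFrame(
        _draw_counts(rng, mu.to_numpy(dtype=float), params.count_dispersion),
        index=mu.index,
        columns=mu.columns,
    )

    samples = [
        SampleMetadata(
            lane_id=f"{p}-{spec}",
            patient_id=p,
            specimen=spec,
            surgery=surgery[i],
            tumour_size_mm=float(sizes[i]),
        )
        for i, p in enumerate(patients)
        for spec in ("core", "excision")
    ]
    dataset = Dataset(CountMatrix(counts, "raw"), probes, samples)

    ihc_records: list[IHCRecord] = []
    for name in protein_names:
        model = params.ihc_models.get(name)
        if model is None:
            continue
        for spec_type, table in (("core", core_ab), ("excision", exc_ab)):
            values = _ihc_score(rng, model, table.loc[name].to_numpy())
            ihc_records.extend(
                IHCRecord(patients[i], spec_type, name, model.scale, float(values[i]))
                for i in range(n)
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = 1.0 - exc_ab.div(core_ab).mean(axis=1)
    truth = SimTruth(
        sizes_mm=pd.Series(sizes, index=patients, name="tumour_size_mm"),
        surgery=pd.Series(surgery, index=patients, name="surgery"),
        delays_h=pd.Series(delays, index=patients, name="excision_delay_h"),
        core_abundance=core_ab,
        excision_abundance=exc_ab,
        mean_linear_reduction=reduction.rename("mean_linear_reduction"),
        lane_effects=lane_effects,
        input_amounts=input_amounts,
    )
    return dataset, ihc_records, truth


def generate_dilution_series(
    params: SimParams | None = None,
    n_samples: int = 6,
    dilutions: tuple[float, ...] = (5.0, 10.0, 20.0),
) -> Dataset:
    """Replicate lanes of ``n_samples`` core specimens at several dilutions.

    Counts scale (before count noise) by ``min(dilutions) / factor``, so
    the least-diluted replicate defines the reference signal level.
    """
    params = params or SimParams()
    params.validate()
    if len(dilutions) < 2:
        raise ValidationError("need at least 2 dilution factors")
    if any(f <= 0 for f in dilutions):
        raise ValidationError("dilution factors must be positive")
    if n_samples < 2:
        raise ValidationError("need at least 2 samples for dilution QC")
    if n_samples > params.n_patients:
        raise ValidationError("n_samples exceeds n_patients")
    rng = np.random.default_rng(params.seed)
    patients = [f"P{i + 1:02d}" for i in range(n_samples)]
    protein_names = [p.name for p in params.proteins]

    abundance = pd.DataFrame(
        {
            spec.name: spec.base_abundance
            * np.exp(rng.normal(0.0, params.abundance_sigma, size=n_samples))
            for spec in params.proteins
        },
        index=patients,
    ).T
    hk_abundance = pd.Series(
        params.housekeeping_base
        * np.exp(rng.normal(0.0, params.housekeeping_sigma, size=n_samples)),
        index=patients,
    )

    reference = min(dilutions)
    lane_ids, tags, lane_patient = [], {}, {}
    for p in patients:
        for f in dilutions:
            tag = f"{f:g}x"
            lane = f"{p}-core-{tag}"
            lane_ids.append(lane)
            tags[lane] = tag
            lane_patient[lane] = p
    lane_effects = pd.Series(
        np.exp(rng.normal(0.0, params.lane_effect_sd, size=len(lane_ids))),
        index=lane_ids,
    )
    input_amounts = pd.Series(
        np.exp(rng.normal(0.0, params.input_amount_sd, size=len(lane_ids))),
        index=lane_ids,
    )
    lane_abundance = pd.DataFrame(
        {lane: abundance[lane_patient[lane]] for lane in lane_ids},
        index=protein_names,
    )
    lane_hk = pd.Series({lane: hk_abundance[lane_patient[lane]] for lane in lane_ids})

    probes = _panel_annotations(params)
    probe_ids = [p.probe_id for p in probes]
    mu = _lane_means(params, lane_abundance, lane_hk, lane_effects, input_amounts, probe_ids)
    scale = pd.Series({lane: reference / float(tags[lane][:-1]) for lane in lane_ids})
    mu = mu.mul(scale, axis=1)
    counts = pd.DataFrame(
        _draw_counts(rng, mu.to_numpy(dtype=float), params.count_dispersion),
        index=mu.index,
        columns=mu.columns,
    )
    samples = [
        SampleMetadata(
            lane_id=lane,
            patient_id=lane_patient[lane],
            specimen="core",
            dilution_tag=tags[lane],
        )
        for lane in lane_ids
    ]
    return Dataset(CountMatrix(counts, "raw"), probes, samples)


def null_params(seed: int = 0, **overrides) -> SimParams:
    """Cohort with no specimen effect: all labilities and stress gains zero."""
    base = SimParams(seed=seed, **overrides)
    base.proteins = [
        replace(p, lability=0.0, stress_gain=0.0) for p in base.proteins
    ]
    return base
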