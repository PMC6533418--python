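"""Simulation studies that validate the pipeline end to end.

Each routine here generates cohorts with :mod:`proteofix.simulate`, pushes
them through the real normalization and analysis code, and summarizes an
operating characteristic: type-I error of the paired test under the
generator null, recovery of a known specimen effect, the delay-size
coupling, lane clustering separation, pooled-vs-stratified IHC
concordance, and dilution-replicate QC reliability. They are the basis of
the package's acceptance checks and are reusable for re-calibration when
generator parameters change.

All routines derive per-cohort seeds from a single master seed and are
deterministic given it.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cluster import dilution_replicate_check, two_way_cluster
from .differential import (
    difference_matrix,
    ihc_concordance,
    paired_protein_tests,
    size_association,
)
from .normalize import NormalizationOptions, run_normalization
from .simulate import (
    ProteinSpec,
    SimParams,
    generate_cohort,
    generate_dilution_series,
    null_params,
)

_SEED_CAP = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=n)


def _uniform_panel(
    n_proteins: int, lability: float, base_abundance: float = 80.0
) -> list[ProteinSpec]:
    return [
        ProteinSpec(f"T{i + 1:02d}", is_phospho=True, base_abundance=base_abundance,
                    lability=lability)
        for i in range(n_proteins)
    ]


def uniform_reduction_params(
    reduction: float, seed: int = 0, n_proteins: int = 10
) -> SimParams:
    """Cohort whose every protein has true mean linear reduction ``reduction``.

    A constant 1 h excision delay and lability ``-ln(1 - reduction)`` make
    the per-patient retention exactly ``1 - reduction``.
    """
    if not 0 <= reduction < 1:
        raise ValueError("reduction must be in [0, 1)")
    lam = -np.log(1.0 - reduction)
    return SimParams(
        proteins=_uniform_panel(n_proteins, lam),
        delay_mode="constant",
        constant_excision_delay_h=1.0,
        ihc_models={},
        seed=seed,
    )


# ------------------------------------------------------------------ 1-2
# (the normalization fixture and the enumeration-oracle comparisons live
# with the test suite / acceptance script, which own the frozen oracles)


def null_rejection_rate(
    n_cohorts: int = 2000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the per-protein paired Wilcoxon under the null.

    Each replicate is an independent 16-pair cohort carrying a single
    endogenous protein with zero lability and stress gain, so the 2,000
    tests are independent and the rejection fraction admits a binomial
    band. Housekeeping-normalization noise is shared across proteins
    within a cohort, which is why multi-protein cohorts would not give
    independent replicates.
    """
    seeds = _child_seeds(seed, n_cohorts)
    rejections = 0
    for s in seeds:
        params = SimParams(
            proteins=[ProteinSpec("T01", False, 80.0)],
            ihc_models={},
            seed=int(s),
        )
        dataset, _, _ = generate_cohort(params)
        expr, report = run_normalization(dataset)
        results = paired_protein_tests(
            expr, dataset.samples, dataset.probes, skip_probes=report.undetected_probes
        )
        if results[0].wilcoxon.p_value <= alpha:
            rejections += 1
    return {"rate": rejections / n_cohorts, "n": n_cohorts, "alpha": alpha}


def effect_recovery(
    reduction: float = 0.5, n_cohorts: int = 200, seed: int = 0, alpha: float = 0.01
) -> dict:
    """Power and bias for a known uniform specimen effect at 16 pairs."""
    seeds = _child_seeds(seed, n_cohorts)
    n_sig = 0
    n_tests = 0
    changes = []
    for s in seeds:
        params = uniform_reduction_params(reduction, seed=int(s))
        dataset, _, _ = generate_cohort(params)
        expr, report = run_normalization(dataset)
        results = paired_protein_tests(
            expr, dataset.samples, dataset.probes, skip_probes=report.undetected_probes
        )
        for r in results:
            n_tests += 1
            if r.wilcoxon.p_value < alpha:
                n_sig += 1
            changes.append(r.mean_percent_change)
    return {
        "power": n_sig / n_tests,
        "mean_percent_change": float(np.mean(changes)),
        "true_percent_change": -100.0 * reduction,
        "n": n_cohorts,
    }


def _ladder_params(seed: int, delay_mode: str) -> tuple[SimParams, list[str], float]:
    """Lability ladder over retention {1, .75, .5, .25} at the median delay."""
    d_ref = 33.5 / 2.0  # median size / 2 at 1 mm/h
    retentions = (1.0, 0.75, 0.5, 0.25)
    lams = [-np.log(r) / d_ref for r in retentions]
    proteins = []
    for j, lam in enumerate(lams):
        for k in range(2):
            proteins.append(
                ProteinSpec(
                    f"L{j}{k}", is_phospho=True, base_abundance=80.0, lability=lam
                )
            )
    midpoint = (min(lams) + max(lams)) / 2.0
    above = [p.name for p in proteins if p.lability > midpoint]
    params = SimParams(
        proteins=proteins,
        delay_mode=delay_mode,
        constant_excision_delay_h=d_ref,
        ihc_models={},
        seed=seed,
    )
    return params, above, midpoint


def size_coupling(n_cohorts: int = 100, seed: int = 0) -> dict:
    """Sign of Spearman(difference, tumour size) under delay-size coupling.

    With delay proportional to size, proteins whose lability exceeds the
    ladder midpoint should correlate negatively with size in most cohorts;
    the constant-delay control should be centred on zero.
    """
    seeds = _child_seeds(seed, n_cohorts)
    neg_counts: dict[str, int] = {}
    null_rhos = []
    for s in seeds:
        params, above, _ = _ladder_params(int(s), "size_proportional")
        dataset, _, _ = generate_cohort(params)
        expr, report = run_normalization(dataset)
        diff, _ = difference_matrix(expr, dataset.samples)
        assoc = size_association(diff, dataset.samples)
        for name in above:
            probe = name  # probe_id == name for ladder proteins
            if probe in assoc and assoc[probe].ok:
                neg_counts[name] = neg_counts.get(name, 0) + (assoc[probe].rho < 0)

        params_null, _, _ = _ladder_params(int(s), "constant")
        dataset, _, _ = generate_cohort(params_null)
        expr, report = run_normalization(dataset)
        diff, _ = difference_matrix(expr, dataset.samples)
        assoc = size_association(diff, dataset.samples)
        null_rhos.extend(r.rho for r in assoc.values() if r.ok)
    fractions = {k: v / n_cohorts for k, v in neg_counts.items()}
    return {
        "min_negative_fraction": min(fractions.values()),
        "per_protein_negative_fraction": fractions,
        "null_mean_rho": float(np.mean(null_rhos)),
        "n": n_cohorts,
    }


def clustering_separation_rate(n_seeds: int = 100, seed: int = 0) -> dict:
    """How often the lane-axis 2-cut splits cores from excisions (<=1 stray)."""
    seeds = _child_seeds(seed, n_seeds)
    hits = 0
    for s in seeds:
        params = SimParams(seed=int(s), ihc_models={})
        dataset, _, _ = generate_cohort(params)
        expr, _ = run_normalization(dataset)
        _, cols, _ = two_way_cluster(expr)
        meta = dataset.sample_map()
        truth = np.array(
            [1 if meta[l].specimen == "core" else 2 for l in cols.two_cut.index]
        )
        pred = cols.two_cut.to_numpy()
        mis = min(
            int((pred != truth).sum()), int((pred != (3 - truth)).sum())
        )
        if mis <= 1:
            hits += 1
    return {"rate": hits / n_seeds, "n": n_seeds}


def concordance_structure(n_cohorts: int = 100, seed: int = 0) -> dict:
    """Pooled vs within-specimen Spearman between expression and IHC."""
    seeds = _child_seeds(seed, n_cohorts)
    pooled, core, excision = [], [], []
    for s in seeds:
        params = SimParams(seed=int(s))
        dataset, ihc, _ = generate_cohort(params)
        expr, report = run_normalization(
            dataset, NormalizationOptions(subtract_igg=False)
        )
        results, _ = ihc_concordance(expr, ihc, dataset.samples, dataset.probes)
        for r in results:
            if r.pooled.ok and r.core_only.ok and r.excision_only.ok:
                pooled.append(r.pooled.rho)
                core.append(r.core_only.rho)
                excision.append(r.excision_only.rho)
    return {
        "pooled_mean_rho": float(np.mean(pooled)),
        "core_mean_rho": float(np.mean(core)),
        "excision_mean_rho": float(np.mean(excision)),
        "n": n_cohorts,
    }


def dilution_qc_pass_rate(
    n_seeds: int = 50,
    seed: int = 0,
    n_samples: int = 6,
    dilutions: tuple[float, ...] = (5.0, 10.0, 20.0),
) -> dict:
    """How often every sample's dilution replicates cluster together."""
    seeds = _child_seeds(seed, n_seeds)
    hits = 0
    for s in seeds:
        params = SimParams(seed=int(s), ihc_models={})
        dataset = generate_dilution_series(params, n_samples=n_samples, dilutions=dilutions)
        passes, _ = dilution_replicate_check(dataset)
        if all(passes.values()):
            hits += 1
    return {"rate": hits / n_seeds, "n": n_seeds}
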