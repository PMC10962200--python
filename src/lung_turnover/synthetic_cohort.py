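"""Synthetic longitudinal lung-microbiota cohorts.

Emulates the statistical structure the analysis assumes so that every stage
is testable without sequencing data: 6-20 samples per patient spread over
785-1166 days; a resident taxon class (high detection probability, high
latent abundance) and a transient class (low, rare), coupled through a
logit-linear link so persistence-abundance relationships are positive by
construction; and clinical covariates in which exacerbation counts are
inversely related to %FEV1.

Two between-sample overlap regimes are provided.  In the ``homogenizing``
regime each patient has a personal taxon pool and a fixed presence template
that every sample re-expresses with small independent flip noise, giving
within-patient overlap far above the cohort-level null.  In the ``drift``
regime every sample is assembled by a weighted lottery from one shared
global pool -- the same kind of draw the Raup-Crick null itself performs:
a community of n taxa (n drawn from the ``sample_richness`` range) is the
top-n of Gumbel-perturbed log-propensities, with per-taxon propensity
``detection_prob ** assembly_evenness``.  Residents (high propensity) are
captured in most lotteries and realize > 50% persistence; transients are
rare.  Temporal memory enters through an AR(1) Gaussian copula on the
Gumbel noise with lag correlation exp(-dt / correlation_time_days): nearby
visits share composition, so the union of observed taxa grows with elapsed
time and the species-time exponent is positive -- much more so for the
transient fraction, whose membership churns, than for the stably captured
residents.  With correlation_time_days = 0 samples are fully independent
lotteries.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr

from .cohort_io import (
    Cohort,
    CohortDataset,
    PatientMetadata,
    SampleRecord,
    SampleType,
    TaxaTimeSeries,
    read_clinical_metadata,
)

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for synthetic cohorts.

    Ranges are closed intervals sampled uniformly per patient/taxon.  The
    resident detection range must sit entirely above 0.5 so that designated
    residents are expected to satisfy the Leeds chronic criterion.
    """

    n_patients_per_cohort: int = 15
    global_pool_size: int = 600
    per_patient_pool: tuple[int, int] = (120, 260)
    resident_fraction: float = 0.12
    resident_detection_prob: tuple[float, float] = (0.70, 0.98)
    transient_detection_prob: tuple[float, float] = (0.02, 0.30)
    abundance_coupling: float = 0.5  # log10 abundance per logit(detection) unit
    abundance_base: float = -2.0  # log10 latent abundance at p = 0.5
    abundance_noise_sd: float = 0.3  # taxon-level scatter, log10 units
    lognormal_sigma: float = 1.0  # per-sample multiplicative noise (ln units)
    n_samples: tuple[int, int] = (6, 20)
    duration_days: tuple[int, int] = (785, 1166)
    regime: str = "drift"
    correlation_time_days: float = 25.0  # drift regime; 0 = independent samples
    assembly_evenness: float = 0.7  # drift lottery propensity = p ** evenness
    sample_richness: tuple[int, int] | None = None  # drift; default per_patient_pool
    flip_noise: float = 0.05  # homogenizing regime template noise
    fev1_mean: Mapping[str, float] = field(
        default_factory=lambda: {"paediatric": 90.5, "adult": 75.9}
    )
    fev1_sd: Mapping[str, float] = field(
        default_factory=lambda: {"paediatric": 14.5, "adult": 18.9}
    )
    exacerbation_intercept: float = 3.0  # log Poisson rate at %FEV1 = 0
    exacerbation_link: float = -0.03  # per %FEV1; negative = inverse relation
    fev1_process_coupling: float = 0.0  # > 0 ties low %FEV1 to longer memory
    sputum_fraction: float = 0.7

    def __post_init__(self) -> None:
        for name in ("resident_detection_prob", "transient_detection_prob"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi < 1.0):
                raise GeneratorError(f"{name} must be within (0, 1)")
        if self.resident_detection_prob[0] <= 0.5:
            raise GeneratorError(
                "resident_detection_prob must lie entirely above 0.5"
            )
        if self.duration_days[0] <= 0 or self.duration_days[0] > self.duration_days[1]:
            raise GeneratorError("duration_days must be a positive range")
        if self.n_samples[0] < 2 or self.n_samples[0] > self.n_samples[1]:
            raise GeneratorError("n_samples must be a range with minimum >= 2")
        if self.n_samples[1] > self.duration_days[0] + 1:
            raise GeneratorError(
                "n_samples range exceeds the shortest duration (need distinct days)"
            )
        if not 0.0 < self.resident_fraction < 1.0:
            raise GeneratorError("resident_fraction must be in (0, 1)")
        if not (2 <= self.per_patient_pool[0] <= self.per_patient_pool[1]
                <= self.global_pool_size):
            raise GeneratorError("per_patient_pool must fit in the global pool")
        if self.regime not in ("homogenizing", "drift"):
            raise GeneratorError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.flip_noise < 0.5:
            raise GeneratorError("flip_noise must be in [0, 0.5)")
        if self.correlation_time_days < 0:
            raise GeneratorError("correlation_time_days must be >= 0")
        if not 0.0 < self.assembly_evenness <= 1.0:
            raise GeneratorError("assembly_evenness must be in (0, 1]")
        lo, hi = self.richness_range
        if not 1 <= lo <= hi <= self.global_pool_size:
            raise GeneratorError("sample_richness must fit in the global pool")

    @property
    def richness_range(self) -> tuple[int, int]:
        return (
            self.sample_richness
            if self.sample_richness is not None
            else self.per_patient_pool
        )


@dataclass(frozen=True)
class TaxonProfile:
    """Latent per-taxon parameters: detection probability and log-abundance."""

    taxa: tuple[str, ...]
    detection_prob: np.ndarray
    log10_abundance: np.ndarray
    is_resident: np.ndarray


def _make_profile(
    config: GeneratorConfig, taxa: tuple[str, ...], rng: np.random.Generator
) -> TaxonProfile:
    n = len(taxa)
    n_resident = max(1, round(config.resident_fraction * n))
    is_resident = np.zeros(n, dtype=bool)
    is_resident[rng.choice(n, size=n_resident, replace=False)] = True
    p = np.where(
        is_resident,
        rng.uniform(*config.resident_detection_prob, size=n),
        rng.uniform(*config.transient_detection_prob, size=n),
    )
    logit = np.log(p / (1.0 - p))
    mu = (
        config.abundance_base
        + config.abundance_coupling * logit
        + rng.normal(0.0, config.abundance_noise_sd, size=n)
    )
    return TaxonProfile(
        taxa=taxa, detection_prob=p, log10_abundance=mu, is_resident=is_resident
    )


def _global_taxa(config: GeneratorConfig) -> tuple[str, ...]:
    width = len(str(config.global_pool_size))
    return tuple(f"t{i:0{width}d}" for i in range(1, config.global_pool_size + 1))


def cohort_taxon_profile(config: GeneratorConfig, seed) -> TaxonProfile:
    """Cohort-level latent profile over the global pool (drift regime)."""
    return _make_profile(config, _global_taxa(config), np.random.default_rng(seed))


def _sampling_days(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(rng.integers(config.n_samples[0], config.n_samples[1] + 1))
    last = int(rng.integers(config.duration_days[0], config.duration_days[1] + 1))
    if n > last + 1:
        raise GeneratorError(f"{n} samples cannot fit in {last} days")
    interior = rng.choice(np.arange(1, last), size=n - 2, replace=False)
    return np.concatenate(([0], np.sort(interior), [last]))


def _patient_tau(
    config: GeneratorConfig, fev1: float | None, cohort: str | None
) -> float:
    tau = config.correlation_time_days
    if config.fev1_process_coupling and fev1 is not None:
        label = cohort or "adult"
        mean = config.fev1_mean[label]
        sd = config.fev1_sd[label]
        # low %FEV1 -> longer compositional memory -> more homogenizing pairs
        tau *= math.exp(config.fev1_process_coupling * (mean - fev1) / sd)
    return tau


def generate_patient_series(
    config: GeneratorConfig,
    patient_id: str,
    seed,
    fev1: float | None = None,
    cohort: str | None = None,
    profile: TaxonProfile | None = None,
) -> TaxaTimeSeries:
    """One patient's taxa x sample relative-abundance series.

    In the drift regime the shared cohort ``profile`` should be passed (it is
    built from ``seed`` otherwise); in the homogenizing regime a personal
    taxon pool and presence template are drawn per patient.
    """
    rng = np.random.default_rng(seed)
    days = _sampling_days(config, rng)
    n_samples = days.size

    if config.regime == "drift":
        if profile is None:
            profile = cohort_taxon_profile(config, rng)
        pres = _lottery_presence(
            config, profile, days, _patient_tau(config, fev1, cohort), rng
        )
    else:
        pool_size = int(
            rng.integers(config.per_patient_pool[0], config.per_patient_pool[1] + 1)
        )
        taxa_all = _global_taxa(config)
        chosen = np.sort(rng.choice(len(taxa_all), size=pool_size, replace=False))
        profile = _make_profile(
            config, tuple(taxa_all[i] for i in chosen), rng
        )
        template = rng.random(pool_size) < profile.detection_prob
        flips = rng.random((pool_size, n_samples)) < config.flip_noise
        pres = template[:, None] ^ flips

    noise = rng.normal(0.0, config.lognormal_sigma, size=pres.shape)
    values = np.where(
        pres, np.exp(LN10 * profile.log10_abundance[:, None] + noise), 0.0
    )
    if np.any(values.sum(axis=0) <= 0):
        raise GeneratorError(
            f"patient {patient_id!r}: a sample detected no taxa; the "
            "configured detection probabilities are infeasibly sparse"
        )
    sample_types = np.where(
        rng.random(n_samples) < config.sputum_fraction,
        SampleType.SPUTUM.value,
        SampleType.COUGH_SWAB.value,
    )
    samples = [
        SampleRecord(
            sample_id=f"{patient_id}_s{j:02d}",
            patient_id=patient_id,
            collection_day=int(day),
            sample_type=SampleType(sample_types[j]),
        )
        for j, day in enumerate(days)
    ]
    return TaxaTimeSeries.from_counts(patient_id, profile.taxa, samples, values)


def _lottery_presence(
    config: GeneratorConfig,
    profile: TaxonProfile,
    days: np.ndarray,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted-lottery assembly with temporal memory.

    Each sample is the top-n of log-propensity + Gumbel noise (a weighted
    draw without replacement, the same construction the Raup-Crick null
    uses); the Gumbel noise comes from an AR(1) Gaussian copula per taxon
    with lag correlation exp(-dt/tau), so compositions decorrelate over
    elapsed time.
    """
    n_taxa, n_samples = len(profile.taxa), days.size
    log_propensity = config.assembly_evenness * np.log(profile.detection_prob)
    z = np.empty((n_taxa, n_samples))
    z[:, 0] = rng.normal(size=n_taxa)
    for j in range(1, n_samples):
        dt = float(days[j] - days[j - 1])
        rho = math.exp(-dt / tau) if tau > 0 else 0.0
        z[:, j] = rho * z[:, j - 1] + math.sqrt(1.0 - rho * rho) * rng.normal(
            size=n_taxa
        )
    uniform = ndtr(z)
    gumbel = -np.log(-np.log(np.clip(uniform, 1e-12, 1.0 - 1e-12)))
    keys = log_propensity[:, None] + gumbel
    lo, hi = config.richness_range
    richness = rng.integers(lo, hi + 1, size=n_samples)
    pres = np.zeros((n_taxa, n_samples), dtype=bool)
    for j in range(n_samples):
        top = np.argpartition(-keys[:, j], richness[j])[: richness[j]]
        pres[top, j] = True
    return pres


def generate_cohort(config: GeneratorConfig, seed) -> CohortDataset:
    """Paediatric-like plus adult-like cohorts with clinical metadata.

    %FEV1 is Normal(cohort mean, cohort SD) truncated positive; exacerbation
    counts are Poisson with log-rate linear in %FEV1 through the (negative)
    ``exacerbation_link``.  Fully reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    profile_seed, meta_seed, *patient_seeds = ss.spawn(
        2 + 2 * config.n_patients_per_cohort
    )
    profile = (
        cohort_taxon_profile(config, profile_seed)
        if config.regime == "drift"
        else None
    )
    meta_rng = np.random.default_rng(meta_seed)

    series: dict[str, TaxaTimeSeries] = {}
    metadata: dict[str, PatientMetadata] = {}
    cohorts = (Cohort.PAEDIATRIC, Cohort.ADULT)
    for k, cohort in enumerate(cohorts):
        for i in range(config.n_patients_per_cohort):
            pid = f"{cohort.value[0]}{i + 1:03d}"
            fev1 = -1.0
            while fev1 <= 0:
                fev1 = float(
                    meta_rng.normal(
                        config.fev1_mean[cohort.value], config.fev1_sd[cohort.value]
                    )
                )
            rate = math.exp(
                config.exacerbation_intercept + config.exacerbation_link * fev1
            )
            metadata[pid] = PatientMetadata(
                patient_id=pid,
                cohort=cohort,
                mean_fev1=round(fev1, 1),
                fev1_sd=round(float(meta_rng.gamma(4.0, 1.5)), 1),
                exacerbations=int(meta_rng.poisson(rate)),
            )
            series[pid] = generate_patient_series(
                config,
                pid,
                patient_seeds[k * config.n_patients_per_cohort + i],
                fev1=metadata[pid].mean_fev1,
                cohort=cohort.value,
                profile=profile,
            )
    return CohortDataset(series=series, metadata=metadata)


def table1_fixture() -> dict[str, PatientMetadata]:
    """Clinical characteristics of the 30-patient reference CF cohort (15
    paediatric, 15 adult) shipped with the package: per-patient cohort,
    study-mean %FEV1 with SD, and acute pulmonary exacerbation count."""
    resource = importlib.resources.files("lung_turnover").joinpath(
        "data/table1_clinical.tsv"
    )
    with importlib.resources.as_file(resource) as path:
        return read_clinical_metadata(path)
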