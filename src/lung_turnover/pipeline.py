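"""End-to-end orchestration: load -> filter -> partition -> PAR -> STR ->
Raup-Crick -> cohort statistics -> write.

Stages can be run selectively (the CLI's classify/str/processes/stats
subcommands); later stages pull in the in-memory results of the earlier ones
they need.  Every excluded patient, dropped taxon, skipped empty sample and
dropped STR point is logged and recorded in the summary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assembly_processes as ap
from . import cohort_statistics as cs
from .cohort_io import (
    Cohort,
    CohortDataset,
    ResultsBundle,
    apply_inclusion_criteria,
    read_clinical_metadata,
    read_taxa_table,
    write_results,
)
from .persistence_classification import (
    Group,
    fit_par,
    partition_leeds,
    subset_series,
    taxon_persistence,
)
from .temporal_turnover import (
    STRMode,
    TurnoverError,
    fit_power_law,
    str_points,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("classify", "str", "processes", "stats")
GROUP_ORDER = (Group.MICROBIOTA, Group.CHRONIC, Group.INTERMITTENT)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    taxa_table: str | None = None
    manifest: str | None = None
    clinical: str | None = None
    out_dir: str | None = None
    min_samples: int = 6
    min_duration_days: int = 731
    persistence_threshold_pct: float = 50.0
    detection_min: float = 0.0
    par_abundance_transform: str = "log10"
    str_mode: str = "pairwise"
    rc_iterations: int = 1000
    rc_threshold: float = 0.95
    rc_weighting: str = "occurrence"
    dunn_adjustment: str = "bonferroni"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.persistence_threshold_pct < 100:
            raise PipelineError("persistence_threshold_pct outside (0, 100)")
        if not 0 < self.rc_threshold <= 1:
            raise PipelineError("rc_threshold outside (0, 1]")
        if self.rc_iterations < 1:
            raise PipelineError("rc_iterations must be >= 1")
        STRMode(self.str_mode)
        ap.Weighting(self.rc_weighting)
        if self.dunn_adjustment not in ("none", "bonferroni", "holm"):
            raise PipelineError(f"unknown dunn_adjustment {self.dunn_adjustment!r}")


@dataclass
class PipelineResults:
    bundle: ResultsBundle
    partitions: dict = field(default_factory=dict)
    par_fits: dict = field(default_factory=dict)
    str_fits: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    written: set = field(default_factory=set)


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Load inputs from the configured paths and run every stage."""
    if config.taxa_table is None or config.manifest is None:
        raise PipelineError("taxa_table and manifest paths are required")
    dataset = read_taxa_table(config.taxa_table, config.manifest)
    if config.clinical:
        dataset = dataset.with_metadata(read_clinical_metadata(config.clinical))
    return run_pipeline_on_dataset(dataset, config)


def run_pipeline_on_dataset(
    dataset: CohortDataset,
    config: PipelineConfig = PipelineConfig(),
    stages: tuple[str, ...] = ALL_STAGES,
) -> PipelineResults:
    """Run the analysis on an in-memory dataset (e.g. a synthetic cohort)."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s) {sorted(unknown)}")
    want_processes = "processes" in stages or "stats" in stages
    want_str = "str" in stages or "stats" in stages

    filtered, exclusions = apply_inclusion_criteria(
        dataset, config.min_samples, config.min_duration_days
    )
    logger.info(
        "inclusion: %d of %d patients retained",
        len(filtered.series), len(dataset.series),
    )
    errors: list[str] = []

    # --- persistence + Leeds partition + PAR (always needed downstream)
    partitions: dict[str, list] = {}
    par_fits: dict[str, object] = {}
    persistence_rows = []
    for pid in filtered.patient_ids:
        series = filtered.series[pid]
        records = partition_leeds(
            taxon_persistence(series, config.detection_min),
            config.persistence_threshold_pct,
        )
        partitions[pid] = records
        for r in records:
            persistence_rows.append(
                {
                    "patient_id": pid,
                    "taxon_id": r.taxon_id,
                    "n_samples_detected": r.n_detected,
                    "n_samples_total": r.n_total,
                    "persistence_pct": r.persistence_pct,
                    "mean_rel_abund_detected": r.mean_abund_detected,
                    "status": r.status.value,
                }
            )
        try:
            par_fits[pid] = fit_par(records, config.par_abundance_transform)
        except Exception as exc:  # noqa: BLE001 - aggregated with context
            errors.append(f"PAR fit, patient {pid}: {exc}")

    # --- species-time relationships
    str_fits: dict[tuple[str, Group], object] = {}
    str_point_rows, str_fit_rows = [], []
    if want_str:
        for pid in filtered.patient_ids:
            series = filtered.series[pid]
            for group in GROUP_ORDER:
                sub = subset_series(series, partitions[pid], group)
                try:
                    points = str_points(sub, config.str_mode, config.detection_min)
                    fit = fit_power_law(points, group=group,
                                        mode=STRMode(config.str_mode))
                except TurnoverError as exc:
                    errors.append(f"STR, patient {pid}, group {group.value}: {exc}")
                    continue
                str_fits[(pid, group)] = fit
                for pt in points:
                    str_point_rows.append(
                        {
                            "patient_id": pid,
                            "group": group.value,
                            "window_start_sample": pt.window_start,
                            "T_days": pt.T,
                            "S_taxa": pt.S,
                        }
                    )
                str_fit_rows.append(
                    {
                        "patient_id": pid, "group": group.value,
                        "c": fit.c, "w": fit.w, "r2": fit.r2, "F": fit.F,
                        "df1": fit.df[0], "df2": fit.df[1], "p": fit.p,
                        "n_points": fit.n_points,
                    }
                )

    # --- Raup-Crick process attribution
    frequencies: dict[tuple[str, Group], ap.ProcessFrequencies] = {}
    rc_rows, freq_rows = [], []
    if want_processes and filtered.series:
        pools = {}
        for group in GROUP_ORDER:
            try:
                pools[group] = ap.build_regional_pool(
                    filtered, group, config.rc_weighting, partitions,
                    config.detection_min,
                )
            except ap.AssemblyError as exc:
                errors.append(f"regional pool, group {group.value}: {exc}")
        for pid in filtered.patient_ids:
            series = filtered.series[pid]
            for group in GROUP_ORDER:
                if group not in pools:
                    continue
                sub = subset_series(series, partitions[pid], group)
                pairs = ap.raup_crick_matrix(
                    sub, pools[group],
                    iterations=config.rc_iterations,
                    seed=config.seed,
                    label=group.value,
                    threshold=config.rc_threshold,
                    detection_min=config.detection_min,
                )
                if not pairs:
                    errors.append(
                        f"Raup-Crick, patient {pid}, group {group.value}: "
                        "fewer than two non-empty samples"
                    )
                    continue
                for pr in pairs:
                    rc_rows.append(
                        {
                            "patient_id": pid, "group": group.value,
                            "sample_a": pr.sample_a, "sample_b": pr.sample_b,
                            "s_rc": pr.s_rc, "process": pr.process.value,
                        }
                    )
                freq = ap.process_frequencies(pairs, pid, group)
                frequencies[(pid, group)] = freq
                freq_rows.append(
                    {
                        "patient_id": pid, "group": group.value,
                        "pct_homogenizing": freq.pct_homogenizing,
                        "pct_drift": freq.pct_drift,
                        "pct_limitation": freq.pct_limitation,
                        "n_pairs": freq.n_pairs,
                    }
                )

    if errors:
        raise PipelineError(
            "pipeline stage errors:\n  " + "\n  ".join(errors)
        )

    summary: dict = {
        "config": dataclasses.asdict(config),
        "n_patients_loaded": len(dataset.series),
        "n_patients_retained": len(filtered.series),
        "exclusions": [dataclasses.asdict(e) for e in exclusions],
        "par_fits": {p: dataclasses.asdict(f) for p, f in par_fits.items()},
    }
    if "stats" in stages and filtered.metadata:
        summary["cohort_statistics"] = _cohort_statistics(
            filtered, partitions, str_fits, frequencies, config
        )

    bundle = ResultsBundle(
        persistence=pd.DataFrame(persistence_rows) if persistence_rows else None,
        str_points=pd.DataFrame(str_point_rows) if str_point_rows else None,
        str_fits=pd.DataFrame(str_fit_rows) if str_fit_rows else None,
        raup_crick_pairs=pd.DataFrame(rc_rows) if rc_rows else None,
        process_frequencies=pd.DataFrame(freq_rows) if freq_rows else None,
        summary=summary,
    )
    results = PipelineResults(
        bundle=bundle,
        partitions=partitions,
        par_fits=par_fits,
        str_fits=str_fits,
        frequencies=frequencies,
    )
    if config.out_dir:
        results.written = write_results(bundle, Path(config.out_dir))
    return results


def _cohort_statistics(dataset, partitions, str_fits, frequencies, config) -> dict:
    """Cohort-level summaries and tests mirroring the study's reporting."""
    meta = dataset.metadata
    out: dict = {}

    fev1 = {p: m.mean_fev1 for p, m in meta.items()}
    out["fev1"] = {
        "summaries": cs.cohort_summaries(fev1, meta),
    }
    by_cohort = {
        c.value: [m.mean_fev1 for m in meta.values() if m.cohort is c]
        for c in Cohort
    }
    if all(len(v) >= 2 for v in by_cohort.values()):
        out["fev1"]["kruskal_paediatric_vs_adult"] = cs.kruskal_wallis(
            by_cohort["paediatric"], by_cohort["adult"]
        )
        out["fev1"]["dunn"] = cs.dunn_posthoc(
            [by_cohort["paediatric"], by_cohort["adult"]], config.dunn_adjustment
        )
    if len(meta) >= 3:
        out["exacerbations_vs_fev1"] = cs.simple_ols(
            [m.mean_fev1 for m in meta.values()],
            [m.exacerbations for m in meta.values()],
        )

    richness = {
        Group.MICROBIOTA: {p: len(r) for p, r in partitions.items()},
        Group.CHRONIC: {
            p: sum(x.status.value == "chronic" for x in r)
            for p, r in partitions.items()
        },
        Group.INTERMITTENT: {
            p: sum(x.status.value == "intermittent" for x in r)
            for p, r in partitions.items()
        },
    }
    out["richness"] = {
        g.value: cs.cohort_summaries(vals, meta) for g, vals in richness.items()
    }

    if str_fits:
        out["temporal_scaling_w"] = {}
        w_by_group = {}
        for group in GROUP_ORDER:
            vals = {
                p: f.w for (p, g), f in str_fits.items() if g is group
            }
            w_by_group[group] = list(vals.values())
            if vals:
                out["temporal_scaling_w"][group.value] = cs.cohort_summaries(
                    vals, meta
                )
        if (
            len(w_by_group.get(Group.CHRONIC, [])) >= 2
            and len(w_by_group.get(Group.INTERMITTENT, [])) >= 2
        ):
            out["w_kruskal_chronic_vs_intermittent"] = cs.kruskal_wallis(
                w_by_group[Group.CHRONIC], w_by_group[Group.INTERMITTENT]
            )

    if frequencies:
        out["process_frequencies"] = {}
        for group in GROUP_ORDER:
            vals = {
                p: f.pct_homogenizing
                for (p, g), f in frequencies.items()
                if g is group
            }
            if vals:
                out["process_frequencies"][group.value] = {
                    "pct_homogenizing": cs.cohort_summaries(vals, meta),
                    "pct_drift": cs.cohort_summaries(
                        {
                            p: f.pct_drift
                            for (p, g), f in frequencies.items()
                            if g is group
                        },
                        meta,
                    ),
                }
        microbiota_freqs = {
            p: f for (p, g), f in frequencies.items() if g is Group.MICROBIOTA
        }
        out["process_vs_fev1"] = {}
        for cohort in Cohort:
            eligible = [
                p for p in microbiota_freqs if meta[p].cohort is cohort
            ]
            if len(eligible) >= 3:
                out["process_vs_fev1"][cohort.value] = (
                    cs.process_lungfunction_regressions(
                        microbiota_freqs, meta, cohort.value
                    )
                )
    return out
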