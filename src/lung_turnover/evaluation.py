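"""Self-contained evaluation runs: reference-cohort statistics, Raup-Crick
oracle agreement, exact species-time fits, and synthetic-regime property
rates.

These functions recompute every headline quantity from scratch by running
the package's own operations; they back both the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from . import assembly_processes as ap
from .cohort_io import Cohort
from .cohort_statistics import kruskal_wallis, simple_ols
from .persistence_classification import Group
from .pipeline import PipelineConfig, run_pipeline_on_dataset
from .synthetic_cohort import GeneratorConfig, generate_cohort, table1_fixture
from .temporal_turnover import STRPoint, fit_power_law


def reference_cohort_statistics() -> dict[str, float]:
    """Recompute the headline clinical statistics from the packaged 30-patient
    reference cohort table: per-cohort mean %FEV1, the paediatric-vs-adult
    Kruskal-Wallis H, and the exacerbations-vs-%FEV1 regression."""
    meta = table1_fixture()
    paed = [m.mean_fev1 for m in meta.values() if m.cohort is Cohort.PAEDIATRIC]
    adult = [m.mean_fev1 for m in meta.values() if m.cohort is Cohort.ADULT]
    kw = kruskal_wallis(paed, adult)
    ols = simple_ols(
        [m.mean_fev1 for m in meta.values()],
        [m.exacerbations for m in meta.values()],
    )
    return {
        "n_patients": len(meta),
        "paediatric_mean_fev1": float(np.mean(paed)),
        "adult_mean_fev1": float(np.mean(adult)),
        "fev1_kruskal_H": kw.H,
        "fev1_kruskal_p": kw.p,
        "exacerbation_fev1_r2": ols.r2,
        "exacerbation_fev1_F": ols.F,
        "exacerbation_fev1_p": ols.p,
    }


def _uniform_pool(size: int) -> ap.SpeciesPool:
    return ap.SpeciesPool(
        taxa=tuple(f"t{i}" for i in range(size)),
        occurrence=np.ones(size, dtype=int),
        weights=np.full(size, 1.0 / size),
    )


def rc_oracle_agreement(
    seed: int, n_cases: int = 50, iterations: int = 100_000
) -> dict[str, float]:
    """Monte-Carlo vs closed-form hypergeometric S_RC on random uniform pools
    of <= 12 taxa, plus the two worked identical-pair values (pool sizes 6
    and 10, two shared taxa)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for case in range(n_cases):
        size = int(rng.integers(3, 13))
        pool = _uniform_pool(size)
        n_a = int(rng.integers(1, size + 1))
        n_b = int(rng.integers(1, size + 1))
        set_a = list(rng.choice(pool.taxa, n_a, replace=False))
        set_b = list(rng.choice(pool.taxa, n_b, replace=False))
        shared = len(set(set_a) & set(set_b))
        exact = ap.exact_null_srcs(pool, n_a, n_b, shared)
        mc = ap.raup_crick_pair(
            set_a, set_b, pool, iterations=iterations,
            seed=int(rng.integers(2**31)),
        ).s_rc
        p_exact = (exact + 1.0) / 2.0
        se = 2.0 * np.sqrt(p_exact * (1.0 - p_exact) / iterations)
        if abs(mc - exact) <= 3.0 * se + 1e-12:
            agree += 1
    pool6, pool10 = _uniform_pool(6), _uniform_pool(10)
    return {
        "mc_within_3se_pct": 100.0 * agree / n_cases,
        "n_cases": n_cases,
        "exact_srcs_pool6": ap.exact_null_srcs(pool6, 2, 2, 2),
        "exact_srcs_pool10": ap.exact_null_srcs(pool10, 2, 2, 2),
    }


def str_exact_checks(seed: int = 0) -> dict[str, float]:
    """Exact species-time facts: the power-law triple (10,20)->(1000,80)
    recovers w = log10(2) with r2 = 1; a constant community has w = 0; and
    pairwise S equals the presence-set union cardinality on a simulated
    series (fraction of adjacent pairs agreeing with a brute-force union
    count)."""
    triple = [
        STRPoint(T=10, S=20, window_start=0, window_len=2),
        STRPoint(T=100, S=40, window_start=1, window_len=2),
        STRPoint(T=1000, S=80, window_start=2, window_len=2),
    ]
    fit = fit_power_law(triple)
    constant = [
        STRPoint(T=t, S=7, window_start=i, window_len=2)
        for i, t in enumerate((20, 50, 90, 160))
    ]
    flat = fit_power_law(constant)

    from .synthetic_cohort import generate_patient_series
    from .temporal_turnover import str_points

    series = generate_patient_series(
        GeneratorConfig(), "check", np.random.SeedSequence(seed)
    )
    points = str_points(series)
    sets = series.presence_sets()
    matches = sum(
        int(pt.S == len(sets[i] | sets[i + 1]))
        for i, pt in enumerate(points)
    )
    return {
        "power_law_w": fit.w,
        "power_law_c": fit.c,
        "power_law_r2": fit.r2,
        "constant_community_w": flat.w,
        "pairwise_union_match_pct": 100.0 * matches / len(points),
    }


def synthetic_regime_properties(
    seed: int,
    n_patients_per_cohort: int = 50,
    rc_iterations: int = 1000,
) -> dict[str, float]:
    """Property rates on freshly generated cohorts (drift and homogenizing
    regimes), computed by the full pipeline.

    Returns per-patient success rates for: positive significant PARs, the
    chronic-vs-intermittent turnover ordering, drift being the modal
    whole-microbiota process (drift regime), chronic-group homogenizing
    dominance (homogenizing regime), frequency-sum integrity, and full-run
    determinism.
    """
    out: dict[str, float] = {}
    pipe = PipelineConfig(rc_iterations=rc_iterations, seed=seed)

    drift = generate_cohort(
        GeneratorConfig(n_patients_per_cohort=n_patients_per_cohort), seed
    )
    res = run_pipeline_on_dataset(drift, pipe)

    par = list(res.par_fits.values())
    out["par_positive_significant_pct"] = 100.0 * float(
        np.mean([f.slope > 0 and f.p < 0.05 for f in par])
    )
    w_ch = [f.w for (p, g), f in res.str_fits.items() if g is Group.CHRONIC]
    w_int = [f.w for (p, g), f in res.str_fits.items() if g is Group.INTERMITTENT]
    out["median_w_chronic"] = float(np.median(w_ch))
    out["median_w_intermittent"] = float(np.median(w_int))
    out["w_kruskal_p"] = kruskal_wallis(w_ch, w_int).p

    modal = []
    sums_ok = True
    for (pid, group), freq in res.frequencies.items():
        total = freq.pct_homogenizing + freq.pct_drift + freq.pct_limitation
        sums_ok = sums_ok and abs(total - 100.0) <= 1e-9
        if group is Group.MICROBIOTA:
            modal.append(
                freq.pct_drift > max(freq.pct_homogenizing, freq.pct_limitation)
            )
    out["drift_modal_microbiota_pct"] = 100.0 * float(np.mean(modal))

    homog = generate_cohort(
        GeneratorConfig(
            n_patients_per_cohort=n_patients_per_cohort, regime="homogenizing"
        ),
        seed + 1,
    )
    res_h = run_pipeline_on_dataset(homog, pipe)
    chronic_high = [
        f.pct_homogenizing >= 80.0
        for (p, g), f in res_h.frequencies.items()
        if g is Group.CHRONIC
    ]
    for (pid, group), freq in res_h.frequencies.items():
        total = freq.pct_homogenizing + freq.pct_drift + freq.pct_limitation
        sums_ok = sums_ok and abs(total - 100.0) <= 1e-9
    out["homogenizing_chronic_ge80_pct"] = 100.0 * float(np.mean(chronic_high))
    out["frequency_sums_ok"] = float(sums_ok)
    out["n_patients"] = 2 * n_patients_per_cohort
    return out


def determinism_check(seed: int, out_root: str | Path) -> bool:
    """Run the full pipeline twice with one seed into two directories and
    compare every output byte for byte (the JSON summary's config echo is
    compared with its run-specific output path normalized out)."""
    import json

    out_root = Path(out_root)
    cohort_cfg = GeneratorConfig(n_patients_per_cohort=2)
    paths = []
    for run_id in ("a", "b"):
        out_dir = out_root / f"run_{run_id}"
        dataset = generate_cohort(cohort_cfg, seed)
        run_pipeline_on_dataset(
            dataset,
            PipelineConfig(rc_iterations=200, seed=seed, out_dir=str(out_dir)),
        )
        paths.append(out_dir)
    names = sorted(p.name for p in paths[0].iterdir())
    if names != sorted(p.name for p in paths[1].iterdir()):
        return False
    tsvs = [n for n in names if n.endswith(".tsv")]
    match, mismatch, errors = filecmp.cmpfiles(
        paths[0], paths[1], tsvs, shallow=False
    )
    if mismatch or errors:
        return False
    summaries = []
    for path in paths:
        doc = json.loads((path / "cohort_summary.json").read_text())
        doc["config"]["out_dir"] = None
        summaries.append(doc)
    return summaries[0] == summaries[1]
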