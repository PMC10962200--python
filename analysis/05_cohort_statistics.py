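"""Cohort-level statistics: the reference clinical table and the
process-vs-lung-function relationships.

First recomputes the headline statistics of the packaged 30-patient
reference CF cohort (per-cohort mean %FEV1, paediatric-vs-adult
Kruskal-Wallis, exacerbations-vs-%FEV1 regression).  Then simulates a cohort
whose compositional memory lengthens as lung function declines
(fev1_process_coupling > 0) and checks that the regression of
homogenizing-dispersal frequency on %FEV1 recovers the negative slope.
"""

import json
from pathlib import Path

from lung_turnover import GeneratorConfig, Group, generate_cohort
from lung_turnover.cohort_statistics import process_lungfunction_regressions
from lung_turnover.evaluation import reference_cohort_statistics
from lung_turnover.pipeline import PipelineConfig, run_pipeline_on_dataset

OUT_DIR = Path(__file__).resolve().parent.parent / "results" / "05_statistics"


def main() -> None:
    ref = reference_cohort_statistics()
    print("reference 30-patient clinical table:")
    print(f"  paediatric mean %FEV1 = {ref['paediatric_mean_fev1']:.1f}")
    print(f"  adult mean %FEV1      = {ref['adult_mean_fev1']:.1f}")
    print(
        f"  Kruskal-Wallis H = {ref['fev1_kruskal_H']:.2f} "
        f"(p = {ref['fev1_kruskal_p']:.3f})"
    )
    print(
        f"  exacerbations ~ %FEV1: R2 = {ref['exacerbation_fev1_r2']:.2f}, "
        f"F(1,28) = {ref['exacerbation_fev1_F']:.1f}"
    )

    coupled = generate_cohort(
        GeneratorConfig(fev1_process_coupling=1.0), seed=2
    )
    results = run_pipeline_on_dataset(
        coupled, PipelineConfig(rc_iterations=500, seed=2)
    )
    freqs = {
        pid: f for (pid, g), f in results.frequencies.items()
        if g is Group.MICROBIOTA
    }
    fits = process_lungfunction_regressions(freqs, coupled.metadata, "adult")
    print("\ncoupled synthetic cohort, adult patients:")
    for process, fit in fits.items():
        print(
            f"  {process} % ~ %FEV1: slope = {fit.slope:.2f}, "
            f"R2 = {fit.r2:.2f}, p = {fit.p:.3f}"
        )

    OUT_DIR.mkdir(parents=True, exist_ok=True)
    with open(OUT_DIR / "summary.json", "w") as fh:
        json.dump(
            {
                "reference_cohort": ref,
                "process_vs_fev1_adult": {
                    k: {"slope": v.slope, "r2": v.r2, "p": v.p}
                    for k, v in fits.items()
                },
            },
            fh,
            indent=2,
        )
    print(f"\nwrote {OUT_DIR / 'summary.json'}")


if __name__ == "__main__":
    main()
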