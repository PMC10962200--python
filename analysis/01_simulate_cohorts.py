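"""Simulate the two synthetic study cohorts used by the downstream analyses.

Writes, under results/synthetic/<regime>/, the standard input TSV triple
(taxa_table, manifest, clinical) for a 30-patient cohort (15 paediatric-like,
15 adult-like) in each between-sample overlap regime: `drift` (weighted
lottery assembly from the shared regional pool, short compositional memory)
and `homogenizing` (per-patient template re-expressed with flip noise).
"""

from pathlib import Path

from lung_turnover import GeneratorConfig, generate_cohort
from lung_turnover.cohort_io import write_clinical_metadata, write_taxa_table

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    for regime in ("drift", "homogenizing"):
        out = ROOT / regime
        out.mkdir(parents=True, exist_ok=True)
        config = GeneratorConfig(regime=regime)
        cohort = generate_cohort(config, SEED)
        write_taxa_table(cohort, out / "taxa_table.tsv", out / "manifest.tsv")
        write_clinical_metadata(cohort.metadata, out / "clinical.tsv")
        n_samples = [ts.n_samples for ts in cohort.series.values()]
        durations = [ts.duration_days for ts in cohort.series.values()]
        print(
            f"{regime}: {len(cohort.series)} patients, "
            f"{min(n_samples)}-{max(n_samples)} samples each over "
            f"{min(durations)}-{max(durations)} days -> {out}"
        )


if __name__ == "__main__":
    main()
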