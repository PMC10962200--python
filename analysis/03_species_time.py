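"""Species-time relationships: how much of whole-microbiota turnover is
carried by the intermittent colonizers?

Fits S = c T^w per patient for the whole microbiota and the chronic and
intermittent groups (pairwise moving window, T in elapsed days) on the
simulated drift-regime cohort, then compares the temporal scaling exponents
between groups with a Kruskal-Wallis test.
"""

import importlib
from pathlib import Path

from lung_turnover.cohort_statistics import kruskal_wallis
from lung_turnover.pipeline import PipelineConfig, run_pipeline_on_dataset

loader = importlib.import_module("02_persistence_par")

OUT_DIR = Path(__file__).resolve().parent.parent / "results" / "03_species_time"


def main() -> None:
    dataset = loader.load_drift_cohort()
    results = run_pipeline_on_dataset(
        dataset,
        PipelineConfig(seed=1, out_dir=str(OUT_DIR)),
        stages=("str",),
    )
    fits = results.bundle.str_fits
    medians = fits.groupby("group")["w"].median()
    print("median temporal scaling exponent w:")
    for group in ("microbiota", "chronic", "intermittent"):
        print(f"  {group:12s} {medians[group]:.3f}")
    w_by_group = {
        g: fits.loc[fits.group == g, "w"].tolist()
        for g in ("chronic", "intermittent")
    }
    kw = kruskal_wallis(w_by_group["chronic"], w_by_group["intermittent"])
    print(
        f"chronic vs intermittent w: Kruskal-Wallis H = {kw.H:.2f}, "
        f"p = {kw.p:.2e}"
    )
    print(f"wrote {OUT_DIR / 'str_points.tsv'} and str_fits.tsv")


if __name__ == "__main__":
    main()
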