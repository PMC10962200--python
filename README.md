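# lung-turnover

Ecological analysis of temporal turnover in longitudinal lung-infection
microbiota.

Chronic airway infections — cystic fibrosis being the motivating case — are
polymicrobial and temporally dynamic: taxa immigrate, persist or vanish
across years of clinic visits.  Treating each patient's lungs as an island
habitat, this package quantifies that dynamic from a per-patient taxa ×
visit relative-abundance table:

* **Chronic/intermittent partition (modified Leeds criterion).**  A taxon
  with persistence (fraction of a patient's samples it is detected in)
  strictly above 50% is a chronic colonizer of that patient; ≤ 50% is
  intermittent.  Persistence–abundance relationships (persistence vs log10
  mean relative abundance over detected samples) visualise the resident
  (persistent, common) vs transient (infrequent, rare) structure.
* **Species–time relationships.**  Observed richness accumulates with
  observation span as *S = cT^w*; the temporal scaling exponent *w* is fit
  by OLS on log–log axes from a pairwise moving window (richness of a
  visit plus taxa newly observed at the next, against elapsed days), which
  counts repeated immigration/extinction events.  Larger *w* = faster
  turnover.
* **Raup–Crick process attribution.**  Each within-patient sample pair's
  shared-taxa count is compared with a Monte-Carlo null that reassembles
  both communities from the cohort-wide species pool (occurrence-weighted
  draws without replacement).  The rescaled index *S*<sub>RC</sub> = 2p − 1 ∈
  [−1, 1] classifies pairs as homogenizing dispersal (≥ 0.95), dispersal
  limitation (≤ −0.95) or ecological drift (between).
* **Cohort statistics.**  Tie-corrected Kruskal–Wallis with Dunn post-hoc,
  simple OLS (R², F(1, n−2), p), per-cohort mean ± SD summaries, and
  regressions of process frequencies on lung function (%FEV1).

A synthetic-cohort generator (`lung_turnover.synthetic_cohort`) emulates
the study conditions — 6–20 samples per patient over 785–1166 days,
resident/transient taxon classes with persistence–abundance coupling, two
between-sample overlap regimes (`homogenizing` template resampling vs
`drift` lottery assembly), and clinical covariates with an inverse
exacerbation–%FEV1 link — so the whole pipeline is testable with no
sequencing data.  A transcription of the reference study's 30-patient
clinical characteristics table ships with the package
(`lung_turnover.table1_fixture()`).

## Worked example

```python
import lung_turnover as lt
from lung_turnover.pipeline import PipelineConfig, run_pipeline_on_dataset

cohort = lt.generate_cohort(lt.GeneratorConfig(n_patients_per_cohort=5), seed=7)
results = run_pipeline_on_dataset(
    cohort, PipelineConfig(rc_iterations=1000, seed=7, out_dir="results/demo")
)

fits = results.bundle.str_fits
print(fits.groupby("group")["w"].median().round(3))

freq = results.bundle.process_frequencies
print(freq.groupby("group")[["pct_homogenizing", "pct_drift"]].mean().round(1))

stats = results.bundle.summary["cohort_statistics"]
print(stats["w_kruskal_chronic_vs_intermittent"])
```

prints

```
group
chronic         0.009
intermittent    0.064
microbiota      0.046
Name: w, dtype: float64
              pct_homogenizing  pct_drift
group
chronic                  100.0        0.0
intermittent             14.2       83.7
microbiota               24.3       75.7
KruskalResult(H=9.142857142857139, p=0.00249690891514156, group_ns=(10, 10))
```

Reading it: turnover in the intermittent colonizers (median *w* = 0.064) is
several times that of the chronic group (0.009) and carries the
whole-microbiota signal (0.046); the Kruskal–Wallis test on the two *w*
lists rejects equality (H = 9.14, p = 0.002).  In this drift-regime cohort,
drift is the modal process for the microbiota (75.7% of pairwise
comparisons) while the persistent chronic fraction is, as expected, far
more similar between visits than null assembly predicts (100%
homogenizing dispersal).  Six output files (persistence, STR points/fits,
Raup–Crick pairs, process frequencies, JSON summary) land in
`results/demo/`.

The same pipeline runs from the shell on TSV inputs:

```sh
lung-turnover simulate --out-dir data --seed 7 --n-patients 5
lung-turnover run --taxa-table data/taxa_table.tsv --manifest data/manifest.tsv \
    --clinical data/clinical.tsv --out-dir results/demo --seed 7
```

The `analysis/` directory holds the numbered study scripts
(`01_simulate_cohorts.py` … `05_cohort_statistics.py`): thin drivers that
simulate both regimes, run each stage, and write their tables under
`results/`.

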