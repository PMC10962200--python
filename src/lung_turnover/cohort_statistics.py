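"""Nonparametric group comparisons and simple regressions for cohort claims.

Kruskal-Wallis (tie-corrected) with Dunn's post-hoc test on pooled ranks, a
closed-form simple OLS (slope, R^2, F on 1 and n-2 df), per-cohort summary
statistics, and the lung-function vs ecological-process regressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class KruskalResult:
    H: float
    p: float
    group_ns: tuple[int, ...]


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    r2: float
    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class DunnComparison:
    group_a: int
    group_b: int
    z: float
    p: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float  # sample SD (n-1 denominator); 0 for singleton groups


def kruskal_wallis(*groups: Sequence[float]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H; p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise StatsError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise StatsError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # scipy raises on all-identical input
        return KruskalResult(H=0.0, p=1.0, group_ns=tuple(g.size for g in arrays))
    H, p = sps.kruskal(*arrays)
    return KruskalResult(H=float(H), p=float(p), group_ns=tuple(g.size for g in arrays))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "bonferroni",
) -> list[DunnComparison]:
    """Dunn's z statistics on pooled tie-corrected ranks for all group pairs.

    With two groups this is the single unadjusted comparison.  Adjustment is
    one of {none, bonferroni, holm} across the pairwise family.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise StatsError(f"unknown adjustment {adjustment!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("dunn_posthoc needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise StatsError("empty group")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(arrays))]
    variance_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    raw = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            raw.append((i, j, float(z), float(p)))

    if adjustment == "none":
        adj = [p for *_, p in raw]
    else:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([p for *_, p in raw], method=adjustment)[1].tolist()
    return [
        DunnComparison(i, j, z, p, float(pa))
        for (i, j, z, p), pa in zip(raw, adj)
    ]


def simple_ols(x: Sequence[float], y: Sequence[float]) -> OlsResult:
    """OLS of y on x with R^2, F = (R^2/(1-R^2)) (n-2), p from F(1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise StatsError("need at least 3 observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise StatsError("zero variance in predictor")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0:
        # response constant: perfect (degenerate) fit with zero slope
        return OlsResult(slope, intercept, r2=0.0, F=0.0, df=(1, n - 2), p=1.0)
    r2 = min((sxy * sxy) / (sxx * syy), 1.0)
    if 1.0 - r2 < 1e-15:
        return OlsResult(slope, intercept, r2=1.0, F=np.inf, df=(1, n - 2), p=0.0)
    F = (r2 / (1.0 - r2)) * (n - 2)
    p = float(sps.f.sf(F, 1, n - 2))
    return OlsResult(slope, intercept, float(r2), float(F), (1, n - 2), p)


def cohort_summaries(
    values: Mapping[str, float],
    metadata: Mapping[str, "PatientMetadata"],  # noqa: F821 - avoids import cycle
) -> dict[str, GroupSummary]:
    """Per-cohort mean and sample SD of per-patient values."""
    by_cohort: dict[str, list[float]] = {}
    for pid, v in values.items():
        if pid not in metadata:
            raise StatsError(f"unknown patient {pid!r}")
        by_cohort.setdefault(metadata[pid].cohort.value, []).append(float(v))
    out = {}
    for label, vals in sorted(by_cohort.items()):
        arr = np.asarray(vals)
        if arr.size == 1:
            logger.warning("cohort %s has a single patient; SD reported as 0", label)
            sd = 0.0
        else:
            sd = float(arr.std(ddof=1))
        out[label] = GroupSummary(label=label, n=arr.size, mean=float(arr.mean()), sd=sd)
    return out


def process_lungfunction_regressions(
    frequencies: Mapping[str, "ProcessFrequencies"],  # noqa: F821
    metadata: Mapping[str, "PatientMetadata"],  # noqa: F821
    cohort: str | None = None,
) -> dict[str, OlsResult]:
    """OLS of per-patient homogenizing-dispersal % and drift % on mean %FEV1.

    ``frequencies`` should hold one whole-microbiota frequency record per
    patient.  ``cohort`` restricts to one cohort label; None pools patients.
    """
    pids = [
        p for p in sorted(frequencies)
        if cohort is None or metadata[p].cohort.value == cohort
    ]
    if len(pids) < 3:
        raise StatsError(
            f"need >= 3 patients for regression (got {len(pids)} in "
            f"cohort {cohort!r})"
        )
    fev1 = [metadata[p].mean_fev1 for p in pids]
    return {
        "homogenizing_dispersal": simple_ols(
            fev1, [frequencies[p].pct_homogenizing for p in pids]
        ),
        "drift": simple_ols(fev1, [frequencies[p].pct_drift for p in pids]),
    }
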