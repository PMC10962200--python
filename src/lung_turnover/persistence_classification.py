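"""Per-taxon temporal persistence, Leeds chronic/intermittent partition, and
persistence-abundance relationships (PARs).

Persistence is the percentage of a patient's longitudinal samples in which a
taxon is detected.  Under the modified Leeds criteria a taxon with > 50%
persistence is a chronic colonizer of that patient; <= 50% is intermittent.
The PAR is the temporal analogue of the occupancy-abundance relationship:
persistence regressed on (log10) mean relative abundance over the samples the
taxon was detected in.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_io import TaxaTimeSeries
from .cohort_statistics import OlsResult, StatsError, simple_ols


class PersistenceError(ValueError):
    pass


class Status(str, enum.Enum):
    CHRONIC = "chronic"
    INTERMITTENT = "intermittent"


class Group(str, enum.Enum):
    """Analysis groups: the whole microbiota or one Leeds partition."""

    MICROBIOTA = "microbiota"
    CHRONIC = "chronic"
    INTERMITTENT = "intermittent"


@dataclass(frozen=True)
class PersistenceRecord:
    taxon_id: str
    n_detected: int
    n_total: int
    persistence_pct: float
    mean_abund_detected: float
    status: Status | None = None


@dataclass(frozen=True)
class PARFit:
    slope: float
    intercept: float
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    n_taxa: int


def taxon_persistence(
    series: TaxaTimeSeries, detection_min: float = 0.0
) -> list[PersistenceRecord]:
    """One record per detected taxon: persistence % and detected-sample mean
    relative abundance.  Status is left unset (see :func:`partition_leeds`)."""
    if series.n_samples < 1:
        raise PersistenceError("series has no samples")
    pres = series.presence(detection_min)
    records = []
    for i, taxon in enumerate(series.taxa):
        n_det = int(pres[i].sum())
        if n_det == 0:
            continue
        mean_abund = float(series.abundance[i, pres[i]].mean())
        records.append(
            PersistenceRecord(
                taxon_id=taxon,
                n_detected=n_det,
                n_total=series.n_samples,
                persistence_pct=100.0 * n_det / series.n_samples,
                mean_abund_detected=mean_abund,
            )
        )
    return records


def partition_leeds(
    records: Sequence[PersistenceRecord], threshold_pct: float = 50.0
) -> list[PersistenceRecord]:
    """Set status: chronic iff persistence strictly exceeds the threshold
    (exactly 50% is intermittent)."""
    if not 0.0 < threshold_pct < 100.0:
        raise PersistenceError(
            f"threshold_pct must be in (0, 100), got {threshold_pct}"
        )
    return [
        dataclasses.replace(
            r,
            status=Status.CHRONIC
            if r.persistence_pct > threshold_pct
            else Status.INTERMITTENT,
        )
        for r in records
    ]


def fit_par(
    records: Sequence[PersistenceRecord],
    abundance_transform: str = "log10",
) -> PARFit:
    """OLS of persistence % on (transformed) mean detected abundance."""
    if abundance_transform not in ("log10", "identity"):
        raise PersistenceError(
            f"unknown abundance_transform {abundance_transform!r}"
        )
    if len(records) < 3:
        raise PersistenceError("need at least 3 taxa to fit a PAR")
    x = np.array([r.mean_abund_detected for r in records], dtype=float)
    if abundance_transform == "log10":
        x = np.log10(x)
    y = np.array([r.persistence_pct for r in records], dtype=float)
    try:
        fit: OlsResult = simple_ols(x, y)
    except StatsError as exc:
        raise PersistenceError(f"PAR fit failed: {exc}") from exc
    return PARFit(
        slope=fit.slope,
        intercept=fit.intercept,
        r2=fit.r2,
        F=fit.F,
        df=fit.df,
        p=fit.p,
        n_taxa=len(records),
    )


def subset_series(
    series: TaxaTimeSeries,
    records: Sequence[PersistenceRecord],
    group: Group | str,
) -> TaxaTimeSeries:
    """Restrict a series to one Leeds group's taxa.

    ``microbiota`` returns the input unchanged.  Subset abundances are NOT
    renormalized: downstream use of group subsets is presence/absence.
    """
    group = Group(group)
    if group is Group.MICROBIOTA:
        return series
    status = {r.taxon_id: r.status for r in records}
    missing = [t for t in series.taxa if t not in status]
    if missing:
        raise PersistenceError(
            f"records do not cover taxa {missing[:5]} of patient "
            f"{series.patient_id!r}"
        )
    if any(s is None for s in status.values()):
        raise PersistenceError("records have unset status; run partition_leeds")
    want = Status.CHRONIC if group is Group.CHRONIC else Status.INTERMITTENT
    keep = np.array([status[t] is want for t in series.taxa], dtype=bool)
    return TaxaTimeSeries(
        patient_id=series.patient_id,
        taxa=[t for t, k in zip(series.taxa, keep) if k],
        samples=list(series.samples),
        abundance=series.abundance[keep],
        normalized=False,
    )
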