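"""Species-time relationships (STRs) and power-law turnover exponents.

The STR describes how observed richness S grows with the time span T over
which a community is watched, modelled as S = c T^w; w, the temporal scaling
exponent, measures turnover.  Points are built with a moving window over the
sample sequence.  The default ``pairwise`` mode slides a two-sample window
along adjacent visits: S is the richness of the first sample plus the taxa
new in the second (equivalently the size of the union of the two presence
sets) and T is the elapsed days between them.  This counts repeated
immigration/extinction of the same taxon each time it happens, rather than
only first appearances.  A classical variable-length ``window`` mode (union
over samples i..i+L-1, T the day span of the window) is kept for sensitivity
analysis.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_io import TaxaTimeSeries
from .cohort_statistics import StatsError, simple_ols
from .persistence_classification import Group, PersistenceRecord, subset_series

logger = logging.getLogger(__name__)


class TurnoverError(ValueError):
    pass


class STRMode(str, enum.Enum):
    PAIRWISE = "pairwise"
    WINDOW = "window"


@dataclass(frozen=True)
class STRPoint:
    T: float  # elapsed days spanned by the window (> 0)
    S: int  # observed richness over the window
    window_start: int  # index of the window's first sample
    window_len: int  # number of samples in the window (>= 2)


@dataclass(frozen=True)
class STRFit:
    c: float
    w: float
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    n_points: int
    group: Group | None = None
    mode: STRMode = STRMode.PAIRWISE


def str_points(
    series: TaxaTimeSeries,
    mode: STRMode | str = STRMode.PAIRWISE,
    detection_min: float = 0.0,
) -> list[STRPoint]:
    """Moving-window richness-vs-time points for one patient (or group
    subset)."""
    mode = STRMode(mode)
    if series.n_samples < 2:
        raise TurnoverError(
            f"patient {series.patient_id!r}: need >= 2 samples for an STR"
        )
    pres = series.presence(detection_min)
    days = series.days
    points: list[STRPoint] = []
    if mode is STRMode.PAIRWISE:
        for i in range(series.n_samples - 1):
            union = int(np.sum(pres[:, i] | pres[:, i + 1]))
            points.append(
                STRPoint(
                    T=float(days[i + 1] - days[i]),
                    S=union,
                    window_start=i,
                    window_len=2,
                )
            )
    else:
        for length in range(2, series.n_samples + 1):
            for i in range(series.n_samples - length + 1):
                union = int(np.sum(pres[:, i:i + length].any(axis=1)))
                points.append(
                    STRPoint(
                        T=float(days[i + length - 1] - days[i]),
                        S=union,
                        window_start=i,
                        window_len=length,
                    )
                )
    return points


def fit_power_law(
    points: Sequence[STRPoint],
    group: Group | None = None,
    mode: STRMode = STRMode.PAIRWISE,
) -> STRFit:
    """OLS of log10 S on log10 T; w is the slope and c = 10^intercept.

    Points with S = 0 (possible in sparse group subsets) carry no turnover
    signal and are dropped with a warning before the log transform.
    """
    usable = [p for p in points if p.S > 0]
    dropped = len(points) - len(usable)
    if dropped:
        logger.warning("dropping %d STR point(s) with S = 0", dropped)
    if len(usable) < 3:
        raise TurnoverError(
            f"need >= 3 usable points for a power-law fit, got {len(usable)}"
        )
    if any(p.T <= 0 for p in usable):
        raise TurnoverError("all STR points must have T > 0")
    log_t = np.log10([p.T for p in usable])
    log_s = np.log10([p.S for p in usable])
    try:
        fit = simple_ols(log_t, log_s)
    except StatsError as exc:
        raise TurnoverError(f"power-law fit failed: {exc}") from exc
    return STRFit(
        c=float(10.0 ** fit.intercept),
        w=float(fit.slope),
        r2=fit.r2,
        F=fit.F,
        df=fit.df,
        p=fit.p,
        n_points=len(usable),
        group=group,
        mode=mode,
    )


def str_for_groups(
    series: TaxaTimeSeries,
    records: Sequence[PersistenceRecord],
    mode: STRMode | str = STRMode.PAIRWISE,
    detection_min: float = 0.0,
) -> dict[Group, STRFit]:
    """Fit STRs for the whole microbiota and the chronic / intermittent
    subsets of one patient.  Presence/absence is evaluated on each subset
    matrix; errors from degenerate subsets propagate."""
    mode = STRMode(mode)
    fits: dict[Group, STRFit] = {}
    for group in Group:
        sub = subset_series(series, records, group)
        points = str_points(sub, mode=mode, detection_min=detection_min)
        fits[group] = fit_power_law(points, group=group, mode=mode)
    return fits
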