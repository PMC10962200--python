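"""Raup-Crick null-model similarity and ecological process attribution.

For each within-patient sample pair, the observed number of shared taxa is
compared with a Monte-Carlo null in which two communities of the same
richnesses are assembled at random from the regional species pool (all taxa
observed across every patient's time series), drawing taxa without
replacement with probability proportional to their occurrence frequency (or
uniformly).  The probability p that a null pair shares fewer taxa than
observed (ties split half-weight) is rescaled to the similarity index

    S_RC = 2p - 1  in [-1, 1],

so +1 means far more similar than chance and -1 far less.  Following the
standard null-model interpretation of turnover, pairs with S_RC >= 0.95 are
attributed to homogenizing dispersal, pairs with S_RC <= -0.95 to dispersal
limitation, and everything between to ecological drift (the thresholds
approximate a two-sided test at alpha = 0.05).  Speciation cannot be
separated by a presence/absence index on these time scales and is not
scored.
"""

from __future__ import annotations

import enum
import hashlib
import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .cohort_io import CohortDataset, TaxaTimeSeries
from .persistence_classification import Group, PersistenceRecord, Status

logger = logging.getLogger(__name__)

UNIFORM_TOL = 1e-12
MAX_ENUMERATION_POOL = 12


class AssemblyError(ValueError):
    pass


class Process(str, enum.Enum):
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    DRIFT = "drift"
    DISPERSAL_LIMITATION = "dispersal_limitation"


class Weighting(str, enum.Enum):
    OCCURRENCE = "occurrence"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class SpeciesPool:
    """Regional pool: taxa, their occurrence counts over all samples, and the
    sampling weights used for null assembly."""

    taxa: tuple[str, ...]
    occurrence: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.taxa) == 0:
            raise AssemblyError("empty species pool")
        if np.any(self.occurrence < 1):
            raise AssemblyError("every pool taxon must have occurrence >= 1")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise AssemblyError("pool weights must sum to 1")

    @property
    def size(self) -> int:
        return len(self.taxa)

    @property
    def is_uniform(self) -> bool:
        return bool(np.ptp(self.weights) <= UNIFORM_TOL)

    def index_of(self, taxa: Iterable[str]) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.taxa)}
        try:
            return np.array([lookup[t] for t in taxa], dtype=int)
        except KeyError as exc:
            raise AssemblyError(f"taxon {exc.args[0]!r} not in pool") from None


@dataclass(frozen=True)
class RaupCrickPair:
    sample_a: str
    sample_b: str
    n_a: int
    n_b: int
    shared_obs: int
    s_rc: float
    process: Process


@dataclass(frozen=True)
class ProcessFrequencies:
    patient_id: str
    group: Group
    pct_homogenizing: float
    pct_drift: float
    pct_limitation: float
    n_pairs: int


def build_regional_pool(
    dataset: CohortDataset,
    group: Group | str = Group.MICROBIOTA,
    weighting: Weighting | str = Weighting.OCCURRENCE,
    partitions: Mapping[str, Sequence[PersistenceRecord]] | None = None,
    detection_min: float = 0.0,
) -> SpeciesPool:
    """Pool = union of taxa detected in any sample of any patient, with
    occurrence = number of samples (cohort-wide) each taxon was detected in.

    For the chronic/intermittent groups the pool is restricted to taxa
    holding that status in at least one patient (``partitions`` maps
    patient_id to Leeds-labelled records).
    """
    group = Group(group)
    weighting = Weighting(weighting)
    if not dataset.series:
        raise AssemblyError("empty dataset")
    if group is not Group.MICROBIOTA and partitions is None:
        raise AssemblyError("group pools need the per-patient Leeds partitions")

    counts: dict[str, int] = {}
    for pid in sorted(dataset.series):
        ts = dataset.series[pid]
        pres = ts.presence(detection_min)
        for i, taxon in enumerate(ts.taxa):
            n = int(pres[i].sum())
            if n:
                counts[taxon] = counts.get(taxon, 0) + n

    if group is not Group.MICROBIOTA:
        want = Status.CHRONIC if group is Group.CHRONIC else Status.INTERMITTENT
        eligible = {
            r.taxon_id
            for records in partitions.values()
            for r in records
            if r.status is want
        }
        counts = {t: c for t, c in counts.items() if t in eligible}

    if not counts:
        raise AssemblyError(f"no taxa in the {group.value} pool")
    taxa = tuple(sorted(counts))
    occurrence = np.array([counts[t] for t in taxa], dtype=int)
    if weighting is Weighting.OCCURRENCE:
        weights = occurrence / occurrence.sum()
    else:
        weights = np.full(len(taxa), 1.0 / len(taxa))
    return SpeciesPool(taxa=taxa, occurrence=occurrence, weights=weights)


# ---------------------------------------------------------------------------
# null sampling


def _derive_seed(*parts) -> int:
    """Stable substream id from string/int parts (sha256, not hash())."""
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:8], "big") >> 1  # keep below 2**63


def _gumbel_ranks(
    weights: np.ndarray, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-iteration ranking of pool taxa under weighted sampling without
    replacement (Gumbel-top-k: descending log w + Gumbel noise reproduces
    successive draws proportional to remaining weight)."""
    keys = np.log(weights)[None, :] + rng.gumbel(size=(iterations, weights.size))
    order = np.argsort(-keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(weights.size)[None, :], axis=1)
    return ranks


def _null_shared_counts(
    pool: SpeciesPool, n_a: int, n_b: int, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    ranks_a = _gumbel_ranks(pool.weights, iterations, rng)
    ranks_b = _gumbel_ranks(pool.weights, iterations, rng)
    return np.sum((ranks_a < n_a) & (ranks_b < n_b), axis=1)


def _srcs_from_null(null_shared: np.ndarray, shared_obs: int) -> float:
    less = float(np.sum(null_shared < shared_obs))
    ties = float(np.sum(null_shared == shared_obs))
    p = (less + 0.5 * ties) / null_shared.size
    return 2.0 * p - 1.0


def raup_crick_pair(
    presence_a: Iterable[str],
    presence_b: Iterable[str],
    pool: SpeciesPool,
    iterations: int = 1000,
    seed: int = 0,
    threshold: float = 0.95,
) -> RaupCrickPair:
    """Monte-Carlo S_RC for one sample pair (deterministic given seed)."""
    set_a, set_b = frozenset(presence_a), frozenset(presence_b)
    if not set_a or not set_b:
        raise AssemblyError("both presence sets must be nonempty")
    if iterations < 1:
        raise AssemblyError("iterations must be >= 1")
    idx_a, idx_b = pool.index_of(set_a), pool.index_of(set_b)
    n_a, n_b = len(set_a), len(set_b)
    if n_a > pool.size or n_b > pool.size:
        raise AssemblyError("presence richness exceeds pool size")
    shared = len(set_a & set_b)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # sorted richnesses so s_rc(a, b) == s_rc(b, a) for the same seed
    null = _null_shared_counts(pool, min(n_a, n_b), max(n_a, n_b), iterations, rng)
    s_rc = _srcs_from_null(null, shared)
    return RaupCrickPair(
        sample_a="a",
        sample_b="b",
        n_a=n_a,
        n_b=n_b,
        shared_obs=shared,
        s_rc=s_rc,
        process=classify_process(s_rc, threshold),
    )


# ---------------------------------------------------------------------------
# exact oracle


def exact_null_distribution(
    pool: SpeciesPool, n_a: int, n_b: int
) -> np.ndarray:
    """Exact pmf of the null shared-taxa count (index = shared count).

    Uniform weights: closed-form hypergeometric for any pool size.  Weighted
    pools: exhaustive enumeration of both draws, refused above
    ``MAX_ENUMERATION_POOL`` taxa.
    """
    P = pool.size
    if not (1 <= n_a <= P and 1 <= n_b <= P):
        raise AssemblyError("richness must be within [1, pool size]")
    support = np.arange(min(n_a, n_b) + 1)
    if pool.is_uniform:
        pmf = np.zeros(support.size)
        pmf[:] = sps.hypergeom.pmf(support, P, n_a, n_b)
        return pmf
    if P > MAX_ENUMERATION_POOL:
        raise AssemblyError(
            f"weighted enumeration refused for pools > {MAX_ENUMERATION_POOL} taxa"
        )
    subset_prob = _subset_probabilities(pool.weights)
    masks_a = [(m, p) for m, p in subset_prob.items() if bin(m).count("1") == n_a]
    masks_b = [(m, p) for m, p in subset_prob.items() if bin(m).count("1") == n_b]
    ma = np.array([m for m, _ in masks_a], dtype=np.uint64)
    pa = np.array([p for _, p in masks_a])
    mb = np.array([m for m, _ in masks_b], dtype=np.uint64)
    pb = np.array([p for _, p in masks_b])
    inter = np.bitwise_count(ma[:, None] & mb[None, :])
    pmf = np.zeros(support.size)
    joint = pa[:, None] * pb[None, :]
    for s in support:
        pmf[s] = float(joint[inter == s].sum())
    return pmf


def _subset_probabilities(weights: np.ndarray) -> dict[int, float]:
    """P(draw exactly this taxon set) under successive weighted sampling
    without replacement, for every subset (bitmask keyed), by dynamic
    programming over subsets ordered by size."""
    P = weights.size
    w = weights / weights.sum()
    probs: dict[int, float] = {0: 1.0}
    frontier = [0]
    for _ in range(P):
        nxt: dict[int, float] = {}
        for mask in frontier:
            drawn = w[[i for i in range(P) if mask >> i & 1]].sum()
            remaining = 1.0 - drawn
            g = probs[mask]
            for i in range(P):
                if not mask >> i & 1:
                    new = mask | (1 << i)
                    nxt[new] = nxt.get(new, 0.0) + g * w[i] / remaining
        probs.update(nxt)
        frontier = list(nxt)
    return probs


def exact_null_srcs(
    pool: SpeciesPool, n_a: int, n_b: int, shared_obs: int
) -> float:
    """Exact S_RC with the same tie-splitting and rescaling as the
    Monte-Carlo estimator."""
    lo = max(0, n_a + n_b - pool.size)
    hi = min(n_a, n_b)
    if not lo <= shared_obs <= hi:
        raise AssemblyError(
            f"shared_obs {shared_obs} impossible for richnesses ({n_a}, {n_b}) "
            f"in a pool of {pool.size} (feasible range [{lo}, {hi}])"
        )
    pmf = exact_null_distribution(pool, n_a, n_b)
    p = float(pmf[:shared_obs].sum() + 0.5 * pmf[shared_obs])
    return 2.0 * p - 1.0


# ---------------------------------------------------------------------------
# matrices and classification


def classify_process(s_rc: float, threshold: float = 0.95) -> Process:
    """Boundary-inclusive attribution: >= threshold homogenizing dispersal,
    <= -threshold dispersal limitation, otherwise drift."""
    if not -1.0 <= s_rc <= 1.0:
        raise AssemblyError(f"s_rc {s_rc} outside [-1, 1]")
    if not 0.0 < threshold <= 1.0:
        raise AssemblyError(f"threshold {threshold} outside (0, 1]")
    if s_rc >= threshold:
        return Process.HOMOGENIZING_DISPERSAL
    if s_rc <= -threshold:
        return Process.DISPERSAL_LIMITATION
    return Process.DRIFT


def raup_crick_matrix(
    series: TaxaTimeSeries,
    pool: SpeciesPool,
    iterations: int = 1000,
    seed: int = 0,
    label: str = "microbiota",
    threshold: float = 0.95,
    detection_min: float = 0.0,
) -> list[RaupCrickPair]:
    """S_RC for every unordered within-patient sample pair.

    Null distributions are drawn from substreams derived (sha256) from the
    master seed, the patient, the analysis group label and the sorted
    richness pair, then cached: results are deterministic, symmetric in the
    pair, and independent of evaluation order.  Samples with no detected
    taxa in the chosen group are skipped with a log message.
    """
    presence = series.presence_sets(detection_min)
    usable = []
    for rec, pres in zip(series.samples, presence):
        if pres:
            usable.append((rec.sample_id, pres))
        else:
            logger.info(
                "patient %s, group %s: skipping empty sample %s",
                series.patient_id, label, rec.sample_id,
            )
    if len(usable) < 2:
        return []

    # shared ranking matrices for this (patient, label); each sorted richness
    # combination reads a nested prefix of the same weighted permutations
    base = np.random.SeedSequence(
        entropy=[int(seed), _derive_seed(series.patient_id, label)]
    )
    rng = np.random.default_rng(base)
    ranks_a = _gumbel_ranks(pool.weights, iterations, rng)
    ranks_b = _gumbel_ranks(pool.weights, iterations, rng)

    null_cache: dict[tuple[int, int], np.ndarray] = {}

    def null_for(n_lo: int, n_hi: int) -> np.ndarray:
        key = (n_lo, n_hi)
        if key not in null_cache:
            null_cache[key] = np.sum(
                (ranks_a < n_lo) & (ranks_b < n_hi), axis=1
            )
        return null_cache[key]

    pairs: list[RaupCrickPair] = []
    for (id_a, pres_a), (id_b, pres_b) in itertools.combinations(usable, 2):
        n_a, n_b = len(pres_a), len(pres_b)
        if n_a > pool.size or n_b > pool.size:
            raise AssemblyError(
                f"sample richness exceeds the {label} pool size {pool.size}"
            )
        shared = len(pres_a & pres_b)
        null = null_for(min(n_a, n_b), max(n_a, n_b))
        s_rc = _srcs_from_null(null, shared)
        pairs.append(
            RaupCrickPair(
                sample_a=id_a,
                sample_b=id_b,
                n_a=n_a,
                n_b=n_b,
                shared_obs=shared,
                s_rc=s_rc,
                process=classify_process(s_rc, threshold),
            )
        )
    return pairs


def process_frequencies(
    pairs: Sequence[RaupCrickPair],
    patient_id: str = "",
    group: Group | str = Group.MICROBIOTA,
) -> ProcessFrequencies:
    """Percentage of a patient's pairwise comparisons attributed to each
    process; the three percentages sum to 100."""
    if not pairs:
        raise AssemblyError("no pairs to summarize")
    n = len(pairs)
    counts = {proc: 0 for proc in Process}
    for pair in pairs:
        counts[pair.process] += 1
    return ProcessFrequencies(
        patient_id=patient_id,
        group=Group(group),
        pct_homogenizing=100.0 * counts[Process.HOMOGENIZING_DISPERSAL] / n,
        pct_drift=100.0 * counts[Process.DRIFT] / n,
        pct_limitation=100.0 * counts[Process.DISPERSAL_LIMITATION] / n,
        n_pairs=n,
    )
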