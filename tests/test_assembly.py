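"""Raup-Crick null model, exact oracles, and process attribution."""

import numpy as np
import pytest

import lung_turnover as lt
from lung_turnover.assembly_processes import (
    AssemblyError,
    Process,
    exact_null_distribution,
)

from conftest import make_series


def uniform_pool(size):
    return lt.SpeciesPool(
        taxa=tuple(f"t{i}" for i in range(size)),
        occurrence=np.ones(size, dtype=int),
        weights=np.full(size, 1.0 / size),
    )


class TestRegionalPool:
    def test_union_and_occurrence_counts(self):
        def patient(pid, columns, days):
            counts = np.array(columns, dtype=float).T
            samples = [
                lt.SampleRecord(f"{pid}_s{j}", pid, int(d))
                for j, d in enumerate(days)
            ]
            # from_counts drops never-detected rows, as the loader would
            return lt.TaxaTimeSeries.from_counts(
                pid, ["A", "B", "C", "D"], samples, counts
            )

        ds = lt.CohortDataset(series={
            "P1": patient(
                "P1", [[0.5, 0.3, 0.2, 0.0], [0.2, 0.8, 0.0, 0.0]], [0, 40]
            ),
            "P2": patient(
                "P2", [[0.0, 0.6, 0.2, 0.2], [0.0, 0.1, 0.4, 0.5]], [0, 60]
            ),
        })
        pool = lt.build_regional_pool(ds)
        assert pool.taxa == ("A", "B", "C", "D")
        occ = dict(zip(pool.taxa, pool.occurrence))
        assert occ == {"A": 2, "B": 4, "C": 3, "D": 2}
        assert pool.weights == pytest.approx(pool.occurrence / 11)

    def test_uniform_weighting(self):
        series = make_series(
            "P", [[0.25] * 4, [0.25] * 4], [0, 30], taxa=list("WXYZ")
        )
        pool = lt.build_regional_pool(
            lt.CohortDataset(series={"P": series}), weighting="uniform"
        )
        assert pool.weights == pytest.approx([0.25] * 4)

    def test_group_pool_restricted_to_status_holders(self, drift_cohort):
        partitions = {
            pid: lt.partition_leeds(lt.taxon_persistence(ts))
            for pid, ts in drift_cohort.series.items()
        }
        chronic_pool = lt.build_regional_pool(
            drift_cohort, lt.Group.CHRONIC, partitions=partitions
        )
        chronic_anywhere = {
            r.taxon_id
            for recs in partitions.values()
            for r in recs
            if r.status is lt.Status.CHRONIC
        }
        assert set(chronic_pool.taxa) == chronic_anywhere


class TestExactOracle:
    def test_worked_identical_pair_values(self):
        assert lt.exact_null_srcs(uniform_pool(6), 2, 2, 2) == pytest.approx(
            2 * (14.5 / 15) - 1, abs=1e-12
        )
        assert lt.exact_null_srcs(uniform_pool(10), 2, 2, 2) == pytest.approx(
            2 * (44.5 / 45) - 1, abs=1e-12
        )

    def test_infeasible_shared_count_rejected(self):
        pool = uniform_pool(6)
        with pytest.raises(AssemblyError, match="impossible"):
            lt.exact_null_srcs(pool, 6, 6, 0)  # full pools must share all
        with pytest.raises(AssemblyError, match="impossible"):
            lt.exact_null_srcs(pool, 2, 2, 3)

    def test_weighted_enumeration_refused_above_limit(self):
        weights = np.arange(1.0, 14.0)
        pool = lt.SpeciesPool(
            taxa=tuple(f"t{i}" for i in range(13)),
            occurrence=np.arange(1, 14),
            weights=weights / weights.sum(),
        )
        with pytest.raises(AssemblyError, match="refused"):
            lt.exact_null_srcs(pool, 2, 2, 1)

    def test_pmf_sums_to_one(self):
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        pool = lt.SpeciesPool(
            taxa=("a", "b", "c", "d"),
            occurrence=np.array([4, 3, 2, 1]),
            weights=weights,
        )
        pmf = exact_null_distribution(pool, 2, 3)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weighted_enumeration_matches_large_monte_carlo(self):
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        pool = lt.SpeciesPool(
            taxa=("a", "b", "c", "d"),
            occurrence=np.array([4, 3, 2, 1]),
            weights=weights,
        )
        exact = lt.exact_null_srcs(pool, 2, 2, 1)
        mc = lt.raup_crick_pair(
            ["a", "b"], ["a", "c"], pool, iterations=1_000_000, seed=9
        ).s_rc
        p_exact = (exact + 1) / 2
        se = 2 * np.sqrt(p_exact * (1 - p_exact) / 1_000_000)
        assert abs(mc - exact) <= 3 * se


class TestRaupCrickPair:
    def test_entire_pool_communities_are_all_ties(self):
        pool = uniform_pool(5)
        pair = lt.raup_crick_pair(
            pool.taxa, pool.taxa, pool, iterations=500, seed=1
        )
        assert pair.s_rc == 0.0  # every null draw shares everything
        assert pair.process is Process.DRIFT

    def test_monte_carlo_tracks_exact_on_random_uniform_cases(self):
        rng = np.random.default_rng(21)
        iterations = 10_000
        failures = 0
        cases = 50
        for _ in range(cases):
            size = int(rng.integers(3, 13))
            pool = uniform_pool(size)
            n_a = int(rng.integers(1, size + 1))
            n_b = int(rng.integers(1, size + 1))
            a = list(rng.choice(pool.taxa, n_a, replace=False))
            b = list(rng.choice(pool.taxa, n_b, replace=False))
            shared = len(set(a) & set(b))
            exact = lt.exact_null_srcs(pool, n_a, n_b, shared)
            mc = lt.raup_crick_pair(
                a, b, pool, iterations=iterations, seed=int(rng.integers(2**31))
            ).s_rc
            p_exact = (exact + 1) / 2
            se = 2 * np.sqrt(p_exact * (1 - p_exact) / iterations)
            if abs(mc - exact) > 3 * se * 2:
                failures += 1
        assert failures == 0

    def test_symmetry_and_determinism(self):
        pool = uniform_pool(8)
        a, b = ["t0", "t1", "t2"], ["t1", "t2", "t3", "t4"]
        first = lt.raup_crick_pair(a, b, pool, iterations=2000, seed=5)
        swapped = lt.raup_crick_pair(b, a, pool, iterations=2000, seed=5)
        rerun = lt.raup_crick_pair(a, b, pool, iterations=2000, seed=5)
        assert first.s_rc == swapped.s_rc == rerun.s_rc

    def test_richness_beyond_pool_rejected(self):
        pool = uniform_pool(3)
        with pytest.raises(AssemblyError):
            lt.raup_crick_pair(["t0", "t1", "t2", "x"], ["t0"], pool, seed=0)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "s_rc, process",
        [
            (0.95, Process.HOMOGENIZING_DISPERSAL),
            (1.0, Process.HOMOGENIZING_DISPERSAL),
            (0.9499, Process.DRIFT),
            (0.0, Process.DRIFT),
            (-0.9499, Process.DRIFT),
            (-0.95, Process.DISPERSAL_LIMITATION),
            (-0.97, Process.DISPERSAL_LIMITATION),
        ],
    )
    def test_boundary_inclusive_thresholds(self, s_rc, process):
        assert lt.classify_process(s_rc) is process

    def test_out_of_range_rejected(self):
        with pytest.raises(AssemblyError):
            lt.classify_process(1.2)


class TestRaupCrickMatrix:
    def test_pair_count_and_determinism(self, drift_cohort):
        pid, series = next(iter(drift_cohort.series.items()))
        pool = lt.build_regional_pool(drift_cohort)
        pairs = lt.raup_crick_matrix(series, pool, iterations=200, seed=4)
        n = series.n_samples
        assert len(pairs) == n * (n - 1) // 2
        again = lt.raup_crick_matrix(series, pool, iterations=200, seed=4)
        assert [p.s_rc for p in pairs] == [p.s_rc for p in again]

    def test_empty_group_samples_skipped(self, caplog):
        # second sample has no detected taxa once restricted to taxon t0
        cols = [[0.6, 0.4], [0.0, 1.0], [0.5, 0.5]]
        series = make_series("P", cols, [0, 50, 120])
        sub = lt.TaxaTimeSeries(
            "P", ["t0"], series.samples, series.abundance[:1],
            normalized=False,
        )
        pool = uniform_pool(4)
        with caplog.at_level("INFO"):
            pairs = lt.raup_crick_matrix(sub, pool, iterations=100, seed=0)
        assert len(pairs) == 1  # only samples 0 and 2 usable
        assert any("skipping empty sample" in r.message for r in caplog.records)

    def test_null_self_consistency_of_drift_classification(self):
        # presence sets drawn by the same weighted lottery the null uses
        rng = np.random.default_rng(13)
        size = 40
        occurrence = rng.integers(1, 20, size)
        weights = occurrence / occurrence.sum()
        pool = lt.SpeciesPool(
            taxa=tuple(f"t{i}" for i in range(size)),
            occurrence=occurrence,
            weights=weights,
        )
        drift_calls = 0
        n_pairs = 120
        for k in range(n_pairs):
            n_a, n_b = rng.integers(5, 20, 2)
            a = rng.choice(pool.taxa, n_a, replace=False, p=weights)
            b = rng.choice(pool.taxa, n_b, replace=False, p=weights)
            pair = lt.raup_crick_pair(
                a, b, pool, iterations=1000, seed=int(rng.integers(2**31))
            )
            drift_calls += pair.process is Process.DRIFT
        assert drift_calls >= 0.90 * n_pairs


class TestProcessFrequencies:
    def _pairs(self, processes):
        return [
            lt.RaupCrickPair(
                sample_a="a", sample_b="b", n_a=2, n_b=2, shared_obs=1,
                s_rc={"h": 0.99, "d": 0.0, "l": -0.99}[p],
                process={
                    "h": Process.HOMOGENIZING_DISPERSAL,
                    "d": Process.DRIFT,
                    "l": Process.DISPERSAL_LIMITATION,
                }[p],
            )
            for p in processes
        ]

    def test_all_drift(self):
        freq = lt.process_frequencies(self._pairs("d" * 15), "P")
        assert (freq.pct_homogenizing, freq.pct_drift, freq.pct_limitation) == (
            0.0, 100.0, 0.0,
        )

    def test_arithmetic(self):
        freq = lt.process_frequencies(self._pairs("h" * 12 + "d" * 3), "P")
        assert freq.pct_homogenizing == pytest.approx(80.0)
        assert freq.pct_drift == pytest.approx(20.0)
        assert freq.n_pairs == 15

    def test_sums_to_100(self, drift_cohort):
        pool = lt.build_regional_pool(drift_cohort)
        for series in drift_cohort.series.values():
            pairs = lt.raup_crick_matrix(series, pool, iterations=100, seed=2)
            freq = lt.process_frequencies(pairs, series.patient_id)
            total = freq.pct_homogenizing + freq.pct_drift + freq.pct_limitation
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_empty_pairs_rejected(self):
        with pytest.raises(AssemblyError):
            lt.process_frequencies([], "P")
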