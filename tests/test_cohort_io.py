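"""Loading, validation, inclusion filtering and result writing."""

import json

import numpy as np
import pandas as pd
import pytest

import lung_turnover as lt
from lung_turnover.cohort_io import CohortIOError, ResultsBundle, write_results
from lung_turnover.pipeline import PipelineConfig, run_pipeline_on_dataset

from conftest import TOY_MANIFEST, TOY_TABLE, make_series


class TestReadTaxaTable:
    def test_two_patients_with_expected_nonzero_rows(self, toy_paths):
        table, manifest, _ = toy_paths
        dataset = lt.read_taxa_table(table, manifest)
        assert set(dataset.series) == {"P1", "P2"}
        # hand count: P1 (s1, s2) detects A, B, C; P2 (s3..s5) all four taxa
        assert dataset.series["P1"].n_taxa == 3
        assert dataset.series["P2"].n_taxa == 4
        assert set(dataset.series["P1"].taxa) == {"A", "B", "C"}

    def test_counts_normalized_to_relative_abundance(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "taxon_id\tx1\nA\t10\nB\t30\nC\t60\n"
        )
        (tmp_path / "m.tsv").write_text(
            "sample_id\tpatient_id\tcollection_day\tsample_type\n"
            "x1\tQ\t0\tsputum\n"
        )
        ts = lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv").series["Q"]
        assert np.allclose(ts.abundance[:, 0], [0.1, 0.3, 0.6])

    def test_every_column_sums_to_one(self, toy_dataset):
        for ts in toy_dataset.series.values():
            assert np.allclose(ts.abundance.sum(axis=0), 1.0, atol=1e-9)

    def test_manifest_sample_missing_from_table_names_it(self, tmp_path):
        (tmp_path / "t.tsv").write_text(TOY_TABLE)
        (tmp_path / "m.tsv").write_text(
            TOY_MANIFEST + "s9\tP2\t200\tsputum\n"
        )
        with pytest.raises(CohortIOError, match="s9"):
            lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text(TOY_TABLE)
        (tmp_path / "m.tsv").write_text(
            TOY_MANIFEST + "s1\tP2\t200\tsputum\n"
        )
        with pytest.raises(CohortIOError, match="duplicate"):
            lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_negative_day_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text(TOY_TABLE)
        (tmp_path / "m.tsv").write_text(
            TOY_MANIFEST.replace("s2\tP1\t30", "s2\tP1\t-3")
        )
        with pytest.raises(CohortIOError, match="negative"):
            lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_non_numeric_abundance_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text(TOY_TABLE.replace("\t3\t", "\tNA\t", 1))
        (tmp_path / "m.tsv").write_text(TOY_MANIFEST)
        with pytest.raises(CohortIOError, match="non-numeric"):
            lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_same_day_samples_rejected_unless_merged(self, tmp_path):
        (tmp_path / "t.tsv").write_text(TOY_TABLE)
        (tmp_path / "m.tsv").write_text(
            TOY_MANIFEST.replace("s2\tP1\t30", "s2\tP1\t0")
        )
        with pytest.raises(CohortIOError, match="same|day"):
            lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        merged = lt.read_taxa_table(
            tmp_path / "t.tsv", tmp_path / "m.tsv", merge_same_day=True
        )
        assert merged.series["P1"].n_samples == 1

    def test_iso_dates_converted_to_day_offsets(self, tmp_path):
        (tmp_path / "t.tsv").write_text(TOY_TABLE)
        (tmp_path / "m.tsv").write_text(
            "sample_id\tpatient_id\tcollection_day\tsample_type\n"
            "s1\tP1\t2020-01-05\tsputum\n"
            "s2\tP1\t2020-02-04\tcough_swab\n"
            "s3\tP2\t2020-01-01\tsputum\n"
            "s4\tP2\t2020-02-10\tsputum\n"
            "s5\tP2\t2020-04-10\tsputum\n"
        )
        ds = lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert list(ds.series["P1"].days) == [0, 30]
        assert list(ds.series["P2"].days) == [0, 40, 100]


class TestClinicalMetadata:
    def test_packaged_reference_table(self):
        meta = lt.table1_fixture()
        assert len(meta) == 30
        cohorts = [m.cohort for m in meta.values()]
        assert cohorts.count(lt.Cohort.PAEDIATRIC) == 15
        assert cohorts.count(lt.Cohort.ADULT) == 15
        assert meta["110"].mean_fev1 == pytest.approx(120.1)
        assert meta["110"].cohort is lt.Cohort.ADULT
        assert meta["106"].exacerbations == 8
        assert meta["216"].mean_fev1 == pytest.approx(117.8)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("")
        with pytest.raises(CohortIOError, match="no records"):
            lt.read_clinical_metadata(path)
        path.write_text("patient_id\tcohort\tmean_fev1\tfev1_sd\texacerbations\n")
        with pytest.raises(CohortIOError, match="no records"):
            lt.read_clinical_metadata(path)

    def test_missing_column_and_bad_number(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("patient_id\tcohort\tmean_fev1\n1\tadult\t90\n")
        with pytest.raises(CohortIOError, match="missing column"):
            lt.read_clinical_metadata(path)
        path.write_text(
            "patient_id\tcohort\tmean_fev1\tfev1_sd\texacerbations\n"
            "1\tadult\tninety\t1\t0\n"
        )
        with pytest.raises(CohortIOError):
            lt.read_clinical_metadata(path)

    def test_unknown_cohort_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "patient_id\tcohort\tmean_fev1\tfev1_sd\texacerbations\n"
            "1\tneonatal\t90\t1\t0\n"
        )
        with pytest.raises(CohortIOError, match="cohort"):
            lt.read_clinical_metadata(path)


class TestInclusionCriteria:
    @pytest.mark.parametrize(
        "n_samples, last_day, retained, reason",
        [
            (5, 900, False, "too few samples"),
            (8, 730, False, "duration"),
            (6, 785, True, None),
            (6, 731, True, None),
        ],
    )
    def test_rules(self, n_samples, last_day, retained, reason):
        days = np.linspace(0, last_day, n_samples).astype(int)
        days = np.unique(days)
        cols = [[1.0] for _ in days]
        series = make_series("P", cols, days)
        filtered, excluded = lt.apply_inclusion_criteria(
            lt.CohortDataset(series={"P": series})
        )
        assert ("P" in filtered.series) is retained
        if not retained:
            assert excluded[0].reason.startswith(reason)

    def test_idempotent(self, drift_cohort):
        once, _ = lt.apply_inclusion_criteria(drift_cohort)
        twice, report = lt.apply_inclusion_criteria(once)
        assert set(once.series) == set(twice.series)
        assert report == []


class TestRoundTrip:
    def test_write_then_read_preserves_abundances(self, tmp_path, drift_cohort):
        lt.write_taxa_table(
            drift_cohort, tmp_path / "t.tsv", tmp_path / "m.tsv"
        )
        back = lt.read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert set(back.series) == set(drift_cohort.series)
        for pid, original in drift_cohort.series.items():
            loaded = back.series[pid]
            assert loaded.taxa == original.taxa
            assert [s.sample_id for s in loaded.samples] == [
                s.sample_id for s in original.samples
            ]
            assert np.max(np.abs(loaded.abundance - original.abundance)) <= 1e-12


class TestWriteResults:
    def test_full_pipeline_outputs(self, tmp_path, drift_cohort):
        config = PipelineConfig(rc_iterations=100, seed=1, out_dir=str(tmp_path))
        results = run_pipeline_on_dataset(drift_cohort, config)
        names = {p.name for p in results.written}
        assert names == {
            "persistence.tsv", "str_points.tsv", "str_fits.tsv",
            "raup_crick_pairs.tsv", "process_frequencies.tsv",
            "cohort_summary.json",
        }
        freq = pd.read_csv(tmp_path / "process_frequencies.tsv", sep="\t")
        # one row per retained patient x group
        assert len(freq) == len(results.frequencies)
        fits = pd.read_csv(tmp_path / "str_fits.tsv", sep="\t")
        assert len(fits) == 3 * len(drift_cohort.series)

    def test_rerun_is_byte_identical(self, tmp_path, drift_cohort):
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        for out in (out_a, out_b):
            run_pipeline_on_dataset(
                drift_cohort,
                PipelineConfig(rc_iterations=100, seed=5, out_dir=str(out)),
            )
        for name in ("persistence.tsv", "raup_crick_pairs.tsv", "str_fits.tsv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_empty_bundle_writes_summary_only(self, tmp_path):
        written = write_results(ResultsBundle(summary={"note": "empty"}), tmp_path)
        assert {p.name for p in written} == {"cohort_summary.json"}
        assert json.loads((tmp_path / "cohort_summary.json").read_text()) == {
            "note": "empty"
        }


class TestBiomReader:
    def test_json_biom_matches_tsv(self, tmp_path, toy_paths):
        table, manifest, _ = toy_paths
        tsv = lt.read_taxa_table(table, manifest)
        doc = {
            "id": "toy", "format": "1.0", "matrix_type": "dense",
            "rows": [{"id": t} for t in "ABCD"],
            "columns": [{"id": f"s{i}"} for i in range(1, 6)],
            "data": [
                [1, 2, 1, 0, 0], [0, 1, 2, 1, 1],
                [3, 0, 0, 1, 2], [0, 0, 1, 1, 0],
            ],
        }
        biom = tmp_path / "t.biom"
        biom.write_text(json.dumps(doc))
        loaded = lt.read_biom_table(biom, manifest)
        for pid in tsv.series:
            assert np.allclose(
                loaded.series[pid].abundance, tsv.series[pid].abundance
            )

    def test_sparse_json_biom(self, tmp_path, toy_paths):
        _, manifest, _ = toy_paths
        doc = {
            "matrix_type": "sparse",
            "rows": [{"id": "A"}, {"id": "B"}],
            "columns": [{"id": f"s{i}"} for i in range(1, 6)],
            "data": [[0, j, 1.0] for j in range(5)] + [[1, 0, 3.0]],
        }
        biom = tmp_path / "t.biom"
        biom.write_text(json.dumps(doc))
        loaded = lt.read_biom_table(biom, manifest)
        assert loaded.series["P1"].abundance[:, 0] == pytest.approx([0.25, 0.75])
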