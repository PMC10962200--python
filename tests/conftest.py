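"""Shared fixtures: a hand-checkable two-patient toy dataset on disk and
small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import lung_turnover as lt

TOY_TABLE = """\
taxon_id\ts1\ts2\ts3\ts4\ts5
A\t1\t2\t1\t0\t0
B\t0\t1\t2\t1\t1
C\t3\t0\t0\t1\t2
D\t0\t0\t1\t1\t0
"""

# s1,s2 belong to patient P1 (days 0, 30); s3..s5 to P2 (days 0, 40, 100)
TOY_MANIFEST = """\
sample_id\tpatient_id\tcollection_day\tsample_type
s1\tP1\t0\tsputum
s2\tP1\t30\tcough_swab
s3\tP2\t0\tsputum
s4\tP2\t40\tsputum
s5\tP2\t100\tsputum
"""

TOY_CLINICAL = """\
patient_id\tcohort\tmean_fev1\tfev1_sd\texacerbations
P1\tpaediatric\t92.5\t4.0\t1
P2\tadult\t71.0\t6.5\t3
"""


@pytest.fixture
def toy_paths(tmp_path):
    table = tmp_path / "table.tsv"
    manifest = tmp_path / "manifest.tsv"
    clinical = tmp_path / "clinical.tsv"
    table.write_text(TOY_TABLE)
    manifest.write_text(TOY_MANIFEST)
    clinical.write_text(TOY_CLINICAL)
    return table, manifest, clinical


@pytest.fixture
def toy_dataset(toy_paths):
    table, manifest, clinical = toy_paths
    dataset = lt.read_taxa_table(table, manifest)
    return dataset.with_metadata(lt.read_clinical_metadata(clinical))


def make_series(patient_id, columns, days, taxa=None):
    """Series from explicit relative-abundance columns (lists per sample)."""
    matrix = np.array(columns, dtype=float).T
    taxa = taxa or [f"t{i}" for i in range(matrix.shape[0])]
    samples = [
        lt.SampleRecord(f"{patient_id}_s{j}", patient_id, int(d))
        for j, d in enumerate(days)
    ]
    return lt.TaxaTimeSeries(patient_id, list(taxa), samples, matrix)


@pytest.fixture(scope="session")
def drift_cohort():
    return lt.generate_cohort(lt.GeneratorConfig(n_patients_per_cohort=3), seed=42)


@pytest.fixture(scope="session")
def homogenizing_cohort():
    return lt.generate_cohort(
        lt.GeneratorConfig(n_patients_per_cohort=3, regime="homogenizing"), seed=43
    )
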