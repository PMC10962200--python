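"""Data model, ingestion, validation, inclusion filtering and result writing.

The pipeline operates on per-patient longitudinal taxa tables: rows are
bacterial taxa, columns are respiratory samples (sputum or cough swab) taken
at clinic visits over a multi-year window.  Counts are normalized to relative
abundance on load; the time axis is integer days since each patient's first
sample.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLUMN_SUM_TOL = 1e-9

MANIFEST_COLUMNS = ("sample_id", "patient_id", "collection_day", "sample_type")
CLINICAL_COLUMNS = ("patient_id", "cohort", "mean_fev1", "fev1_sd", "exacerbations")


class CohortIOError(ValueError):
    """Raised on malformed input tables or manifests."""


class SampleType(str, enum.Enum):
    SPUTUM = "sputum"
    COUGH_SWAB = "cough_swab"


class Cohort(str, enum.Enum):
    PAEDIATRIC = "paediatric"
    ADULT = "adult"


@dataclass(frozen=True)
class SampleRecord:
    """One respiratory sample: identity, owner, day on the patient's time axis."""

    sample_id: str
    patient_id: str
    collection_day: int
    sample_type: SampleType = SampleType.SPUTUM

    def __post_init__(self) -> None:
        if self.collection_day < 0:
            raise CohortIOError(
                f"sample {self.sample_id!r}: negative collection_day "
                f"{self.collection_day}"
            )


@dataclass
class TaxaTimeSeries:
    """One patient's taxa x sample relative-abundance matrix.

    Columns each sum to 1 (within ``COLUMN_SUM_TOL``) unless the series is a
    group subset, in which case ``normalized`` is False and downstream use is
    presence/absence only.  Samples are strictly ordered by collection day.
    """

    patient_id: str
    taxa: list[str]
    samples: list[SampleRecord]
    abundance: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.taxa), len(self.samples)):
            raise CohortIOError(
                f"patient {self.patient_id!r}: abundance shape "
                f"{self.abundance.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise CohortIOError(f"patient {self.patient_id!r}: duplicate taxon ids")
        days = self.days
        if len(days) and days[0] != 0:
            raise CohortIOError(
                f"patient {self.patient_id!r}: first sample must be at day 0"
            )
        if np.any(np.diff(days) <= 0):
            raise CohortIOError(
                f"patient {self.patient_id!r}: collection days not strictly "
                "increasing (same-day duplicates must be merged or rejected)"
            )
        if np.any(self.abundance < 0):
            raise CohortIOError(f"patient {self.patient_id!r}: negative abundance")
        if self.normalized:
            sums = self.abundance.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > COLUMN_SUM_TOL)[0]
            if bad.size:
                raise CohortIOError(
                    f"patient {self.patient_id!r}: column(s) {bad.tolist()} do not "
                    "sum to 1; normalize counts on load (all-zero columns are an "
                    "error)"
                )
            if np.any(self.abundance.sum(axis=1) == 0):
                raise CohortIOError(
                    f"patient {self.patient_id!r}: all-zero taxon row(s); drop "
                    "undetected taxa on load"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def days(self) -> np.ndarray:
        return np.array([s.collection_day for s in self.samples], dtype=int)

    @property
    def duration_days(self) -> int:
        return int(self.days[-1]) if self.samples else 0

    def presence(self, detection_min: float = 0.0) -> np.ndarray:
        """Boolean taxa x sample detection matrix (abundance > detection_min)."""
        return self.abundance > detection_min

    def presence_sets(self, detection_min: float = 0.0) -> list[frozenset[str]]:
        pres = self.presence(detection_min)
        taxa = np.asarray(self.taxa, dtype=object)
        return [frozenset(taxa[pres[:, j]]) for j in range(self.n_samples)]

    @classmethod
    def from_counts(
        cls,
        patient_id: str,
        taxa: Iterable[str],
        samples: Iterable[SampleRecord],
        counts: np.ndarray,
    ) -> "TaxaTimeSeries":
        """Normalize a counts (or unnormalized abundance) matrix column-wise."""
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=0)
        if np.any(sums <= 0):
            raise CohortIOError(
                f"patient {patient_id!r}: all-zero sample column(s) "
                f"{np.where(sums <= 0)[0].tolist()}"
            )
        taxa = list(taxa)
        keep = counts.sum(axis=1) > 0
        if not np.all(keep):
            dropped = [t for t, k in zip(taxa, keep) if not k]
            logger.info(
                "patient %s: dropping %d all-zero taxon rows: %s",
                patient_id, len(dropped), dropped[:10],
            )
        return cls(
            patient_id=patient_id,
            taxa=[t for t, k in zip(taxa, keep) if k],
            samples=list(samples),
            abundance=counts[keep] / sums,
        )


@dataclass
class PatientMetadata:
    """Clinical covariates: cohort, study-mean %FEV1 (+- SD), exacerbations."""

    patient_id: str
    cohort: Cohort
    mean_fev1: float
    fev1_sd: float
    exacerbations: int

    def __post_init__(self) -> None:
        self.cohort = Cohort(self.cohort)
        if not self.mean_fev1 > 0:
            raise CohortIOError(
                f"patient {self.patient_id!r}: mean_fev1 must be > 0"
            )
        if self.fev1_sd < 0:
            raise CohortIOError(f"patient {self.patient_id!r}: fev1_sd must be >= 0")
        if self.exacerbations < 0:
            raise CohortIOError(
                f"patient {self.patient_id!r}: exacerbations must be >= 0"
            )


@dataclass
class CohortDataset:
    """All per-patient series plus (optionally) their clinical metadata."""

    series: dict[str, TaxaTimeSeries] = field(default_factory=dict)
    metadata: dict[str, PatientMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metadata:
            missing_meta = set(self.series) - set(self.metadata)
            missing_series = set(self.metadata) - set(self.series)
            if missing_meta or missing_series:
                raise CohortIOError(
                    "series/metadata patient mismatch: "
                    f"no metadata for {sorted(missing_meta)}, "
                    f"no series for {sorted(missing_series)}"
                )

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.series)

    def with_metadata(self, metadata: Mapping[str, PatientMetadata]) -> "CohortDataset":
        return CohortDataset(series=dict(self.series), metadata=dict(metadata))


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortIOError(f"{path}: no records") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise CohortIOError(f"{path}: no records")
    return df


def _manifest_days(manifest: pd.DataFrame, path: str | Path) -> pd.Series:
    """Integer days since each patient's first sample.

    Accepts integer day offsets or ISO calendar dates; dates are converted to
    day offsets per patient (first visit = day 0).
    """
    raw = manifest["collection_day"]
    try:
        days = raw.astype(int)
    except (ValueError, TypeError):
        try:
            dates = pd.to_datetime(raw, format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise CohortIOError(
                f"{path}: collection_day must be integer days or ISO dates"
            ) from exc
        days = (
            (dates - dates.groupby(manifest["patient_id"]).transform("min"))
            .dt.days.astype(int)
        )
    if (days < 0).any():
        bad = manifest.loc[days < 0, "sample_id"].tolist()
        raise CohortIOError(f"{path}: negative collection_day for sample(s) {bad}")
    return days


def read_taxa_table(
    table_path: str | Path,
    manifest_path: str | Path,
    merge_same_day: bool = False,
) -> CohortDataset:
    """Load a taxa x sample TSV plus its sample manifest into per-patient series.

    Columns are normalized to relative abundance; taxa never detected in a
    patient are dropped from that patient's series.  Two samples of one
    patient on the same day are an error unless ``merge_same_day`` is set, in
    which case their abundances are averaged.
    """
    table_path, manifest_path = Path(table_path), Path(manifest_path)
    manifest = _read_tsv(manifest_path, MANIFEST_COLUMNS)
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].tolist()
        raise CohortIOError(f"{manifest_path}: duplicate sample_id(s) {dup}")
    manifest = manifest.assign(collection_day=_manifest_days(manifest, manifest_path))

    table = pd.read_csv(table_path, sep="\t", index_col=0)
    if table.index.name not in (None, "taxon_id"):
        logger.warning(
            "%s: first column named %r, expected 'taxon_id'",
            table_path, table.index.name,
        )
    if table.columns.duplicated().any():
        raise CohortIOError(f"{table_path}: duplicate sample column(s)")
    try:
        matrix = table.astype(float)
    except ValueError as exc:
        raise CohortIOError(f"{table_path}: non-numeric abundance value") from exc
    if matrix.isna().any().any():
        raise CohortIOError(
            f"{table_path}: non-numeric or missing abundance value"
        )

    known = set(manifest["sample_id"])
    unknown = [c for c in matrix.columns if c not in known]
    if unknown:
        raise CohortIOError(
            f"sample(s) {unknown} in {table_path} are absent from the manifest"
        )
    absent = [s for s in manifest["sample_id"] if s not in set(matrix.columns)]
    if absent:
        raise CohortIOError(
            f"sample(s) {absent} listed in the manifest are absent from the table"
        )

    series: dict[str, TaxaTimeSeries] = {}
    for patient_id, rows in manifest.groupby("patient_id", sort=True):
        rows = rows.sort_values(["collection_day", "sample_id"])
        if rows["collection_day"].duplicated().any():
            if not merge_same_day:
                dup_days = rows.loc[
                    rows["collection_day"].duplicated(), "collection_day"
                ].tolist()
                raise CohortIOError(
                    f"patient {patient_id!r}: multiple samples on day(s) "
                    f"{dup_days}; pass merge_same_day=True to union them"
                )
            merged_cols, merged_records = [], []
            for day, grp in rows.groupby("collection_day", sort=True):
                cols = matrix[grp["sample_id"].tolist()].to_numpy()
                merged_cols.append(cols.mean(axis=1))
                first = grp.iloc[0]
                merged_records.append(
                    SampleRecord(
                        sample_id="+".join(grp["sample_id"]),
                        patient_id=patient_id,
                        collection_day=int(day) - int(rows["collection_day"].min()),
                        sample_type=SampleType(first["sample_type"]),
                    )
                )
            counts = np.column_stack(merged_cols)
            records = merged_records
        else:
            counts = matrix[rows["sample_id"].tolist()].to_numpy()
            day0 = int(rows["collection_day"].min())
            records = [
                SampleRecord(
                    sample_id=r.sample_id,
                    patient_id=patient_id,
                    collection_day=int(r.collection_day) - day0,
                    sample_type=SampleType(r.sample_type),
                )
                for r in rows.itertuples()
            ]
        series[patient_id] = TaxaTimeSeries.from_counts(
            patient_id, list(matrix.index), records, counts
        )
    return CohortDataset(series=series)


def read_clinical_metadata(path: str | Path) -> dict[str, PatientMetadata]:
    """Load the patient clinical table (cohort, mean %FEV1 +- SD, exacerbations)."""
    df = _read_tsv(path, CLINICAL_COLUMNS)
    records: dict[str, PatientMetadata] = {}
    for row in df.itertuples():
        pid = str(row.patient_id)
        if pid in records:
            raise CohortIOError(f"{path}: duplicate patient_id {pid!r}")
        try:
            cohort = Cohort(row.cohort)
        except ValueError:
            raise CohortIOError(
                f"{path}: patient {pid!r}: unknown cohort {row.cohort!r} "
                f"(expected one of {[c.value for c in Cohort]})"
            ) from None
        try:
            records[pid] = PatientMetadata(
                patient_id=pid,
                cohort=cohort,
                mean_fev1=float(row.mean_fev1),
                fev1_sd=float(row.fev1_sd),
                exacerbations=int(row.exacerbations),
            )
        except (ValueError, TypeError) as exc:
            raise CohortIOError(f"{path}: patient {pid!r}: {exc}") from exc
    return records


def read_biom_table(path: str | Path, manifest_path: str | Path) -> CohortDataset:
    """Optional reader for standard BIOM tables (JSON or HDF5 layout).

    Converts the table to the in-memory TSV representation and defers to
    :func:`read_taxa_table` semantics via ``TaxaTimeSeries.from_counts``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head.startswith(b"\x89HDF"):
        df = _biom_hdf5_frame(path)
    else:
        df = _biom_json_frame(path)
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        tsv = Path(tmp) / "table.tsv"
        df.to_csv(tsv, sep="\t", index_label="taxon_id")
        return read_taxa_table(tsv, manifest_path)


def _biom_json_frame(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    data = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            data[int(i), int(j)] = v
    else:
        data[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(data, index=taxa, columns=samples)


def _biom_hdf5_frame(path: Path) -> pd.DataFrame:
    import h5py

    with h5py.File(path, "r") as fh:
        taxa = [t.decode() if isinstance(t, bytes) else str(t)
                for t in fh["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in fh["sample/ids"][:]]
        # CSR over observations
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    dense = np.zeros((len(taxa), len(samples)))
    for i in range(len(taxa)):
        cols = indices[indptr[i]:indptr[i + 1]]
        dense[i, cols] = data[indptr[i]:indptr[i + 1]]
    return pd.DataFrame(dense, index=taxa, columns=samples)


# ---------------------------------------------------------------------------
# inclusion filtering


def apply_inclusion_criteria(
    dataset: CohortDataset,
    min_samples: int = 6,
    min_duration_days: int = 731,
) -> tuple[CohortDataset, list[Exclusion]]:
    """Retain patients with >= min_samples samples AND sampling duration
    reaching at least ``min_duration_days`` (default: beyond day 730, i.e.
    into a third year of follow-up).  Returns the filtered dataset and an
    exclusion report.
    """
    kept: dict[str, TaxaTimeSeries] = {}
    excluded: list[Exclusion] = []
    for pid in sorted(dataset.series):
        ts = dataset.series[pid]
        reasons = []
        if ts.n_samples < min_samples:
            reasons.append("too few samples")
        if ts.duration_days < min_duration_days:
            reasons.append("duration")
        if reasons:
            excluded.append(Exclusion(pid, "; ".join(reasons)))
            logger.info("excluding patient %s: %s", pid, "; ".join(reasons))
        else:
            kept[pid] = ts
    meta = {p: m for p, m in dataset.metadata.items() if p in kept}
    return CohortDataset(series=kept, metadata=meta), excluded


# ---------------------------------------------------------------------------
# writers

RESULT_SCHEMAS = {
    "persistence.tsv": [
        "patient_id", "taxon_id", "n_samples_detected", "n_samples_total",
        "persistence_pct", "mean_rel_abund_detected", "status",
    ],
    "str_points.tsv": ["patient_id", "group", "window_start_sample", "T_days", "S_taxa"],
    "str_fits.tsv": [
        "patient_id", "group", "c", "w", "r2", "F", "df1", "df2", "p", "n_points",
    ],
    "raup_crick_pairs.tsv": [
        "patient_id", "group", "sample_a", "sample_b", "s_rc", "process",
    ],
    "process_frequencies.tsv": [
        "patient_id", "group", "pct_homogenizing", "pct_drift", "pct_limitation",
        "n_pairs",
    ],
}


@dataclass
class ResultsBundle:
    """Tabular outputs of the pipeline plus the cohort-level JSON summary."""

    persistence: pd.DataFrame | None = None
    str_points: pd.DataFrame | None = None
    str_fits: pd.DataFrame | None = None
    raup_crick_pairs: pd.DataFrame | None = None
    process_frequencies: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> set[Path]:
    """Write the fixed-schema TSVs plus cohort_summary.json; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: set[Path] = set()
    frames = {
        "persistence.tsv": bundle.persistence,
        "str_points.tsv": bundle.str_points,
        "str_fits.tsv": bundle.str_fits,
        "raup_crick_pairs.tsv": bundle.raup_crick_pairs,
        "process_frequencies.tsv": bundle.process_frequencies,
    }
    for name, df in frames.items():
        if df is None:
            continue
        cols = RESULT_SCHEMAS[name]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortIOError(f"{name}: missing column(s) {missing}")
        path = out_dir / name
        df.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.add(path)
    summary_path = out_dir / "cohort_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True, default=_jsonable)
    written.add(summary_path)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, enum.Enum):
        return obj.value
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_taxa_table(
    dataset: CohortDataset, table_path: str | Path, manifest_path: str | Path
) -> None:
    """Round-trippable writer for the input TSV pair (abundances at full
    precision; taxon rows in sorted order, so a reload preserves each
    patient's row order whenever the series order taxa consistently)."""
    all_taxa = sorted({t for ts in dataset.series.values() for t in ts.taxa})
    global_idx = {t: i for i, t in enumerate(all_taxa)}
    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    for pid in sorted(dataset.series):
        ts = dataset.series[pid]
        rows = np.array([global_idx[t] for t in ts.taxa], dtype=int)
        for j, rec in enumerate(ts.samples):
            col = np.zeros(len(all_taxa))
            col[rows] = ts.abundance[:, j]
            columns[rec.sample_id] = col
            manifest_rows.append(
                {
                    "sample_id": rec.sample_id,
                    "patient_id": rec.patient_id,
                    "collection_day": rec.collection_day,
                    "sample_type": rec.sample_type.value,
                }
            )
    pd.DataFrame(columns, index=pd.Index(all_taxa, name="taxon_id")).to_csv(
        table_path, sep="\t", float_format="%.17g"
    )
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)


def write_clinical_metadata(
    metadata: Mapping[str, PatientMetadata], path: str | Path
) -> None:
    rows = [
        {
            "patient_id": m.patient_id,
            "cohort": m.cohort.value,
            "mean_fev1": m.mean_fev1,
            "fev1_sd": m.fev1_sd,
            "exacerbations": m.exacerbations,
        }
        for _, m in sorted(metadata.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
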