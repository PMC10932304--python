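"""Reading, validation and alignment of the peak table and clinical table.

The pipeline starts from a processed LC-MS peak table (samples x annotated
features, raw intensity scale) plus per-sample annotations: acquisition batch,
injection order within batch, and sample role (``study``, ``qc`` or ``blank``).
Study samples are joined 1:1 with clinical records (patient, timepoint, liver
chemistry) into a :class:`Cohort`, the object every downstream stage consumes.

On-disk conventions
-------------------
Peak table CSV/TSV, default orientation samples-as-rows::

    sample_id,batch,injection_order,role,<feature_1>,<feature_2>,...
    S001,B1,1,qc,10432.1,884.2,...

Empty cells and ``NA`` are missing values; zeros are measured zeros. The
alternate orientation (features as rows) is handled by ``orientation=
"features_rows"``, which transposes on read; annotation columns then live in
a companion block of rows named ``batch``/``injection_order``/``role``.

Clinical table CSV/TSV with at least ``sample_id, patient_id, timepoint,
alt, alp, bilirubin``; optional ``days_from_onset, drug, clinician_label``.

A YAML *manifest* names both files plus dialect/orientation flags and a
``corrected`` flag stating whether the peak table is already drift-corrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dili_ternary")

ROLES = ("study", "qc", "blank")
CLINICIAN_LABELS = ("cholestatic", "hepatocellular", "mixed", "recovered")

ANNOTATION_COLUMNS = ("batch", "injection_order", "role")


class ValidationError(ValueError):
    """A table violates the cohort data contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Samples x features intensity matrix with acquisition annotations.

    ``intensities`` is a DataFrame indexed by sample_id with feature_id
    columns, raw (nonnegative) intensity scale, NaN for missing cells.
    ``batch``, ``injection_order`` and ``role`` are Series aligned to the
    sample index.
    """

    intensities: pd.DataFrame
    batch: pd.Series
    injection_order: pd.Series
    role: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def rows(self, role: str) -> pd.DataFrame:
        """Intensity sub-matrix for one sample role."""
        return self.intensities.loc[self.role == role]

    def validate(self) -> None:
        idx = self.intensities.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate sample IDs: {dups}")
        cols = self.intensities.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate feature IDs: {dups}")
        for name, s in (("batch", self.batch),
                        ("injection_order", self.injection_order),
                        ("role", self.role)):
            if not s.index.equals(idx):
                raise ValidationError(f"{name} not aligned with sample index")
        bad_roles = set(self.role) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative intensities present")
        inj = self.injection_order
        if (inj <= 0).any() or not np.allclose(inj, inj.astype(int)):
            raise ValidationError("injection_order must be positive integers")
        for b, grp in inj.groupby(self.batch):
            if grp.duplicated().any():
                raise ValidationError(
                    f"injection_order not unique within batch {b!r}")

    def copy(self) -> "PeakTable":
        return PeakTable(self.intensities.copy(), self.batch.copy(),
                         self.injection_order.copy(), self.role.copy())


@dataclass
class SampleRecord:
    """Clinical chemistry and identifiers for one study sample."""

    sample_id: str
    patient_id: str
    timepoint_index: int
    alt: float | None          # U/L
    alp: float | None          # U/L
    bilirubin: float | None    # mg/dL
    days_from_onset: int | None = None
    drug: str | None = None
    clinician_label: str | None = None

    def __post_init__(self) -> None:
        if self.timepoint_index < 1:
            raise ValidationError(
                f"{self.sample_id}: timepoint_index must be >= 1")
        for name in ("alt", "alp", "bilirubin"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.sample_id}: negative {name}")
        if (self.clinician_label is not None
                and self.clinician_label not in CLINICIAN_LABELS):
            raise ValidationError(
                f"{self.sample_id}: unknown clinician_label "
                f"{self.clinician_label!r}")


@dataclass
class JoinReport:
    """Sample IDs on either side of the join that found no partner."""

    unmatched_peak_samples: list[str] = field(default_factory=list)
    unmatched_clinical_samples: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.unmatched_peak_samples and not self.unmatched_clinical_samples


@dataclass
class Cohort:
    """A validated peak table joined with clinical records.

    Records are aligned 1:1 with the *study* rows of the peak table; QC and
    blank rows carry no record.
    """

    peak_table: PeakTable
    records: list[SampleRecord]

    def __post_init__(self) -> None:
        study_ids = set(
            self.peak_table.intensities.index[self.peak_table.role == "study"])
        rec_ids = [r.sample_id for r in self.records]
        if len(set(rec_ids)) != len(rec_ids):
            raise ValidationError("duplicate sample_id among records")
        missing = study_ids - set(rec_ids)
        extra = set(rec_ids) - study_ids
        if missing or extra:
            raise ValidationError(
                f"records do not match study samples (missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]})")
        keys = {(r.patient_id, r.timepoint_index) for r in self.records}
        if len(keys) != len(self.records):
            raise ValidationError("(patient_id, timepoint_index) not unique")
        # canonical ordering: records follow peak-table row order
        order = {s: i for i, s in enumerate(self.peak_table.sample_ids)}
        self.records = sorted(self.records, key=lambda r: order[r.sample_id])

    @property
    def study_sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def study_intensities(self) -> pd.DataFrame:
        return self.peak_table.intensities.loc[self.study_sample_ids]

    def clinical_frame(self) -> pd.DataFrame:
        """Records as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            [{
                "sample_id": r.sample_id, "patient_id": r.patient_id,
                "timepoint_index": r.timepoint_index,
                "days_from_onset": r.days_from_onset, "drug": r.drug,
                "alt": r.alt, "alp": r.alp, "bilirubin": r.bilirubin,
                "clinician_label": r.clinician_label,
            } for r in self.records]).set_index("sample_id")


@dataclass
class CohortManifest:
    peak_table: Path
    clinical_table: Path
    dialect: str = "csv"
    orientation: str = "samples_rows"
    corrected: bool = False


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sep(dialect: str) -> str:
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be csv or tsv, got {dialect!r}")
    return "," if dialect == "csv" else "\t"


def read_peak_table(path: str | Path, dialect: str = "csv",
                    orientation: str = "samples_rows") -> PeakTable:
    """Read and validate a peak table.

    ``orientation="samples_rows"`` (default) expects one row per sample with
    ``batch``/``injection_order``/``role`` annotation columns;
    ``"features_rows"`` expects the transpose (one row per feature, annotation
    rows named after the annotation fields) and transposes on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str,
                     na_values=_NA_VALUES, keep_default_na=False,
                     float_precision="round_trip")
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.rename("sample_id")
    df.columns = df.columns.rename(None)
    missing_ann = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_ann:
        raise ValidationError(f"missing annotation columns: {missing_ann}")
    feat_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    # element-wise float() parse: exact round-trip of repr()ed values
    intens = df[feat_cols].map(lambda v: np.nan if pd.isna(v) else float(v))
    inj = pd.to_numeric(df["injection_order"]).astype(int)
    return PeakTable(intensities=intens.astype(float),
                     batch=df["batch"].astype(str),
                     injection_order=inj,
                     role=df["role"].astype(str))


def write_peak_table(pt: PeakTable, path: str | Path,
                     dialect: str = "csv") -> None:
    """Write a peak table in the samples-as-rows layout (round-trips read)."""
    df = pd.concat(
        [pt.batch.rename("batch"),
         pt.injection_order.rename("injection_order"),
         pt.role.rename("role"),
         pt.intensities], axis=1)
    df.index.name = "sample_id"
    # repr round-trips float64 exactly
    df.to_csv(Path(path), sep=_sep(dialect), na_rep="NA",
              float_format=lambda v: repr(float(v)))


_CLINICAL_ALIASES = {
    "timepoint": "timepoint_index", "timepoint_index": "timepoint_index",
    "bil": "bilirubin", "bilirubin": "bilirubin",
    "dili_type": "clinician_label", "clinician_label": "clinician_label",
}
_MANDATORY = ("sample_id", "patient_id", "timepoint_index",
              "alt", "alp", "bilirubin")


def _num(value, where: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        logger.warning("unparseable numeric cell %r at %s -> missing",
                       value, where)
        return None


def read_clinical_table(path: str | Path, dialect: str = "csv") -> list[SampleRecord]:
    """Read the per-sample clinical table into typed records.

    Unparseable numeric cells become missing with a logged warning; rows
    missing mandatory *columns* raise, missing *values* are tolerated where
    the record allows it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str,
                     na_values=_NA_VALUES, keep_default_na=False)
    df.columns = [_CLINICAL_ALIASES.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    if df.empty and not set(_MANDATORY) - set(df.columns):
        return []
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        where = f"{path.name}:{i}"
        tp = row["timepoint_index"]
        if isinstance(tp, str) and tp.startswith("t"):
            tp = tp[1:]
        days = _num(row.get("days_from_onset"), where)
        label = row.get("clinician_label")
        if isinstance(label, float) and np.isnan(label):
            label = None
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            timepoint_index=int(float(tp)),
            alt=_num(row["alt"], where),
            alp=_num(row["alp"], where),
            bilirubin=_num(row["bilirubin"], where),
            days_from_onset=None if days is None else int(days),
            drug=row.get("drug"),
            clinician_label=label,
        ))
    return records


def write_clinical_table(records: Sequence[SampleRecord],
                         path: str | Path, dialect: str = "csv") -> None:
    rows = [{
        "sample_id": r.sample_id, "patient_id": r.patient_id,
        "timepoint_index": r.timepoint_index,
        "days_from_onset": r.days_from_onset, "drug": r.drug,
        "alt": r.alt, "alp": r.alp, "bilirubin": r.bilirubin,
        "clinician_label": r.clinician_label,
    } for r in records]
    pd.DataFrame(rows).to_csv(Path(path), sep=_sep(dialect), index=False,
                              na_rep="NA")


def join_cohort(peak_table: PeakTable,
                records: Sequence[SampleRecord]) -> tuple[Cohort, JoinReport]:
    """Match clinical records to study rows of the peak table by sample_id.

    Returns the joined cohort plus a report of unmatched IDs on both sides.
    QC and blank rows pass through without records. Raises if no study sample
    matches at all.
    """
    study_ids = set(
        peak_table.intensities.index[peak_table.role == "study"])
    by_id = {r.sample_id: r for r in records}
    matched = [by_id[s] for s in peak_table.sample_ids if s in by_id and s in study_ids]
    report = JoinReport(
        unmatched_peak_samples=sorted(study_ids - set(by_id)),
        unmatched_clinical_samples=sorted(set(by_id) - study_ids),
    )
    if not matched:
        raise ValidationError("no clinical record matches any study sample")
    keep = set(r.sample_id for r in matched) | set(
        peak_table.intensities.index[peak_table.role != "study"])
    mask = peak_table.intensities.index.isin(keep)
    if report.unmatched_peak_samples:
        warnings.warn(
            f"{len(report.unmatched_peak_samples)} study samples lack clinical "
            "records and were dropped from the cohort", stacklevel=2)
    pt = PeakTable(peak_table.intensities.loc[mask],
                   peak_table.batch.loc[mask],
                   peak_table.injection_order.loc[mask],
                   peak_table.role.loc[mask])
    return Cohort(peak_table=pt, records=list(matched)), report


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    return CohortManifest(
        peak_table=base / raw["peak_table"],
        clinical_table=base / raw["clinical_table"],
        dialect=raw.get("dialect", "csv"),
        orientation=raw.get("orientation", "samples_rows"),
        corrected=bool(raw.get("corrected", False)),
    )


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    data = {
        "peak_table": str(Path(manifest.peak_table).name),
        "clinical_table": str(Path(manifest.clinical_table).name),
        "dialect": manifest.dialect,
        "orientation": manifest.orientation,
        "corrected": manifest.corrected,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_cohort(manifest_path: str | Path) -> tuple[Cohort, JoinReport, CohortManifest]:
    """Convenience: manifest -> joined cohort."""
    mf = load_manifest(manifest_path)
    pt = read_peak_table(mf.peak_table, mf.dialect, mf.orientation)
    recs = read_clinical_table(mf.clinical_table, mf.dialect)
    cohort, report = join_cohort(pt, recs)
    return cohort, report, mf
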