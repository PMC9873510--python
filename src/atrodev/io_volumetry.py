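"""Reading, writing and joining volumetry tables and scan/clinical metadata.

The pipeline consumes two plain-text inputs:

* a **measure table** in the tab-separated layout of the FreeSurfer stats-table
  exporters (``asegstats2table`` / ``aparcstats2table``): one row per scan,
  first column the scan identifier, remaining columns Desikan–Killiany region
  labels (``lh_parahippocampal`` ...) plus recognized whole-brain summary
  columns such as ``CortexVol``;
* a **metadata CSV** with one row per scan carrying acquisition parameters
  (field strength, TR, TI), the subject's age at scan (or a scan date from
  which it can be derived), the age at the index event (infection), and
  subject-level flags (vaccinated, treated, hospitalized, stable_disease).

`build_cohort` joins the two into one validated long-format table — the
canonical in-memory object every later stage operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ReconciliationError, ValidationError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: Whole-brain summary columns recognized in FreeSurfer-style tables. These are
#: kept out of the per-region parcel set but remain addressable as measures.
GLOBAL_MEASURE_LABELS = frozenset(
    {
        "CortexVol",
        "lhCortexVol",
        "rhCortexVol",
        "TotalGrayVol",
        "SubCortGrayVol",
        "BrainSegVol",
        "BrainSegVolNotVent",
        "EstimatedTotalIntraCranialVol",
        "eTIV",
        "MaskVol",
    }
)

#: Columns of the canonical long-format cohort table.
COHORT_COLUMNS = [
    "subject_id",
    "scan_id",
    "age_at_scan",
    "field_strength",
    "repetition_time",
    "inversion_time",
    "phase",
    "region_label",
    "value",
]


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition parameters and subject age for one MRI scan."""

    scan_id: str
    subject_id: str
    age_at_scan: float  # decimal years
    field_strength: float  # tesla
    repetition_time: float  # ms
    inversion_time: float  # ms
    scanner_model: str | None = None

    def __post_init__(self) -> None:
        if not self.age_at_scan > 0:
            raise ValidationError(
                f"scan {self.scan_id!r}: age_at_scan must be > 0, got {self.age_at_scan}"
            )
        for name in ("field_strength", "repetition_time", "inversion_time"):
            if not getattr(self, name) > 0:
                raise ValidationError(
                    f"scan {self.scan_id!r}: {name} must be > 0, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level clinical flags and the age at the index event (infection)."""

    subject_id: str
    age_at_event: float  # decimal years
    vaccinated: bool
    treated: bool
    stable_disease: bool
    hospitalized: bool | None = None

    def __post_init__(self) -> None:
        if not self.age_at_event > 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: age_at_event must be > 0, got {self.age_at_event}"
            )


@dataclass
class MeasureTable:
    """Wide per-scan measure matrix (scan_id index, region/global columns).

    ``data`` holds one row per scan; columns in ``global_labels`` are
    whole-brain summaries, everything else is treated as an atlas parcel.
    """

    data: pd.DataFrame
    measure_kind: str = "volume"  # "volume" (mm^3) or "thickness" (mm)
    atlas: str = "Desikan-Killiany"
    global_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.measure_kind not in ("volume", "thickness"):
            raise ValidationError(f"unknown measure_kind {self.measure_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate scan_id values: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("measure table contains non-finite values")
        if not np.all(values > 0):
            raise ValidationError("measure table contains non-positive values")

    @property
    def scan_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def region_labels(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.global_labels]


def read_measure_table(path: str | Path, measure_kind: str = "volume") -> MeasureTable:
    """Read a FreeSurfer-style tab-separated stats table.

    The first column holds scan identifiers; the header row holds region
    labels. Recognized whole-brain columns (``CortexVol`` etc.) are kept under
    ``global_labels`` rather than the parcel set.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file or missing header") from exc
    if raw.shape[1] < 2:
        raise FormatError(
            f"{path}: expected a tab-separated table with a scan-id column "
            f"and at least one measure column, found {raw.shape[1]} column(s)"
        )
    id_col = raw.columns[0]
    scan_ids = raw[id_col].astype(str)
    if scan_ids.duplicated().any():
        dups = scan_ids[scan_ids.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate scan_id values: {dups}")

    data = raw.drop(columns=[id_col])
    parsed = {}
    for col in data.columns:
        numeric = pd.to_numeric(data[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric cell {data[col].iloc[row]!r} "
                f"at scan {scan_ids.iloc[row]!r}, column {col!r}"
            )
        parsed[col] = numeric.astype(float)
    frame = pd.DataFrame(parsed)
    frame.index = pd.Index(scan_ids, name="scan_id")
    globals_present = tuple(c for c in frame.columns if c in GLOBAL_MEASURE_LABELS)
    return MeasureTable(data=frame, measure_kind=measure_kind, global_labels=globals_present)


def write_measure_table(table: MeasureTable, path: str | Path) -> Path:
    """Write a MeasureTable back to the tab-separated layout it was read from."""
    path = Path(path)
    out = table.data.copy()
    out.index.name = out.index.name or "scan_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    return path


def _years_between(later: date, earlier: date) -> float:
    return (later - earlier).days / DAYS_PER_YEAR


def _parse_bool(value, column: str, row: str):
    if pd.isna(value) or value == "":
        return None
    text = str(value).strip().lower()
    if text in ("1", "true", "t", "yes", "y"):
        return True
    if text in ("0", "false", "f", "no", "n"):
        return False
    raise ParseError(f"metadata row {row!r}: cannot parse boolean {value!r} in column {column!r}")


def read_metadata(path: str | Path) -> tuple[list[ScanMeta], list[SubjectMeta]]:
    """Read the scan/clinical metadata CSV.

    Required columns: ``subject_id``, ``scan_id``, ``field_strength_T``,
    ``TR_ms``, ``TI_ms``, plus either ``age_at_scan`` or ``scan_date``, and
    either ``age_at_event`` or (``event_date`` with a usable age anchor).
    Flags: ``vaccinated``, ``treated``, ``stable_disease`` (required),
    ``hospitalized`` (optional). Dates are ISO (YYYY-MM-DD); date differences
    are converted to decimal years with actual day counts / 365.25.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = {"subject_id", "scan_id", "field_strength_T", "TR_ms", "TI_ms"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    has = lambda c: c in frame.columns  # noqa: E731

    def _num(row, col):
        try:
            return float(row[col])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: cannot parse {row[col]!r} in column {col!r}, scan {row['scan_id']!r}"
            ) from exc

    def _date(row, col):
        try:
            return date.fromisoformat(str(row[col]))
        except ValueError as exc:
            raise ParseError(
                f"{path}: cannot parse date {row[col]!r} in column {col!r}, scan {row['scan_id']!r}"
            ) from exc

    scans: list[ScanMeta] = []
    subject_rows: dict[str, dict] = {}
    for _, row in frame.iterrows():
        subject_id = str(row["subject_id"])
        scan_id = str(row["scan_id"])

        # subject-level fields: event age (possibly via dates) and flags
        age_at_event = None
        if has("age_at_event") and not pd.isna(row.get("age_at_event")):
            age_at_event = _num(row, "age_at_event")
        elif has("event_date") and has("birth_date") and not pd.isna(row.get("event_date")):
            age_at_event = _years_between(_date(row, "event_date"), _date(row, "birth_date"))

        # scan age, directly or via dates anchored on birth or event
        if has("age_at_scan") and not pd.isna(row.get("age_at_scan")):
            age_at_scan = _num(row, "age_at_scan")
        elif has("scan_date") and not pd.isna(row.get("scan_date")):
            scan_date = _date(row, "scan_date")
            if has("birth_date") and not pd.isna(row.get("birth_date")):
                age_at_scan = _years_between(scan_date, _date(row, "birth_date"))
            elif has("event_date") and age_at_event is not None:
                age_at_scan = age_at_event + _years_between(scan_date, _date(row, "event_date"))
            else:
                raise ValidationError(
                    f"{path}: scan {scan_id!r} has scan_date but no birth_date or "
                    "event_date+age_at_event to anchor the age"
                )
        else:
            raise ValidationError(f"{path}: scan {scan_id!r} has neither age_at_scan nor scan_date")
        if age_at_scan <= 0:
            raise ValidationError(f"{path}: scan {scan_id!r} has non-positive derived age {age_at_scan}")

        scans.append(
            ScanMeta(
                scan_id=scan_id,
                subject_id=subject_id,
                age_at_scan=age_at_scan,
                field_strength=_num(row, "field_strength_T"),
                repetition_time=_num(row, "TR_ms"),
                inversion_time=_num(row, "TI_ms"),
                scanner_model=(str(row["scanner_model"]) if has("scanner_model") and not pd.isna(row.get("scanner_model")) else None),
            )
        )

        if age_at_event is None:
            raise ValidationError(f"{path}: subject {subject_id!r} has no age_at_event (or event/birth dates)")
        info = {
            "age_at_event": age_at_event,
            "vaccinated": _parse_bool(row.get("vaccinated"), "vaccinated", scan_id),
            "treated": _parse_bool(row.get("treated"), "treated", scan_id),
            "stable_disease": _parse_bool(row.get("stable_disease"), "stable_disease", scan_id),
            "hospitalized": _parse_bool(row.get("hospitalized"), "hospitalized", scan_id) if has("hospitalized") else None,
        }
        for key in ("vaccinated", "treated", "stable_disease"):
            if info[key] is None:
                raise ValidationError(f"{path}: subject {subject_id!r} missing flag {key!r} on scan {scan_id!r}")
        previous = subject_rows.get(subject_id)
        if previous is None:
            subject_rows[subject_id] = info
        else:
            for key, val in info.items():
                if key == "age_at_event":
                    consistent = abs(previous[key] - val) < 1e-9
                else:
                    consistent = previous[key] == val
                if not consistent:
                    raise ValidationError(
                        f"{path}: subject {subject_id!r} has inconsistent {key!r} across scan rows"
                    )

    subjects = [
        SubjectMeta(
            subject_id=sid,
            age_at_event=info["age_at_event"],
            vaccinated=info["vaccinated"],
            treated=info["treated"],
            stable_disease=info["stable_disease"],
            hospitalized=info["hospitalized"],
        )
        for sid, info in subject_rows.items()
    ]
    return scans, subjects


def assign_phase(age_at_scan: float, age_at_event: float) -> str:
    """Phase label for one scan: ``post`` from the event age onward, else ``pre``.

    A scan acquired exactly at the event age counts as post — the infection
    has occurred.
    """
    return "post" if age_at_scan >= age_at_event else "pre"


def build_cohort(
    measures: MeasureTable,
    scans: Sequence[ScanMeta],
    subjects: Sequence[SubjectMeta],
    regions: Iterable[str] | None = None,
    normalize_by: str | None = None,
    provenance: Sequence[str] = (),
) -> pd.DataFrame:
    """Join measures and metadata into the canonical long-format cohort table.

    Parameters
    ----------
    regions
        Measure columns to keep (default: all, parcels plus globals).
    normalize_by
        Optional global column (e.g. ``EstimatedTotalIntraCranialVol``) to
        divide every measure by — head-size normalization. Off by default:
        raw mm^3 are analyzed.

    Raises :class:`ReconciliationError` when the scan-id sets of the two
    sources disagree, listing the offending ids.
    """
    scan_by_id = {s.scan_id: s for s in scans}
    subject_by_id = {s.subject_id: s for s in subjects}
    measure_ids = set(measures.scan_ids)
    meta_ids = set(scan_by_id)
    if measure_ids != meta_ids:
        only_measures = sorted(measure_ids - meta_ids)
        only_meta = sorted(meta_ids - measure_ids)
        raise ReconciliationError(
            f"scan sets disagree: only in measures {only_measures}, only in metadata {only_meta}"
        )
    missing_subjects = sorted({s.subject_id for s in scans} - set(subject_by_id))
    if missing_subjects:
        raise ValidationError(f"scans reference unknown subjects: {missing_subjects}")

    data = measures.data
    if regions is not None:
        regions = list(regions)
        absent = [r for r in regions if r not in data.columns]
        if absent:
            raise ValidationError(f"requested measure columns not in table: {absent}")
        data = data[regions]
    if normalize_by is not None:
        if normalize_by not in measures.data.columns:
            raise ValidationError(f"normalization column {normalize_by!r} not in measure table")
        denom = measures.data[normalize_by]
        data = data.drop(columns=[normalize_by], errors="ignore").div(denom, axis=0)
        logger.info("normalized measures by %s", normalize_by)

    long = data.reset_index().melt(id_vars="scan_id", var_name="region_label", value_name="value")
    meta_frame = pd.DataFrame(
        {
            "scan_id": [s.scan_id for s in scans],
            "subject_id": [s.subject_id for s in scans],
            "age_at_scan": [s.age_at_scan for s in scans],
            "field_strength": [s.field_strength for s in scans],
            "repetition_time": [s.repetition_time for s in scans],
            "inversion_time": [s.inversion_time for s in scans],
        }
    )
    meta_frame["phase"] = [
        assign_phase(s.age_at_scan, subject_by_id[s.subject_id].age_at_event) for s in scans
    ]
    cohort = long.merge(meta_frame, on="scan_id", how="left")[COHORT_COLUMNS]
    cohort = cohort.sort_values(["subject_id", "age_at_scan", "scan_id", "region_label"]).reset_index(drop=True)
    cohort.attrs["provenance"] = list(provenance)
    validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort-table invariants; raise :class:`ValidationError` if broken."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if cohort.duplicated(subset=["scan_id", "region_label"]).any():
        raise ValidationError("cohort table has duplicate (scan_id, region_label) pairs")
    if not cohort["phase"].isin(["pre", "post"]).all():
        raise ValidationError("cohort phase column must be 'pre' or 'post'")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Write the long-format cohort table as CSV for audit."""
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table previously written by :func:`write_cohort`."""
    cohort = pd.read_csv(path, dtype={"subject_id": str, "scan_id": str, "region_label": str})
    validate_cohort(cohort)
    return cohort
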