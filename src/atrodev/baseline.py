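"""Per-subject, per-region age-linear baselines and standardized residuals.

This is the computational core of the method. For each eligible scan group
and each region, an ordinary least-squares line

    V(a) = b0 + b1 * a

is fitted to the pre-event volumes with age ``a`` (years) as the only
explanatory variable; ``b1`` is the subject's intraindividual atrophy rate
for that region. Every scan in the group — pre and post — is then expressed
as a standardized residual

    z = (V - (b0 + b1 * a)) / s,    s = sqrt(RSS / (n_pre - 2)),

so deviations are dimensionless and comparable across subjects and regions.
Pre-event z have mean exactly zero within each fit; post-event z measure how
far a scan falls from the subject's own extrapolated trajectory in units of
that subject's baseline scatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .eligibility import EligibleGroup, MatchKey
from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    DegenerateStandardizationError,
    EligibilityViolationError,
    ValidationError,
)
from .io_volumetry import GLOBAL_MEASURE_LABELS

logger = logging.getLogger(__name__)

#: Label under which the global cortical gray-matter measure is analyzed.
GLOBAL_REGION_LABEL = "global_gm"

#: Relative tolerance below which a residual SD counts as exactly zero
#: (noise-free data leaves float-rounding crumbs of order 1e-13 * scale).
_S_ZERO_RTOL = 1e-9
_RAW_ZERO_RTOL = 1e-8

RESIDUAL_COLUMNS = [
    "subject_id",
    "scan_id",
    "region_label",
    "phase",
    "age_at_scan",
    "group_key",
    "predicted",
    "raw_residual",
    "z",
]


@dataclass(frozen=True)
class RegionSeries:
    """One (subject, acquisition key, region) trajectory: the unit a fit sees."""

    subject_id: str
    key: MatchKey
    region_label: str
    scan_ids: tuple[str, ...]
    ages: tuple[float, ...]  # years
    values: tuple[float, ...]  # mm^3 (or mm for thickness)
    phases: tuple[str, ...]  # "pre" / "post"

    def __post_init__(self) -> None:
        n = len(self.scan_ids)
        if not (len(self.ages) == len(self.values) == len(self.phases) == n):
            raise ValidationError("RegionSeries fields must have equal length")
        if any(v <= 0 for v in self.values):
            raise ValidationError(
                f"{self.subject_id}/{self.region_label}: non-positive measure value"
            )

    def pre_mask(self) -> np.ndarray:
        return np.asarray([p == "pre" for p in self.phases])


@dataclass(frozen=True)
class BaselineFit:
    """OLS line through a subject's pre-event points for one region."""

    subject_id: str
    key: MatchKey
    region_label: str
    slope: float  # mm^3 / year (atrophy rate; negative when shrinking)
    intercept: float  # mm^3
    residual_sd: float  # mm^3
    n_pre: int

    @property
    def dof(self) -> int:
        return self.n_pre - 2

    def predict(self, age: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def aggregate_regions(
    cohort: pd.DataFrame,
    mode: str = "bilateral_sum",
    regions: Sequence[str] | None = None,
    include_global: bool = True,
    global_source: str | None = None,
) -> pd.DataFrame:
    """Combine hemispheric parcels into analysis regions.

    ``bilateral_sum`` adds ``lh_X`` and ``rh_X`` into one measure labelled
    ``X`` (a bilateral structure such as "the parahippocampal gyri" is one
    measure); ``per_hemisphere`` keeps labels as they are. Labels without a
    hemisphere prefix pass through unchanged in both modes.

    The global cortical gray-matter measure is appended under
    :data:`GLOBAL_REGION_LABEL` when ``include_global`` — taken from a
    recognized whole-brain column (``CortexVol``, ``TotalGrayVol``, ... or
    ``global_source`` when given) if present, else computed as the sum of all
    cortical parcels; the choice is logged.
    """
    if mode not in ("bilateral_sum", "per_hemisphere"):
        raise ConfigurationError(f"unknown aggregation mode {mode!r}")

    labels = set(cohort["region_label"].unique())
    parcels = {
        lab for lab in labels if lab not in GLOBAL_MEASURE_LABELS and lab != GLOBAL_REGION_LABEL
    }
    paired = sorted(
        {lab[3:] for lab in parcels if lab.startswith("lh_") and ("rh_" + lab[3:]) in parcels}
    )
    unilateral = sorted(
        lab for lab in parcels
        if not (lab.startswith(("lh_", "rh_")) and lab.removeprefix("lh_").removeprefix("rh_") in paired)
    )

    pieces: list[pd.DataFrame] = []
    base_cols = [c for c in cohort.columns if c not in ("region_label", "value")]

    if mode == "per_hemisphere":
        wanted = regions
        if wanted is not None:
            absent = [r for r in wanted if r not in parcels]
            if absent:
                raise ConfigurationError(f"requested region(s) not in cohort: {absent}")
            selected = cohort[cohort["region_label"].isin(wanted)]
        else:
            selected = cohort[cohort["region_label"].isin(parcels)]
        pieces.append(selected.copy())
    else:
        wanted = list(regions) if regions is not None else paired + unilateral
        for region in wanted:
            lh, rh = f"lh_{region}", f"rh_{region}"
            if lh in parcels and rh in parcels:
                left = cohort[cohort["region_label"] == lh].set_index("scan_id")
                right = cohort[cohort["region_label"] == rh].set_index("scan_id")
                merged = left.copy()
                merged["value"] = left["value"] + right.loc[left.index, "value"]
                merged["region_label"] = region
                pieces.append(merged.reset_index())
            elif region in parcels:
                # unknown/unpaired label passes through as a unilateral region
                pieces.append(cohort[cohort["region_label"] == region].copy())
            else:
                raise ConfigurationError(
                    f"region {region!r}: neither a bilateral pair ({lh!r}, {rh!r}) "
                    "nor a plain label in the cohort"
                )

    if include_global:
        source = global_source
        if source is None:
            for candidate in ("CortexVol", "TotalGrayVol", GLOBAL_REGION_LABEL):
                if candidate in labels:
                    source = candidate
                    break
        if source is not None:
            if source not in labels:
                raise ConfigurationError(f"global source column {source!r} not in cohort")
            logger.info("global GM taken from column %r", source)
            glob = cohort[cohort["region_label"] == source].copy()
            glob["region_label"] = GLOBAL_REGION_LABEL
        else:
            logger.info("global GM computed as the sum of %d cortical parcels", len(parcels))
            parcel_rows = cohort[cohort["region_label"].isin(parcels)]
            summed = parcel_rows.groupby("scan_id", as_index=False)["value"].sum()
            meta = parcel_rows.drop(columns=["region_label", "value"]).drop_duplicates("scan_id")
            glob = meta.merge(summed, on="scan_id")
            glob["region_label"] = GLOBAL_REGION_LABEL
        pieces.append(glob[base_cols + ["region_label", "value"]])

    out = pd.concat([p[base_cols + ["region_label", "value"]] for p in pieces], ignore_index=True)
    out = out.sort_values(["subject_id", "age_at_scan", "scan_id", "region_label"]).reset_index(drop=True)
    out.attrs = dict(cohort.attrs)
    return out


def _ols_line(ages: np.ndarray, values: np.ndarray, context: str) -> tuple[float, float, float]:
    """Closed-form simple OLS: (slope, intercept, residual_sd with n-2 dof).

    Residual SD below 1e-9 of the value scale snaps to exactly 0 so that
    collinear (noise-free) points are recognized as such.
    """
    a_centered = ages - ages.mean()
    sxx = float(a_centered @ a_centered)
    if sxx == 0.0:
        raise DegenerateDesignError(f"{context}: all pre-event ages identical")
    slope = float(a_centered @ (values - values.mean()) / sxx)
    intercept = float(values.mean() - slope * ages.mean())
    resid = values - (intercept + slope * ages)
    rss = float(resid @ resid)
    s = float(np.sqrt(rss / (len(ages) - 2)))
    if s < _S_ZERO_RTOL * float(np.abs(values).max()):
        s = 0.0
    return slope, intercept, s


def _standardized(
    ages: np.ndarray, values: np.ndarray, slope: float, intercept: float, s: float, context: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(predicted, raw, z) for all points of a series given its baseline line."""
    predicted = intercept + slope * ages
    raw = values - predicted
    if s == 0.0:
        scale = float(np.abs(values).max())
        if not np.all(np.abs(raw) <= _RAW_ZERO_RTOL * scale):
            worst = float(np.abs(raw).max())
            raise DegenerateStandardizationError(
                f"{context}: residual SD is 0 but a raw residual of {worst:g} exists; z is undefined"
            )
        raw = np.zeros_like(raw)
        z = np.zeros_like(raw)
    else:
        z = raw / s
    return predicted, raw, z


def fit_baseline(series: RegionSeries, min_pre: int = 3) -> BaselineFit:
    """Closed-form OLS fit of volume on age over the pre-event points.

    slope = sum((a - abar)(V - Vbar)) / sum((a - abar)^2); intercept makes the
    line pass through the mean point; residual SD uses n_pre - 2 degrees of
    freedom. Exactly collinear points give residual SD 0.
    """
    pre = series.pre_mask()
    n_pre = int(pre.sum())
    if n_pre < min_pre:
        raise EligibilityViolationError(
            f"{series.subject_id}/{series.region_label}: {n_pre} pre-event scans, need >= {min_pre}"
        )
    ages = np.asarray(series.ages, dtype=float)[pre]
    values = np.asarray(series.values, dtype=float)[pre]
    slope, intercept, s = _ols_line(ages, values, f"{series.subject_id}/{series.region_label}")
    return BaselineFit(
        subject_id=series.subject_id,
        key=series.key,
        region_label=series.region_label,
        slope=slope,
        intercept=intercept,
        residual_sd=s,
        n_pre=n_pre,
    )


def standardize(fit: BaselineFit, series: RegionSeries) -> pd.DataFrame:
    """Standardized residuals z = (V - prediction) / s for every scan in the series.

    Pre- and post-event scans are standardized by the same baseline ``s`` so
    both phases live on one scale. When ``s`` is exactly zero (noise-free
    baseline) residuals that are themselves zero give z = 0; a nonzero
    residual with ``s = 0`` is undefined and raises.
    """
    if (fit.subject_id, fit.key, fit.region_label) != (series.subject_id, series.key, series.region_label):
        raise ValidationError("fit and series refer to different (subject, key, region)")
    ages = np.asarray(series.ages, dtype=float)
    values = np.asarray(series.values, dtype=float)
    predicted, raw, z = _standardized(
        ages, values, fit.slope, fit.intercept, fit.residual_sd,
        f"{series.subject_id}/{series.region_label}",
    )
    return pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "scan_id": list(series.scan_ids),
            "region_label": series.region_label,
            "phase": list(series.phases),
            "age_at_scan": ages,
            "group_key": str(series.key),
            "predicted": predicted,
            "raw_residual": raw,
            "z": z,
        }
    )[RESIDUAL_COLUMNS]


def series_from_cohort(cohort: pd.DataFrame, group: EligibleGroup, region_label: str) -> RegionSeries:
    """Extract the (subject, key, region) trajectory for one eligible group."""
    rows = cohort[
        (cohort["scan_id"].isin(group.scan_ids)) & (cohort["region_label"] == region_label)
    ].sort_values(["age_at_scan", "scan_id"])
    if rows.empty:
        raise ConfigurationError(
            f"region {region_label!r} absent from cohort for subject {group.subject_id!r}"
        )
    return RegionSeries(
        subject_id=group.subject_id,
        key=group.key,
        region_label=region_label,
        scan_ids=tuple(rows["scan_id"]),
        ages=tuple(float(a) for a in rows["age_at_scan"]),
        values=tuple(float(v) for v in rows["value"]),
        phases=tuple(rows["phase"]),
    )


def fit_groups(
    cohort: pd.DataFrame,
    groups: Sequence[EligibleGroup],
    regions: Sequence[str] | None = None,
    min_pre: int = 3,
) -> tuple[list[BaselineFit], pd.DataFrame]:
    """Fit every (eligible group, region) baseline and pool all residuals.

    Returns the fits and one long ResidualTable with columns
    ``subject_id, scan_id, region_label, phase, age_at_scan, group_key,
    predicted, raw_residual, z``.
    """
    if regions is None:
        regions = sorted(cohort["region_label"].unique())

    # one pivot + numpy views instead of per-(group, region) DataFrame filters:
    # the Monte-Carlo evaluation runs this thousands of times
    wide = cohort.pivot(index="scan_id", columns="region_label", values="value")
    absent = [r for r in regions if r not in wide.columns]
    if absent:
        raise ConfigurationError(f"region(s) absent from cohort: {absent}")
    scan_pos = {scan_id: i for i, scan_id in enumerate(wide.index)}
    value_matrix = wide.to_numpy(dtype=float)
    region_col = {r: int(wide.columns.get_loc(r)) for r in regions}
    scan_meta = cohort.drop_duplicates("scan_id").set_index("scan_id")
    age_by_pos = scan_meta["age_at_scan"].reindex(wide.index).to_numpy(dtype=float)

    fits: list[BaselineFit] = []
    out: dict[str, list] = {c: [] for c in RESIDUAL_COLUMNS}
    for group in groups:
        n_pre = len(group.pre_scans)
        if n_pre < min_pre:
            raise EligibilityViolationError(
                f"{group.subject_id}/{group.key}: {n_pre} pre-event scans, need >= {min_pre}"
            )
        idx = np.fromiter((scan_pos[s] for s in group.scan_ids), dtype=int)
        ages = age_by_pos[idx]
        phases = ["pre"] * n_pre + ["post"] * len(group.post_scans)
        key_str = str(group.key)
        for region in regions:
            context = f"{group.subject_id}/{region}"
            values = value_matrix[idx, region_col[region]]
            if np.any(~np.isfinite(values)):
                raise ConfigurationError(f"{context}: missing values for scans in group")
            slope, intercept, s = _ols_line(ages[:n_pre], values[:n_pre], context)
            fits.append(
                BaselineFit(
                    subject_id=group.subject_id,
                    key=group.key,
                    region_label=region,
                    slope=slope,
                    intercept=intercept,
                    residual_sd=s,
                    n_pre=n_pre,
                )
            )
            predicted, raw, z = _standardized(ages, values, slope, intercept, s, context)
            n = len(idx)
            out["subject_id"].extend([group.subject_id] * n)
            out["scan_id"].extend(group.scan_ids)
            out["region_label"].extend([region] * n)
            out["phase"].extend(phases)
            out["age_at_scan"].append(ages)
            out["group_key"].extend([key_str] * n)
            out["predicted"].append(predicted)
            out["raw_residual"].append(raw)
            out["z"].append(z)

    if not fits:
        return [], pd.DataFrame(columns=RESIDUAL_COLUMNS)
    residuals = pd.DataFrame(
        {
            "subject_id": out["subject_id"],
            "scan_id": out["scan_id"],
            "region_label": out["region_label"],
            "phase": out["phase"],
            "age_at_scan": np.concatenate(out["age_at_scan"]),
            "group_key": out["group_key"],
            "predicted": np.concatenate(out["predicted"]),
            "raw_residual": np.concatenate(out["raw_residual"]),
            "z": np.concatenate(out["z"]),
        }
    )
    return fits, residuals


def fits_to_frame(fits: Sequence[BaselineFit]) -> pd.DataFrame:
    """Audit table of baseline fits (one row per subject x key x region)."""
    return pd.DataFrame(
        {
            "subject_id": [f.subject_id for f in fits],
            "group_key": [str(f.key) for f in fits],
            "region_label": [f.region_label for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "residual_sd": [f.residual_sd for f in fits],
            "n_pre": [f.n_pre for f in fits],
            "dof": [f.dof for f in fits],
        }
    )
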