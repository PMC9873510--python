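"""Scan matching and cohort inclusion rules.

A subject enters the analysis only with at least ``min_pre`` pre-event scans
acquired under the same protocol (field strength, repetition time, inversion
time) as at least one post-event scan. Scans are grouped per subject by this
acquisition key; a subject running on two protocols can contribute one group
per qualifying key, each with its own baseline fit so protocol offsets are
absorbed within the group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_volumetry import SubjectMeta

SUBGROUPS = ("all", "untreated_unvaccinated", "treated_or_vaccinated")


@dataclass(frozen=True, order=True)
class MatchKey:
    """Acquisition key on which scans must agree to be comparable.

    TR and TI are rounded to ``tr_tol``/``ti_tol`` ms and field strength to
    ``fs_tol`` tesla before comparison: DICOM headers carry float jitter, and
    exact float equality would spuriously split groups.
    """

    field_strength: float
    repetition_time: float
    inversion_time: float

    @classmethod
    def from_raw(
        cls,
        field_strength: float,
        repetition_time: float,
        inversion_time: float,
        fs_tol: float = 0.1,
        tr_tol: float = 1.0,
        ti_tol: float = 1.0,
    ) -> "MatchKey":
        if min(field_strength, repetition_time, inversion_time) <= 0:
            raise ValidationError("MatchKey components must be positive")
        snap = lambda x, tol: round(round(x / tol) * tol, 6)  # noqa: E731
        return cls(
            field_strength=snap(field_strength, fs_tol),
            repetition_time=snap(repetition_time, tr_tol),
            inversion_time=snap(inversion_time, ti_tol),
        )

    def __str__(self) -> str:
        return f"{self.field_strength:g}T/TR{self.repetition_time:g}/TI{self.inversion_time:g}"


@dataclass(frozen=True)
class EligibleGroup:
    """One subject's acquisition-matched scan set: >= min_pre pre, >= 1 post."""

    subject_id: str
    key: MatchKey
    pre_scans: tuple[str, ...]  # ordered by age ascending
    post_scans: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.pre_scans) & set(self.post_scans):
            raise ValidationError(f"group {self.subject_id}/{self.key}: pre/post scans overlap")

    @property
    def scan_ids(self) -> tuple[str, ...]:
        return self.pre_scans + self.post_scans


@dataclass
class EligibilityReport:
    """Stage-by-stage exclusion accounting, CONSORT-flow style."""

    n_subjects_in: int = 0
    n_no_post: int = 0
    n_insufficient_pre: int = 0
    n_unstable: int = 0
    n_subgroup_excluded: int = 0
    n_eligible: int = 0
    reasons: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.n_no_post
            + self.n_insufficient_pre
            + self.n_unstable
            + self.n_subgroup_excluded
            + self.n_eligible
        )
        if total != self.n_subjects_in:
            raise ValidationError(
                f"eligibility report inconsistent: {self.n_subjects_in} in, stages sum to {total}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"subjects assessed            {self.n_subjects_in}",
            f"  - no post-event scan       {self.n_no_post}",
            f"  - < min matched pre scans  {self.n_insufficient_pre}",
            f"  - unstable disease course  {self.n_unstable}",
            f"  - outside subgroup         {self.n_subgroup_excluded}",
            f"subjects eligible            {self.n_eligible}",
        ]
        for subject, reason in sorted(self.reasons.items()):
            lines.append(f"  {subject}: {reason}")
        return "\n".join(lines)


def _scan_level(cohort: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "subject_id",
        "scan_id",
        "age_at_scan",
        "field_strength",
        "repetition_time",
        "inversion_time",
        "phase",
    ]
    return cohort[cols].drop_duplicates(subset="scan_id")


def match_groups(
    cohort: pd.DataFrame,
    min_pre: int = 3,
    fs_tol: float = 0.1,
    tr_tol: float = 1.0,
    ti_tol: float = 1.0,
) -> list[EligibleGroup]:
    """Group each subject's scans by acquisition key and keep qualifying groups.

    A group qualifies with >= ``min_pre`` pre-event scans and >= 1 post-event
    scan on the same key. An empty result is valid. Pre scans are ordered by
    age ascending.
    """
    scans = _scan_level(cohort)
    order = np.lexsort(
        (scans["scan_id"].to_numpy(), scans["age_at_scan"].to_numpy(), scans["subject_id"].to_numpy())
    )
    subject = scans["subject_id"].to_numpy()[order]
    scan_id = scans["scan_id"].to_numpy()[order]
    phase = scans["phase"].to_numpy()[order]
    keys = [
        MatchKey.from_raw(fs, tr, ti, fs_tol=fs_tol, tr_tol=tr_tol, ti_tol=ti_tol)
        for fs, tr, ti in zip(
            scans["field_strength"].to_numpy()[order],
            scans["repetition_time"].to_numpy()[order],
            scans["inversion_time"].to_numpy()[order],
        )
    ]
    buckets: dict[tuple[str, MatchKey], tuple[list[str], list[str]]] = {}
    for sub, key, sid, ph in zip(subject, keys, scan_id, phase):
        pre, post = buckets.setdefault((sub, key), ([], []))
        (pre if ph == "pre" else post).append(sid)
    groups: list[EligibleGroup] = []
    for (sub, key), (pre, post) in sorted(buckets.items()):
        if len(pre) >= min_pre and len(post) >= 1:
            groups.append(
                EligibleGroup(subject_id=sub, key=key, pre_scans=tuple(pre), post_scans=tuple(post))
            )
    return groups


def filter_subjects(
    groups: Sequence[EligibleGroup],
    subjects: Sequence[SubjectMeta],
    require_stable: bool = True,
    subgroup: str = "all",
    report: EligibilityReport | None = None,
) -> tuple[list[EligibleGroup], EligibilityReport]:
    """Restrict matched groups by disease stability and treatment/vaccination subgroup.

    ``untreated_unvaccinated`` keeps subjects with neither vaccination nor
    antiviral treatment; ``treated_or_vaccinated`` keeps the complement. Each
    exclusion is recorded in the report with its reason.
    """
    if subgroup not in SUBGROUPS:
        raise ConfigurationError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    meta = {s.subject_id: s for s in subjects}
    missing = sorted({g.subject_id for g in groups} - set(meta))
    if missing:
        raise ValidationError(f"groups reference subjects without metadata: {missing}")

    if report is None:
        report = EligibilityReport(n_subjects_in=len({g.subject_id for g in groups}))

    kept: list[EligibleGroup] = []
    decided: set[str] = set()
    for group in groups:
        subject = meta[group.subject_id]
        if require_stable and not subject.stable_disease:
            if group.subject_id not in decided:
                report.n_unstable += 1
                report.reasons[group.subject_id] = "unstable disease course"
                decided.add(group.subject_id)
            continue
        in_subgroup = (
            subgroup == "all"
            or (subgroup == "untreated_unvaccinated" and not subject.vaccinated and not subject.treated)
            or (subgroup == "treated_or_vaccinated" and (subject.vaccinated or subject.treated))
        )
        if not in_subgroup:
            if group.subject_id not in decided:
                report.n_subgroup_excluded += 1
                report.reasons[group.subject_id] = f"outside subgroup {subgroup!r}"
                decided.add(group.subject_id)
            continue
        kept.append(group)
    report.n_eligible = len({g.subject_id for g in kept})
    report.check()
    return kept, report


def run_eligibility(
    cohort: pd.DataFrame,
    subjects: Sequence[SubjectMeta],
    min_pre: int = 3,
    require_stable: bool = True,
    subgroup: str = "all",
    fs_tol: float = 0.1,
    tr_tol: float = 1.0,
    ti_tol: float = 1.0,
) -> tuple[list[EligibleGroup], EligibilityReport]:
    """Full inclusion flow: match scans by key, then filter subjects.

    The report accounts for every subject in the cohort: no post scan at all,
    a post scan but no acquisition key with >= ``min_pre`` matched pre scans,
    unstable disease (when required), outside the requested subgroup, or
    eligible.
    """
    scans = _scan_level(cohort)
    all_subjects = set(scans["subject_id"])
    groups = match_groups(cohort, min_pre=min_pre, fs_tol=fs_tol, tr_tol=tr_tol, ti_tol=ti_tol)
    matched_subjects = {g.subject_id for g in groups}

    report = EligibilityReport(n_subjects_in=len(all_subjects))
    has_post = set(scans.loc[scans["phase"] == "post", "subject_id"])
    for subject_id in sorted(all_subjects - matched_subjects):
        if subject_id not in has_post:
            report.n_no_post += 1
            report.reasons[subject_id] = "no post-event scan"
        else:
            report.n_insufficient_pre += 1
            report.reasons[subject_id] = f"no acquisition key with >= {min_pre} matched pre scans"
    return filter_subjects(groups, subjects, require_stable=require_stable, subgroup=subgroup, report=report)
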