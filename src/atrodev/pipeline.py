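"""End-to-end convenience driver: cohort table in, per-region tests out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .baseline import aggregate_regions, fit_groups, fits_to_frame
from .eligibility import EligibilityReport, run_eligibility
from .inference import AnalysisResult, run_analysis
from .io_volumetry import SubjectMeta


@dataclass
class PipelineOutput:
    """Everything one deviation analysis produces."""

    analysis: AnalysisResult
    residuals: pd.DataFrame
    fits: pd.DataFrame
    report: EligibilityReport


def deviation_analysis(
    cohort: pd.DataFrame,
    subjects: Sequence[SubjectMeta],
    regions: Sequence[str] | None = None,
    mode: str = "bilateral_sum",
    include_global: bool = True,
    min_pre: int = 3,
    require_stable: bool = True,
    subgroup: str = "all",
    pooling: str = "all_scans",
    variant: str = "welch",
    adjust: str = "none",
) -> PipelineOutput:
    """Aggregate regions, select eligible scan groups, fit baselines, test.

    This is the whole method in one call: hemispheric parcels are combined
    (``bilateral_sum`` by default, with the global GM measure appended),
    subjects are filtered by the scan-matching and stability rules, each
    eligible (subject, protocol, region) trajectory gets its age-linear
    pre-event fit, and the pooled standardized residuals are tested per
    region, post vs pre.
    """
    aggregated = aggregate_regions(cohort, mode=mode, regions=regions, include_global=include_global)
    groups, report = run_eligibility(
        aggregated, subjects, min_pre=min_pre, require_stable=require_stable, subgroup="all"
    )
    fits, residuals = fit_groups(aggregated, groups, min_pre=min_pre)
    analysis = run_analysis(
        residuals,
        subgroup=subgroup,
        adjust=adjust,
        subjects=subjects,
        pooling=pooling,
        variant=variant,
    )
    return PipelineOutput(
        analysis=analysis, residuals=residuals, fits=fits_to_frame(fits), report=report
    )
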