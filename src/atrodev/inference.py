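"""Pooling standardized residuals across subjects and testing per region.

For each region the post-event standardized residuals are compared with the
pre-event (baseline) residuals by a two-sided two-sample t test: under the
null of no event effect, post scans scatter around the subject-specific
trajectories just like pre scans do, so the two samples share location 0.
The Welch (unequal-variance) statistic is the default; a pooled-variance
variant exists for sensitivity analyses and for the single-post-scan case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .baseline import GLOBAL_REGION_LABEL
from .eligibility import SUBGROUPS
from .errors import ConfigurationError, NoPostDataError, VariantError
from .io_volumetry import SubjectMeta

POOLINGS = ("all_scans", "per_subject_mean")
VARIANTS = ("welch", "pooled")


@dataclass(frozen=True)
class RegionTestResult:
    """Outcome of the two-sample residual comparison for one region."""

    region_label: str
    n_pre: int
    n_post: int
    mean_pre_z: float
    mean_post_z: float
    t_statistic: float
    dof: float
    p_value: float
    subgroup: str = "all"
    adjusted_p: float | None = None
    no_data: bool = False


@dataclass
class AnalysisResult:
    """All per-region test results plus the configuration needed to re-run them."""

    results: list[RegionTestResult]
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "region_label": [r.region_label for r in self.results],
                "subgroup": [r.subgroup for r in self.results],
                "n_pre": [r.n_pre for r in self.results],
                "n_post": [r.n_post for r in self.results],
                "mean_pre_z": [r.mean_pre_z for r in self.results],
                "mean_post_z": [r.mean_post_z for r in self.results],
                "t_statistic": [r.t_statistic for r in self.results],
                "dof": [r.dof for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "no_data": [r.no_data for r in self.results],
            }
        )
        if any(r.adjusted_p is not None for r in self.results):
            frame["adjusted_p"] = [r.adjusted_p for r in self.results]
        return frame

    def __getitem__(self, region_label: str) -> RegionTestResult:
        for result in self.results:
            if result.region_label == region_label:
                return result
        raise KeyError(region_label)


def test_region(
    pre_z: Sequence[float],
    post_z: Sequence[float],
    variant: str = "welch",
    region_label: str = "",
    subgroup: str = "all",
) -> RegionTestResult:
    """Two-sided two-sample t test of post- vs pre-event standardized residuals.

    ``welch`` uses the unequal-variance statistic with Welch–Satterthwaite
    degrees of freedom and requires at least two observations per sample;
    ``pooled`` uses the classic pooled-variance statistic and is defined down
    to a single post observation. Both samples having zero variance and equal
    means gives t = 0, p = 1.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown test variant {variant!r}; expected one of {VARIANTS}")
    pre = np.asarray(pre_z, dtype=float)
    post = np.asarray(post_z, dtype=float)
    n1, n2 = len(pre), len(post)
    if n2 == 0:
        raise NoPostDataError(f"region {region_label!r}: no post-event residuals")
    if n1 < 2:
        raise VariantError(f"region {region_label!r}: need >= 2 pre residuals, got {n1}")
    if variant == "welch" and n2 < 2:
        raise VariantError(
            f"region {region_label!r}: Welch needs >= 2 post residuals (got {n2}); "
            "use variant='pooled'"
        )
    m1, m2 = float(pre.mean()), float(post.mean())
    v1 = float(pre.var(ddof=1))
    v2 = float(post.var(ddof=1)) if n2 >= 2 else 0.0

    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            t_stat = 0.0 if m1 == m2 else math.copysign(math.inf, m2 - m1)
            dof = float(n1 + n2 - 2)
        else:
            t_stat = (m2 - m1) / math.sqrt(se2)
            dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        dof = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
        if sp2 == 0.0:
            t_stat = 0.0 if m1 == m2 else math.copysign(math.inf, m2 - m1)
        else:
            t_stat = (m2 - m1) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))

    if math.isinf(t_stat):
        p_value = 0.0
    elif t_stat == 0.0 and v1 == 0.0 and v2 == 0.0:
        p_value = 1.0
    else:
        p_value = float(2.0 * stats.t.sf(abs(t_stat), dof))
    return RegionTestResult(
        region_label=region_label,
        n_pre=n1,
        n_post=n2,
        mean_pre_z=m1,
        mean_post_z=m2,
        t_statistic=float(t_stat),
        dof=float(dof),
        p_value=p_value,
        subgroup=subgroup,
    )


def _subgroup_subjects(subjects: Sequence[SubjectMeta] | None, subgroup: str) -> set[str] | None:
    if subgroup == "all":
        return None
    if subjects is None:
        raise ConfigurationError(f"subgroup {subgroup!r} requires subject metadata")
    if subgroup == "untreated_unvaccinated":
        return {s.subject_id for s in subjects if not s.vaccinated and not s.treated}
    if subgroup == "treated_or_vaccinated":
        return {s.subject_id for s in subjects if s.vaccinated or s.treated}
    raise ConfigurationError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")


def run_analysis(
    residuals: pd.DataFrame,
    regions: Sequence[str] | None = None,
    subgroup: str = "all",
    adjust: str = "none",
    subjects: Sequence[SubjectMeta] | None = None,
    pooling: str = "all_scans",
    variant: str = "welch",
    global_label: str = GLOBAL_REGION_LABEL,
) -> AnalysisResult:
    """Per-region deviation tests over the pooled residuals of a subgroup.

    ``pooling='all_scans'`` treats every scan's residual as one observation
    (repeated post scans of one subject enter individually);
    ``'per_subject_mean'`` first averages each subject's post residuals so
    every subject contributes one post observation. Benjamini–Hochberg
    (``adjust='bh'``) runs across the regional tests only — the global
    measure is a distinct hypothesis and stays outside the family. A region
    without post residuals in the subgroup is reported with ``no_data=True``,
    never dropped silently. Results are sorted by p value.
    """
    if adjust not in ("none", "bh"):
        raise ConfigurationError(f"unknown adjust {adjust!r}; expected 'none' or 'bh'")
    if pooling not in POOLINGS:
        raise ConfigurationError(f"unknown pooling {pooling!r}; expected one of {POOLINGS}")
    if regions is None:
        regions = sorted(residuals["region_label"].unique())
    keep = _subgroup_subjects(subjects, subgroup)
    data = residuals if keep is None else residuals[residuals["subject_id"].isin(keep)]

    results: list[RegionTestResult] = []
    for region in regions:
        rows = data[data["region_label"] == region]
        if rows.empty or (rows["phase"] == "post").sum() == 0:
            results.append(
                RegionTestResult(
                    region_label=region,
                    n_pre=int((rows["phase"] == "pre").sum()),
                    n_post=0,
                    mean_pre_z=float("nan"),
                    mean_post_z=float("nan"),
                    t_statistic=float("nan"),
                    dof=float("nan"),
                    p_value=float("nan"),
                    subgroup=subgroup,
                    no_data=True,
                )
            )
            continue
        pre_z = rows.loc[rows["phase"] == "pre", "z"].to_numpy()
        if pooling == "per_subject_mean":
            post_z = rows[rows["phase"] == "post"].groupby("subject_id")["z"].mean().to_numpy()
        else:
            post_z = rows.loc[rows["phase"] == "post", "z"].to_numpy()
        # Welch is undefined against a single post observation; the pooled
        # statistic is the only defined two-sample test there
        region_variant = "pooled" if (variant == "welch" and len(post_z) == 1) else variant
        results.append(
            test_region(pre_z, post_z, variant=region_variant, region_label=region, subgroup=subgroup)
        )

    if adjust == "bh":
        family = [r for r in results if r.region_label != global_label and not r.no_data]
        if family:
            pvals = [r.p_value for r in family]
            _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
            adj_by_region = {r.region_label: float(a) for r, a in zip(family, adjusted)}
            results = [
                RegionTestResult(**{**r.__dict__, "adjusted_p": adj_by_region.get(r.region_label)})
                for r in results
            ]

    results.sort(key=lambda r: (math.isnan(r.p_value), r.p_value, r.region_label))
    config = {
        "regions": list(regions),
        "subgroup": subgroup,
        "adjust": adjust,
        "pooling": pooling,
        "variant": variant,
        "global_label": global_label,
    }
    return AnalysisResult(results=results, config=config)


def plot_residuals(
    result: AnalysisResult,
    residuals: pd.DataFrame,
    out_dir: str | Path,
    fmt: str = "svg",
) -> list[Path]:
    """One figure per analyzed region: standardized residuals vs age, pre vs post.

    Output is deterministic for identical inputs (fixed SVG hash salt, no
    embedded timestamps), so figures can be diffed byte-for-byte.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    with plt.rc_context({"svg.hashsalt": "atrodev"}):
        for region in result.results:
            rows = residuals[residuals["region_label"] == region.region_label]
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for phase, color, marker in (("pre", "#4878a8", "o"), ("post", "#c44e52", "D")):
                sub = rows[rows["phase"] == phase]
                ax.scatter(sub["age_at_scan"], sub["z"], s=22, c=color, marker=marker, label=phase)
            ax.axhline(0.0, color="0.6", lw=0.8, zorder=0)
            title = region.region_label
            if not region.no_data and np.isfinite(region.p_value):
                title += f"  (p = {region.p_value:.3g})"
            ax.set_title(title)
            if region.no_data or (rows["phase"] == "post").sum() == 0:
                ax.annotate("no post-event scans", xy=(0.5, 0.9), xycoords="axes fraction", ha="center", color="#c44e52")
            ax.set_xlabel("age at scan (years)")
            ax.set_ylabel("standardized residual")
            ax.legend(frameon=False, loc="best")
            fig.tight_layout()
            safe = region.region_label.replace("/", "_")
            path = out_dir / f"residuals_{safe}.{fmt}"
            fig.savefig(path, metadata={"Date": None} if fmt == "svg" else None)
            plt.close(fig)
            paths.append(path)
    return paths
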