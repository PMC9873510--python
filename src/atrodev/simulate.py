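"""Synthetic longitudinal volumetry cohorts.

The generator emulates the statistical structure the deviation analysis
assumes: each subject follows a private linear age–volume trajectory per
region, scans are acquired under one of a small set of MRI protocols that
add a constant per-protocol measurement offset, every measurement carries
i.i.d. Gaussian noise, and the index event (infection) can inject a
proportional step drop and/or a post-event slope change into a chosen subset
of regions. Defaults mirror a small MS-registry cohort: 14 subjects with
3–13 pre-event and 1–3 post-event scans each (post-count mean 1.4), event
ages uniform on 17–64 years, roughly yearly pre-event scans and a first
post-event scan 0.4–10 months after the event, mixed 1.5 T / 3 T protocols
with each subject staying on one protocol.

For subject i, region r and a scan at age a the noise-free generative rule is

    V = (B_ir + beta_ir * a + offset_key) * (1 - delta * I[post & affected])
        + slope_change * (a - event_i) * I[post & affected]

with measurement noise N(0, noise_sd^2) added on top. Ground truth (the
drawn intercepts, slopes, offsets and noise-free values) is returned
separately and never feeds the analysis path.

A single master seed drives a hierarchical numpy SeedSequence scheme
(subject -> schedule / region streams), so appending a region to the
configuration does not perturb any other region's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io_volumetry import (
    MeasureTable,
    ScanMeta,
    SubjectMeta,
    build_cohort,
    write_measure_table,
)

MONTHS_PER_YEAR = 12.0
_MIN_FIRST_SCAN_AGE = 16.0  # youngest plausible first MRI; schedules are squeezed to fit


@dataclass(frozen=True)
class RegionParams:
    """Generative parameters for one measure.

    ``bilateral`` regions are emitted as ``lh_<name>`` / ``rh_<name>`` columns
    with independent per-hemisphere intercepts and slopes; otherwise a single
    column ``<name>`` is emitted (used for whole-brain summaries such as
    ``CortexVol``). Units: mm^3 and mm^3/year; ``noise_sd`` is per measurement
    (per hemisphere for bilateral regions).
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    slope_mean: float  # negative: atrophy
    slope_sd: float
    noise_sd: float
    bilateral: bool = True

    def __post_init__(self) -> None:
        if min(self.baseline_sd, self.slope_sd, self.noise_sd) < 0:
            raise ConfigurationError(f"region {self.name!r}: SDs must be >= 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError(f"region {self.name!r}: baseline_mean must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """One acquisition protocol and its additive measurement bias.

    ``offset_frac`` is a fraction of each region's baseline mean; the realized
    additive offset in mm^3 (``offset_frac * baseline_mean``) is constant per
    (protocol, region) and recorded in the ground truth.
    """

    field_strength: float  # tesla
    repetition_time: float  # ms
    inversion_time: float  # ms
    offset_frac: float = 0.0


def default_regions() -> tuple[RegionParams, ...]:
    """Default measure set: one small medial-temporal region (the affected
    candidate), one large frontal region, and global cortical gray matter."""
    return (
        RegionParams("parahippocampal", 2100.0, 250.0, -8.0, 4.0, 30.0, bilateral=True),
        RegionParams("superiorfrontal", 22000.0, 2500.0, -100.0, 40.0, 280.0, bilateral=True),
        RegionParams("CortexVol", 520000.0, 45000.0, -2600.0, 900.0, 3500.0, bilateral=False),
    )


def default_protocols() -> tuple[ProtocolSpec, ...]:
    return (
        ProtocolSpec(3.0, 2300.0, 900.0, 0.0),
        ProtocolSpec(1.5, 1900.0, 1100.0, -0.02),
    )


@dataclass
class SimConfig:
    """Full generative specification of a synthetic cohort."""

    n_subjects: int = 14
    pre_scan_range: tuple[int, int] = (3, 13)
    post_scan_range: tuple[int, int] = (1, 3)
    post_count_weights: tuple[float, ...] = (0.65, 0.30, 0.05)  # mean 1.4
    age_at_event_range: tuple[float, float] = (17.0, 64.0)
    pre_interval_months: tuple[float, float] = (6.0, 18.0)
    post_first_gap_months: tuple[float, float] = (0.4, 10.0)
    post_interval_months: tuple[float, float] = (1.0, 8.0)
    regions: tuple[RegionParams, ...] = field(default_factory=default_regions)
    protocols: tuple[ProtocolSpec, ...] = field(default_factory=default_protocols)
    protocol_weights: tuple[float, ...] = (0.7, 0.3)
    p_switch_protocol: float = 0.0  # per-scan probability of leaving the subject's protocol
    event_effect: float = 0.0  # delta: proportional post-event volume drop
    slope_change: float = 0.0  # mm^3/year added post-event in affected regions
    effect_mode: str = "multiplicative"  # or "additive": subtract event_effect mm^3
    affected_regions: tuple[str, ...] = ("parahippocampal",)
    p_vaccinated: float = 4.0 / 14.0
    p_treated: float = 4.0 / 14.0
    p_hospitalized: float = 4.0 / 14.0
    p_unstable: float = 0.0
    noise_scale: float = 1.0  # multiplies every region's noise_sd (evaluation knob)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not (0 <= self.event_effect < 1):
            raise ConfigurationError("event_effect (delta) must be in [0, 1)")
        if self.effect_mode not in ("multiplicative", "additive"):
            raise ConfigurationError(f"unknown effect_mode {self.effect_mode!r}")
        if self.pre_scan_range[0] < 1 or self.pre_scan_range[0] > self.pre_scan_range[1]:
            raise ConfigurationError("invalid pre_scan_range")
        if self.post_scan_range[0] < 1 or self.post_scan_range[0] > self.post_scan_range[1]:
            raise ConfigurationError("invalid post_scan_range")
        n_counts = self.post_scan_range[1] - self.post_scan_range[0] + 1
        if len(self.post_count_weights) != n_counts:
            raise ConfigurationError(
                f"post_count_weights needs {n_counts} entries for range {self.post_scan_range}"
            )
        if len(self.protocol_weights) != len(self.protocols):
            raise ConfigurationError("protocol_weights must match protocols")
        for rng_pair in (
            self.pre_interval_months,
            self.post_first_gap_months,
            self.post_interval_months,
        ):
            if rng_pair[0] <= 0 or rng_pair[0] > rng_pair[1]:
                raise ConfigurationError(f"infeasible scan-interval range {rng_pair}")
        if not (0 <= self.p_switch_protocol <= 1):
            raise ConfigurationError("p_switch_protocol must be in [0, 1]")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate region names")
        unknown = set(self.affected_regions) - set(names)
        if unknown:
            raise ConfigurationError(f"affected_regions not in regions: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if "regions" in raw:
            raw["regions"] = tuple(RegionParams(**r) for r in raw["regions"])
        if "protocols" in raw:
            raw["protocols"] = tuple(ProtocolSpec(**p) for p in raw["protocols"])
        for key in (
            "pre_scan_range",
            "post_scan_range",
            "post_count_weights",
            "age_at_event_range",
            "pre_interval_months",
            "post_first_gap_months",
            "post_interval_months",
            "protocol_weights",
            "affected_regions",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must not see.

    ``params``: one row per (subject, measure column) with the true intercept,
    slope and per-protocol offsets; ``noise_free``: one row per (scan, measure
    column) with the pre-noise value and the realized event effect.
    """

    params: pd.DataFrame
    noise_free: pd.DataFrame


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: pd.DataFrame
    measures: MeasureTable
    scans: list[ScanMeta]
    subjects: list[SubjectMeta]
    truth: GroundTruth
    config: SimConfig


def _columns_for(region: RegionParams) -> list[str]:
    if region.bilateral:
        return [f"lh_{region.name}", f"rh_{region.name}"]
    return [region.name]


def _subject_schedule(rng: np.random.Generator, config: SimConfig) -> dict:
    """Event age, scan ages and per-scan protocol indices for one subject."""
    event_age = float(rng.uniform(*config.age_at_event_range))
    n_pre = int(rng.integers(config.pre_scan_range[0], config.pre_scan_range[1] + 1))
    counts = np.arange(config.post_scan_range[0], config.post_scan_range[1] + 1)
    weights = np.asarray(config.post_count_weights, dtype=float)
    n_post = int(rng.choice(counts, p=weights / weights.sum()))

    pre_gaps = rng.uniform(*config.pre_interval_months, size=n_pre) / MONTHS_PER_YEAR
    # first pre scan sits one gap before the event too (the last gap is event->nothing)
    span = float(pre_gaps.sum())
    available = event_age - _MIN_FIRST_SCAN_AGE
    if span > available:  # young subject with many scans: squeeze the history to fit
        pre_gaps *= 0.95 * available / span
    pre_ages = event_age - np.cumsum(pre_gaps)[::-1]

    first_gap = rng.uniform(*config.post_first_gap_months) / MONTHS_PER_YEAR
    later_gaps = rng.uniform(*config.post_interval_months, size=n_post - 1) / MONTHS_PER_YEAR
    post_ages = event_age + np.cumsum(np.concatenate([[first_gap], later_gaps]))

    ages = np.concatenate([pre_ages, post_ages])
    base_protocol = int(rng.choice(len(config.protocols), p=np.asarray(config.protocol_weights) / sum(config.protocol_weights)))
    protocol_idx = np.full(len(ages), base_protocol)
    if config.p_switch_protocol > 0 and len(config.protocols) > 1:
        switch = rng.random(len(ages)) < config.p_switch_protocol
        others = [k for k in range(len(config.protocols)) if k != base_protocol]
        protocol_idx[switch] = rng.choice(others, size=int(switch.sum()))

    flags = {
        "vaccinated": bool(rng.random() < config.p_vaccinated),
        "treated": bool(rng.random() < config.p_treated),
        "hospitalized": bool(rng.random() < config.p_hospitalized),
        "stable_disease": not bool(rng.random() < config.p_unstable),
    }
    return {"event_age": event_age, "ages": ages, "protocol_idx": protocol_idx, "flags": flags}


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Draw one synthetic cohort and package it exactly as the I/O layer consumes it.

    Phase labels on the returned cohort table come from the pipeline's own
    phase-assignment rule applied to the generated metadata — the simulator
    only decides scan ages relative to the event.
    """
    config = config if config is not None else SimConfig()
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    config.validate()

    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)

    scan_rows: list[ScanMeta] = []
    subjects: list[SubjectMeta] = []
    measure_rows: dict[str, dict[str, float]] = {}
    truth_params: list[dict] = []
    truth_values: list[dict] = []

    for i, subject_seed in enumerate(subject_seeds):
        subject_id = f"P{i + 1:02d}"
        streams = subject_seed.spawn(1 + len(config.regions))
        schedule = _subject_schedule(np.random.default_rng(streams[0]), config)
        event_age = schedule["event_age"]
        ages = schedule["ages"]
        protocol_idx = schedule["protocol_idx"]

        subjects.append(
            SubjectMeta(
                subject_id=subject_id,
                age_at_event=event_age,
                vaccinated=schedule["flags"]["vaccinated"],
                treated=schedule["flags"]["treated"],
                hospitalized=schedule["flags"]["hospitalized"],
                stable_disease=schedule["flags"]["stable_disease"],
            )
        )
        scan_ids = [f"{subject_id}_s{k + 1:02d}" for k in range(len(ages))]
        for scan_id, age, p_idx in zip(scan_ids, ages, protocol_idx):
            protocol = config.protocols[p_idx]
            scan_rows.append(
                ScanMeta(
                    scan_id=scan_id,
                    subject_id=subject_id,
                    age_at_scan=float(age),
                    field_strength=protocol.field_strength,
                    repetition_time=protocol.repetition_time,
                    inversion_time=protocol.inversion_time,
                )
            )
            measure_rows.setdefault(scan_id, {})

        post_mask = ages >= event_age
        for region, region_stream in zip(config.regions, streams[1:]):
            rng = np.random.default_rng(region_stream)
            affected = region.name in config.affected_regions
            offsets = {
                k: p.offset_frac * region.baseline_mean for k, p in enumerate(config.protocols)
            }
            for column in _columns_for(region):
                intercept_at_event = rng.normal(region.baseline_mean, region.baseline_sd)
                slope = rng.normal(region.slope_mean, region.slope_sd)
                # parameterize the line through the event age so baseline_mean
                # is the expected volume at infection, not at age 0
                intercept = intercept_at_event - slope * event_age
                noise = rng.normal(0.0, region.noise_sd * config.noise_scale, size=len(ages))
                line = intercept + slope * ages + np.array([offsets[k] for k in protocol_idx])
                clean = line.copy()
                if affected:
                    if config.effect_mode == "multiplicative":
                        clean = np.where(post_mask, line * (1.0 - config.event_effect), line)
                    else:
                        clean = np.where(post_mask, line - config.event_effect, line)
                    clean = clean + np.where(post_mask, config.slope_change * (ages - event_age), 0.0)
                values = clean + noise
                if np.any(values <= 0):
                    raise ConfigurationError(
                        f"simulated non-positive volume in {column!r}; "
                        "noise/effect sizes are implausibly large for the baseline mean"
                    )
                for scan_id, value in zip(scan_ids, values):
                    measure_rows[scan_id][column] = float(value)
                truth_params.append(
                    {
                        "subject_id": subject_id,
                        "column": column,
                        "region": region.name,
                        "true_intercept": float(intercept),
                        "true_slope": float(slope),
                        "affected": affected,
                        "event_effect": config.event_effect if affected else 0.0,
                        "slope_change": config.slope_change if affected else 0.0,
                        **{
                            f"offset_{config.protocols[k].field_strength:g}T": float(offsets[k])
                            for k in range(len(config.protocols))
                        },
                    }
                )
                for scan_id, value in zip(scan_ids, clean):
                    truth_values.append(
                        {"subject_id": subject_id, "scan_id": scan_id, "column": column, "noise_free": float(value)}
                    )

    frame = pd.DataFrame.from_dict(measure_rows, orient="index")
    frame.index.name = "scan_id"
    globals_present = tuple(c for c in frame.columns if not c.startswith(("lh_", "rh_")))
    measures = MeasureTable(data=frame, measure_kind="volume", global_labels=globals_present)
    truth = GroundTruth(params=pd.DataFrame(truth_params), noise_free=pd.DataFrame(truth_values))
    cohort = build_cohort(measures, scan_rows, subjects, provenance=[f"simulated(seed={config.seed})"])
    return SimulatedCohort(
        cohort=cohort, measures=measures, scans=scan_rows, subjects=subjects, truth=truth, config=config
    )


def write_fixture(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as the external file pair the pipeline ingests.

    Emits ``volumes.tsv`` (FreeSurfer-style stats table), ``meta.csv``
    (scan/clinical metadata), ``ground_truth_params.csv`` /
    ``ground_truth_scans.csv`` (never read by analysis commands) and
    ``sim_config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"volumes": write_measure_table(sim.measures, out_dir / "volumes.tsv")}

    subject_by_id = {s.subject_id: s for s in sim.subjects}
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in sim.scans],
            "scan_id": [s.scan_id for s in sim.scans],
            "age_at_scan": [f"{s.age_at_scan:.6f}" for s in sim.scans],
            "field_strength_T": [f"{s.field_strength:g}" for s in sim.scans],
            "TR_ms": [f"{s.repetition_time:g}" for s in sim.scans],
            "TI_ms": [f"{s.inversion_time:g}" for s in sim.scans],
            "age_at_event": [f"{subject_by_id[s.subject_id].age_at_event:.6f}" for s in sim.scans],
            "vaccinated": [subject_by_id[s.subject_id].vaccinated for s in sim.scans],
            "treated": [subject_by_id[s.subject_id].treated for s in sim.scans],
            "hospitalized": [subject_by_id[s.subject_id].hospitalized for s in sim.scans],
            "stable_disease": [subject_by_id[s.subject_id].stable_disease for s in sim.scans],
        }
    )
    paths["meta"] = out_dir / "meta.csv"
    meta.to_csv(paths["meta"], index=False)
    paths["truth_params"] = out_dir / "ground_truth_params.csv"
    sim.truth.params.to_csv(paths["truth_params"], index=False, float_format="%.10g")
    paths["truth_scans"] = out_dir / "ground_truth_scans.csv"
    sim.truth.noise_free.to_csv(paths["truth_scans"], index=False, float_format="%.10g")
    paths["config"] = sim.config.to_yaml(out_dir / "sim_config.yaml")
    return paths
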