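"""Synthetic cohorts emulating the three-day weapons-training study.

The generator reproduces the statistical structure of the validation
study — 15 male subjects over 3 training days of 6 h each, daily
average blast overpressures, 4-50 shots per day, pre-training draws
2.1-3.16 h before training and post-training draws 0.48-2.90 h after —
and produces model-generated serum observations under multiplicative
lognormal measurement noise (mean-one, configurable CV).  Every
downstream stage (simulation, calibration, validation) can therefore
be exercised without any external data.

Daily BOPs default to 3-8 psi, bracketing the 4-psi injury threshold
from both sides so cohorts contain sub- and supra-threshold days.
Demographics are drawn independently of exposure, so regressions of
model error on age or service years have a known near-zero truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .exposure import InputError, TrainingSchedule
from .simulate import PredictionSeries, SubjectScenario, predict_serum, scenario_from_schedule


@dataclass(frozen=True)
class CohortDesign:
    """Sampling ranges defining a synthetic study cohort."""

    n_subjects: int = 15
    n_days: int = 3
    bop_range: tuple[float, float] = (3.0, 8.0)  # psi, uniform
    shots_range: tuple[int, int] = (4, 50)  # integer uniform, inclusive
    pre_offset_range: tuple[float, float] = (2.1, 3.16)  # h before training
    post_offset_range: tuple[float, float] = (0.48, 2.90)  # h after training
    age_range: tuple[int, int] = (33, 52)  # years, integer uniform
    service_range: tuple[int, int] = (8, 26)  # years, integer uniform
    noise_cv: float = 0.05  # fractional assay CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_days < 0:
            raise InputError("n_subjects and n_days must be >= 0")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        for name in ("bop_range", "pre_offset_range", "post_offset_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise InputError(f"{name} must satisfy 0 <= low < high")
        for name in ("shots_range", "age_range", "service_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise InputError(f"{name} must satisfy 0 <= low <= high")


@dataclass
class SyntheticCohort:
    """Scenarios, noise-free truth, noisy observations, and provenance."""

    design: CohortDesign
    seed: int
    scenarios: list[SubjectScenario]
    truth: dict[str, PredictionSeries]
    observations: pd.DataFrame  # subject_id, draw_label, time_h, abeta42_pg_ml
    config_hash: str

    @property
    def provenance(self) -> dict:
        return {
            "design": asdict(self.design),
            "seed": self.seed,
            "config_hash": self.config_hash,
        }


def config_hash(design: CohortDesign, config: ModelConfig) -> str:
    payload = json.dumps(
        {"design": asdict(design), "config": config.model_dump(mode="json")},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def draw_subject(
    design: CohortDesign,
    rng: np.random.Generator,
    subject_id: str,
    training_start_hour: float = 9.0,
    day_length_h: float = 24.0,
) -> SubjectScenario:
    """Draw one subject's schedule, draw offsets and demographics."""
    bops = rng.uniform(*design.bop_range, size=design.n_days)
    shots = rng.integers(design.shots_range[0], design.shots_range[1] + 1, size=design.n_days)
    pre = rng.uniform(*design.pre_offset_range, size=design.n_days)
    post = rng.uniform(*design.post_offset_range, size=design.n_days)
    age = int(rng.integers(design.age_range[0], design.age_range[1] + 1))
    service = int(rng.integers(design.service_range[0], design.service_range[1] + 1))
    schedule = TrainingSchedule(
        n_days=design.n_days,
        daily_bop=tuple(bops),
        shots_per_day=tuple(int(s) for s in shots),
        training_start_hour=training_start_hour,
        day_length=day_length_h,
    )
    return scenario_from_schedule(
        subject_id, schedule, tuple(pre), tuple(post), age=age, service_years=service
    )


def generate_cohort(
    design: CohortDesign,
    config: ModelConfig | None = None,
    seed: int | None = None,
    dense: bool = False,
) -> SyntheticCohort:
    """Draw a cohort, simulate noise-free truth, add measurement noise.

    Per subject: one average BOP and shot count per day, per-day draw
    offsets, and demographics, all from the design's uniform ranges via
    a single seeded generator.  Observations are the truth at the draw
    times multiplied by mean-one lognormal noise with CV ``noise_cv``.
    """
    config = config or ModelConfig()
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sim = config.simulation

    scenarios: list[SubjectScenario] = []
    truth: dict[str, PredictionSeries] = {}
    rows: list[dict] = []
    sigma = float(np.sqrt(np.log1p(design.noise_cv**2)))
    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        scenario = draw_subject(design, rng, sid, sim.training_start_hour, sim.day_length_h)
        series = predict_serum(scenario, config, dense=dense)
        noise = np.exp(sigma * rng.standard_normal(series.sample_times.size) - 0.5 * sigma**2)
        observed = series.sample_raw * noise
        scenarios.append(scenario)
        truth[sid] = series
        for lab, t, val in zip(series.sample_labels, series.sample_times, observed):
            rows.append(
                {"subject_id": sid, "draw_label": lab, "time_h": t, "abeta42_pg_ml": val}
            )
    obs = pd.DataFrame(rows, columns=["subject_id", "draw_label", "time_h", "abeta42_pg_ml"])
    return SyntheticCohort(design, seed, scenarios, truth, obs, config_hash(design, config))


def export_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write exposures.csv, serum.csv, truth.csv and provenance.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.csv" for name in ("exposures", "serum", "truth")}
    paths["provenance"] = directory / "provenance.json"

    exp_rows = []
    for sc in cohort.scenarios:
        sch = sc.schedule
        for day in range(sch.n_days):
            exp_rows.append(
                {
                    "subject_id": sc.subject_id,
                    "day": day + 1,
                    "avg_bop_psi": sch.daily_bop[day],
                    "shots": sch.shots_per_day[day] if sch.shots_per_day else "",
                    "training_start": sch.training_start_hour,
                    "training_hours": sch.training_duration,
                }
            )
    pd.DataFrame(
        exp_rows,
        columns=["subject_id", "day", "avg_bop_psi", "shots", "training_start", "training_hours"],
    ).to_csv(paths["exposures"], index=False)

    cohort.observations.to_csv(paths["serum"], index=False)

    truth_rows = []
    for sid, series in cohort.truth.items():
        for t, raw, norm in zip(series.times, series.serum_raw, series.serum_normalized):
            truth_rows.append(
                {"subject_id": sid, "time_h": t, "serum_pg_ml": raw, "serum_normalized": norm}
            )
    pd.DataFrame(
        truth_rows, columns=["subject_id", "time_h", "serum_pg_ml", "serum_normalized"]
    ).to_csv(paths["truth"], index=False)

    paths["provenance"].write_text(json.dumps(cohort.provenance, indent=2) + "\n")
    return paths
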