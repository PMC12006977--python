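"""Cohort-level blast-dose model with statsmodels-style fit/results.

:class:`BlastDoseModel` wraps a cohort (per-subject training schedules
and serum draws) together with a :class:`~bxk.config.ModelConfig`.
``fit()`` estimates the APP-synthesis amplification constant ``x``
(one shared value across subjects, other parameters optionally free)
by least squares on baseline-normalized serum concentrations, and
returns a :class:`CalibrationResults` carrying estimates, residuals,
and a ``summary()`` table.

Because the PBPK subsystem is linear in concentrations, the damage
states do not depend on ``x``, and the normalization baseline precedes
the first blast, the predicted normalized serum is exactly affine in
``x``:  ``pred(t; x) = 1 + x * u(t)`` with a subject-specific profile
``u`` obtainable from a single simulation.  When ``x`` is the only
free parameter the fit solves this linear least-squares problem in
closed form; otherwise a seeded multistart bounded optimizer is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import CalibrationConfig, ModelConfig
from .exposure import InputError
from .simulate import PredictionSeries, SubjectScenario, predict_serum
from .stats import ValidationTable, build_validation_table, validation_report

logger = logging.getLogger(__name__)

# the calibration spec is the calibration section of the config
CalibrationSpec = CalibrationConfig


class NonIdentifiableError(RuntimeError):
    """The requested parameter leaves the objective flat (no blast signal)."""


def _set_param(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a config copy with one (possibly dotted) parameter replaced."""
    if name == "x":
        name = "pbpk.x"
    if "." not in name:
        raise InputError(f"unknown calibration parameter {name!r}")
    section, attr = name.split(".", 1)
    group = getattr(config, section, None)
    if group is None or not hasattr(group, attr):
        raise InputError(f"unknown calibration parameter {name!r}")
    return config.model_copy(
        update={section: group.model_copy(update={attr: value})}, deep=True
    )


class BlastDoseModel:
    """Blast-dose biomarker-kinetics model for a cohort of subjects.

    Parameters
    ----------
    scenarios:
        One :class:`SubjectScenario` per subject.
    observations:
        Mapping ``subject_id -> {draw_label -> serum pg/mL}`` (raw
        concentrations; normalization to each subject's first draw is
        applied internally).
    config:
        Full model configuration; defaults are used when omitted.
    """

    def __init__(
        self,
        scenarios: list[SubjectScenario],
        observations: dict[str, dict[str, float]],
        config: ModelConfig | None = None,
    ) -> None:
        if not scenarios:
            raise InputError("model needs at least one subject")
        self.scenarios = list(scenarios)
        self.config = config or ModelConfig()
        self.observations_raw = observations
        self.observations = {}
        for sc in self.scenarios:
            if sc.subject_id not in observations:
                raise InputError(f"no serum draws for subject {sc.subject_id!r}")
            obs = observations[sc.subject_id]
            first = sc.sample_labels[0]
            if first not in obs:
                raise InputError(
                    f"subject {sc.subject_id!r} is missing its baseline draw {first!r}"
                )
            base = obs[first]
            if base <= 0:
                raise InputError(f"non-positive baseline draw for {sc.subject_id!r}")
            self.observations[sc.subject_id] = {k: v / base for k, v in obs.items()}

    # -- constructors --------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort, config: ModelConfig | None = None) -> "BlastDoseModel":
        """Build from a :class:`~bxk.synthetic.SyntheticCohort`."""
        obs: dict[str, dict[str, float]] = {}
        for row in cohort.observations.itertuples():
            obs.setdefault(row.subject_id, {})[row.draw_label] = row.abeta42_pg_ml
        return cls(cohort.scenarios, obs, config)

    @classmethod
    def from_csv(
        cls, exposures_csv, serum_csv, config: ModelConfig | None = None
    ) -> "BlastDoseModel":
        """Build from exposure and serum CSV files (see :mod:`bxk.dataio`)."""
        from .dataio import load_cohort_tables

        scenarios, obs = load_cohort_tables(exposures_csv, serum_csv, config or ModelConfig())
        return cls(scenarios, obs, config)

    # -- prediction ----------------------------------------------------

    def predict(
        self, config: ModelConfig | None = None, dense: bool = True
    ) -> dict[str, PredictionSeries]:
        config = config or self.config
        return {sc.subject_id: predict_serum(sc, config, dense=dense) for sc in self.scenarios}

    def _scored_draws(self, sc: SubjectScenario) -> list[str]:
        """Draw labels entering the objective (the baseline draw is excluded)."""
        obs = self.observations[sc.subject_id]
        labels = []
        for lab in sc.sample_labels[1:]:
            if lab in obs:
                labels.append(lab)
            else:
                warnings.warn(f"subject {sc.subject_id}: draw {lab} missing, excluded")
        return labels

    def objective(
        self, theta: np.ndarray, spec: CalibrationSpec | None = None
    ) -> float:
        """Sum of squared normalized-concentration residuals at ``theta``."""
        spec = spec or self.config.calibration
        config = self.config
        for name, value in zip(spec.free, np.atleast_1d(theta)):
            config = _set_param(config, name, float(value))
        sse = 0.0
        for sc in self.scenarios:
            series = predict_serum(sc, config, dense=False)
            pred = dict(zip(series.sample_labels, series.sample_normalized))
            obs = self.observations[sc.subject_id]
            for lab in self._scored_draws(sc):
                r = pred[lab] - obs[lab]
                if spec.objective == "sse_log":
                    r = np.log(pred[lab] / obs[lab])
                sse += float(r) ** 2
        return sse

    # -- fitting -------------------------------------------------------

    def _linear_profiles(self) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
        """Per-draw response slopes u and observed excesses (obs - 1).

        One simulation per subject at x = 1 yields the affine structure
        ``pred_normalized = 1 + x * u`` exactly (see module docstring).
        """
        unit_config = _set_param(self.config, "x", 1.0)
        u_list: list[float] = []
        y_list: list[float] = []
        keys: list[tuple[str, str]] = []
        for sc in self.scenarios:
            series = predict_serum(sc, unit_config, dense=False)
            norm = dict(zip(series.sample_labels, series.sample_normalized))
            obs = self.observations[sc.subject_id]
            for lab in self._scored_draws(sc):
                u_list.append(norm[lab] - 1.0)
                y_list.append(obs[lab] - 1.0)
                keys.append((sc.subject_id, lab))
        return np.array(u_list), np.array(y_list), keys

    def fit(self, spec: CalibrationSpec | None = None) -> "CalibrationResults":
        """Estimate the free parameters; deterministic for a given seed."""
        spec = spec or self.config.calibration
        if tuple(spec.free) == ("x",) and spec.objective == "sse_normalized":
            return self._fit_linear(spec)
        return self._fit_multistart(spec)

    def _fit_linear(self, spec: CalibrationSpec) -> "CalibrationResults":
        u, y, keys = self._linear_profiles()
        denom = float(u @ u)
        if denom <= 1e-20 * max(1, u.size):
            raise NonIdentifiableError(
                "x is not identifiable: no draw shows any blast response "
                "(all scenarios sub-threshold or blast-free)"
            )
        x_hat = float(np.clip((u @ y) / denom, spec.lower[0], spec.upper[0]))
        resid = y - x_hat * u
        sse = float(resid @ resid)
        logger.info("linear calibration: x = %.6g, sse = %.6g over %d draws", x_hat, sse, u.size)
        return CalibrationResults(
            model=self,
            spec=spec,
            params={"x": x_hat},
            objective_value=sse,
            residual_frame=pd.DataFrame(
                {
                    "subject_id": [k[0] for k in keys],
                    "draw_label": [k[1] for k in keys],
                    "observed_normalized": y + 1.0,
                    "predicted_normalized": x_hat * u + 1.0,
                    "residual": resid,
                }
            ),
            converged=True,
            method="linear least squares (exact, x-affine structure)",
        )

    def _fit_multistart(self, spec: CalibrationSpec) -> "CalibrationResults":
        rng = np.random.default_rng(spec.seed)
        lo = np.array(spec.lower)
        hi = np.array(spec.upper)
        starts = [lo + (hi - lo) * rng.random(lo.size) for _ in range(spec.multistart)]
        best = None
        for x0 in starts:
            res = minimize(
                lambda th: self.objective(th, spec),
                x0,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = np.atleast_1d(best.x)
        if best.fun > 0 and self.objective(lo, spec) == self.objective(hi, spec) == best.fun:
            raise NonIdentifiableError("objective is flat across the parameter bounds")
        params = {name: float(v) for name, v in zip(spec.free, theta)}
        rows = []
        config = self.config
        for name, value in params.items():
            config = _set_param(config, name, value)
        for sc in self.scenarios:
            series = predict_serum(sc, config, dense=False)
            pred = dict(zip(series.sample_labels, series.sample_normalized))
            obs = self.observations[sc.subject_id]
            for lab in self._scored_draws(sc):
                rows.append(
                    {
                        "subject_id": sc.subject_id,
                        "draw_label": lab,
                        "observed_normalized": obs[lab],
                        "predicted_normalized": pred[lab],
                        "residual": obs[lab] - pred[lab],
                    }
                )
        return CalibrationResults(
            model=self,
            spec=spec,
            params=params,
            objective_value=float(best.fun),
            residual_frame=pd.DataFrame(rows),
            converged=bool(best.success),
            method=f"multistart L-BFGS-B ({spec.multistart} starts, seed {spec.seed})",
        )


@dataclass
class CalibrationResults:
    """Fitted parameters, residuals and diagnostics of a cohort calibration."""

    model: BlastDoseModel
    spec: CalibrationSpec
    params: dict[str, float]
    objective_value: float
    residual_frame: pd.DataFrame
    converged: bool
    method: str

    @property
    def fitted_config(self) -> ModelConfig:
        config = self.model.config
        for name, value in self.params.items():
            config = _set_param(config, name, value)
        return config

    def predict(self, dense: bool = True) -> dict[str, PredictionSeries]:
        """Per-subject serum predictions at the fitted parameters."""
        return self.model.predict(self.fitted_config, dense=dense)

    def per_subject_sse(self) -> pd.Series:
        return self.residual_frame.groupby("subject_id")["residual"].apply(
            lambda r: float(np.sum(np.square(r)))
        )

    def validation_table(self) -> ValidationTable:
        """Relative-percent-error table of fitted predictions vs observations."""
        preds = {}
        for sid, series in self.predict(dense=False).items():
            preds[sid] = dict(zip(series.sample_labels, series.sample_normalized))
        demo = {
            sc.subject_id: (sc.age, sc.service_years)
            for sc in self.model.scenarios
            if sc.age is not None and sc.service_years is not None
        }
        return build_validation_table(preds, self.model.observations, demo or None)

    def validation_report(self) -> dict:
        return validation_report(self.validation_table())

    def summary(self) -> str:
        lines = [
            "Blast-dose BxK model calibration",
            "=" * 48,
            f"subjects:          {len(self.model.scenarios)}",
            f"scored draws:      {len(self.residual_frame)}",
            f"method:            {self.method}",
            f"converged:         {self.converged}",
            f"objective (SSE):   {self.objective_value:.6g}",
            "-" * 48,
        ]
        for name, value in self.params.items():
            lo, hi = (
                self.spec.lower[self.spec.free.index(name)] if name in self.spec.free else float("nan"),
                self.spec.upper[self.spec.free.index(name)] if name in self.spec.free else float("nan"),
            )
            lines.append(f"{name:<12s} {value:>12.6g}   bounds [{lo:g}, {hi:g}]")
        lines.append("-" * 48)
        rms = float(np.sqrt(np.mean(np.square(self.residual_frame["residual"]))))
        lines.append(f"RMS residual (normalized conc.): {rms:.4g}")
        return "\n".join(lines)

    def plot_fit(self, subjects: list[str] | None = None):
        """Overlay fitted serum traces and observed draws per subject."""
        import matplotlib.pyplot as plt

        preds = self.predict(dense=True)
        sids = subjects or list(preds)[:4]
        fig, axes = plt.subplots(len(sids), 1, figsize=(7, 2.8 * len(sids)), squeeze=False)
        for ax, sid in zip(axes.ravel(), sids):
            series = preds[sid]
            series.plot(ax=ax)
            obs = self.model.observations[sid]
            labs = [l for l in series.sample_labels if l in obs]
            ts = [t for t, l in zip(series.sample_times, series.sample_labels) if l in obs]
            ax.plot(ts, [obs[l] for l in labs], "s", color="crimson", ms=5, label="observed")
            ax.legend(frameon=False)
        fig.tight_layout()
        return fig
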