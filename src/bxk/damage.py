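"""Mechanical damage and phasic biological responses to blast.

Three dimensionless states evolve on the study clock:

* ``R_M`` — mechanical damage to brain microstructures.  Each blast
  event injects a first-order source pulse (time constant ``tau_r``,
  ~40 ms) normalized so that R_M peaks ~500 ms after the event with
  amplitude ``dose_scale * BOP``; between events R_M relaxes at rate
  ``alpha / t_d`` toward the residual damage level ``lambda`` (zero
  below the injury threshold, > 0 above it):

      dR_M/dt = s(t) - (alpha / t_d) * (R_M - lambda(t))

* ``R_B1`` — hyperacute biological response, driven by R_M and cleared
  at a rate that slows while damage is high (prolonged recovery):

      dR_B1/dt = k_in * R_M - k_out1 * R_B1 / (R_M + R_M0)

* ``R_B2`` — acute response fed by R_B1 clearance:

      dR_B2/dt = k_out1 * R_B1 - k_out2 * R_B2

State continuity across events makes repeated exposure inside the
recovery window additive: a second blast rides on the unresolved
remnant of the first, so its peak is strictly higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import DamageConfig, DoseConfig
from .exposure import ExposureTimeline, InputError, lambda_profile


def decay_rate(params: DamageConfig) -> float:
    """Mechanical-damage relaxation rate alpha / t_d, 1/h."""
    return params.alpha / params.t_d_h


def rise_tau_for_peak(k_per_h: float, t_peak_s: float = 0.5) -> float:
    """Rise time constant (s) putting the pulse peak at ``t_peak_s``.

    For a first-order source ``A exp(-t/tau_r)`` feeding linear decay at
    rate ``k``, the response peaks at ``ln(a/k) / (a - k)`` with
    ``a = 1/tau_r``; this inverts that relation.
    """
    t_peak_h = t_peak_s / 3600.0

    def f(log_a: float) -> float:
        a = np.exp(log_a)
        return np.log(a / k_per_h) / (a - k_per_h) - t_peak_h

    log_a = brentq(f, np.log(k_per_h * 1.001) + 1e-9, np.log(1e9))
    return 3600.0 / np.exp(log_a)


def _pulse_shape(a: float, k: float) -> tuple[float, float]:
    """Peak time (h) and unit-amplitude peak value of the double exponential."""
    t_p = np.log(a / k) / (a - k)
    peak = (np.exp(-k * t_p) - np.exp(-a * t_p)) / (a - k)
    return t_p, peak


@dataclass
class DamageTrajectory:
    """Time series of the three damage/response states."""

    times: np.ndarray  # h
    r_m: np.ndarray
    r_b1: np.ndarray
    r_b2: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "R_M": self.r_m, "R_B1": self.r_b1, "R_B2": self.r_b2}
        )


def rm_rhs(r_m: float, lam: float, source: float, params: DamageConfig) -> float:
    """dR_M/dt at one instant: source minus relaxation toward lambda."""
    return source - decay_rate(params) * (r_m - lam)


def rb_rhs(
    r_m: float, r_b1: float, r_b2: float, params: DamageConfig
) -> tuple[float, float]:
    """(dR_B1/dt, dR_B2/dt) given the current mechanical damage."""
    d_b1 = params.k_in * r_m - params.k_out1 * r_b1 / (r_m + params.r_m0)
    d_b2 = params.k_out1 * r_b1 - params.k_out2 * r_b2
    return d_b1, d_b2


class DamageSystem:
    """Blast-driven damage/response ODE system for one exposure timeline.

    Precomputes per-event pulse amplitudes and the piecewise-constant
    residual-damage profile; exposes vectorized source and lambda
    lookups plus the 3-state right-hand side used by the integrators.
    """

    def __init__(
        self,
        timeline: ExposureTimeline,
        damage: DamageConfig,
        dose: DoseConfig,
    ) -> None:
        self.damage = damage
        self.dose = dose
        self.k = decay_rate(damage)
        self.a = 3600.0 / dose.rise_tau_s  # pulse decay rate, 1/h
        if self.a <= self.k:
            raise InputError("rise_tau_s too slow relative to damage recovery rate")
        t_p, unit_peak = _pulse_shape(self.a, self.k)
        self.t_peak_h = t_p
        self.event_times = np.array([e.time for e in timeline], dtype=float)
        bops = np.array([e.overpressure for e in timeline], dtype=float)
        # amplitude so that each pulse alone peaks at dose_scale * BOP
        self.amplitudes = dose.dose_scale * bops / unit_peak
        prof = lambda_profile(timeline, dose)
        self.lambda_levels = np.array([v for _, v in prof], dtype=float)

    def source_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Total blast source at time(s) t: sum of event pulses."""
        t = np.asarray(t, dtype=float)
        dt = t[..., None] - self.event_times  # (..., n_events)
        with np.errstate(under="ignore"):
            pulses = np.where(dt >= 0.0, np.exp(-self.a * np.clip(dt, 0.0, None)), 0.0)
        out = pulses @ self.amplitudes if self.event_times.size else np.zeros_like(t)
        return out if out.ndim else float(out)

    def lambda_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Residual damage level in force at time(s) t."""
        t = np.asarray(t, dtype=float)
        if self.event_times.size == 0:
            out = np.zeros_like(t)
        else:
            idx = np.searchsorted(self.event_times, t, side="right")
            levels = np.concatenate([[0.0], self.lambda_levels])
            out = levels[idx]
        return out if out.ndim else float(out)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        r_m, r_b1, r_b2 = y
        d_m = rm_rhs(r_m, self.lambda_at(t), self.source_at(t), self.damage)
        d_b1, d_b2 = rb_rhs(r_m, r_b1, r_b2, self.damage)
        return np.array([d_m, d_b1, d_b2])

    def segment_boundaries(self, t0: float, t1: float, pulse_window_h: float) -> list[tuple[float, float, bool]]:
        """Split [t0, t1] at events; flag the refined window after each event.

        Returns (start, stop, is_pulse_window) triples covering [t0, t1].
        """
        cuts: list[float] = [t0]
        for te in self.event_times:
            if t0 < te < t1:
                cuts.append(te)
            tw = te + pulse_window_h
            if t0 < tw < t1:
                cuts.append(tw)
        cuts.append(t1)
        cuts = sorted(set(cuts))
        segs = []
        for s, e in zip(cuts, cuts[1:]):
            mid = 0.5 * (s + e)
            in_pulse = any(te <= mid < te + pulse_window_h for te in self.event_times)
            segs.append((s, e, in_pulse))
        return segs

    def rm_closed_form(self, times: np.ndarray, r_m_init: float = 0.0) -> np.ndarray:
        """Exact analytic R_M(t): superposed pulse responses + lambda relaxation.

        The R_M equation is linear, so each event pulse contributes an
        independent double exponential and the piecewise-constant lambda
        drives a separate relaxation term.  Used as an oracle for the
        numerical integrators.
        """
        times = np.asarray(times, dtype=float)
        t0 = times[0] if times.size else 0.0
        out = np.full(times.shape, 0.0)
        with np.errstate(under="ignore"):
            # pulse contributions
            for te, amp in zip(self.event_times, self.amplitudes):
                dt = times - te
                mask = dt >= 0
                contrib = np.zeros_like(times)
                contrib[mask] = (amp / (self.a - self.k)) * (
                    np.exp(-self.k * dt[mask]) - np.exp(-self.a * dt[mask])
                )
                out += contrib
            # lambda relaxation: integrate dR/dt = -k (R - lambda(t)) piecewise
            knots = [t0] + [te for te in self.event_times if te > t0] + [np.inf]
            r_at_knot = 0.0
            for i, (ts, te_next) in enumerate(zip(knots, knots[1:])):
                lam = self.lambda_at(ts + 0.0) if ts > t0 else self.lambda_at(ts)
                mask = (times >= ts) & (times < te_next)
                out[mask] += lam + (r_at_knot - lam) * np.exp(-self.k * (times[mask] - ts))
                if np.isfinite(te_next):
                    r_at_knot = lam + (r_at_knot - lam) * np.exp(-self.k * (te_next - ts))
            # initial condition relaxes toward the lambda track already handled;
            # add the homogeneous part of a nonzero start
            out += (r_m_init - 0.0) * np.exp(-self.k * (times - t0))
        return out


def simulate_damage(
    timeline: ExposureTimeline,
    damage: DamageConfig,
    dose: DoseConfig,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    pulse_window_s: float = 2.0,
    y0: np.ndarray | None = None,
) -> DamageTrajectory:
    """Integrate the damage system over ``t_grid`` (hours, increasing).

    Integration restarts at each event and uses a locally refined step
    inside a short window after it so the millisecond-scale rise is
    resolved without a globally tiny step.  State is continuous across
    events, which is what makes repeated exposures additive.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise InputError("t_grid must be a 1-D strictly increasing array")
    sys = DamageSystem(timeline, damage, dose)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if sys.event_times.size and (
        sys.event_times.min() < t0 or sys.event_times.max() > t1
    ):
        raise InputError("all events must lie inside t_grid")

    y = np.zeros(3) if y0 is None else np.asarray(y0, dtype=float).copy()
    pulse_window_h = pulse_window_s / 3600.0
    out = np.empty((3, t_grid.size))
    filled = 0
    if t_grid[0] == t0:
        out[:, 0] = y
        filled = 1
    rise_tau_h = dose.rise_tau_s / 3600.0
    for s, e, in_pulse in sys.segment_boundaries(t0, t1, pulse_window_h):
        grid_pts = t_grid[(t_grid > s) & (t_grid <= e)]
        n_grid = grid_pts.size
        t_eval = grid_pts if (n_grid and grid_pts[-1] == e) else np.append(grid_pts, e)
        sol = solve_ivp(
            sys.rhs,
            (s, e),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            max_step=rise_tau_h / 2.0 if in_pulse else np.inf,
        )
        if not sol.success:
            raise RuntimeError(f"damage integration failed in [{s}, {e}]: {sol.message}")
        out[:, filled : filled + n_grid] = sol.y[:, :n_grid]
        filled += n_grid
        y = sol.y[:, -1].copy()
    assert filled == t_grid.size, "output grid not fully covered"
    out = np.clip(out, 0.0, None)  # guard vanishing negatives from the solver
    return DamageTrajectory(t_grid.copy(), out[0], out[1], out[2])
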