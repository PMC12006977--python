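"""Validation statistics for model predictions against serum draws.

Errors are signed relative percent errors on baseline-normalized serum
concentrations (positive = model over-approximates).  The cohort table
mirrors the study layout: per subject, five errors labeled d1_post,
d2_pre, d2_post, d3_pre, d3_post (the day-1 pre-training error is zero
by normalization and excluded).

The pre/post accuracy contrast uses an exact two-sided Wilcoxon
signed-rank test: the null distribution is enumerated over all 2^n
sign assignments (via a generating-function convolution, equivalent to
explicit enumeration), with average ranks for tied absolute
differences and zero differences dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from .exposure import InputError

ERROR_LABELS = ("d1_post", "d2_pre", "d2_post", "d3_pre", "d3_post")
PRE_LABELS = ("d2_pre", "d3_pre")
POST_LABELS = ("d1_post", "d2_post", "d3_post")


def relative_percent_error(predicted, observed):
    """Signed relative percent error 100 * (predicted - observed) / observed."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(observed <= 0):
        raise InputError("observed concentrations must be > 0")
    out = 100.0 * (predicted - observed) / observed
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ValidationTable:
    """Per-subject relative percent errors plus demographics."""

    frame: pd.DataFrame  # subject_id, age, service_years, five error columns

    def __post_init__(self) -> None:
        missing = [c for c in ("subject_id", *ERROR_LABELS) if c not in self.frame.columns]
        if missing:
            raise InputError(f"validation table missing columns: {missing}")
        bad = self.frame[self.frame[list(ERROR_LABELS)].isna().any(axis=1)]
        if len(bad):
            raise InputError(
                f"missing error entries for subjects: {bad['subject_id'].tolist()}"
            )

    @property
    def errors(self) -> np.ndarray:
        """(n_subjects, 5) signed errors ordered as ERROR_LABELS."""
        return self.frame[list(ERROR_LABELS)].to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def per_subject_mean_abs(self, labels: tuple[str, ...]) -> np.ndarray:
        return np.abs(self.frame[list(labels)].to_numpy(dtype=float)).mean(axis=1)


def load_table1() -> ValidationTable:
    """The packaged 15-subject validation table (printed study errors)."""
    with resources.files("bxk.data").joinpath("table1.csv").open() as fh:
        frame = pd.read_csv(fh)
    return ValidationTable(frame)


def summarize_errors(table: ValidationTable, ddof: int = 0) -> tuple[float, float]:
    """Mean and SD of the absolute errors over all entries.

    Population SD by default (``ddof=0``); pass ``ddof=1`` for the
    sample SD — both round to the same value on the study table.
    """
    abs_err = np.abs(table.errors).ravel()
    return float(abs_err.mean()), float(abs_err.std(ddof=ddof))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    n_effective: int  # nonzero differences
    p_two_sided: float
    method: str = "exact"
    degenerate: bool = False


def exact_signed_rank(diffs: np.ndarray) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The null distribution of W+ is computed exactly over all
    2^n sign assignments by convolution over doubled (hence integer)
    ranks, so tied/half-integer ranks are handled without rounding.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 0, 1.0, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    doubled = np.rint(2.0 * ranks).astype(np.int64)  # average ranks are k or k + 1/2
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(round(2.0 * w_plus))
    n_assign = 2.0**n
    p_le = counts[: w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(w_plus, n, p)


def pre_post_comparison(table: ValidationTable) -> WilcoxonResult:
    """Paired contrast of per-subject mean |pre| vs mean |post| errors."""
    pre = table.per_subject_mean_abs(PRE_LABELS)
    post = table.per_subject_mean_abs(POST_LABELS)
    return exact_signed_rank(pre - post)


@dataclass(frozen=True)
class OverApproxResult:
    fraction: float
    exact: Fraction
    n_positive: int
    n_total: int


def fraction_overapproximated(table: ValidationTable, which: str = "pre") -> OverApproxResult:
    """Fraction of strictly positive errors (model above observation).

    ``which`` selects pre-training entries (default), post-training, or
    all five columns.  A zero entry counts as not over-approximated.
    """
    labels = {"pre": PRE_LABELS, "post": POST_LABELS, "all": ERROR_LABELS}[which]
    vals = table.frame[list(labels)].to_numpy(dtype=float).ravel()
    n_pos = int((vals > 0).sum())
    return OverApproxResult(n_pos / vals.size, Fraction(n_pos, vals.size), n_pos, vals.size)


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    slope: float
    intercept: float
    pearson_r: float
    p_value: float


def regression_r2(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with R²; slope and Pearson r reported for transparency."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InputError("regression needs at least 3 subjects")
    if np.all(x == x[0]):
        raise InputError("covariate is constant; slope undefined")
    if np.all(y == y[0]):
        # flat response: SS_res = SS_tot = 0; no variance is explained
        return RegressionResult(0.0, 0.0, float(y[0]), 0.0, 1.0)
    fit = linregress(x, y)
    return RegressionResult(fit.rvalue**2, fit.slope, fit.intercept, fit.rvalue, fit.pvalue)


def validation_report(table: ValidationTable) -> dict:
    """All validation-layer summaries as a JSON-ready dict."""
    mean_abs, sd_pop = summarize_errors(table, ddof=0)
    _, sd_sample = summarize_errors(table, ddof=1)
    wil = pre_post_comparison(table)
    over = fraction_overapproximated(table, "pre")
    pre_mean = table.per_subject_mean_abs(PRE_LABELS)
    out = {
        "mean_abs_error_pct": mean_abs,
        "sd_abs_error_pct": sd_pop,
        "sd_abs_error_pct_sample": sd_sample,
        "wilcoxon": {
            "W": wil.statistic,
            "n": wil.n_effective,
            "p": wil.p_two_sided,
            "method": wil.method,
        },
        "frac_pre_overapprox": over.fraction,
        "frac_pre_overapprox_exact": f"{over.exact.numerator}/{over.exact.denominator}",
    }
    for cov, key in (("age", "r2_age"), ("service_years", "r2_service")):
        if cov in table.frame.columns and table.frame[cov].notna().all():
            reg = regression_r2(table.frame[cov].to_numpy(float), pre_mean)
            out[key] = reg.r_squared
            out[key + "_slope"] = reg.slope
    return out


def build_validation_table(
    predictions: dict[str, dict[str, float]],
    observations: dict[str, dict[str, float]],
    demographics: dict[str, tuple[float, float]] | None = None,
) -> ValidationTable:
    """Assemble the error table from normalized predictions and observations.

    Both inputs map subject_id -> {draw label -> normalized value};
    labels beyond the five scored ones (e.g. d1_pre) are ignored.
    """
    rows = []
    for sid, pred in predictions.items():
        if sid not in observations:
            raise InputError(f"no observations for subject {sid!r}")
        obs = observations[sid]
        row: dict[str, object] = {"subject_id": sid}
        if demographics and sid in demographics:
            row["age"], row["service_years"] = demographics[sid]
        for lab in ERROR_LABELS:
            if lab not in pred or lab not in obs:
                raise InputError(f"subject {sid!r} missing draw {lab!r}")
            row[lab] = relative_percent_error(pred[lab], obs[lab])
        rows.append(row)
    return ValidationTable(pd.DataFrame(rows))
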