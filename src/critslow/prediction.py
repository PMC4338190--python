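"""Tipping-point prediction from truncated recovery-rate series.

Knowing which bifurcation governs the approach to spiking, its scaling law
can be extrapolated to predict the critical voltage before it is reached:
the recovery rate is fit to the membrane potential by

    lambda = a * (V_cp - V)^theta

with the exponent ``theta`` held fixed and ``(a, V_cp)`` free, after
omitting the last ``n_exclude`` (default 5) measurements before spiking.
The predicted distance to threshold ``delta_V_p = V_cp - V_last`` is then
compared with the measured distance ``delta_V_m = V_cm - V_last`` across
trials; a correct ``theta`` yields a significant across-trial regression of
``delta_V_p`` on ``delta_V_m``, a wrong one does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .errors import (
    InsufficientDataError,
    PredictionFailedError,
    UndefinedCorrelationError,
)
from .markers import MarkerSeries

__all__ = [
    "TippingPrediction",
    "PredictionCorrelation",
    "predict_critical_voltage",
    "correlate_predictions",
    "ThresholdPredictionModel",
    "ThresholdPredictionResults",
]


@dataclass
class TippingPrediction:
    V_cp: float              # predicted critical voltage (mV)
    prefactor_a: float
    theta_used: float
    V_last: float            # last voltage included in the fit
    delta_V_p: float         # V_cp - V_last
    delta_V_m: float | None  # V_cm - V_last (absent if V_cm unknown)
    n_excluded: int
    fit_r_squared: float


@dataclass
class PredictionCorrelation:
    r: float
    p_value: float
    slope: float
    intercept: float
    n_trials: int
    theta_used: float


def predict_critical_voltage(
    series: MarkerSeries,
    theta: float = 0.5,
    n_exclude: int = 5,
    *,
    v_cm: float | None = None,
    max_extrapolation: float = 50.0,
) -> TippingPrediction:
    """Fit ``lambda = a*(V_cp - V)^theta`` with ``theta`` fixed.

    The ``n_exclude`` recovery-rate samples nearest onset in time are
    omitted; at least 5 must remain.  ``V_cp`` is constrained to lie above
    the last included voltage and within ``max_extrapolation`` of it.
    Least squares is taken in plain lambda space.
    """
    if theta <= 0:
        raise InsufficientDataError("theta must be > 0")
    order = np.argsort(series.pulse_time)
    lam = series.lam[order]
    volt = series.mean_voltage[order]
    ok = np.isfinite(lam) & (lam > 0) & np.isfinite(volt)
    lam, volt = lam[ok], volt[ok]
    if n_exclude > 0:
        lam, volt = lam[:-n_exclude] if n_exclude < len(lam) else lam[:0], \
            volt[:-n_exclude] if n_exclude < len(volt) else volt[:0]
    if len(lam) < 5:
        raise InsufficientDataError(
            f"only {len(lam)} usable samples remain after excluding {n_exclude}"
        )

    v_last = float(volt.max())
    v_first = float(volt.min())
    span = max(v_last - v_first, 1e-9)
    tiny = 1e-9 + 1e-9 * abs(v_last)
    lo, hi = v_last + tiny, v_last + max_extrapolation
    vc0 = min(max(v_last + 2.0 * span / len(volt), lo + tiny), hi - tiny)
    i0 = int(np.argmin(volt))
    a0 = float(lam[i0] / (vc0 - volt[i0]) ** theta)

    def model(v, a, vc):
        return a * np.power(np.clip(vc - v, 1e-12, None), theta)

    try:
        popt, _ = curve_fit(
            model, volt, lam, p0=[a0, vc0],
            bounds=([0.0, lo], [np.inf, hi]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise PredictionFailedError(f"tipping-point fit did not converge: {exc}")
    a, v_cp = (float(p) for p in popt)
    resid = lam - model(volt, a, v_cp)
    ss_tot = float(np.sum((lam - lam.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else math.nan

    if v_cm is None:
        v_cm = series.V_cm
    return TippingPrediction(
        V_cp=v_cp,
        prefactor_a=a,
        theta_used=float(theta),
        V_last=v_last,
        delta_V_p=v_cp - v_last,
        delta_V_m=(v_cm - v_last) if v_cm is not None else None,
        n_excluded=int(n_exclude),
        fit_r_squared=r2,
    )


def correlate_predictions(predictions: list[TippingPrediction]) -> PredictionCorrelation:
    """Across-trial regression of predicted on measured distance to threshold."""
    pairs = [
        (p.delta_V_m, p.delta_V_p)
        for p in predictions
        if p.delta_V_m is not None and math.isfinite(p.delta_V_m) and math.isfinite(p.delta_V_p)
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 trials with both delta_V_p and delta_V_m, got {len(pairs)}"
        )
    dvm = np.asarray([p[0] for p in pairs])
    dvp = np.asarray([p[1] for p in pairs])
    if np.ptp(dvm) == 0:
        raise UndefinedCorrelationError("zero variance in measured distances delta_V_m")
    res = stats.linregress(dvm, dvp)
    thetas = {p.theta_used for p in predictions}
    return PredictionCorrelation(
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_trials=len(pairs),
        theta_used=thetas.pop() if len(thetas) == 1 else math.nan,
    )


class ThresholdPredictionModel:
    """Tipping-point prediction over a batch of trials.

    Construct from one or more :class:`MarkerSeries`; :meth:`fit` runs the
    per-trial constrained fit and, when at least three trials carry both a
    predicted and a measured distance, the across-trial regression.
    """

    def __init__(self, series, theta: float = 0.5, n_exclude: int = 5,
                 max_extrapolation: float = 50.0):
        self.series_list = [series] if isinstance(series, MarkerSeries) else list(series)
        self.theta = theta
        self.n_exclude = n_exclude
        self.max_extrapolation = max_extrapolation

    def fit(self) -> "ThresholdPredictionResults":
        predictions = []
        failures = []
        for i, s in enumerate(self.series_list):
            try:
                predictions.append(
                    predict_critical_voltage(
                        s, self.theta, self.n_exclude,
                        max_extrapolation=self.max_extrapolation,
                    )
                )
            except (InsufficientDataError, PredictionFailedError) as exc:
                failures.append((i, exc))
        correlation = None
        if sum(p.delta_V_m is not None for p in predictions) >= 3:
            try:
                correlation = correlate_predictions(predictions)
            except UndefinedCorrelationError:
                correlation = None
        return ThresholdPredictionResults(self, predictions, failures, correlation)


class ThresholdPredictionResults:
    def __init__(self, model, predictions, failures, correlation):
        self.model = model
        self.predictions = predictions
        self.failures = failures
        self.correlation = correlation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "V_cp": [p.V_cp for p in self.predictions],
                "V_cm": [
                    p.V_last + p.delta_V_m if p.delta_V_m is not None else math.nan
                    for p in self.predictions
                ],
                "V_last": [p.V_last for p in self.predictions],
                "delta_V_p": [p.delta_V_p for p in self.predictions],
                "delta_V_m": [p.delta_V_m for p in self.predictions],
                "theta": [p.theta_used for p in self.predictions],
                "r2": [p.fit_r_squared for p in self.predictions],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Tipping-point prediction (theta = {self.model.theta}, "
            f"{self.model.n_exclude} samples excluded)",
            "=" * 60,
            f"trials fit: {len(self.predictions)}   failed: {len(self.failures)}",
        ]
        if self.correlation is not None:
            c = self.correlation
            lines.append(
                f"delta_V_p vs delta_V_m: r = {c.r:.3f}, p = {c.p_value:.3g}, "
                f"slope = {c.slope:.3f} (n = {c.n_trials})"
            )
        else:
            lines.append("across-trial regression: not available (< 3 usable trials)")
        return "\n".join(lines)
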