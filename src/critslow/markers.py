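"""Per-perturbation markers of critical slowing down.

For every impulse delivered before spiking onset this module extracts

* the recovery rate ``lambda`` from an exponential fit
  ``V(t) = a*exp(-lambda*t) + b`` to the post-pulse window,
* the variance of the unperturbed pre-pulse window, and
* the lag-normalized autocorrelation
  ``ACF(s) = ACF*(s) / ACF*(1)`` with
  ``ACF*(s) = sum_t (F(t)-mu)(F(t+s)-mu) / v``

each indexed by the distance to the bifurcation ``delta_I`` (``I_c - I`` in
pA for recordings, the control value ``y`` resp. ``-y`` in model units).

Window conventions follow the two acquisition modes: recordings use a 1 s
pre-pulse segment and a 4800-sample (192 ms at 25 kHz) post-pulse fit
window starting after the pulse offset; model trajectories use 5000-sample
pre segments and 5000-sample post windows (for the Hopf form the recovery
is fit on the radius, see :func:`compute_markers`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    CritslowError,
    DegenerateFitError,
    EmptySeriesError,
    InsufficientBaselineError,
    InsufficientDataError,
    UndefinedACFError,
    UnstableNormalizationError,
)
from .sde import HOPF, SADDLE_NODE, Trajectory, detrend_saddle_node

logger = logging.getLogger(__name__)

#: default ACF lag, in samples, for each acquisition mode
ACF_LAG_RECORDING_S = 0.050   # 50 ms -> 1250 samples at 25 kHz
ACF_LAG_MODEL = 100

POST_WINDOW_RECORDING_S = 0.192  # 4800 samples at 25 kHz
PRE_WINDOW_RECORDING_S = 1.0
PRE_SAMPLES_MODEL = 5000
# Both model systems fit recoveries over the full half inter-pulse interval
# (30 time units at dt = 0.006).  For the Hopf form the fitted signal is the
# radius sqrt(V1^2+V2^2), whose decay is a clean exponential; fitting V1
# itself is only meaningful over a window shorter than a quarter rotation
# period (~500 samples), which cannot resolve the vanishing recovery rates
# near the bifurcation.
POST_SAMPLES_MODEL = {SADDLE_NODE: 5000, HOPF: 5000}

__all__ = [
    "PerturbationEvent",
    "RecoveryFit",
    "MarkerSample",
    "MarkerSeries",
    "locate_perturbations",
    "fit_recovery",
    "segment_variance",
    "autocorrelation",
    "detect_onset",
    "critical_current",
    "compute_markers",
]


@dataclass
class PerturbationEvent:
    """One impulse with its statistics (pre) and recovery-fit (post) windows.

    Windows are half-open index ranges ``[start, stop)`` on the voltage grid;
    the equivalent time spans are kept for reporting.
    """

    index: int
    pulse_time: float
    pre_start: int
    pre_stop: int
    post_start: int
    post_stop: int
    mean_voltage_pre: float = math.nan
    mean_current_pre: float = math.nan

    @property
    def pre_window(self) -> tuple[int, int]:
        return (self.pre_start, self.pre_stop)

    @property
    def post_window(self) -> tuple[int, int]:
        return (self.post_start, self.post_stop)


@dataclass
class RecoveryFit:
    a: float
    lam: float
    b: float
    r_squared: float
    converged: bool


@dataclass
class MarkerSample:
    delta_I: float
    lam: float
    variance: float
    acf: float
    mean_voltage: float
    pulse_time: float
    r_squared: float = math.nan


@dataclass
class MarkerSeries:
    """Markers for all usable perturbations of one trial, ordered in time."""

    samples: list[MarkerSample]
    I_c: float | None
    V_cm: float | None
    onset_time: float | None
    acf_lag: int
    acf_lag_time: float
    kind: str  # "recording", "saddle_node" or "hopf"

    def __len__(self) -> int:
        return len(self.samples)

    def _arr(self, attr: str) -> np.ndarray:
        return np.asarray([getattr(s, attr) for s in self.samples], dtype=float)

    @property
    def delta_I(self) -> np.ndarray:
        return self._arr("delta_I")

    @property
    def lam(self) -> np.ndarray:
        return self._arr("lam")

    @property
    def variance(self) -> np.ndarray:
        return self._arr("variance")

    @property
    def acf(self) -> np.ndarray:
        return self._arr("acf")

    @property
    def mean_voltage(self) -> np.ndarray:
        return self._arr("mean_voltage")

    @property
    def pulse_time(self) -> np.ndarray:
        return self._arr("pulse_time")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_time_s": self.pulse_time,
                "delta_I_pA": self.delta_I,
                "lambda_per_s": self.lam,
                "variance_mV2": self.variance,
                "acf": self.acf,
                "mean_voltage_mV": self.mean_voltage,
            }
        )


def _is_recording(data) -> bool:
    return hasattr(data, "voltage_mV")


def locate_perturbations(
    data,
    protocol=None,
    *,
    pre_samples: int | None = None,
    post_samples: int | None = None,
) -> list[PerturbationEvent]:
    """Build pre/post analysis windows for every pulse delivered before onset.

    ``data`` is a :class:`~critslow.protocol.Recording` or a
    :class:`~critslow.sde.Trajectory` (pass the detrended trajectory for
    saddle-node paths so that windows respect the truncation at the
    bifurcation crossing).  Events whose post window would cross the onset,
    the next pulse, or the end of the data are dropped with a logged count.
    """
    if _is_recording(data):
        return _locate_recording(data, protocol, pre_samples, post_samples)
    return _locate_trajectory(data, pre_samples, post_samples)


def _locate_recording(rec, protocol, pre_samples, post_samples):
    protocol = protocol or rec.protocol
    sr = rec.v_sampling_hz
    pre_len = pre_samples if pre_samples is not None else int(round(PRE_WINDOW_RECORDING_S * sr))
    post_len = post_samples if post_samples is not None else int(round(POST_WINDOW_RECORDING_S * sr))
    width_s = protocol.pulse_width_ms / 1000.0
    n = len(rec.voltage_mV)
    onset_idx = int(round(rec.onset_time_s * sr)) if rec.onset_time_s is not None else n
    pulse_idx = [int(round(t * sr)) for t in rec.pulse_times_s]

    events: list[PerturbationEvent] = []
    dropped = 0
    for k, (tp, p_idx) in enumerate(zip(rec.pulse_times_s, pulse_idx)):
        post_start = int(round((tp + width_s) * sr)) + 1
        post_stop = post_start + post_len
        pre_stop = p_idx
        pre_start = p_idx - pre_len
        next_pulse = pulse_idx[k + 1] if k + 1 < len(pulse_idx) else n
        if p_idx >= onset_idx or pre_start < 0 or post_stop > min(onset_idx, next_pulse, n):
            dropped += 1
            continue
        j0 = int(round((tp - pre_len / sr) * rec.i_sampling_hz))
        j1 = int(round(tp * rec.i_sampling_hz))
        events.append(
            PerturbationEvent(
                index=k,
                pulse_time=float(tp),
                pre_start=pre_start,
                pre_stop=pre_stop,
                post_start=post_start,
                post_stop=post_stop,
                mean_voltage_pre=float(np.mean(rec.voltage_mV[pre_start:pre_stop])),
                mean_current_pre=float(np.mean(rec.current_pA[max(j0, 0):j1])),
            )
        )
    if dropped:
        logger.info("locate_perturbations: dropped %d of %d pulses", dropped, len(pulse_idx))
    if not events:
        raise EmptySeriesError("no usable perturbation events before onset")
    return events


def _locate_trajectory(traj: Trajectory, pre_samples, post_samples):
    dt = traj.dt
    pre_len = pre_samples if pre_samples is not None else PRE_SAMPLES_MODEL
    post_len = post_samples if post_samples is not None else POST_SAMPLES_MODEL[traj.kind]
    n = len(traj)
    pulse_idx = [int(round(t / dt)) for t in traj.pulse_times]

    events: list[PerturbationEvent] = []
    dropped = 0
    for k, p_idx in enumerate(pulse_idx):
        post_start = p_idx + 1
        post_stop = post_start + post_len
        pre_start = p_idx - pre_len
        next_pulse = pulse_idx[k + 1] if k + 1 < len(pulse_idx) else n
        if pre_start < 0 or post_stop > min(next_pulse, n):
            dropped += 1
            continue
        obs = traj.observable
        events.append(
            PerturbationEvent(
                index=k,
                pulse_time=p_idx * dt,
                pre_start=pre_start,
                pre_stop=p_idx,
                post_start=post_start,
                post_stop=post_stop,
                mean_voltage_pre=float(np.mean(obs[pre_start:p_idx])),
            )
        )
    if dropped:
        logger.info("locate_perturbations: dropped %d of %d pulses", dropped, len(pulse_idx))
    if not events:
        raise EmptySeriesError("no usable perturbation events before the bifurcation")
    return events


def _exp_decay(t, a, lam, b):
    return a * np.exp(-lam * t) + b


def fit_recovery(segment, sampling_rate: float) -> RecoveryFit:
    """Nonlinear least-squares fit of ``a*exp(-lambda*t) + b`` to a segment.

    The segment mean is subtracted before fitting (shifting only ``b``);
    ``t = 0`` at the segment start.  ``lambda`` is constrained to
    ``(0, sampling_rate/2)``.  Non-convergence is reported through
    ``converged=False`` rather than raised; a constant segment raises
    :class:`DegenerateFitError`.
    """
    seg = np.asarray(segment, dtype=float)
    n = len(seg)
    if n < 20:
        raise InsufficientDataError(f"recovery fit needs >= 20 samples, got {n}")
    if np.ptp(seg) == 0:
        raise DegenerateFitError("constant segment: no recovery to fit")
    y = seg - seg.mean()
    t = np.arange(n) / sampling_rate
    window = n / sampling_rate
    tail = y[-max(1, n // 10):]
    b0 = float(tail.mean())
    a0 = float(y[0] - b0)
    lam0 = 5.0 / window
    nyquist = sampling_rate / 2.0
    try:
        popt, _ = curve_fit(
            _exp_decay,
            t,
            y,
            p0=[a0, lam0, b0],
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, nyquist, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return RecoveryFit(a=math.nan, lam=math.nan, b=math.nan, r_squared=-math.inf, converged=False)
    a, lam, b = (float(p) for p in popt)
    resid = y - _exp_decay(t, a, lam, b)
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid * resid)) / ss_tot
    return RecoveryFit(a=a, lam=lam, b=b, r_squared=r2, converged=True)


def segment_variance(segment) -> float:
    """Population variance (divide by N) of a voltage segment."""
    seg = np.asarray(segment, dtype=float)
    if len(seg) < 2:
        raise InsufficientDataError("variance needs >= 2 samples")
    return float(np.var(seg))


def autocorrelation(segment, lag: int) -> float:
    """Lag-1-normalized autocorrelation ``ACF(s) = ACF*(s)/ACF*(1)``.

    ``ACF*(s) = sum_{t} (F(t)-mu)(F(t+s)-mu) / v`` with the population
    variance ``v``; the unusual lag-1 normalization means ``ACF(1) = 1`` by
    construction.  Because the normalization is by the lag-1 sum, segments
    dominated by white noise can drive the denominator toward zero; such
    segments raise :class:`UnstableNormalizationError`.
    """
    seg = np.asarray(segment, dtype=float)
    n = len(seg)
    lag = int(lag)
    if lag < 1 or lag > n // 2:
        raise InsufficientDataError(f"lag must satisfy 1 <= lag <= N/2 (N={n}, lag={lag})")
    v = float(np.var(seg))
    if v == 0:
        raise UndefinedACFError("zero-variance segment: autocorrelation undefined")
    f = seg - seg.mean()
    acf1 = float(f[:-1] @ f[1:]) / v
    if abs(acf1) < 1e-12 * n:
        raise UnstableNormalizationError("lag-1 autocorrelation too close to zero")
    acf_s = float(f[:-lag] @ f[lag:]) / v
    return acf_s / acf1


def detect_onset(recording, threshold_mV: float | None = None) -> float | None:
    """First time the voltage crosses ``threshold_mV`` upward, or ``None``.

    Also accepts a bare (voltage array, sampling rate) pair via
    ``detect_onset((v, sr), thr)``.
    """
    if _is_recording(recording):
        v = recording.voltage_mV
        sr = recording.v_sampling_hz
        if threshold_mV is None:
            threshold_mV = recording.protocol.spike_threshold_mV
    else:
        v, sr = recording
        if threshold_mV is None:
            raise InsufficientDataError("threshold_mV required for bare arrays")
    v = np.asarray(v, dtype=float)
    above = v >= threshold_mV
    if above[0]:
        return 0.0
    crossings = np.flatnonzero(above[1:] & ~above[:-1])
    if len(crossings) == 0:
        return None
    return float((crossings[0] + 1) / sr)


def critical_current(recording, onset: float) -> float:
    """Mean injected current over the 1 s interval before the first spike."""
    if onset < 1.0:
        raise InsufficientBaselineError(
            f"onset at {onset:.3f} s: less than 1 s of baseline current available"
        )
    i_hz = recording.i_sampling_hz
    j0 = int(round((onset - 1.0) * i_hz))
    j1 = int(round(onset * i_hz))
    return float(np.mean(recording.current_pA[j0:j1]))


def _tagged(exc: CritslowError, index: int) -> CritslowError:
    exc.args = (f"event {index}: {exc.args[0]}",) + exc.args[1:]
    return exc


def compute_markers(
    data,
    events: list[PerturbationEvent] | None = None,
    acf_lag: int | None = None,
    *,
    i_critical: float | None = None,
) -> MarkerSeries:
    """Full marker extraction for one recording or model trajectory.

    Saddle-node trajectories are detrended along the stable branch first;
    recovery rate, variance and autocorrelation are computed from the
    detrended (resp. raw recorded) series while the reported mean voltage is
    always that of the raw observable.  ``delta_I`` is ``I_c - <I>_pre`` for
    recordings and the signed distance to the bifurcation (``y`` for
    saddle-node, ``-y`` for Hopf) for trajectories.  Recovery fits that fail
    to converge contribute ``NaN`` recovery rates but keep their variance and
    autocorrelation samples.
    """
    if _is_recording(data):
        return _markers_recording(data, events, acf_lag, i_critical)
    return _markers_trajectory(data, events, acf_lag)


def _markers_recording(rec, events, acf_lag, i_critical):
    sr = rec.v_sampling_hz
    if acf_lag is None:
        acf_lag = int(round(ACF_LAG_RECORDING_S * sr))
    events = events if events is not None else locate_perturbations(rec)
    if not events:
        raise EmptySeriesError("no perturbation events supplied")

    onset = rec.onset_time_s
    I_c = i_critical
    V_cm = None
    if onset is not None and onset >= 1.0:
        if I_c is None:
            I_c = critical_current(rec, onset)
        o_idx = int(round(onset * sr))
        V_cm = float(np.mean(rec.voltage_mV[o_idx - int(round(sr)):o_idx]))
    elif I_c is None:
        # no onset (e.g. the no-bifurcation control): fall back to the
        # protocol-implied critical current carried in the provenance
        I_c = getattr(rec, "i_critical_nominal_pA", None)

    samples = []
    for ev in events:
        post = rec.voltage_mV[ev.post_start:ev.post_stop]
        pre = rec.voltage_mV[ev.pre_start:ev.pre_stop]
        lam, r2 = _safe_recovery(post, sr, ev.index)
        try:
            var = segment_variance(pre)
            acf = autocorrelation(pre, acf_lag)
        except CritslowError as exc:
            raise _tagged(exc, ev.index)
        delta = I_c - ev.mean_current_pre if I_c is not None else math.nan
        samples.append(
            MarkerSample(
                delta_I=float(delta),
                lam=lam,
                variance=var,
                acf=acf,
                mean_voltage=ev.mean_voltage_pre,
                pulse_time=ev.pulse_time,
                r_squared=r2,
            )
        )
    return MarkerSeries(
        samples=samples,
        I_c=I_c,
        V_cm=V_cm,
        onset_time=onset,
        acf_lag=acf_lag,
        acf_lag_time=acf_lag / sr,
        kind="recording",
    )


def _markers_trajectory(traj: Trajectory, events, acf_lag):
    if acf_lag is None:
        acf_lag = ACF_LAG_MODEL
    raw = traj
    det = detrend_saddle_node(traj) if (traj.kind == SADDLE_NODE and not traj.detrended) else traj
    sr = 1.0 / traj.dt
    events = events if events is not None else locate_perturbations(det)
    if not events:
        raise EmptySeriesError("no perturbation events supplied")

    obs_det = det.observable
    obs_raw = raw.observable
    # Recovery fits for the Hopf form use the radius sqrt(V1^2 + V2^2): the
    # linearized flow is a rotation times e^{-|y| t}, so the radius decays as
    # a clean exponential while V1 alone oscillates through zero within the
    # fit window and its exponential fit measures the rotation, not the
    # damping.  Variance/ACF stay on the designated observable V1.
    fit_signal = obs_det if traj.kind == SADDLE_NODE else np.hypot(
        det.state[:, 0], det.state[:, 1])
    sign = 1.0 if traj.kind == SADDLE_NODE else -1.0

    onset = raw.escape_time
    V_cm = None
    if onset is not None:
        o_idx = int(round(onset / traj.dt))
        lo = max(0, o_idx - PRE_SAMPLES_MODEL)
        if o_idx - lo >= 2:
            V_cm = float(np.mean(obs_raw[lo:o_idx]))

    samples = []
    for ev in events:
        lam, r2 = _safe_recovery(fit_signal[ev.post_start:ev.post_stop], sr, ev.index)
        pre = obs_det[ev.pre_start:ev.pre_stop]
        try:
            var = segment_variance(pre)
            acf = autocorrelation(pre, acf_lag)
        except CritslowError as exc:
            raise _tagged(exc, ev.index)
        p_idx = int(round(ev.pulse_time / traj.dt))
        samples.append(
            MarkerSample(
                delta_I=float(sign * raw.y[p_idx]),
                lam=lam,
                variance=var,
                acf=acf,
                mean_voltage=float(np.mean(obs_raw[ev.pre_start:ev.pre_stop])),
                pulse_time=ev.pulse_time,
                r_squared=r2,
            )
        )
    return MarkerSeries(
        samples=samples,
        I_c=None,
        V_cm=V_cm,
        onset_time=onset,
        acf_lag=acf_lag,
        acf_lag_time=acf_lag * traj.dt,
        kind=traj.kind,
    )


def _safe_recovery(segment, sr, index) -> tuple[float, float]:
    try:
        fit = fit_recovery(segment, sr)
    except DegenerateFitError:
        return math.nan, math.nan
    except CritslowError as exc:
        raise _tagged(exc, index)
    if not fit.converged:
        return math.nan, fit.r_squared
    return fit.lam, fit.r_squared
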