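"""Power-law scaling of slowing-down markers and bifurcation classification.

Near a bifurcation the recovery rate, variance and autocorrelation follow
power laws in the distance to the bifurcation ``delta_I``:

    lambda ~ delta_I^theta,   v ~ delta_I^tau,   ACF ~ delta_I^kappa

with (theta, tau) = (0.5, -0.5) for a saddle-node and (1, -1) for a
(subcritical) Hopf bifurcation.  Exponents are estimated by ordinary least
squares in log-log space, ``log x = A*log(delta_I) + B``; fits with
``R^2 < 0.1`` are flagged rejected.  To make the estimate robust against
the choice of fit interval, the fit is repeated over a sweep of minimal
cutoffs ``delta_I_min`` (samples with ``delta_I <= delta_I_min`` discarded)
and the reported exponent is the mean over accepted fits.

``kappa`` is reported but never used for classification: it depends on the
lag at which the autocorrelation is measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AllFitsRejectedError, ConfigError, InsufficientDataError, UnclassifiableError
from .markers import MarkerSeries

MARKERS = ("lambda", "variance", "acf")
_MARKER_ATTR = {"lambda": "lam", "variance": "variance", "acf": "acf"}
_MARKER_SYMBOL = {"lambda": "theta", "variance": "tau", "acf": "kappa"}

#: template exponent pairs (theta, tau) used by the classifier
TEMPLATES = {"saddle_node": (0.5, -0.5), "hopf": (1.0, -1.0)}

__all__ = [
    "MARKERS",
    "TEMPLATES",
    "PowerLawFit",
    "ExponentEstimate",
    "BifurcationClass",
    "fit_power_law",
    "default_cutoff_grid",
    "sweep_exponents",
    "classify_bifurcation",
    "ScalingLawModel",
    "ScalingLawResults",
]


@dataclass
class PowerLawFit:
    exponent_A: float
    intercept_B: float
    r_squared: float
    n_points: int
    delta_I_min: float
    marker: str
    rejected: bool


@dataclass
class ExponentEstimate:
    """Exponent for one marker, aggregated over the cutoff sweep."""

    marker: str
    symbol: str
    mean_exponent: float
    sd_exponent: float
    per_cutoff: list[PowerLawFit]
    grid: np.ndarray

    @property
    def n_accepted(self) -> int:
        return sum(not f.rejected for f in self.per_cutoff)


@dataclass
class BifurcationClass:
    label: str          # "saddle_node", "hopf" or "indeterminate"
    distance: float     # Euclidean distance to the nearest template
    distances: dict[str, float]
    reason: str = ""


def _usable(series: MarkerSeries, marker: str, delta_I_min: float):
    x = series.delta_I
    v = getattr(series, _MARKER_ATTR[marker])
    mask = np.isfinite(x) & np.isfinite(v) & (x > 0) & (v > 0) & (x > delta_I_min)
    return x[mask], v[mask]


def fit_power_law(
    series: MarkerSeries,
    marker: str,
    delta_I_min: float = 0.0,
    *,
    r2_threshold: float = 0.1,
    min_points: int = 5,
) -> PowerLawFit:
    """OLS fit of ``log(marker)`` on ``log(delta_I)`` above a cutoff.

    Samples with nonpositive ``delta_I`` (events recorded after the critical
    current was crossed), missing recovery rates, or nonpositive marker
    values are excluded before taking logs.
    """
    if marker not in MARKERS:
        raise ConfigError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    x, v = _usable(series, marker, delta_I_min)
    if len(x) < min_points:
        raise InsufficientDataError(
            f"{marker}: only {len(x)} qualifying samples above delta_I_min="
            f"{delta_I_min:.4g} (need {min_points})"
        )
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise InsufficientDataError(f"{marker}: no spread in delta_I above the cutoff")
    res = stats.linregress(lx, np.log(v))
    r2 = res.rvalue ** 2
    return PowerLawFit(
        exponent_A=float(res.slope),
        intercept_B=float(res.intercept),
        r_squared=float(r2),
        n_points=int(len(x)),
        delta_I_min=float(delta_I_min),
        marker=marker,
        rejected=bool(r2 < r2_threshold),
    )


def default_cutoff_grid(series: MarkerSeries, n: int = 8,
                        percentiles: tuple[float, float] = (5.0, 60.0)) -> np.ndarray:
    """Logarithmically spaced ``delta_I_min`` cutoffs.

    Spans the 5th to 60th percentile of the observed positive distances, so
    the sweep always retains a usable upper range of samples.
    """
    x = series.delta_I
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) == 0:
        raise InsufficientDataError("no positive delta_I values to build a cutoff grid")
    lo, hi = np.percentile(x, percentiles)
    if lo <= 0:
        lo = float(np.min(x))
    if hi <= lo:
        return np.full(n, float(lo))
    return np.geomspace(lo, hi, n)


def sweep_exponents(
    series: MarkerSeries,
    marker: str,
    grid: np.ndarray | None = None,
    *,
    r2_threshold: float = 0.1,
    min_points: int = 5,
) -> ExponentEstimate:
    """Exponent estimate aggregated over the ``delta_I_min`` sweep.

    Cutoffs with too few qualifying points are skipped; if every remaining
    fit is rejected (``R^2 < r2_threshold``) an :class:`AllFitsRejectedError`
    is raised, carrying the individual fits for inspection -- distinct from
    :class:`InsufficientDataError`, which means nothing could be fit at all.
    """
    if grid is None:
        grid = default_cutoff_grid(series)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("empty delta_I_min grid")
    fits: list[PowerLawFit] = []
    for cutoff in grid:
        try:
            fits.append(
                fit_power_law(series, marker, float(cutoff),
                              r2_threshold=r2_threshold, min_points=min_points)
            )
        except InsufficientDataError:
            continue
    if not fits:
        raise InsufficientDataError(
            f"{marker}: no cutoff in the sweep left enough samples to fit"
        )
    accepted = [f for f in fits if not f.rejected]
    if not accepted:
        raise AllFitsRejectedError(
            f"{marker}: all {len(fits)} power-law fits rejected (R^2 < {r2_threshold})",
            fits=fits,
        )
    exps = np.asarray([f.exponent_A for f in accepted])
    return ExponentEstimate(
        marker=marker,
        symbol=_MARKER_SYMBOL[marker],
        mean_exponent=float(exps.mean()),
        sd_exponent=float(exps.std(ddof=1)) if len(exps) > 1 else 0.0,
        per_cutoff=fits,
        grid=grid,
    )


def _mean_exp(est) -> float:
    return float(getattr(est, "mean_exponent", est))


def classify_bifurcation(theta, tau, *, max_distance: float = 0.35) -> BifurcationClass:
    """Nearest-template classification in (theta, tau) exponent space.

    ``theta`` and ``tau`` may be :class:`ExponentEstimate` objects or plain
    numbers.  The label is indeterminate when the nearest template is
    farther than ``max_distance``, when the two templates are equidistant,
    or when theta and tau disagree about which template is nearer.
    """
    th = _mean_exp(theta)
    ta = _mean_exp(tau)
    if not (math.isfinite(th) and math.isfinite(ta)):
        raise UnclassifiableError("non-finite exponent estimates")
    distances = {
        name: math.hypot(th - t_th, ta - t_ta) for name, (t_th, t_ta) in TEMPLATES.items()
    }
    names = sorted(distances, key=distances.get)
    best, second = names[0], names[1]
    d_best = distances[best]

    def axis_vote(value, axis):
        deltas = {name: abs(value - TEMPLATES[name][axis]) for name in TEMPLATES}
        ordered = sorted(deltas, key=deltas.get)
        if math.isclose(deltas[ordered[0]], deltas[ordered[1]], rel_tol=0.0, abs_tol=1e-12):
            return None
        return ordered[0]

    vote_th = axis_vote(th, 0)
    vote_ta = axis_vote(ta, 1)
    if math.isclose(d_best, distances[second], rel_tol=0.0, abs_tol=1e-12):
        return BifurcationClass("indeterminate", d_best, distances, "templates equidistant")
    if vote_th is None or vote_ta is None or vote_th != vote_ta:
        return BifurcationClass(
            "indeterminate", d_best, distances,
            f"theta favours {vote_th}, tau favours {vote_ta}",
        )
    if d_best > max_distance:
        return BifurcationClass(
            "indeterminate", d_best, distances,
            f"nearest template farther than {max_distance}",
        )
    return BifurcationClass(best, d_best, distances)


class ScalingLawModel:
    """Scaling-law estimation for one marker series.

    Statsmodels-style front end: construct from a :class:`MarkerSeries`
    (``from_dataframe`` accepts the tidy marker table instead) and call
    :meth:`fit` to obtain a :class:`ScalingLawResults` carrying the exponent
    estimates, their spread over the cutoff sweep, and the bifurcation
    classification.
    """

    def __init__(
        self,
        series: MarkerSeries,
        markers: tuple[str, ...] = MARKERS,
        *,
        cutoff_grid: np.ndarray | None = None,
        r2_threshold: float = 0.1,
        min_points: int = 5,
        classification_max_distance: float = 0.35,
    ):
        unknown = set(markers) - set(MARKERS)
        if unknown:
            raise ConfigError(f"unknown markers {sorted(unknown)}")
        self.series = series
        self.markers = tuple(markers)
        self.cutoff_grid = cutoff_grid
        self.r2_threshold = r2_threshold
        self.min_points = min_points
        self.classification_max_distance = classification_max_distance

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ScalingLawModel":
        """Build from a tidy marker table (columns as written by the io module)."""
        from .markers import MarkerSample  # local import to avoid cycle at module load

        samples = [
            MarkerSample(
                delta_I=row.get("delta_I_pA", math.nan),
                lam=row.get("lambda_per_s", math.nan),
                variance=row.get("variance_mV2", math.nan),
                acf=row.get("acf", math.nan),
                mean_voltage=row.get("mean_voltage_mV", math.nan),
                pulse_time=row.get("pulse_time_s", math.nan),
            )
            for _, row in frame.iterrows()
        ]
        series = MarkerSeries(
            samples=samples, I_c=None, V_cm=None, onset_time=None,
            acf_lag=0, acf_lag_time=math.nan, kind="recording",
        )
        return cls(series, **kwargs)

    def fit(self) -> "ScalingLawResults":
        grid = self.cutoff_grid
        if grid is None:
            grid = default_cutoff_grid(self.series)
        estimates: dict[str, ExponentEstimate] = {}
        failures: dict[str, Exception] = {}
        for marker in self.markers:
            try:
                estimates[marker] = sweep_exponents(
                    self.series, marker, grid,
                    r2_threshold=self.r2_threshold, min_points=self.min_points,
                )
            except (InsufficientDataError, AllFitsRejectedError) as exc:
                failures[marker] = exc
        if "lambda" in estimates and "variance" in estimates:
            classification = classify_bifurcation(
                estimates["lambda"], estimates["variance"],
                max_distance=self.classification_max_distance,
            )
        else:
            missing = [m for m in ("lambda", "variance") if m not in estimates]
            classification = BifurcationClass(
                "indeterminate", math.inf, {},
                f"no accepted exponent for {', '.join(missing)}",
            )
        return ScalingLawResults(self, np.asarray(grid), estimates, failures, classification)


class ScalingLawResults:
    """Fitted exponents, their cutoff-sweep spread, and the classification."""

    def __init__(self, model, grid, estimates, failures, classification):
        self.model = model
        self.grid = grid
        self.estimates = estimates
        self.failures = failures
        self.classification = classification

    @property
    def theta(self) -> float:
        return self._exp("lambda")

    @property
    def tau(self) -> float:
        return self._exp("variance")

    @property
    def kappa(self) -> float:
        return self._exp("acf")

    def _exp(self, marker: str) -> float:
        est = self.estimates.get(marker)
        return est.mean_exponent if est is not None else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for marker in self.model.markers:
            est = self.estimates.get(marker)
            fits = est.per_cutoff if est is not None else getattr(
                self.failures.get(marker), "fits", [])
            for f in fits:
                rows.append(
                    {
                        "marker": f.marker,
                        "symbol": _MARKER_SYMBOL[f.marker],
                        "delta_I_min": f.delta_I_min,
                        "exponent": f.exponent_A,
                        "intercept": f.intercept_B,
                        "r2": f.r_squared,
                        "accepted": not f.rejected,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Scaling-law fit of critical slowing down",
            "=" * 56,
            f"{'marker':<10}{'symbol':<8}{'exponent':>10}{'sd':>8}{'accepted':>10}",
            "-" * 56,
        ]
        for marker in self.model.markers:
            est = self.estimates.get(marker)
            if est is None:
                reason = type(self.failures[marker]).__name__
                lines.append(f"{marker:<10}{_MARKER_SYMBOL[marker]:<8}{'--':>10}{'--':>8}{reason:>14}")
            else:
                lines.append(
                    f"{marker:<10}{est.symbol:<8}{est.mean_exponent:>10.3f}"
                    f"{est.sd_exponent:>8.3f}{est.n_accepted:>7d}/{len(est.per_cutoff)}"
                )
        lines.append("-" * 56)
        c = self.classification
        lines.append(f"classification: {c.label} (distance {c.distance:.3f})")
        if c.reason:
            lines.append(f"  reason: {c.reason}")
        lines.append(
            f"cutoff sweep: {len(self.grid)} values of delta_I_min in "
            f"[{self.grid.min():.4g}, {self.grid.max():.4g}]"
        )
        return "\n".join(lines)
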