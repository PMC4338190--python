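"""Stochastic normal forms drifting slowly toward a bifurcation.

Two model systems are implemented, each the normal form of one of the two
robust routes from neuronal quiescence to repetitive spiking:

* saddle-node (fold):  ``dV = (-y + rho*V^2) dt + sigma1 dW + impulses``,
  with the control parameter ramped as ``dy = -epsilon dt``.  For ``y > 0``
  a stable equilibrium ``V- = -sqrt(y/rho)`` coexists with an unstable one
  at ``+sqrt(y/rho)``; they collide at ``y = 0``.  The linearized recovery
  rate on the stable branch is ``lambda = 2*sqrt(rho*y)``.

* subcritical Hopf: the two-component normal form
  ``dV1 = (y*V1 - V2 + V1*(V1^2+V2^2)) dt + sigma1 dW1 + impulses``,
  ``dV2 = (V1 + y*V2 + V2*(V1^2+V2^2)) dt + sigma2 dW2 + impulses``,
  stable focus at the origin for ``y < 0`` with recovery rate ``|y|``.

In both systems the control parameter ramps *toward* the bifurcation at
``y = 0`` at rate ``epsilon``: downward from ``y0 > 0`` for the
saddle-node, upward from ``y0 < 0`` for the Hopf, so the crossing time is
``t_c = |y0|/epsilon`` in either case.

Small additive impulses ("current pulses") of size ``pulse_amplitude`` are
applied every ``pulse_spacing`` time units; the decay back to the drifting
equilibrium after each impulse is what the markers stage fits.

Integration is explicit Euler--Maruyama at fixed step ``dt``.  The inner
loops run over plain Python floats on pre-drawn noise, which is both exactly
reproducible under a fixed seed and fast enough for the million-step paths
used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, IntegrationError, NoEquilibriumError, UnsupportedKindError

SADDLE_NODE = "saddle_node"
HOPF = "hopf"

__all__ = [
    "SADDLE_NODE",
    "HOPF",
    "SDEConfig",
    "Trajectory",
    "simulate_saddle_node",
    "simulate_hopf",
    "simulate",
    "stable_branch",
    "detrend_saddle_node",
    "linearized_recovery_rate",
]


@dataclass(frozen=True)
class SDEConfig:
    """Parameters of one drifting normal-form simulation.

    Defaults are the saddle-node study conditions (Fig-2-style run):
    ``y0 = 1.6``, ``V0 = -4`` (on the stable branch), ``epsilon = 0.001``,
    ``rho = 0.1``, ``sigma1 = 0.001`` and an impulse of ``0.1`` every 60 time
    units, so the deterministic bifurcation crossing is at ``t_c = 1600``.
    ``dt = 0.006`` makes each inter-pulse interval exactly 10 000 samples
    (5000 pre-pulse + 5000 post-pulse analysis points).
    """

    bifurcation_kind: str = SADDLE_NODE
    epsilon: float = 0.001       # drift rate of the control parameter per time unit
    rho: float = 0.1             # quadratic coefficient (saddle-node only)
    sigma1: float = 0.001        # white-noise amplitude on V (or V1)
    sigma2: float = 0.001        # white-noise amplitude on V2 (Hopf only)
    pulse_amplitude: float = 0.1  # additive state kick per impulse
    pulse_spacing: float = 60.0   # time between impulses
    y0: float = 1.6              # initial control-parameter value
    state0: tuple[float, ...] = (-4.0,)
    dt: float = 0.006
    seed: int = 0
    escape_bound: float = 50.0   # |state| terminating integration
    t_end: float | None = None   # default: t_c + 5 pulse spacings

    @classmethod
    def saddle_node(cls, **overrides) -> "SDEConfig":
        return cls(bifurcation_kind=SADDLE_NODE, **overrides)

    @classmethod
    def hopf(cls, *, fast_drive: bool = False, **overrides) -> "SDEConfig":
        """Hopf study conditions.

        The default set (``epsilon = 0.001``, ``sigma1 = sigma2 = 0.001``,
        impulse ``0.005`` every 60 time units, ``y0 = -2``) places the
        bifurcation crossing at ``t_c = 2000``.  ``fast_drive=True`` selects
        the alternative, strongly driven set (``epsilon = 0.02``,
        ``sigma1 = sigma2 = 0.01``, impulse ``0.05``).

        """
        base = dict(
            bifurcation_kind=HOPF,
            epsilon=0.001,
            sigma1=0.001,
            sigma2=0.001,
            pulse_amplitude=0.005,
            pulse_spacing=60.0,
            y0=-2.0,
            state0=(0.0, 0.0),
            escape_bound=50.0,
        )
        if fast_drive:
            base.update(epsilon=0.02, sigma1=0.01, sigma2=0.01, pulse_amplitude=0.05)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.bifurcation_kind not in (SADDLE_NODE, HOPF):
            raise ConfigError(f"unknown bifurcation_kind {self.bifurcation_kind!r}")
        if not self.dt > 0:
            raise ConfigError("dt must be > 0")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if not self.pulse_spacing > 0:
            raise ConfigError("pulse_spacing must be > 0")
        if self.bifurcation_kind == SADDLE_NODE:
            if not self.rho > 0:
                raise ConfigError("rho must be > 0 for the saddle-node form")
            if not self.y0 > 0:
                raise ConfigError("saddle-node runs need y0 > 0 (stable branch exists)")
            if len(self.state0) != 1:
                raise ConfigError("saddle-node state0 must be a 1-tuple (V0,)")
        else:
            if not self.y0 < 0:
                raise ConfigError("Hopf runs need y0 < 0 (stable focus exists)")
            if len(self.state0) != 2:
                raise ConfigError("Hopf state0 must be a 2-tuple (V1_0, V2_0)")
        if self.epsilon == 0 and self.t_end is None:
            raise ConfigError("t_end is required when epsilon == 0 (no bifurcation crossing)")

    @property
    def t_c(self) -> float:
        """Deterministic bifurcation-crossing time ``(y0 - y_c)/epsilon`` (y_c = 0)."""
        if self.epsilon == 0:
            return math.inf
        return abs(self.y0) / self.epsilon

    def _t_end(self) -> float:
        if self.t_end is not None:
            return float(self.t_end)
        return self.t_c + 5.0 * self.pulse_spacing


@dataclass
class Trajectory:
    """A simulated path on a uniform time grid.

    ``state`` has shape ``(n,)`` for the saddle-node form and ``(n, 2)`` for
    the Hopf form; ``observable`` is the designated scalar readout (V, or V1).
    ``y`` is the control-parameter series on the same grid.
    """

    kind: str
    times: np.ndarray
    state: np.ndarray
    y: np.ndarray
    pulse_times: np.ndarray
    t_c: float
    escape_time: float | None
    config: SDEConfig
    detrended: bool = False

    @property
    def dt(self) -> float:
        return self.config.dt

    @property
    def observable(self) -> np.ndarray:
        return self.state if self.state.ndim == 1 else self.state[:, 0]

    def __len__(self) -> int:
        return len(self.times)


def _pulse_schedule(config: SDEConfig, n_steps: int) -> tuple[set, list]:
    """Grid indices and times of the impulse train t_i, 2 t_i, 3 t_i, ..."""
    idx: set[int] = set()
    times: list[float] = []
    if config.pulse_amplitude == 0.0:
        return idx, times
    k = 1
    while True:
        t = k * config.pulse_spacing
        i = int(round(t / config.dt))
        if i > n_steps:
            break
        idx.add(i)
        times.append(i * config.dt)
        k += 1
    return idx, times


def simulate_saddle_node(config: SDEConfig) -> Trajectory:
    """Euler--Maruyama path of the drifting, noisy saddle-node normal form.

    Impulses are instantaneous additive kicks: the sample *at* each pulse
    time already contains the kick.  Integration stops at the end time or
    when the state escapes past the unstable branch
    (``V > sqrt(max(y,0)/rho) + 1``) or ``|V| > escape_bound``, whichever
    comes first; the escape sample is kept and ``escape_time`` recorded.
    """
    if config.bifurcation_kind != SADDLE_NODE:
        raise ConfigError("simulate_saddle_node requires bifurcation_kind='saddle_node'")
    config.validate()
    dt = config.dt
    eps = config.epsilon
    rho = config.rho
    amp = config.pulse_amplitude
    eb = config.escape_bound
    t_end = config._t_end()
    n_steps = int(round(t_end / dt))
    pulse_idx, pulse_times = _pulse_schedule(config, n_steps)

    rng = np.random.default_rng(config.seed)
    if config.sigma1 > 0:
        w = (rng.standard_normal(n_steps) * (config.sigma1 * math.sqrt(dt))).tolist()
    else:
        w = [0.0] * n_steps

    deterministic = config.sigma1 == 0 and amp == 0
    V = float(config.state0[0])
    y = float(config.y0)
    out = [V]
    push = out.append
    escape_time = None
    for i in range(1, n_steps + 1):
        V = V + (rho * V * V - y) * dt + w[i - 1]
        y = config.y0 - eps * (i * dt)
        if i in pulse_idx:
            V += amp
        if V - V != 0.0:  # catches NaN and +-inf without a function call
            raise IntegrationError(
                f"non-finite state at step {i} (t = {i * dt:.6g})", step=i
            )
        unstable = math.sqrt(y / rho) + 1.0 if y > 0 else 1.0
        push(V)
        if V > unstable or V > eb or V < -eb:
            if deterministic and y > 0:
                raise IntegrationError(
                    f"state escaped at step {i} (t = {i * dt:.6g}) before the "
                    f"bifurcation in a noise-free, pulse-free run; dt = {dt} is "
                    "too large for a stable explicit step",
                    step=i,
                )
            escape_time = i * dt
            break

    state = np.asarray(out)
    times = np.arange(len(state)) * dt
    y_arr = config.y0 - eps * times
    return Trajectory(
        kind=SADDLE_NODE,
        times=times,
        state=state,
        y=y_arr,
        pulse_times=np.asarray([t for t in pulse_times if t <= times[-1] + dt / 2]),
        t_c=config.t_c,
        escape_time=escape_time,
        config=config,
    )


def simulate_hopf(config: SDEConfig) -> Trajectory:
    """Euler--Maruyama path of the drifting, noisy subcritical Hopf normal form.

    Independent white noise drives the two components (``sigma1`` on V1,
    ``sigma2`` on V2); each impulse kicks both components by
    ``pulse_amplitude`` simultaneously.  Escape is declared when the radius
    exceeds ``max(2*sqrt(-y), 0.5)`` (outside the shrinking basin) or
    ``escape_bound``.  Escape while the focus is still stable (y < 0) only
    warns: with enough noise the path can legitimately leave the basin
    before the bifurcation.
    """
    if config.bifurcation_kind != HOPF:
        raise ConfigError("simulate_hopf requires bifurcation_kind='hopf'")
    config.validate()
    dt = config.dt
    eps = config.epsilon
    amp = config.pulse_amplitude
    eb2 = config.escape_bound ** 2
    t_end = config._t_end()
    n_steps = int(round(t_end / dt))
    pulse_idx, pulse_times = _pulse_schedule(config, n_steps)

    rng = np.random.default_rng(config.seed)
    sq = math.sqrt(dt)
    w1 = (rng.standard_normal(n_steps) * (config.sigma1 * sq)).tolist() \
        if config.sigma1 > 0 else [0.0] * n_steps
    w2 = (rng.standard_normal(n_steps) * (config.sigma2 * sq)).tolist() \
        if config.sigma2 > 0 else [0.0] * n_steps

    v1 = float(config.state0[0])
    v2 = float(config.state0[1])
    y = float(config.y0)
    out1 = [v1]
    out2 = [v2]
    escape_time = None
    escape_y = None
    for i in range(1, n_steps + 1):
        r2 = v1 * v1 + v2 * v2
        nv1 = v1 + (y * v1 - v2 + v1 * r2) * dt + w1[i - 1]
        nv2 = v2 + (v1 + y * v2 + v2 * r2) * dt + w2[i - 1]
        v1, v2 = nv1, nv2
        y = config.y0 + eps * (i * dt)
        if i in pulse_idx:
            v1 += amp
            v2 += amp
        if (v1 - v1 != 0.0) or (v2 - v2 != 0.0):
            raise IntegrationError(
                f"non-finite state at step {i} (t = {i * dt:.6g})", step=i
            )
        out1.append(v1)
        out2.append(v2)
        basin = max(2.0 * math.sqrt(-y), 0.5) if y < 0 else 0.5
        rad2 = v1 * v1 + v2 * v2
        if rad2 > basin * basin or rad2 > eb2:
            escape_time = i * dt
            escape_y = y
            break

    if escape_time is not None and escape_y is not None and escape_y < -1e-12:
        warnings.warn(
            f"Hopf path left the basin of attraction at t = {escape_time:.6g} "
            f"while the focus was still stable (y = {escape_y:.4g})",
            stacklevel=2,
        )

    state = np.column_stack([out1, out2])
    times = np.arange(len(state)) * dt
    y_arr = config.y0 + eps * times
    return Trajectory(
        kind=HOPF,
        times=times,
        state=state,
        y=y_arr,
        pulse_times=np.asarray([t for t in pulse_times if t <= times[-1] + dt / 2]),
        t_c=config.t_c,
        escape_time=escape_time,
        config=config,
    )


def simulate(config: SDEConfig) -> Trajectory:
    """Dispatch to the simulator matching ``config.bifurcation_kind``."""
    if config.bifurcation_kind == SADDLE_NODE:
        return simulate_saddle_node(config)
    return simulate_hopf(config)


def stable_branch(y, rho: float):
    """Stable equilibrium ``-sqrt(y/rho)`` of the saddle-node form.

    Accepts a scalar or an array of control values; every value must be
    strictly positive (past ``y = 0`` the equilibria have annihilated).
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0):
        raise NoEquilibriumError("no stable branch for y <= 0 (at or past the bifurcation)")
    branch = -np.sqrt(y_arr / rho)
    return float(branch) if np.isscalar(y) or y_arr.ndim == 0 else branch


def detrend_saddle_node(traj: Trajectory) -> Trajectory:
    """Subtract the moving stable branch from a saddle-node path.

    Returns a new trajectory ``V_d(t) = V(t) + sqrt(y(t)/rho)`` truncated at
    the bifurcation crossing (first grid point with ``y <= 0``) or at escape,
    whichever comes first.  Residual fluctuations and pulse transients around
    zero are what the marker statistics are computed from.
    """
    if traj.kind != SADDLE_NODE:
        raise UnsupportedKindError(
            "detrending along the stable branch applies to saddle-node paths only "
            "(the Hopf equilibrium is 0; no detrending is needed)"
        )
    if traj.detrended:
        return traj
    nonpos = traj.y <= 0
    end = int(np.argmax(nonpos)) if nonpos.any() else len(traj.y)
    if end == 0:
        raise NoEquilibriumError("trajectory starts at or past the bifurcation")
    rho = traj.config.rho
    v_d = traj.state[:end] + np.sqrt(traj.y[:end] / rho)
    t_last = traj.times[end - 1]
    esc = traj.escape_time if traj.escape_time is not None and traj.escape_time <= t_last else None
    return Trajectory(
        kind=traj.kind,
        times=traj.times[:end],
        state=v_d,
        y=traj.y[:end],
        pulse_times=traj.pulse_times[traj.pulse_times <= t_last + traj.dt / 2],
        t_c=traj.t_c,
        escape_time=esc,
        config=traj.config,
        detrended=True,
    )


def linearized_recovery_rate(y: float, config: SDEConfig) -> float:
    """Analytic recovery rate at frozen control value ``y``.

    ``2*sqrt(rho*y)`` on the saddle-node stable branch (y > 0), ``|y|`` at
    the Hopf focus (y < 0).  Raises past the bifurcation, where no stable
    equilibrium exists and the rate goes to zero.
    """
    if config.bifurcation_kind == SADDLE_NODE:
        if y <= 0:
            raise NoEquilibriumError("recovery rate undefined for y <= 0 (saddle-node)")
        return 2.0 * math.sqrt(config.rho * y)
    if y >= 0:
        raise NoEquilibriumError("recovery rate undefined for y >= 0 (Hopf)")
    return -y
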