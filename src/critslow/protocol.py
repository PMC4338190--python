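"""Patch-clamp protocol emulation in physical units.

Binds the saddle-node normal-form dynamics to the experimental stimulation
protocol: a step current rising by 3 pA every 4.01 s with 50 pA / 5 ms
perturbation pulses at 1800 ms and 3805 ms on each step, membrane voltage
sampled at 25 kHz and current at 2.5 kHz, the ramp terminating when the
cell starts to spike.

The mapping is deliberately minimal -- no conductance-based neuron is
simulated, because power-law exponents are invariant under the affine maps
used here:

* the control parameter ``y`` follows the current staircase (a fixed
  ``delta_y = epsilon * time_scale * step_duration`` per 3 pA step), so the
  distance to the critical current is proportional to ``y``;
* model time runs at ``time_scale`` time units per protocol second, with
  one Euler step per voltage sample;
* the recorded voltage is ``V_rest + R*I_step(t) + scale * V_d(t)`` where
  ``V_d`` is the normal-form fluctuation around the stable branch.  The
  ohmic term ``R*I`` emulates the passive depolarisation that dominates a
  real recording, which is what makes the recorded voltage approximately
  affine in the injected current (and hence the voltage-space recovery-rate
  exponent 0.5 for a saddle-node); setting ``input_resistance_mV_per_pA=0``
  leaves the purely affine state map.

A control mode holds ``y`` fixed far from the bifurcation while the
staircase still ramps: the recorded statistics then carry no slowing-down
trend, emulating the sodium-channel-blocked (TTX) control experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, IntegrationError, UnsupportedKindError
from .sde import SADDLE_NODE, SDEConfig

__all__ = [
    "PatchProtocolConfig",
    "Recording",
    "emulate_patch_recording",
    "generate_prediction_batch",
]


@dataclass(frozen=True)
class PatchProtocolConfig:
    """Stimulation protocol and unit maps for the patch emulation."""

    step_increment_pA: float = 3.0
    step_duration_s: float = 4.01
    pulse_amplitude_pA: float = 50.0
    pulse_width_ms: float = 5.0
    pulse_offsets_ms: tuple[float, ...] = (1800.0, 3805.0)
    v_sampling_hz: float = 25000.0
    i_sampling_hz: float = 2500.0
    voltage_scale_mV: float = 20.0        # mV per model-state unit
    voltage_offset_mV: float = -70.0      # resting potential at zero injected current
    input_resistance_mV_per_pA: float = 0.9
    current_base_pA: float = 0.0
    time_scale: float = 30.0              # model time units per protocol second
    spike_threshold_mV: float = 0.0
    model_kick: float = 0.1               # state kick representing one 50 pA / 5 ms pulse

    def validate(self) -> None:
        if self.v_sampling_hz <= 0 or self.i_sampling_hz <= 0:
            raise ConfigError("sampling rates must be > 0")
        if self.step_increment_pA <= 0:
            raise ConfigError("step_increment_pA must be > 0")
        if self.step_duration_s <= 0:
            raise ConfigError("step_duration_s must be > 0")
        if self.voltage_scale_mV == 0:
            raise ConfigError("voltage_scale_mV must be nonzero (map must be invertible)")
        if self.time_scale <= 0:
            raise ConfigError("time_scale must be > 0")
        if self.pulse_width_ms <= 0:
            raise ConfigError("pulse_width_ms must be > 0")
        for off in self.pulse_offsets_ms:
            if not 0 <= off < self.step_duration_s * 1000.0:
                raise ConfigError(
                    f"pulse offset {off} ms outside [0, {self.step_duration_s * 1000.0}) ms"
                )

    def delta_y_per_step(self, sde: SDEConfig) -> float:
        """Control-parameter decrement locked to one 3 pA step."""
        return sde.epsilon * self.time_scale * self.step_duration_s


@dataclass
class Recording:
    """An emulated whole-cell recording in physical units."""

    voltage_mV: np.ndarray
    current_pA: np.ndarray
    v_sampling_hz: float
    i_sampling_hz: float
    pulse_times_s: np.ndarray
    onset_time_s: float | None
    i_critical_nominal_pA: float   # staircase current at which mapped y crosses 0
    protocol: PatchProtocolConfig
    sde: SDEConfig
    control: bool = False

    @property
    def duration_s(self) -> float:
        return len(self.voltage_mV) / self.v_sampling_hz


def emulate_patch_recording(
    protocol: PatchProtocolConfig,
    sde: SDEConfig,
    *,
    control: bool = False,
) -> Recording:
    """Run the staircase protocol over the saddle-node normal form.

    ``sde`` supplies the dynamics (rho, sigma1, y0, seed, model kick size is
    taken from the protocol); its ``dt`` is ignored -- the integration grid
    is one Euler step per voltage sample, ``dt = time_scale/v_sampling_hz``.
    In control mode ``y`` stays at ``y0`` for the whole ramp and no onset
    occurs.
    """
    protocol.validate()
    if sde.bifurcation_kind != SADDLE_NODE:
        raise UnsupportedKindError("patch emulation drives the saddle-node form only")
    if sde.epsilon <= 0:
        raise ConfigError("patch emulation needs epsilon > 0 to map the staircase onto y")
    if not sde.y0 > 0:
        raise ConfigError("patch emulation needs y0 > 0")

    ts = protocol.time_scale
    v_hz = protocol.v_sampling_hz
    dtm = ts / v_hz                      # model time units per voltage sample
    rho = sde.rho
    dy = protocol.delta_y_per_step(sde)
    n_cross = math.ceil(sde.y0 / dy)     # first step index with y <= 0
    n_steps_total = n_cross + 2
    samples_per_step = int(round(protocol.step_duration_s * v_hz))
    n_samples = n_steps_total * samples_per_step

    # pulse schedule (voltage-grid indices)
    kick_idx = set()
    pulse_times = []
    for s in range(n_steps_total):
        for off in protocol.pulse_offsets_ms:
            t = s * protocol.step_duration_s + off / 1000.0
            i = int(round(t * v_hz))
            if 0 < i <= n_samples:
                kick_idx.add(i)
                pulse_times.append(i / v_hz)

    rng = np.random.default_rng(sde.seed)
    if sde.sigma1 > 0:
        w = (rng.standard_normal(n_samples) * (sde.sigma1 * math.sqrt(dtm))).tolist()
    else:
        w = [0.0] * n_samples

    kick = protocol.model_kick
    r_in = protocol.input_resistance_mV_per_pA
    scale = protocol.voltage_scale_mV
    inc = protocol.step_increment_pA

    v = float(sde.state0[0])
    out = [v]
    push = out.append
    step_y = []            # y per protocol step actually integrated
    escaped = False
    i = 1
    for s in range(n_steps_total):
        y = sde.y0 if control else sde.y0 - s * dy
        step_y.append(y)
        # per-step constants: branch, escape level and mapped stop level
        unstable = math.sqrt(y / rho) + 1.0 if y > 0 else 1.0
        dc = protocol.voltage_offset_mV + r_in * s * inc
        branch = -math.sqrt(y / rho) if y > 0 else 0.0
        stop_state = branch + (protocol.spike_threshold_mV + 20.0 - dc) / abs(scale)
        stop_state = max(stop_state, unstable + 0.5)
        block_end = min((s + 1) * samples_per_step, n_samples)
        while i <= block_end:
            v = v + (rho * v * v - y) * dtm + w[i - 1]
            if i in kick_idx:
                v += kick
            if v - v != 0.0:
                raise IntegrationError(f"non-finite state at sample {i}", step=i)
            push(v)
            if v > stop_state or abs(v) > sde.escape_bound:
                escaped = True
                break
            i += 1
        if escaped:
            break

    v_model = np.asarray(out)
    m = len(v_model)
    times = np.arange(m) / v_hz
    step_index = np.minimum((times / protocol.step_duration_s).astype(int), n_steps_total - 1)
    y_arr = np.full(m, sde.y0) if control else sde.y0 - step_index * dy
    branch = np.where(y_arr > 0, -np.sqrt(np.maximum(y_arr, 1e-300) / rho), 0.0)
    v_d = v_model - branch
    i_stair = protocol.current_base_pA + step_index * inc
    voltage = protocol.voltage_offset_mV + r_in * (i_stair - protocol.current_base_pA) \
        + scale * v_d

    # onset: first upward crossing of the spike threshold
    above = voltage >= protocol.spike_threshold_mV
    onset_time = None
    if above.any():
        first = int(np.argmax(above))
        onset_time = first / v_hz
        keep = min(m, first + int(round(0.010 * v_hz)))
        voltage = voltage[:keep]
        times = times[:keep]
        m = keep

    # current trace on its own (coarser) grid
    n_i = int(math.ceil(m * protocol.i_sampling_hz / v_hz))
    t_i = np.arange(n_i) / protocol.i_sampling_hz
    s_i = np.minimum((t_i / protocol.step_duration_s).astype(int), n_steps_total - 1)
    current = protocol.current_base_pA + s_i * inc
    width_s = protocol.pulse_width_ms / 1000.0
    for tp in pulse_times:
        mask = (t_i >= tp) & (t_i < tp + width_s)
        current[mask] += protocol.pulse_amplitude_pA

    i_critical = protocol.current_base_pA + (sde.y0 / dy) * inc
    t_last = times[-1]
    return Recording(
        voltage_mV=voltage,
        current_pA=current.astype(float),
        v_sampling_hz=v_hz,
        i_sampling_hz=protocol.i_sampling_hz,
        pulse_times_s=np.asarray([t for t in pulse_times if t <= t_last]),
        onset_time_s=onset_time,
        i_critical_nominal_pA=float(i_critical),
        protocol=protocol,
        sde=sde,
        control=control,
    )


def generate_prediction_batch(
    n_trials: int = 20,
    seed: int = 0,
    *,
    protocol: PatchProtocolConfig | None = None,
    heterogeneity: bool = True,
) -> list[Recording]:
    """Emulated recordings with across-cell variability, one per trial.

    Real prediction batches pool trials from different cells, so each trial
    draws its own input resistance (N(0.9, 0.1) mV/pA, clipped to
    [0.6, 1.2]), resting potential (N(-70, 2) mV), initial distance to the
    bifurcation (y0 ~ N(1.6, 0.15), clipped to [1.2, 2.0]) and noise level
    (sigma1 lognormal around 0.001, sd 0.25 in log).  With
    ``heterogeneity=False`` only the noise seed varies.
    """
    base = protocol or PatchProtocolConfig()
    children = np.random.SeedSequence(seed).spawn(n_trials)
    recordings = []
    for child in children:
        rng = np.random.default_rng(child)
        trial_seed = int(child.generate_state(1)[0] % (2 ** 31))
        if heterogeneity:
            r_in = float(np.clip(rng.normal(0.9, 0.1), 0.6, 1.2))
            v_rest = float(rng.normal(-70.0, 2.0))
            y0 = float(np.clip(rng.normal(1.6, 0.15), 1.2, 2.0))
            sigma1 = float(0.001 * math.exp(rng.normal(0.0, 0.25)))
            prot = replace(base, input_resistance_mV_per_pA=r_in, voltage_offset_mV=v_rest)
        else:
            y0, sigma1, prot = 1.6, 0.001, base
        sde = SDEConfig.saddle_node(
            y0=y0, state0=(-math.sqrt(y0 / 0.1),), sigma1=sigma1, seed=trial_seed
        )
        recordings.append(emulate_patch_recording(prot, sde))
    return recordings
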