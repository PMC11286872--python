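"""Temporal cascade: from biphasic pulse trains to perceived brightness over time.

The model converts a stimulating current waveform into a perceptual intensity
time course through four stages:

1. a one-stage leaky integrator (time constant ``tau1``, ~0.3 ms) standing in
   for cellular integration of current, ``dR1/dt = p(t) - R1/tau1``;
2. extraction of a "spike response strength" at the offset of the positive
   phase of each biphasic pulse, attenuated by a refractory factor
   ``1 - exp(-tau_r * (delta_i + delta))`` that depends on the inter-event
   interval ``delta_i``;
3. a slow n-stage leaky integrator, implemented as convolution of the event
   train with a gamma kernel (time constant ``tau2``, ``n_cascades`` stages);
4. a compressive nonlinearity ``s_out * tanh(s_in * R2 / p_div)`` mapping the
   slow response onto a 0-10 brightness-rating scale.

Everything before stage 4 is linear in stimulus amplitude, which the
psychophysics layer exploits for exact threshold computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.special import gammainc


@dataclass(frozen=True)
class PulseTrain:
    """Parametric biphasic pulse train.

    Parameters
    ----------
    amplitude : float
        Current amplitude per phase, in microamps (>= 0).
    pulse_width : float
        Duration of each phase, in ms.
    frequency : float
        Pulse rate in Hz.
    train_duration : float
        Total train duration in seconds.
    polarity : str
        ``"cathodic-first"`` (negative phase leads, the clinical default) or
        ``"anodic-first"``.
    interphase_gap : float
        Gap between the two phases, in ms (default 0).
    dt : float
        Sampling step for the rasterised waveform, in ms.
    """

    amplitude: float
    pulse_width: float
    frequency: float
    train_duration: float
    polarity: str = "cathodic-first"
    interphase_gap: float = 0.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0")
        if self.frequency <= 0 or self.train_duration <= 0:
            raise ValueError("frequency and train_duration must be > 0")
        if self.polarity not in ("cathodic-first", "anodic-first"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        period_ms = 1000.0 / self.frequency
        if 2 * self.pulse_width + self.interphase_gap > period_ms:
            raise ValueError(
                "pulse period too short for two phases plus interphase gap"
            )

    @property
    def n_pulses(self) -> int:
        """Number of complete biphasic pulses, floor(duration * frequency)."""
        return int(math.floor(self.train_duration * self.frequency + 1e-9))

    @property
    def charge_per_phase(self) -> float:
        """Charge delivered per phase, in uA*ms."""
        return self.amplitude * self.pulse_width

    def phase_windows(self) -> list[tuple[float, float, float]]:
        """(start_ms, stop_ms, sign) for every phase of every pulse."""
        lead = -1.0 if self.polarity == "cathodic-first" else 1.0
        period = 1000.0 / self.frequency
        out = []
        for i in range(self.n_pulses):
            t0 = i * period
            out.append((t0, t0 + self.pulse_width, lead))
            t1 = t0 + self.pulse_width + self.interphase_gap
            out.append((t1, t1 + self.pulse_width, -lead))
        return out

    def positive_phase_offsets(self) -> np.ndarray:
        """Times (ms) of the offset of the positive phase of each pulse.

        Spiking is assumed to occur at these instants.  For cathodic-first
        pulses this is the end of the second phase; for anodic-first, the end
        of the first.
        """
        period = 1000.0 / self.frequency
        starts = np.arange(self.n_pulses) * period
        if self.polarity == "cathodic-first":
            return starts + 2 * self.pulse_width + self.interphase_gap
        return starts + self.pulse_width


@dataclass(frozen=True)
class TemporalParams:
    """Constants of the temporal cascade (all configurable).

    Defaults: tau1 = 0.3 ms; refractory rate tau_r = 50 s^-1 with offset
    delta = 1 ms (these reproduce the 0.6501 attenuation factor at 50 Hz);
    slow stage tau2 = 150 ms with n_cascades = 3; compression s_in = 0.57,
    p_div = 15.6, s_out = 10 rating units; drawing threshold theta_draw = 1
    (the lowest visible rating).  ``theta_thresh`` is the detection threshold
    on the pre-compression response and is set by calibration against the
    standard electrode (see :mod:`cortisim.psychophysics`).
    """

    tau1: float = 0.3          # ms
    tau_r: float = 50.0        # s^-1
    delta: float = 0.001       # s
    tau2: float = 150.0        # ms
    n_cascades: int = 3
    s_in: float = 0.57
    p_div: float = 15.6
    s_out: float = 10.0
    theta_thresh: float | None = None
    theta_draw: float = 1.0
    dt_slow: float = 1.0       # ms, grid for the slow stage

    def __post_init__(self) -> None:
        if min(self.tau1, self.tau2) <= 0 or self.tau_r <= 0:
            raise ValueError("time constants and rates must be > 0")
        if self.n_cascades < 1:
            raise ValueError("n_cascades must be >= 1")
        if self.s_out <= 0 or self.p_div <= 0:
            raise ValueError("s_out and p_div must be > 0")
        if self.theta_draw < 0:
            raise ValueError("theta_draw must be >= 0")

    def with_(self, **kw) -> "TemporalParams":
        return replace(self, **kw)


@dataclass
class ResponseTrace:
    """A sampled signal: strictly increasing times (ms) and values."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have the same length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at time(s) t (ms)."""
        return np.interp(t, self.time, self.value)


@dataclass
class SpikeEvents:
    """Discrete spiking-activity events extracted from the fast stage."""

    times: np.ndarray       # s
    strengths: np.ndarray   # response units, >= 0
    attenuated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.strengths < 0):
            raise ValueError("strengths must be >= 0")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-event intervals (s); the first event has interval inf."""
        out = np.full(self.times.shape, np.inf)
        if self.times.size > 1:
            out[1:] = np.diff(self.times)
        return out


# ---------------------------------------------------------------------------
# stage operations


def build_pulse_train(spec: PulseTrain) -> ResponseTrace:
    """Rasterise a pulse train to a sampled current waveform (uA vs ms).

    Samples are left-aligned: sample k holds the mean current over
    [k*dt, (k+1)*dt), with phase boundaries apportioned by sub-sample
    overlap, so the waveform is exactly charge balanced for any pulse
    width (sum of samples * dt == 0 to rounding).
    """
    dt = spec.dt
    if dt > spec.pulse_width / 10:
        raise ValueError("dt must be <= pulse_width/10 for adequate resolution")
    n = int(round(spec.train_duration * 1000.0 / dt))
    p = np.zeros(n + 1)
    for start, stop, sign in spec.phase_windows():
        i0, i1 = int(start / dt), min(int(stop / dt), n)
        lo = np.maximum(np.arange(i0, i1 + 1) * dt, start)
        hi = np.minimum(np.arange(i0, i1 + 1) * dt + dt, stop)
        p[i0:i1 + 1] += sign * spec.amplitude * np.maximum(hi - lo, 0.0) / dt
    p = p[:n]
    return ResponseTrace(np.arange(n) * dt, p)


def integrate_stage1(waveform: ResponseTrace, tau1: float) -> ResponseTrace:
    """Fast leaky integrator dR1/dt = p(t) - R1/tau1.

    Uses exponential stepping, which is exact when the input is piecewise
    constant over each sample:
    ``R1[k+1] = R1[k] * exp(-dt/tau1) + p[k] * tau1 * (1 - exp(-dt/tau1))``.
    The returned trace holds R1 at the sample times of the input (R1(0) = 0).
    """
    dt = waveform.dt
    a = math.exp(-dt / tau1)
    b = tau1 * (1.0 - a)
    # R1[k] = a*R1[k-1] + b*p[k-1]  ->  IIR filter on the shifted input
    shifted = np.concatenate([[0.0], waveform.value[:-1]])
    r1 = lfilter([b], [1.0, -a], shifted)
    return ResponseTrace(waveform.time, r1)


def stage1_closed_form(spec: PulseTrain, tau1: float,
                       times: np.ndarray) -> np.ndarray:
    """Analytic R1 at arbitrary times for a pulse train (piecewise solution).

    Within a window of constant input A starting at t0 with initial value R0:
    ``R1(t) = A*tau1 + (R0 - A*tau1) * exp(-(t - t0)/tau1)``.
    Used for robust, dt-independent evaluation at event times.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    events = []
    for start, stop, sign in spec.phase_windows():
        events.append((start, sign * spec.amplitude))
        events.append((stop, 0.0))
    # at coincident breakpoints the onset of the next phase must win
    events.sort(key=lambda e: (e[0], abs(e[1])))
    # collapse into piecewise-constant segments
    seg_t = [0.0]
    seg_a = [0.0]
    for t0, a0 in events:
        if t0 > seg_t[-1]:
            seg_t.append(t0)
            seg_a.append(a0)
        else:
            seg_a[-1] = a0
    out = np.empty_like(times)
    for j, t in enumerate(times):
        r = 0.0
        tprev = 0.0
        for i in range(len(seg_t)):
            t0 = seg_t[i]
            t1 = seg_t[i + 1] if i + 1 < len(seg_t) else np.inf
            a = seg_a[i]
            if t <= t0:
                break
            tend = min(t, t1)
            r = a * tau1 + (r - a * tau1) * math.exp(-(tend - t0) / tau1)
            if t <= t1:
                break
        out[j] = r
    return out


def extract_spike_strengths(r1: ResponseTrace, train: PulseTrain,
                            analytic: bool = True,
                            tau1: float | None = None) -> SpikeEvents:
    """One spiking event per pulse, at the offset of the positive phase.

    Strength is R1 at the event instant, clipped at zero (with cathodic-first
    pulses the piecewise solution is positive there; clipping guards
    anodic-first and degenerate configurations).  By default the strengths
    are evaluated from the analytic piecewise solution (robust to dt);
    ``analytic=False`` interpolates the numerical trace instead.
    """
    t_ms = train.positive_phase_offsets()
    if analytic:
        if tau1 is None:
            raise ValueError("analytic evaluation requires tau1")
        vals = stage1_closed_form(train, tau1, t_ms)
    else:
        vals = r1.at(t_ms)
    return SpikeEvents(times=t_ms / 1000.0, strengths=np.maximum(vals, 0.0))


def refractory_factor(interval_s: np.ndarray | float, tau_r: float,
                      delta: float) -> np.ndarray | float:
    """Refractory attenuation ``1 - exp(-tau_r * (interval + delta))``.

    ``tau_r`` is a rate in s^-1 (default 50), ``delta`` an offset in s
    (default 0.001).  At 50 Hz (interval 1/50 s) the factor is 0.6501.
    Strictly increasing in the interval; in (0, 1] for interval >= 0.
    """
    return 1.0 - np.exp(-tau_r * (np.asarray(interval_s, dtype=float) + delta))


def apply_refractory(events: SpikeEvents, tau_r: float,
                     delta: float) -> SpikeEvents:
    """Attenuate event strengths by the refractory factor.

    The first event has no predecessor: its interval is infinite and its
    factor is exactly 1.
    """
    factors = np.ones_like(events.strengths)
    if events.times.size > 1:
        factors[1:] = refractory_factor(np.diff(events.times), tau_r, delta)
    return SpikeEvents(times=events.times.copy(),
                       strengths=events.strengths * factors,
                       attenuated=True)


def gamma_kernel(tau2: float, n: int, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalised gamma impulse response of an n-stage leaky integrator.

    ``G(t) = (t/tau2)^(n-1) * exp(-t/tau2) / (tau2_s * (n-1)!)`` sampled at
    dt (ms, like tau2) over [0, 20*n*tau2].  G is a probability *density
    over seconds* (tau2_s = tau2/1000 in the normalisation), so its
    integral over time-in-seconds is 1.  The mode sits at (n-1)*tau2.
    Returns (t_ms, g).
    """
    t = np.arange(0.0, 20.0 * n * tau2, dt)
    g = (t / tau2) ** (n - 1) * np.exp(-t / tau2) / (
        (tau2 / 1000.0) * math.factorial(n - 1))
    return t, g


def slow_integrate(events: SpikeEvents, tau2: float, n_cascades: int,
                   dt: float, t_max: float | None = None) -> ResponseTrace:
    """Slow stage: R2(t) = sum_i S_i * G(t - t_i).

    The event train is treated as a train of weighted unit impulses, with G
    a unit-mass density over seconds; a single event of strength 1 yields
    R2 peaking (n-1)*tau2 after the event.  Linear in the strengths by
    construction.  The per-second normalisation anchors the response scale
    so that, after calibration, a detection-threshold stimulus sits near
    brightness rating 1 (the dimmest visible percept on the rating scale).
    """
    if dt > tau2 / 20:
        raise ValueError("dt must be <= tau2/20 for the slow stage")
    t_events_ms = events.times * 1000.0
    if t_max is None:
        last = t_events_ms[-1] if t_events_ms.size else 0.0
        t_max = last + 10.0 * n_cascades * tau2
    t = np.arange(0.0, t_max, dt)
    r2 = np.zeros_like(t)
    norm = (tau2 / 1000.0) * math.factorial(n_cascades - 1)
    for ti, si in zip(t_events_ms, events.strengths):
        if si == 0.0:
            continue
        tau_rel = t - ti
        m = tau_rel >= 0
        x = tau_rel[m] / tau2
        r2[m] += si * x ** (n_cascades - 1) * np.exp(-x) / norm
    return ResponseTrace(t, r2)


def compress(r2: ResponseTrace | np.ndarray, s_in: float, p_div: float,
             s_out: float):
    """Compressive nonlinearity ``s_out * tanh(s_in * R2 / p_div)``.

    Bounded in [-s_out, s_out] and monotone; near zero the slope is
    s_out*s_in/p_div, so the response is linear in the small-signal regime.
    """
    if isinstance(r2, ResponseTrace):
        return ResponseTrace(r2.time,
                             s_out * np.tanh(s_in * r2.value / p_div))
    return s_out * np.tanh(s_in * np.asarray(r2, dtype=float) / p_div)


@dataclass
class TemporalResult:
    brightness: ResponseTrace
    r2: ResponseTrace
    max_brightness: float
    max_r2: float
    events: SpikeEvents


def simulate_temporal(train: PulseTrain, params: TemporalParams,
                      ) -> TemporalResult:
    """Run the full four-stage cascade for one pulse train.

    Returns the brightness trace together with the maxima over time of the
    compressed (brightness) and pre-compression (R2) responses; the latter is
    homogeneous of degree 1 in amplitude and drives threshold logic.
    """
    if train.amplitude == 0:
        t = np.arange(0.0, train.train_duration * 1000.0 +
                      10 * params.n_cascades * params.tau2, params.dt_slow)
        z = ResponseTrace(t, np.zeros_like(t))
        return TemporalResult(z, z, 0.0, 0.0,
                              SpikeEvents(np.array([]), np.array([])))
    waveform = build_pulse_train(train)
    r1 = integrate_stage1(waveform, params.tau1)
    events = extract_spike_strengths(r1, train, analytic=True,
                                     tau1=params.tau1)
    events = apply_refractory(events, params.tau_r, params.delta)
    r2 = slow_integrate(events, params.tau2, params.n_cascades,
                        params.dt_slow)
    brightness = compress(r2, params.s_in, params.p_div, params.s_out)
    return TemporalResult(brightness, r2,
                          float(np.max(brightness.value)),
                          float(np.max(r2.value)), events)


def max_r2_unit(train_template: PulseTrain, params: TemporalParams) -> float:
    """Max-over-time pre-compression response at unit (1 uA) amplitude.

    Because every stage before compression is linear in amplitude,
    ``max_R2(A) = A * max_r2_unit`` — the basis for exact threshold solves.
    """
    unit = replace(train_template, amplitude=1.0)
    return simulate_temporal(unit, params).max_r2
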