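"""Modified Hodgkin–Huxley simulation of cortical-neuron excitability.

The model keeps the classic m³h sodium / n⁴ potassium / leak structure
but re-parameterizes the gating steady states as Boltzmann curves, so
midpoints and slope factors fitted from voltage-clamp gating data plug
in directly. Voltage-dependent time constants use a Gaussian bell
(minimum + amplitude peaking near the gating midpoint), a standard
reduced form when rate constants are not measured separately.

A drug condition is expressed as a transform of the model: fractional
reduction of the Na and K conductance densities plus a shift of the Na
inactivation midpoint (the hallmark of an inactivated-state-stabilizing
blocker). The stimulus mimics current-clamp step families: a series of
increasing-amplitude current injections, each followed by a recovery
gap.

Integration is fixed-step classic Runge–Kutta (RK4), deterministic by
construction; dt = 0.01 ms resolves the fastest gate by an order of
magnitude.

Units: mV, ms, μA/cm², mS/cm², μF/cm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateParams",
    "TauBell",
    "NeuronModel",
    "StimulusProtocol",
    "SimResult",
    "cortical_neuron",
    "apply_drug_condition",
    "simulate",
    "detect_spikes",
]


@dataclass(frozen=True)
class GateParams:
    """Boltzmann steady state for one gating variable.

    ``sign`` +1 for activation gates (open with depolarization), −1 for
    inactivation gates; ``k`` stays positive either way.
    """

    v_half: float
    k: float
    sign: int = 1

    def steady(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp(self.sign * (self.v_half - v) / self.k))


@dataclass(frozen=True)
class TauBell:
    """Gaussian-bell voltage dependence of a gating time constant (ms).

    τ(V) = base + amp · exp(−((V − v_peak)/width)²)
    """

    base: float
    amp: float
    v_peak: float
    width: float

    def tau(self, v: float) -> float:
        x = (v - self.v_peak) / self.width
        return self.base + self.amp * math.exp(-x * x)


@dataclass(frozen=True)
class NeuronModel:
    """Single-compartment conductance-based neuron."""

    cm: float = 1.0          # μF/cm²
    g_na: float = 56.0       # mS/cm²
    g_k: float = 6.0
    g_leak: float = 0.0205
    e_na: float = 60.0       # mV
    e_k: float = -90.0
    e_leak: float = -70.4
    m_gate: GateParams = field(default_factory=lambda: GateParams(-41.9, 3.6, +1))
    h_gate: GateParams = field(default_factory=lambda: GateParams(-69.7, 5.0, -1))
    n_gate: GateParams = field(default_factory=lambda: GateParams(-35.0, 9.0, +1))
    tau_m: TauBell = field(default_factory=lambda: TauBell(0.02, 0.10, -40.0, 30.0))
    tau_h: TauBell = field(default_factory=lambda: TauBell(0.5, 6.0, -62.0, 22.0))
    tau_n: TauBell = field(default_factory=lambda: TauBell(0.5, 3.0, -50.0, 40.0))

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise ValueError("conductances must be non-negative")

    def membrane_current(self, v: float, m: float, h: float, n: float) -> float:
        """Total ionic current (μA/cm², outward positive)."""
        return (self.g_na * m ** 3 * h * (v - self.e_na)
                + self.g_k * n ** 4 * (v - self.e_k)
                + self.g_leak * (v - self.e_leak))

    def steady_gates(self, v: float) -> tuple[float, float, float]:
        return (self.m_gate.steady(v), self.h_gate.steady(v),
                self.n_gate.steady(v))


def cortical_neuron() -> NeuronModel:
    """Default model: regular-firing cortical pyramidal parameter set.

    Conductance densities follow single-compartment cortical models
    (g_Na ≫ g_K ≫ g_leak); the Na activation and inactivation midpoints
    and slopes are the fitted whole-cell gating values the package's
    analysis side produces (activation −41.9 mV / 3.6 mV, availability
    −69.7 mV / 5.0 mV).
    """
    return NeuronModel()


def apply_drug_condition(model: NeuronModel, na_block: float, k_block: float,
                         inact_shift: float) -> NeuronModel:
    """Return the model under a drug condition.

    ``na_block`` and ``k_block`` are fractions of the respective
    conductances removed (0–1); ``inact_shift`` (mV, signed) moves the
    Na inactivation midpoint — negative values hyperpolarize it,
    stabilizing the inactivated state. Everything else is untouched.
    """
    for name, frac in (("na_block", na_block), ("k_block", k_block)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    h = replace(model.h_gate, v_half=model.h_gate.v_half + inact_shift)
    return replace(model, g_na=model.g_na * (1.0 - na_block),
                   g_k=model.g_k * (1.0 - k_block), h_gate=h)


@dataclass(frozen=True)
class StimulusProtocol:
    """Step-family current-clamp stimulus.

    ``amplitudes`` (μA/cm²) are injected one after another, each for
    ``step_ms`` followed by ``gap_ms`` of zero current; ``settle_ms``
    of zero current precedes the first step.
    """

    amplitudes: tuple
    step_ms: float = 100.0
    gap_ms: float = 50.0
    settle_ms: float = 50.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        if self.step_ms <= 0 or self.gap_ms < 0 or self.settle_ms < 0:
            raise ValueError("durations must be positive")

    @property
    def total_ms(self) -> float:
        return self.settle_ms + len(self.amplitudes) * (self.step_ms + self.gap_ms)

    def step_windows(self) -> list[tuple[float, float]]:
        """[(t_on, t_off), ...] for each step, ms."""
        out, t = [], self.settle_ms
        for _ in self.amplitudes:
            out.append((t, t + self.step_ms))
            t += self.step_ms + self.gap_ms
        return out

    def current(self, t: float) -> float:
        """Injected current at time ``t`` (ms)."""
        if t < self.settle_ms:
            return 0.0
        period = self.step_ms + self.gap_ms
        idx = int((t - self.settle_ms) // period)
        if idx >= len(self.amplitudes):
            return 0.0
        within = (t - self.settle_ms) - idx * period
        return self.amplitudes[idx] if within < self.step_ms else 0.0

    @classmethod
    def default_family(cls) -> "StimulusProtocol":
        """Five increasing 100-ms steps with 50-ms recovery gaps."""
        return cls(amplitudes=(2.0, 4.0, 6.0, 8.0, 10.0))


@dataclass
class SimResult:
    """Simulated trace plus spike-based excitability readouts."""

    t: np.ndarray                 # ms
    v: np.ndarray                 # mV
    spike_times: np.ndarray       # ms
    spike_peaks: np.ndarray       # mV
    spike_thresholds: np.ndarray  # mV (dV/dt-criterion crossing)
    per_step_counts: list         # spikes within each stimulus step

    def __post_init__(self) -> None:
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def total_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def first_spike_peak(self) -> float:
        return float(self.spike_peaks[0]) if len(self.spike_peaks) else math.nan

    @property
    def first_spike_threshold(self) -> float:
        return float(self.spike_thresholds[0]) if len(self.spike_thresholds) else math.nan

    def summary(self) -> dict:
        return {
            "total_spikes": self.total_spikes,
            "per_step_counts": list(self.per_step_counts),
            "first_spike_peak_mV": self.first_spike_peak,
            "first_spike_threshold_mV": self.first_spike_threshold,
            "spike_times_ms": self.spike_times.tolist(),
        }


class IntegrationError(RuntimeError):
    """Raised when the membrane state becomes non-finite."""

    def __init__(self, t_ms: float):
        super().__init__(f"non-finite membrane state at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


def _derivs(model: NeuronModel, stim: float, v, m, h, n):
    dv = (stim - model.membrane_current(v, m, h, n)) / model.cm
    dm = (model.m_gate.steady(v) - m) / model.tau_m.tau(v)
    dh = (model.h_gate.steady(v) - h) / model.tau_h.tau(v)
    dn = (model.n_gate.steady(v) - n) / model.tau_n.tau(v)
    return dv, dm, dh, dn


def rhs_vector(model: NeuronModel, protocol: StimulusProtocol):
    """State-derivative function f(t, y) for external ODE solvers.

    Provided so that the fixed-step integrator can be cross-checked
    against adaptive references (e.g. scipy's solve_ivp).
    """
    def f(t, y):
        return _derivs(model, protocol.current(t), *y)
    return f


def simulate(model: NeuronModel, protocol: StimulusProtocol, *,
             dt: float = 0.01, v_init: float = -70.0,
             spike_threshold: float = 0.0,
             dvdt_criterion: float = 20.0) -> SimResult:
    """Integrate the model under the protocol and extract spikes.

    Fixed-step RK4 at ``dt`` (ms); ``dt`` must be ≤ 0.025 ms, at which
    point halving it moves any spike time by under 0.1 ms. Gates start
    at their steady state for ``v_init``.
    """
    if dt > 0.025:
        raise ValueError("dt must be ≤ 0.025 ms for the fixed-step integrator")
    n_steps = int(round(protocol.total_ms / dt))
    t_out = np.arange(n_steps + 1) * dt
    v_out = np.empty(n_steps + 1)

    v = float(v_init)
    m, h, n = model.steady_gates(v)
    v_out[0] = v
    current = protocol.current
    for i in range(n_steps):
        t = i * dt
        i1 = current(t)
        i2 = current(t + 0.5 * dt)
        i3 = current(t + dt)
        k1 = _derivs(model, i1, v, m, h, n)
        k2 = _derivs(model, i2, v + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1],
                     h + 0.5 * dt * k1[2], n + 0.5 * dt * k1[3])
        k3 = _derivs(model, i2, v + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1],
                     h + 0.5 * dt * k2[2], n + 0.5 * dt * k2[3])
        k4 = _derivs(model, i3, v + dt * k3[0], m + dt * k3[1],
                     h + dt * k3[2], n + dt * k3[3])
        v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        h += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not (math.isfinite(v) and math.isfinite(m)
                and math.isfinite(h) and math.isfinite(n)):
            raise IntegrationError(t + dt)
        v_out[i + 1] = v

    times, peaks, thresholds = detect_spikes(
        t_out, v_out, threshold=spike_threshold, dvdt_criterion=dvdt_criterion)
    counts = []
    for t0, t1 in protocol.step_windows():
        counts.append(int(np.sum((times >= t0) & (times < t1))))
    return SimResult(t=t_out, v=v_out, spike_times=times, spike_peaks=peaks,
                     spike_thresholds=thresholds, per_step_counts=counts)


def detect_spikes(t, v, *, threshold: float = 0.0,
                  dvdt_criterion: float = 20.0,
                  refractory_ms: float = 1.0):
    """Find action potentials in a uniformly sampled voltage trace.

    A spike is an upward crossing of ``threshold`` (mV) separated from
    the previous one by at least ``refractory_ms``. For each spike the
    peak is the local maximum before repolarization below threshold,
    and the per-spike voltage threshold is Vm where dV/dt first exceeds
    ``dvdt_criterion`` (mV/ms) in the rising phase.

    Returns (spike_times, peaks, thresholds) as arrays.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) != len(v) or len(t) < 2:
        raise ValueError("need equal-length t and v with ≥2 samples")
    dt = float(t[1] - t[0])
    dvdt = np.gradient(v, dt)
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1

    times, peaks, thrs = [], [], []
    last = -math.inf
    for idx in crossings:
        if t[idx] - last < refractory_ms:
            continue
        last = t[idx]
        # peak: local max until the trace falls back below threshold
        j = idx
        while j + 1 < len(v) and v[j + 1] >= threshold:
            j += 1
        seg = v[idx:j + 1]
        peaks.append(float(seg.max()))
        # walk back through the rising phase to the dV/dt criterion
        k = idx
        while k > 0 and dvdt[k - 1] >= dvdt_criterion:
            k -= 1
        thrs.append(float(v[k]))
        times.append(float(t[idx]))
    return np.asarray(times), np.asarray(peaks), np.asarray(thrs)
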