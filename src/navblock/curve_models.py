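"""Parametric models used throughout voltage-clamp pharmacology analysis.

This module is the single home of every model the package fits or
evaluates: the Hill–Langmuir concentration–response curve, Boltzmann
gating curves (activation and availability polarity), mono- and
biexponential time courses, and the two-receptor-state (resting /
inactivated) equilibrium block model that links apparent potency to
holding potential.

All evaluators are pure functions of (input, fit object); units are
fixed package-wide: mV for membrane potential, s for recovery/onset
time, μM for concentration. Fractions live in [0, 1]; percent appears
only at I/O boundaries.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Polarity",
    "HillFit",
    "BoltzmannFit",
    "BiexpFit",
    "MonoexpFit",
    "StateBlockModel",
    "hill_inhibition",
    "boltzmann",
    "biexp_recovery",
    "monoexp",
    "apparent_ic50",
]


class Polarity(str, enum.Enum):
    """Sign convention of a Boltzmann gating curve.

    ``ACTIVATION`` curves rise with depolarization (conductance
    activation); ``AVAILABILITY`` curves fall with depolarization
    (steady-state fast inactivation, SSFI). Both are 0.5 at ``v_half``
    and keep the slope factor ``k`` positive so fitted slopes are
    directly comparable between the two conventions.
    """

    ACTIVATION = "activation"
    AVAILABILITY = "availability"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class HillFit:
    """Hill–Langmuir concentration–response parameters.

    Normalized inhibition Y as a function of compound concentration C:

        Y(C) = C^h / (IC50^h + C^h)

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration, μM (> 0).
    h : float
        Hill coefficient (> 0); steep slopes (h ≈ 3) indicate multiple
        compound–channel interactions rather than 1:1 binding.
    fixed_slope : bool
        True when ``h`` was held constant during fitting.
    """

    ic50: float
    h: float
    fixed_slope: bool = False

    def __post_init__(self) -> None:
        _require(self.ic50 > 0, f"ic50 must be > 0, got {self.ic50}")
        _require(self.h > 0, f"Hill coefficient must be > 0, got {self.h}")

    def inhibition(self, c):
        """Fraction inhibited at concentration ``c`` (μM); vectorized."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        # Work in log space around IC50 to avoid overflow at extreme c/h.
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / self.ic50) ** self.h, 0.0)
        out = ratio / (1.0 + ratio)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "model": "hill",
            "ic50_uM": self.ic50,
            "hill_slope": self.h,
            "fixed_slope": self.fixed_slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillFit":
        return cls(ic50=d["ic50_uM"], h=d["hill_slope"],
                   fixed_slope=bool(d.get("fixed_slope", False)))


@dataclass(frozen=True)
class BoltzmannFit:
    """Boltzmann gating-curve parameters (midpoint and slope factor).

    Activation polarity:   f(Vm) = 1 / (1 + exp((v_half − Vm) / k))
    Availability polarity: f(Vm) = 1 / (1 + exp((Vm − v_half) / k))

    ``k`` is kept positive under both conventions so printed slope
    factors plug in directly; the polarity flag fixes the sign of the
    exponent instead.
    """

    v_half: float
    k: float
    polarity: Polarity = Polarity.ACTIVATION

    def __post_init__(self) -> None:
        _require(self.k > 0, f"slope factor k must be > 0, got {self.k}")
        object.__setattr__(self, "polarity", Polarity(self.polarity))

    def value(self, vm):
        """Fraction (conductance or availability) at potential ``vm`` (mV)."""
        vm = np.asarray(vm, dtype=float)
        if self.polarity is Polarity.ACTIVATION:
            x = (self.v_half - vm) / self.k
        else:
            x = (vm - self.v_half) / self.k
        out = 1.0 / (1.0 + np.exp(x))
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "model": "boltzmann",
            "v_half_mV": self.v_half,
            "slope_mV": self.k,
            "polarity": self.polarity.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoltzmannFit":
        return cls(v_half=d["v_half_mV"], k=d["slope_mV"],
                   polarity=Polarity(d["polarity"]))


@dataclass(frozen=True)
class BiexpFit:
    """Biexponential time-course parameters (recovery from inactivation).

    Y(t) = Plateau + SpanFast·exp(−K_fast·t) + SpanSlow·exp(−K_slow·t)

    with SpanFast = (Y0 − Plateau)·PercentFast/100 and
    SpanSlow = (Y0 − Plateau)·(100 − PercentFast)/100, so that
    Y(0) = Y0 and SpanFast + SpanSlow = Y0 − Plateau always holds.
    Components are labelled so that k_fast ≥ k_slow; constructing with
    the rates swapped relabels (and complements percent_fast)
    automatically.
    """

    y0: float
    plateau: float
    k_fast: float
    k_slow: float
    percent_fast: float

    def __post_init__(self) -> None:
        _require(self.k_fast > 0 and self.k_slow > 0,
                 "rates must be positive")
        _require(0.0 <= self.percent_fast <= 100.0,
                 f"percent_fast must be in [0, 100], got {self.percent_fast}")
        if self.k_fast < self.k_slow:  # relabel so fast means fast
            kf, ks = self.k_slow, self.k_fast
            object.__setattr__(self, "k_fast", kf)
            object.__setattr__(self, "k_slow", ks)
            object.__setattr__(self, "percent_fast", 100.0 - self.percent_fast)

    @property
    def tau_fast(self) -> float:
        """Fast time constant, s."""
        return 1.0 / self.k_fast

    @property
    def tau_slow(self) -> float:
        """Slow time constant, s."""
        return 1.0 / self.k_slow

    @property
    def span_fast(self) -> float:
        return (self.y0 - self.plateau) * self.percent_fast * 0.01

    @property
    def span_slow(self) -> float:
        return (self.y0 - self.plateau) * (100.0 - self.percent_fast) * 0.01

    def value(self, t):
        """Signal at lag ``t`` (s, ≥ 0); vectorized."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = (self.plateau
               + self.span_fast * np.exp(-self.k_fast * t)
               + self.span_slow * np.exp(-self.k_slow * t))
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "model": "biexponential",
            "y0": self.y0,
            "plateau": self.plateau,
            "k_fast_per_s": self.k_fast,
            "k_slow_per_s": self.k_slow,
            "tau_fast_s": self.tau_fast,
            "tau_slow_s": self.tau_slow,
            "percent_fast": self.percent_fast,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiexpFit":
        return cls(y0=d["y0"], plateau=d["plateau"],
                   k_fast=d["k_fast_per_s"], k_slow=d["k_slow_per_s"],
                   percent_fast=d["percent_fast"])


@dataclass(frozen=True)
class MonoexpFit:
    """Single-exponential time-course parameters (e.g. block onset).

    Y(t) = (Y0 − Plateau)·exp(−K·t) + Plateau;  τ_obs = 1/K.
    """

    y0: float
    plateau: float
    k: float

    def __post_init__(self) -> None:
        _require(self.k > 0, f"rate k must be > 0, got {self.k}")

    @property
    def tau_obs(self) -> float:
        """Observed time constant, s (1/k)."""
        return 1.0 / self.k

    def value(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = (self.y0 - self.plateau) * np.exp(-self.k * t) + self.plateau
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "model": "monoexponential",
            "y0": self.y0,
            "plateau": self.plateau,
            "k_per_s": self.k,
            "tau_obs_s": self.tau_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MonoexpFit":
        return cls(y0=d["y0"], plateau=d["plateau"], k=d["k_per_s"])


@dataclass(frozen=True)
class StateBlockModel:
    """Two-receptor-state equilibrium block model.

    Channels partition between resting and fast-inactivated states
    according to an availability Boltzmann h∞(V); the blocker binds the
    two states with different dissociation constants K_r (resting) and
    K_i (inactivated). The apparent dissociation constant at holding
    potential V follows the modulated-receptor equilibrium:

        1 / K_app(V) = h∞(V) / K_r + (1 − h∞(V)) / K_i

    so K_app interpolates between K_r (fully rested) and K_i (fully
    inactivated) and is monotone in the inactivated fraction.
    """

    kd_rest: float
    kd_inact: float
    availability: BoltzmannFit

    def __post_init__(self) -> None:
        _require(self.kd_rest > 0, "kd_rest must be > 0")
        _require(self.kd_inact > 0, "kd_inact must be > 0")
        _require(self.availability.polarity is Polarity.AVAILABILITY,
                 "availability curve must have availability polarity")

    @property
    def fold_ratio(self) -> float:
        """Resting/inactivated affinity ratio K_r / K_i."""
        return self.kd_rest / self.kd_inact

    def fraction_rested(self, vh):
        return self.availability.value(vh)

    def apparent_ic50(self, vh):
        """Apparent IC50 (μM) at holding potential ``vh`` (mV)."""
        f_rest = np.asarray(self.availability.value(vh), dtype=float)
        inv = f_rest / self.kd_rest + (1.0 - f_rest) / self.kd_inact
        out = 1.0 / inv
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "model": "state_block",
            "kd_rest_uM": self.kd_rest,
            "kd_inact_uM": self.kd_inact,
            "fold_ratio": self.fold_ratio,
            "availability": self.availability.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateBlockModel":
        return cls(kd_rest=d["kd_rest_uM"], kd_inact=d["kd_inact_uM"],
                   availability=BoltzmannFit.from_dict(d["availability"]))


# -- module-level functional forms ------------------------------------------

def hill_inhibition(c, fit: HillFit):
    """Fraction of current inhibited at concentration ``c`` (μM)."""
    return fit.inhibition(c)


def boltzmann(vm, fit: BoltzmannFit):
    """Boltzmann gating fraction at membrane potential ``vm`` (mV)."""
    return fit.value(vm)


def biexp_recovery(t, fit: BiexpFit):
    """Biexponential signal at lag ``t`` (s)."""
    return fit.value(t)


def monoexp(t, fit: MonoexpFit):
    """Monoexponential signal at time ``t`` (s)."""
    return fit.value(t)


def apparent_ic50(vh, model: StateBlockModel):
    """Apparent IC50 (μM) of a state-dependent blocker at holding ``vh`` (mV)."""
    return model.apparent_ic50(vh)


_MODEL_CLASSES = {
    "hill": HillFit,
    "boltzmann": BoltzmannFit,
    "biexponential": BiexpFit,
    "monoexponential": MonoexpFit,
    "state_block": StateBlockModel,
}


def fit_to_json(fit) -> str:
    """Serialize any fit object to a JSON string with unit-bearing keys."""
    return json.dumps(fit.to_dict(), indent=2, sort_keys=True)


def fit_from_json(s: str):
    """Inverse of :func:`fit_to_json`."""
    d = json.loads(s)
    try:
        cls = _MODEL_CLASSES[d["model"]]
    except KeyError as e:
        raise ValueError(f"unknown model tag in JSON: {d.get('model')!r}") from e
    return cls.from_dict(d)
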