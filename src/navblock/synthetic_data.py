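"""Synthetic voltage-clamp data with the structure the pipeline assumes.

Every generator emits the same tabular schemas the plate pipeline
consumes, so the full stack — generate, normalize, pool, fit — can be
exercised end to end without recordings. The statistical structure
emulated:

* concentration–response plates with one concentration per cell,
  vehicle wells running down monoexponentially, a drug epoch relaxing
  toward its Hill-predicted equilibrium, and a saturating full-block
  epoch that defines the zero of the inhibition scale;
* peak I/V families and steady-state fast-inactivation (SSFI) prepulse
  families following G·(V − E_Na)·Boltzmann;
* two-pulse recovery-from-inactivation series (biexponential);
* block-onset time courses at fixed holding (monoexponential, with the
  observed time constant saturating at high concentration);
* the 180-pulse-per-holding-potential state-dependence protocol, whose
  equilibrium block at each holding follows the resting/inactivated
  two-state model.

Noise model: additive Gaussian (σ, default 0.03) on normalized peak
currents plus a multiplicative lognormal cell-size factor (σ_log,
default 0.2) on raw amplitudes — chosen to reproduce standard errors
of roughly 10% at the usual 3–15 cells per condition. Every generator
derives all randomness from ``config.seed``; the same seed yields
bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults
from .curve_models import (
    BiexpFit,
    BoltzmannFit,
    HillFit,
    MonoexpFit,
    Polarity,
    StateBlockModel,
)
from .io import CELL_COLUMNS, SWEEP_COLUMNS

__all__ = [
    "SynthConfig",
    "onset_tau",
    "gen_plate",
    "gen_gating_family",
    "gen_recovery_series",
    "gen_onset_series",
    "gen_state_dependence_run",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generating ("true") parameters and experiment-design settings."""

    seed: int = 0
    channel: str = defaults.DEFAULT_CHANNEL
    hill: HillFit = field(
        default_factory=lambda: defaults.HILL_BY_CHANNEL[defaults.DEFAULT_CHANNEL])
    activation: BoltzmannFit = field(
        default_factory=lambda: defaults.ACTIVATION_VEHICLE)
    availability: BoltzmannFit = field(
        default_factory=lambda: defaults.AVAILABILITY_VEHICLE)
    state_model: StateBlockModel = field(
        default_factory=lambda: defaults.STATE_MODEL_TRUE)
    noise_sigma: float = 0.03          # additive, on normalized currents
    cell_size_sigma_log: float = 0.2   # multiplicative lognormal on amplitude
    rundown_per_min: float = 0.02      # compound-independent decay rate
    cells_per_conc: int = 6
    qc_fail_rate: float = 0.1
    temp_C: float = 28.0
    e_rev_mV: float = defaults.E_REV_NA_MV
    baseline_peak_pA: float = defaults.BASELINE_PEAK_PA
    full_block_residual: float = defaults.FULL_BLOCK_RESIDUAL
    plate_onset_tau_s: float = 40.0    # drug-epoch equilibration

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.cell_size_sigma_log < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.cells_per_conc < 1:
            raise ValueError("cells_per_conc must be ≥1")


def _sweep_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def _cell_amp(cfg: SynthConfig, rng) -> float:
    """Cell-size lognormal scatter on the nominal peak amplitude."""
    factor = math.exp(rng.normal(0.0, cfg.cell_size_sigma_log)) \
        if cfg.cell_size_sigma_log > 0 else 1.0
    return cfg.baseline_peak_pA * factor


def _rundown(cfg: SynthConfig, t_s: float) -> float:
    return math.exp(-cfg.rundown_per_min * t_s / 60.0)


def _qc_metrics(cfg: SynthConfig, rng, amp: float) -> tuple[float, float, float]:
    """(Rm, Rs, amplitude) — a qc_fail_rate fraction of cells fail one gate."""
    if rng.random() < cfg.qc_fail_rate:
        mode = rng.integers(3)
        if mode == 0:
            return float(rng.uniform(100, 450)), float(rng.uniform(2, 8)), amp
        if mode == 1:
            return float(rng.uniform(600, 2000)), float(rng.uniform(12, 20)), amp
        return (float(rng.uniform(600, 2000)), float(rng.uniform(2, 8)),
                amp * 300.0 / abs(cfg.baseline_peak_pA))
    return float(rng.uniform(600, 2000)), float(rng.uniform(2, 8)), amp


def gen_plate(cfg: SynthConfig,
              concentrations=(0.3, 1.0, 3.3, 10.0, 30.0), *,
              baseline_s: float = 60.0, drug_s: float = 600.0,
              sample_interval_s: float = 5.0,
              n_vehicle_cells: int | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentration–response plate: (sweep table, cell QC table).

    Each drug cell sees a single concentration: a baseline epoch in
    vehicle, a drug epoch relaxing monoexponentially toward the
    Hill-predicted equilibrium inhibition, and a final full-block epoch
    (saturating blocker leaving ``full_block_residual`` of the
    current). Vehicle cells run the same schedule with no compound, so
    time-matched rundown can be estimated from them.
    """
    rng = np.random.default_rng(cfg.seed)
    n_veh = cfg.cells_per_conc if n_vehicle_cells is None else n_vehicle_cells
    conditions = [("vehicle", 0.0)] * n_veh
    for c in concentrations:
        conditions += [("drug", float(c))] * cfg.cells_per_conc

    sigma = cfg.noise_sigma
    resid = cfg.full_block_residual
    t_base = np.arange(0.0, baseline_s, sample_interval_s)
    t_drug = np.arange(0.0, drug_s + 1e-9, sample_interval_s)
    rows, cells = [], []
    for idx, (role, conc) in enumerate(conditions):
        cid = f"C{idx:03d}"
        well = f"{chr(ord('A') + idx % 16)}{idx // 16 + 1:02d}"
        amp = _cell_amp(cfg, rng)
        rm, rs, amp = _qc_metrics(cfg, rng, amp)
        cells.append({"cell_id": cid, "rm_MOhm": rm, "rs_MOhm": rs,
                      "cap_pF": float(rng.uniform(5, 20)),
                      "baseline_peak_pA": amp})
        inh_eq = cfg.hill.inhibition(conc) if role == "drug" else 0.0

        def emit(epoch, t, frac, compound, c_um, sweep0):
            for j, (ti, fi) in enumerate(zip(t, frac)):
                noisy = fi + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
                rows.append({
                    "cell_id": cid, "well": well, "protocol": "conc_response",
                    "epoch": epoch, "sweep": sweep0 + j, "time_s": float(ti),
                    "holding_mV": -45.0, "test_mV": -20.0, "prepulse_ms": 0.0,
                    "peak_pA": noisy * amp * _rundown(cfg, ti),
                    "steady_pA": 0.0, "temp_C": cfg.temp_C,
                    "compound": compound, "conc_uM": c_um,
                })

        emit("baseline", t_base, np.ones_like(t_base), "vehicle", 0.0, 0)
        t0 = baseline_s
        inh_t = inh_eq * (1.0 - np.exp(-t_drug / cfg.plate_onset_tau_s))
        frac = 1.0 - inh_t * (1.0 - resid)
        emit("drug", t_drug + t0, frac,
             "CBD" if role == "drug" else "vehicle", conc, len(t_base))
        t1 = t0 + drug_s + sample_interval_s
        t_fb = np.arange(0.0, 5 * sample_interval_s, sample_interval_s)
        emit("full_block", t_fb + t1, np.full_like(t_fb, resid), "TTX", 0.0,
             len(t_base) + len(t_drug))
    return _sweep_frame(rows), pd.DataFrame(cells, columns=CELL_COLUMNS)


def gen_gating_family(cfg: SynthConfig, kind, *, fit: BoltzmannFit = None,
                      prepulse_ms: float = 500.0, cell_id: str = "C000",
                      conductance_nS: float | None = None) -> pd.DataFrame:
    """Peak I/V family (activation) or SSFI prepulse family (availability).

    Activation: test potentials −100…+80 mV in 5-mV steps, peak current
    G·act(V)·(V − E_Na). Availability: prepulse potentials −120…+10 mV
    in 5-mV steps (duration ``prepulse_ms``), test-pulse current
    I_max·avail(V_pre).
    """
    kind = Polarity(kind)
    rng = np.random.default_rng(cfg.seed)
    if fit is None:
        fit = cfg.activation if kind is Polarity.ACTIVATION else cfg.availability
    if fit.polarity is not kind:
        raise ValueError(f"fit polarity {fit.polarity} does not match {kind}")
    rows = []
    if kind is Polarity.ACTIVATION:
        g = (abs(cfg.baseline_peak_pA) / abs(cfg.e_rev_mV)
             if conductance_nS is None else conductance_nS)
        volts = np.arange(-100.0, 80.0 + 1e-9, 5.0)
        for i, v in enumerate(volts):
            frac = fit.value(v) + (rng.normal(0.0, cfg.noise_sigma)
                                   if cfg.noise_sigma > 0 else 0.0)
            rows.append({
                "cell_id": cell_id, "well": "A01", "protocol": "iv_family",
                "epoch": "baseline", "sweep": i, "time_s": float(i),
                "holding_mV": -120.0, "test_mV": float(v), "prepulse_ms": 0.0,
                "peak_pA": g * frac * (v - cfg.e_rev_mV), "steady_pA": 0.0,
                "temp_C": cfg.temp_C, "compound": "vehicle", "conc_uM": 0.0,
            })
    else:
        amp = cfg.baseline_peak_pA
        volts = np.arange(-120.0, 10.0 + 1e-9, 5.0)
        for i, v in enumerate(volts):
            frac = fit.value(v) + (rng.normal(0.0, cfg.noise_sigma)
                                   if cfg.noise_sigma > 0 else 0.0)
            rows.append({
                "cell_id": cell_id, "well": "A01", "protocol": "ssfi",
                "epoch": "baseline", "sweep": i, "time_s": float(i),
                "holding_mV": -120.0, "test_mV": -20.0,
                "prepulse_ms": prepulse_ms, "prepulse_mV": float(v),
                "peak_pA": amp * frac, "steady_pA": 0.0,
                "temp_C": cfg.temp_C, "compound": "vehicle", "conc_uM": 0.0,
            })
    df = pd.DataFrame(rows)
    cols = SWEEP_COLUMNS + [c for c in df.columns if c not in SWEEP_COLUMNS]
    return df.loc[:, cols]


def gen_recovery_series(cfg: SynthConfig, prepulse_s: float = 10.0, *,
                        condition: str = "cbd", fit: BiexpFit = None,
                        n_lags: int = 20, lag_min_s: float = 1e-3,
                        lag_max_s: float = 60.0) -> pd.DataFrame:
    """Two-pulse recovery-from-inactivation series on a log-spaced lag grid.

    Fractional availability follows the configured biexponential for
    (condition, prepulse duration); defaults cover vehicle and drug at
    0.3-s and 10-s prepulses.
    """
    rng = np.random.default_rng(cfg.seed)
    if fit is None:
        try:
            fit = defaults.RECOVERY_BIEXP[(condition, prepulse_s)]
        except KeyError:
            raise KeyError(f"no default recovery parameters for "
                           f"({condition!r}, {prepulse_s} s); pass fit=")
    if abs(fit.y0 - fit.plateau) < 1e-12:
        raise ValueError("degenerate recovery series: zero span "
                         "(y0 equals plateau)")
    lags = np.geomspace(lag_min_s, lag_max_s, n_lags)
    frac = fit.value(lags)
    if cfg.noise_sigma > 0:
        frac = frac + rng.normal(0.0, cfg.noise_sigma, size=lags.shape)
    return pd.DataFrame({"lag_s": lags, "fraction_recovered": frac,
                         "prepulse_s": prepulse_s, "condition": condition})


def onset_tau(conc_uM: float, temp_C: float,
              table: dict = None) -> float:
    """Observed block-onset time constant (s) for a concentration.

    Log-linear interpolation in concentration within the reference
    table, clamped at the ends — onset saturates at a minimum τ at
    high concentration instead of speeding up indefinitely.
    """
    table = defaults.ONSET_TAU_S if table is None else table
    if temp_C not in table:
        raise KeyError(f"no onset kinetics at {temp_C} °C; "
                       f"have {sorted(table)}")
    by_conc = table[temp_C]
    concs = np.array(sorted(by_conc))
    taus = np.array([by_conc[c] for c in concs])
    return float(np.interp(math.log(conc_uM), np.log(concs), taus))


def gen_onset_series(cfg: SynthConfig,
                     concentrations=(6.3, 12.5, 25.0, 50.0), *,
                     temp_C: float = 20.0, duration_s: float = 120.0,
                     rate_hz: float = 1.0) -> pd.DataFrame:
    """Block-onset time courses: normalized current after compound addition.

    Current decays monoexponentially from 1 toward the Hill-predicted
    equilibrium (IC50 at the given temperature, slope fixed across
    temperatures), with τ_obs from the concentration/temperature map.
    """
    rng = np.random.default_rng(cfg.seed)
    if temp_C in defaults.IC50_UM_BY_TEMP_C:
        hill = HillFit(defaults.IC50_UM_BY_TEMP_C[temp_C],
                       defaults.TEMP_HILL_SLOPE, fixed_slope=True)
    else:
        hill = cfg.hill
    t = np.arange(0.0, duration_s + 1e-9, 1.0 / rate_hz)
    frames = []
    for c in concentrations:
        tau = onset_tau(c, temp_C)
        fit = MonoexpFit(y0=1.0, plateau=1.0 - hill.inhibition(c), k=1.0 / tau)
        y = fit.value(t)
        if cfg.noise_sigma > 0:
            y = y + rng.normal(0.0, cfg.noise_sigma, size=t.shape)
        frames.append(pd.DataFrame({
            "time_s": t, "norm_current": y, "conc_uM": float(c),
            "temp_C": temp_C, "tau_true_s": tau,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_state_dependence_run(cfg: SynthConfig,
                             concentrations=(1.0, 2.0, 5.0, 10.0, 20.0, 50.0),
                             *, holdings=(-100.0, -90.0, -80.0, -70.0),
                             n_pulses: int = 180, rate_hz: float = 1.0,
                             tau_block_s: float = 30.0,
                             n_baseline: int = 5) -> pd.DataFrame:
    """Pulse-train state-dependence protocol.

    For each holding potential the channel is pulsed ``n_pulses`` times
    at ``rate_hz``; per-pulse normalized peaks relax monoexponentially
    (τ = ``tau_block_s``) toward the equilibrium block given by the
    Hill curve evaluated at the state model's apparent IC50 for that
    holding. With τ below 45 s the pulse-180 block sits within 1% of
    equilibrium. ``n_baseline`` pre-compound pulses define the baseline.
    """
    rng = np.random.default_rng(cfg.seed)
    amp = cfg.baseline_peak_pA
    h = cfg.hill.h
    rows = []
    for vh in holdings:
        k_app = cfg.state_model.apparent_ic50(vh)
        for c in concentrations:
            inh_eq = HillFit(k_app, h).inhibition(c)
            for p in range(-n_baseline, n_pulses):
                t = p / rate_hz
                if p < 0:
                    frac, epoch = 1.0, "baseline"
                else:
                    frac = 1.0 - inh_eq * (1.0 - math.exp(-t / tau_block_s))
                    epoch = "drug"
                if cfg.noise_sigma > 0:
                    frac += rng.normal(0.0, cfg.noise_sigma)
                rows.append({"holding_mV": float(vh), "conc_uM": float(c),
                             "pulse": p + 1, "epoch": epoch,
                             "time_s": t, "peak_pA": frac * amp})
    return pd.DataFrame(rows)
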