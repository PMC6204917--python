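"""End-to-end synthetic reanalysis producing the headline quantities.

Each function regenerates the inputs it needs with the synthetic-data
module (noiseless unless noted), pushes them through the pipeline and
fitters, and returns the measured quantity — nothing is read off a
constant. ``build_report`` collects everything into one dict for the
CLI ``report`` subcommand.
"""

from __future__ import annotations

import numpy as np

from . import defaults
from .curve_models import BoltzmannFit, HillFit, MonoexpFit, Polarity
from .fitting import (
    fit_biexponential,
    fit_boltzmann,
    fit_hill,
    fit_monoexponential,
    fit_state_model,
)
from .neuron_sim import StimulusProtocol, apply_drug_condition, cortical_neuron, simulate
from .plate_pipeline import (
    availability_curve,
    percent_block_from_densities,
    v_half_shift,
)
from .synthetic_data import SynthConfig, gen_gating_family, gen_recovery_series

__all__ = ["build_report"]


def conductance_block_percent() -> float:
    """Percent of peak Na conductance lost, from mean current densities."""
    return percent_block_from_densities(defaults.DENSITY_VEHICLE_PA_PF,
                                        defaults.DENSITY_CBD_PA_PF)


def _refit_availability(fit: BoltzmannFit, seed: int) -> BoltzmannFit:
    cfg = SynthConfig(seed=seed, noise_sigma=0.0)
    fam = gen_gating_family(cfg, Polarity.AVAILABILITY, fit=fit)
    curve = availability_curve(fam["prepulse_mV"], fam["peak_pA"])
    res = fit_boltzmann(curve)
    if not res.converged:
        raise RuntimeError(f"availability refit failed: {res.message}")
    return res.params


def ssfi_shift_mV(vehicle: BoltzmannFit, drug: BoltzmannFit, *,
                  seed: int = 0) -> float:
    """Drug-induced SSFI midpoint shift via regenerate-and-refit (signed)."""
    a = _refit_availability(vehicle, seed)
    b = _refit_availability(drug, seed + 1)
    return v_half_shift(a, b)


def percent_inactivated_at(vh_mV: float, fit: BoltzmannFit) -> float:
    """Percent of channels inactivated at a holding potential."""
    return 100.0 * (1.0 - fit.value(vh_mV))


def hill_refit_ic50(truth: HillFit, *, fix_slope=None,
                    c_min: float = 0.1, c_max: float = 30.0,
                    n: int = 8) -> float:
    """IC50 recovered from a noiseless log-spaced inhibition curve."""
    c = np.geomspace(c_min, c_max, n)
    res = fit_hill(c, truth.inhibition(c), fix_slope=fix_slope)
    if not res.converged:
        raise RuntimeError(f"Hill refit failed: {res.message}")
    return res.params.ic50


def recovery_refit_tau_slow(*, condition: str = "cbd",
                            prepulse_s: float = 10.0,
                            seed: int = 0) -> float:
    """Slow recovery time constant from a regenerated noiseless series."""
    cfg = SynthConfig(seed=seed, noise_sigma=0.0)
    ser = gen_recovery_series(cfg, prepulse_s, condition=condition)
    res = fit_biexponential(ser["lag_s"], ser["fraction_recovered"])
    if not res.converged:
        raise RuntimeError(f"biexponential refit failed: {res.message}")
    return res.params.tau_slow


def onset_refit_tau(tau_s: float, *, plateau: float = 0.1,
                    duration_s: float = 120.0) -> float:
    """τ_obs recovered from a noiseless 1-Hz onset trace."""
    t = np.arange(0.0, duration_s + 1e-9, 1.0)
    truth = MonoexpFit(y0=1.0, plateau=plateau, k=1.0 / tau_s)
    res = fit_monoexponential(t, truth.value(t))
    if not res.converged:
        raise RuntimeError(f"onset refit failed: {res.message}")
    return res.params.tau_obs


def state_model_fold_ratio() -> float:
    """K_rest/K_inact from the reference apparent-IC50-vs-holding points."""
    res = fit_state_model(defaults.APPARENT_IC50_BY_HOLDING,
                          defaults.AVAILABILITY_VEHICLE)
    if not res.converged:
        raise RuntimeError(f"state-model fit failed: {res.message}")
    return res.params.fold_ratio


def excitability_comparison(*, na_block: float = 0.5, k_block: float = 0.5,
                            inact_shift: float = -8.1) -> dict:
    """Vehicle vs drug spike output of the cortical-neuron model."""
    model = cortical_neuron()
    protocol = StimulusProtocol.default_family()
    veh = simulate(model, protocol)
    drug = simulate(apply_drug_condition(model, na_block, k_block,
                                         inact_shift), protocol)
    return {
        "vehicle_per_step": veh.per_step_counts,
        "drug_per_step": drug.per_step_counts,
        "vehicle_total": veh.total_spikes,
        "drug_total": drug.total_spikes,
        "vehicle_first_peak_mV": veh.first_spike_peak,
        "drug_first_peak_mV": drug.first_spike_peak,
        "vehicle_first_threshold_mV": veh.first_spike_threshold,
        "drug_first_threshold_mV": drug.first_spike_threshold,
    }


def build_report(seed: int = 0) -> dict:
    """Recompute every headline quantity from regenerated synthetic data."""
    d = defaults
    shift_hek = ssfi_shift_mV(d.AVAILABILITY_VEHICLE, d.AVAILABILITY_CBD,
                              seed=seed)
    shift_ipsc = ssfi_shift_mV(d.SSFI_IPSC_VEHICLE, d.SSFI_IPSC_CBD,
                               seed=seed + 10)
    inact_wt = percent_inactivated_at(-45.0, d.SSFI_WT_HNAV11)
    inact_mut = percent_inactivated_at(-45.0, d.SSFI_F1763A)
    fold_mut = (d.HILL_BY_CHANNEL["hNav1.1-F1763A"].ic50
                / d.HILL_BY_CHANNEL["hNav1.1"].ic50)
    taus20 = d.ONSET_TAU_S[20.0]
    return {
        "conductance_block_percent": conductance_block_percent(),
        "ssfi_shift_hek_mV": shift_hek,
        "ssfi_shift_ipsc_mV": shift_ipsc,
        "percent_inactivated_at_-45mV": {
            "wt": inact_wt, "pore_mutant": inact_mut,
            "min": min(inact_wt, inact_mut)},
        "pore_mutant_ic50_fold_change": fold_mut,
        "hill_ic50_refit_nachbac_uM": hill_refit_ic50(
            d.HILL_BY_CHANNEL["NaChBac"]),
        "hill_ic50_refit_20C_fixed_slope_uM": hill_refit_ic50(
            HillFit(d.IC50_UM_BY_TEMP_C[20.0], d.TEMP_HILL_SLOPE),
            fix_slope=d.TEMP_HILL_SLOPE),
        "recovery_tau_slow_refit_s": recovery_refit_tau_slow(seed=seed),
        "onset_tau_refit_25uM_20C_s": onset_refit_tau(taus20[25.0]),
        "onset_tau_saturates": taus20[50.0] >= taus20[25.0] * 0.9,
        "state_model_fold_ratio": state_model_fold_ratio(),
        "excitability": excitability_comparison(),
    }
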