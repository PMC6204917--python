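"""Reference parameter sets used as generator defaults.

These are the "true" values the synthetic-data module emulates: fitted
cannabidiol (CBD) potencies, gating-curve parameters, recovery and
onset kinetics for heterologously expressed voltage-gated sodium
channels, plus the bacterial homolog NaChBac and the potassium channel
Kv2.1. Holding them in one versioned module keeps every round-trip
test and worked example pointing at the same numbers.

Values marked "assumed" are not measured quantities; they fill slots
(e.g. the fast-component fraction of recovery) that the reference
measurements constrain only graphically.
"""

from __future__ import annotations

from .curve_models import (
    BiexpFit,
    BoltzmannFit,
    HillFit,
    Polarity,
    StateBlockModel,
)

# --- concentration–response (inactivated-state holding) --------------------
# IC50 μM / Hill slope per channel at the standard depolarized holding.
HILL_BY_CHANNEL = {
    "hNav1.1": HillFit(ic50=2.5, h=2.0),
    "hNav1.1-F1763A": HillFit(ic50=4.8, h=4.1),   # local-anesthetic-site mutant
    "hNav1.6": HillFit(ic50=3.0, h=3.1),
    "hNav1.2-manual": HillFit(ic50=1.3, h=2.1),   # manual patch, ~20 °C
    "NaChBac": HillFit(ic50=1.5, h=2.8),
    "NaChBac-55mV": HillFit(ic50=0.24, h=2.8),
    "Kv2.1": HillFit(ic50=3.7, h=1.1),
}
DEFAULT_CHANNEL = "hNav1.1"

# N1768D inactivation-deficient mutant: peak vs persistent current potency.
HILL_N1768D_PEAK = HillFit(ic50=10.0, h=2.0)
HILL_N1768D_PERSISTENT = HillFit(ic50=6.4, h=1.3)

# --- temperature dependence of potency and onset kinetics ------------------
IC50_UM_BY_TEMP_C = {20.0: 2.1, 28.0: 3.4, 33.0: 4.7}
TEMP_HILL_SLOPE = 3.4  # slope held fixed across temperatures

# Observed block-onset time constants τ_obs (s) by temperature and
# concentration; τ_obs saturates at a minimum at high concentration.
ONSET_TAU_S = {
    20.0: {6.3: 51.0, 12.5: 42.2, 25.0: 21.6, 50.0: 23.3},
    28.0: {6.3: 162.6, 12.5: 87.7, 25.0: 42.8, 50.0: 30.4},
    33.0: {6.3: 299.0, 12.5: 137.0, 25.0: 79.2, 50.0: 84.1},
}

# --- gating curves (hNav1.1, whole-cell) -----------------------------------
ACTIVATION_VEHICLE = BoltzmannFit(-41.9, 3.6, Polarity.ACTIVATION)
ACTIVATION_CBD = BoltzmannFit(-40.3, 7.2, Polarity.ACTIVATION)
AVAILABILITY_VEHICLE = BoltzmannFit(-69.7, 5.0, Polarity.AVAILABILITY)
AVAILABILITY_CBD = BoltzmannFit(-77.8, 5.8, Polarity.AVAILABILITY)

# Inactivation midpoints used for the pore-mutant comparison: both WT and
# F1763A are majority-inactivated at the −45 mV holding potential.
SSFI_WT_HNAV11 = BoltzmannFit(-62.0, 7.2, Polarity.AVAILABILITY)
SSFI_F1763A = BoltzmannFit(-49.3, 6.4, Polarity.AVAILABILITY)

# iPSC-neuron SSFI before/after CBD perfusion (~16 mV hyperpolarization).
SSFI_IPSC_VEHICLE = BoltzmannFit(-50.0, 6.4, Polarity.AVAILABILITY)
SSFI_IPSC_CBD = BoltzmannFit(-66.1, 8.1, Polarity.AVAILABILITY)

# --- peak current densities (pA/pF), hNav1.1 at 3.3 μM CBD -----------------
DENSITY_VEHICLE_PA_PF = -75.3
DENSITY_CBD_PA_PF = -6.8

# --- recovery from inactivation (hNav1.6, 3.7 μM CBD) ----------------------
# keyed by (condition, prepulse seconds); percent_fast is assumed (the
# component fractions are constrained only graphically).
RECOVERY_BIEXP = {
    ("vehicle", 0.3): BiexpFit(y0=0.0, plateau=1.0, k_fast=1 / 0.00173,
                               k_slow=1 / 0.0688, percent_fast=70.0),
    ("cbd", 0.3): BiexpFit(y0=0.0, plateau=1.0, k_fast=1 / 0.00654,
                           k_slow=1 / 0.516, percent_fast=70.0),
    ("vehicle", 10.0): BiexpFit(y0=0.0, plateau=1.0, k_fast=1 / 0.0715,
                                k_slow=1 / 0.696, percent_fast=70.0),
    ("cbd", 10.0): BiexpFit(y0=0.0, plateau=1.0, k_fast=1 / 0.272,
                            k_slow=1 / 8.72, percent_fast=50.0),
}

# --- state-dependent block --------------------------------------------------
# Apparent IC50 (μM) at four holding potentials, pulse 180 of a 1-Hz train.
APPARENT_IC50_BY_HOLDING = [(-100.0, 12.7), (-90.0, 10.3),
                            (-80.0, 6.7), (-70.0, 2.9)]

# Generator truth for round-trip tests: ~10-fold higher affinity for the
# inactivated state.
STATE_MODEL_TRUE = StateBlockModel(kd_rest=12.0, kd_inact=1.2,
                                   availability=AVAILABILITY_VEHICLE)

# --- recording conventions --------------------------------------------------
E_REV_NA_MV = 65.0          # Na reversal used for conductance transforms
BASELINE_PEAK_PA = -1000.0  # nominal healthy-cell peak current
FULL_BLOCK_RESIDUAL = 0.02  # fraction of current left in saturating blocker
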