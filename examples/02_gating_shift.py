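"""Steady-state fast inactivation before and after drug.

Regenerates SSFI prepulse families for the vehicle and drug conditions,
refits the availability Boltzmann, and reports the midpoint shift — the
signature of a blocker that stabilizes the inactivated state.
"""

from navblock import SynthConfig, availability_curve, fit_boltzmann, gen_gating_family
from navblock.curve_models import Polarity
from navblock.defaults import AVAILABILITY_CBD, AVAILABILITY_VEHICLE
from navblock.plate_pipeline import v_half_shift

cfg = SynthConfig(seed=7, noise_sigma=0.0)
fits = {}
for label, truth in [("vehicle", AVAILABILITY_VEHICLE),
                     ("drug", AVAILABILITY_CBD)]:
    fam = gen_gating_family(cfg, Polarity.AVAILABILITY, fit=truth)
    curve = availability_curve(fam["prepulse_mV"], fam["peak_pA"])
    fits[label] = fit_boltzmann(curve).params
    print(f"{label:8s}: V1/2 = {fits[label].v_half:7.2f} mV, "
          f"k = {fits[label].k:.2f} mV")

shift = v_half_shift(fits["vehicle"], fits["drug"])
print(f"midpoint shift = {shift:+.2f} mV "
      "(negative = hyperpolarizing: channels inactivate more readily)")
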