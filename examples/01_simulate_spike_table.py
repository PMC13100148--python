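"""Simulate a small two-condition experiment and inspect its structure.

Builds a 20-neuron spike table (two timescale classes, 6x4 stimulus grid,
20 trials per location per stimulus type per condition) and prints the
table shapes, the trial event times, and the ground-truth parameters of
one neuron.
"""

import spiketau as st

config = st.small_config(n_neurons_short=10, n_neurons_long=10, seed=1)
table, truth = st.simulate_experiment(config)

print(f"neurons: {len(table.neurons)}  trials: {len(table.trials)}  "
      f"spikes: {len(table.spikes)}")
first = table.trials.iloc[0]
print(f"trial events (ms): fixation_on={first['fixation_on']:.0f}  "
      f"stimulus_on={first['stimulus_on']:.0f}  "
      f"stimulus_off={first['stimulus_off']:.0f}  trial_end={first['trial_end']:.0f}")
row = truth.params.iloc[0]
print(f"neuron 0: class={row['class_label']}  true tau={row['true_tau']:.1f} ms "
      f"(inactivation: {row['true_tau_inactivation']:.1f} ms)  "
      f"RF peak location={row['rf_peak']}  baseline rate={row['baseline_rate']:.1f} sp/s")
# The trial/spike tables round-trip through plain CSV for downstream stages:
# st.write_spike_table(table, "spike_table/") / st.read_spike_table("spike_table/")
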