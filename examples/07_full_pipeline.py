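"""Run the whole analysis pipeline on a simulated experiment.

Simulation -> timescales (both conditions) -> bimodality test and
classification -> indices/onsets -> robust regression with permutation
p-values -> class-stratified decoding -> inactivation contrasts.  All
artifacts are written as delimited text under the output directory, with
run_meta.json recording the package version, configuration hash and seed.

Scaled down for a quick run; drop the overrides for a full-scale analysis.
"""

import json

import spiketau as st

config = st.RunConfig(
    out_dir="scratch/pipeline_demo",
    sim=st.small_config(n_neurons_short=40, n_neurons_long=40, seed=21),
    seed=21,
    n_perm=199,          # default 10,000
    n_bootstrap=99,      # default 500
    run_decoding=False,  # see 06_population_decoding.py for the decoding stage
)
summary = st.run_pipeline(config)

print(json.dumps(
    {
        "n_neurons": summary["n_neurons"],
        "timescales": summary["timescales"],
        "modality": summary.get("modality"),
        "class_sizes": summary.get("class_sizes"),
        "onset_detection_rate": round(summary["onset_detection_rate"], 2),
    },
    indent=2, default=str,
))
print(f"artifacts in {config.out_dir}/")
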