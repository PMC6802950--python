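"""Regenerate the model-prediction summary (both codes) at a small scale.

Runs the labelled-line and hemifield sweeps over a reduced grid, writes
tidy CSVs plus quick-look plots under scratch/, and prints the RMS-bias
profile of each model -- flat for the place code, decreasing with level
for the rate code.
"""

from itdcode import RunConfig, reproduce_fig1, rms_bias

config = RunConfig(which="fig1_both", seed=1, output_dir="scratch/fig1_demo",
                   n_rep=25, n_boot=50, make_plots=True,
                   itds_us=(-375.0, -225.0, -75.0, 75.0, 225.0, 375.0))
results = reproduce_fig1(config)

for name, summary in results.items():
    rb = rms_bias(summary)
    profile = "  ".join(f"{lv:g}dB:{v:5.1f}" for lv, v in rb.items())
    print(f"{name:13s} RMS bias vs top level (us):  {profile}")
print(f"\nCSV summaries and plots in {config.output_dir}/")
# labelled line: no trend of RMS bias with level (level-invariant means);
# hemifield: RMS bias shrinks as level rises (medial bias fades)
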