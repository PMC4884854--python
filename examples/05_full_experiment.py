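"""End-to-end compression-enhanced elastography experiment (reduced size).

Runs the complete pipeline — compression, shear-wave simulation,
directional filter, time-of-flight reconstruction and ROI reporting — at
two compression levels on a coarsened configuration, and prints the
contrast table.  The contrast (G_tumor - G_surr)/G_surr grows with
compression because the tumor strain-hardens faster than the background.

For the full-resolution four-level reproduction run either
``nlswei run --config paper --out results`` or ``python
scripts/acceptance.py --seed 1 --out results/acceptance.json`` (minutes).
"""

from nlswei import fast_config, run_experiment, speed_increase_ratio

config = fast_config(levels=[0.0, 0.15])
report = run_experiment(config, log=print)

cols = ["level", "g_tumor", "g_surr", "contrast", "strain_tumor", "strain_surr"]
print(report.table[cols].to_string(index=False))
ratio = speed_increase_ratio(report, 0.0, 0.15)
print(f"tumor/background speed-increase ratio (0 -> 15%): {ratio:.2f}")
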