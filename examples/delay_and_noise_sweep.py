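"""Quantify the documentation-delay effect with a parameter sweep.

Notes that reach the record late bound how early a text-based screener
can recommend a patient. Sweeping the delay mean with paired seeds and
measuring recall at a fixed early cutoff makes the effect visible; final
-state metrics stay high because the notes do arrive eventually.
"""

from trialscreen import GeneratorConfig
from trialscreen.metrics import noise_sweep, sweep_summary

base = GeneratorConfig(n_patients=120, window_minutes=60.0)
sweep = noise_sweep(
    {"delay_mean_minutes": [0.0, 10.0, 30.0]},
    seeds=[11, 12, 13],
    base_config=base,
    cutoff_minutes=70.0,
)
summary = sweep_summary(sweep, ["delay_mean_minutes"])

print(summary[["delay_mean_minutes", "cutoff_recall_mean", "cutoff_recall_std",
               "micro_f_mean"]].to_string(index=False))
print()
print("Recall at the 70-minute cutoff falls as the delay mean grows — "
      "eligible patients whose qualifying note is still unfiled cannot be "
      "recommended yet — while end-of-stream micro F is unaffected.")
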