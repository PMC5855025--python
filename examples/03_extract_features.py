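"""Windowed feature extraction from the phasic component.

Segments the phasic conductance into 5 s windows with 4 s overlap and
computes the 18 spectro-temporal features per window.
"""

from edadrive import (DEFAULT_PROFILES, SynthConfig, decompose,
                      extract_table, preprocess, segment,
                      synthesize_recording)

rows = []
for condition in ("normal", "phone", "text"):
    rec, _ = synthesize_recording(SynthConfig(seed=11),
                                  DEFAULT_PROFILES[condition])
    clean = preprocess(rec)
    dec = decompose(clean)
    wins = segment(dec.sc_phasic, clean.fs, subject_id="s00",
                   condition=condition)
    rows.append(extract_table(wins, total_task_s=clean.duration_s,
                              peak_threshold=0.001))

import pandas as pd

table = pd.concat(rows, ignore_index=True)
print(f"{len(table)} windows x {18} features "
      f"({len(table) // 3} windows per 2 min recording)\n")
summary = table.groupby("condition")[["f1", "f2", "f4", "f6", "f7"]].mean()
print(summary.round(4))
print("\nf1 = mean phasic level, f2 = variance, f4 = window maximum, "
      "f6 = number of detected SCR peaks, f7 = summed peak amplitudes.  "
      "All grow with distraction load, mirroring the denser impulse "
      "bursts of the phone and text conditions.")
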