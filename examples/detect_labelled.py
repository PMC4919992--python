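"""Screen a simulated paired experiment for isotope-labelled taxa.

Simulates 3 replicate gradients per treatment for a 50-taxon community in
which 5 taxa (>=2% abundance) are fully ¹³C-labelled, then runs the
buoyant-density shift screen and prints the per-taxon calls.
"""

import numpy as np

from sipshift import GradientConfig, detect_labelled, make_community, shift_table, total_shift_check
from sipshift.evaluate import paired_experiment

taxa = make_community(50, 5, rng=np.random.default_rng(11))
truth = sorted(t.taxon_id for t in taxa if t.labelled)
runs13, runs12 = paired_experiment(taxa, GradientConfig(seed=11), replicates=3)

ts = total_shift_check(runs13, runs12)
print(f"whole-community copy-weighted density shift: {ts.shift:+.4f} g/ml "
      f"(detected: {ts.detected})")

results = detect_labelled(runs13, runs12)
table = shift_table(results)
called = table[table.labelled]
print()
print(called[["total_abundance", "com_12c", "com_13c", "com_shift",
              "heavy_gain"]].round(4).to_string())
print()
print(f"called labelled: {sorted(called.index)}")
print(f"ground truth:    {truth}")
print()
print("com_shift is each taxon's centre-of-mass buoyant density difference"
      " (13C minus 12C arm); the labelled taxa sit near +0.035 g/ml — the"
      " full-label shift minus the smear dilution — while unlabelled taxa"
      " scatter around zero, far below the 0.010 g/ml call threshold.")
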