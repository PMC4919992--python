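"""The packaged three-soil demo, end to end.

Two soils (D, F) share a labelled guild of five taxa, the third (W)
carries a disjoint guild. An early timepoint has weak labelling, a late
one strong labelling. The pipeline simulates all gradients, runs the
whole-community qPCR shift check per timepoint, screens for labelled taxa,
and writes the report bundle.
"""

import tempfile

from sipshift.pipeline import demo_config_path, run_pipeline

with tempfile.TemporaryDirectory() as out:
    result = run_pipeline(demo_config_path(), out)

    print("whole-community density shift per soil and timepoint:")
    print(result.total_shifts.round(4).to_string(index=False))
    print()
    for (soil, day), labelled in sorted(result.labelled_sets.items()):
        truth = sorted(result.ground_truth[soil])
        print(f"soil {soil} day {day:2d}: called {sorted(labelled) or '-'}"
              f"  (ground truth {truth})")
    print()
    print("files written:", len(result.figures), "figures plus shift/delta/"
          "community tables and manifest.json")

print()
print("At day 18 the label is too dilute: no whole-pool shift is detected"
      " and no taxa are called. At day 32 every soil shows a detected pool"
      " shift and the screen recovers each soil's configured guild exactly —"
      " the D/F guilds match while W's is disjoint.")
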