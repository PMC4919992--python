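"""Biomass δ¹³C from fumigation-extraction pairs, plus qPCR efficiency.

Reads the packaged synthetic demo measurements (triplicate fumigated /
non-fumigated soil extracts for a ¹³C-spiked and an unspiked microcosm)
and applies the isotope mixing formula per replicate.
"""

import os

from sipshift.isotope import qpcr_efficiency, read_isotope_table, summarize_delta13c_mic
from sipshift.pipeline import demo_config_path

table = os.path.join(os.path.dirname(demo_config_path()), "demo_isotope.tsv")
summary = summarize_delta13c_mic(read_isotope_table(table))
print(summary.to_string(index=False))
print()
print(f"qPCR efficiency for a standard-curve slope of -3.4748: "
      f"{qpcr_efficiency(-3.4748):.1%}")
print()
print("The 13C rows show strongly positive biomass delta13C (tens of permil"
      " vs V-PDB): the microbes assimilated the labelled substrate. The 12C"
      " control sits near -28 permil, ordinary soil organic carbon. An"
      " efficiency near 94% is a well-behaved qPCR assay.")
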