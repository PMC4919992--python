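"""TRFLP-style processing: digest, normalize, filter, rarefy.

Collapses a small OTU fraction matrix onto shared terminal-restriction-
fragment lengths, applies the standard exclusion rules (fragments < 50 bp,
TRFs contributing < 1% of a profile), and rarefies a count table.
"""

import numpy as np
import pandas as pd

from sipshift import filter_trfs, insilico_trflp, normalize_profile, rarefy

otus = pd.DataFrame(
    {"f1": [300.0, 250.0, 420.0, 25.0, 5.0]},
    index=["otu_a", "otu_b", "otu_c", "otu_d", "otu_e"],
)
# otu_a and otu_b share a 56 bp terminal fragment after digestion
trf = insilico_trflp(
    otus, {"otu_a": 56, "otu_b": 56, "otu_c": 148, "otu_d": 73, "otu_e": 802}
)
print("TRF profile (signal):")
print(trf.to_string())

filtered = filter_trfs(trf)
print("\nafter length/abundance filtering and renormalization:")
print(filtered.round(4).to_string())

counts = pd.DataFrame(
    {"s1": [2600, 900, 450, 50], "s2": [4000, 200, 700, 100]},
    index=[56, 73, 148, 802],
)
rare = rarefy(counts, depth=1000, seed=0)
print("\nrarefied to 1000 reads per sample:")
print(rare.to_string())
print()
print("The shared 56 bp fragment sums both OTUs' signal; otu_e's 802 bp"
      " fragment survives the length rule but its 0.5% share fails the 1%"
      " rule and is excluded before renormalization. Rarefied columns each"
      " total exactly 1000 reads, drawn without replacement.")
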