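"""Per-read error profiling on a simulated 24× long-read run.

Builds the 2 Mb error-regime genome (per-base rates 0.01% SNV, 0.02%
insertion, 0.10% deletion, 5× elevated in the outer 5% of each read),
extracts variants from the emulated alignments and prints the recovered
error ratios and the end-window enrichment.
"""

import numpy as np

from longread_audit import synthetic_data as sd
from longread_audit import variant_profile as vp

bundle = sd.run_simulation(sd.error_profile_scenario(seed=1))
events = vp.extract_read_variants(bundle.records)
summary = vp.error_summary(events, bundle.records)

print(f"aligned read bases: {summary.aligned_bases:,}")
for vtype in ("SNV", "INS", "DEL"):
    print(f"  {vtype} ratio: {100 * summary.ratio(vtype):.4f}%  "
          f"({summary.counts[vtype]} events)")
counts = summary.windows.to_numpy().sum(axis=1)
outer = np.r_[counts[:5], counts[-5:]].mean()
inner = counts[5:-5].mean()
print(f"end-window enrichment: {outer / inner:.1f}× "
      "(events per 1%-of-read window, outer 5% vs interior)")
# The ratios recover the configured error rates; the ~5× enrichment shows
# errors concentrating at read ends, as the positional profile expects.
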