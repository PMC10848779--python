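"""Quantify the repaired fraction from an HPLC-style chromatogram.

The damaged tetramer elutes at 8.4 min and the repaired sequence at 9.9 min.
A 30/70 damaged/repaired mixture is synthesised with 1% detector noise and a
baseline drift, then quantified from response-corrected peak areas.
"""

import numpy as np

from cpdrepair.chromatography import (
    ChromatogramConfig,
    quantify_chromatogram,
    synthesize_chromatogram,
)

peak_max = 1.0 / (0.12 * np.sqrt(2 * np.pi))
config = ChromatogramConfig(noise_sigma=0.01 * peak_max, baseline_slope=0.02)
chrom = synthesize_chromatogram(
    {"damaged": 0.3, "repaired": 0.7}, config, rng=np.random.default_rng(0)
)
q = quantify_chromatogram(chrom)

print(f"peak area 8.4 min (damaged) : {q.areas['damaged']:.4f}")
print(f"peak area 9.9 min (repaired): {q.areas['repaired']:.4f}")
print(f"repaired fraction           : {q.repaired_fraction:.3f}  (generated: 0.700)")
# Relative areas translate to composition because both oligomers share the
# same base content; a response-factor table corrects for hypochromicity.
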