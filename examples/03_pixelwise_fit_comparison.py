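"""Classical comparator: pixel-wise exponential fitting of bleach rates.

Fits I(t) = A exp(-t/tau) + C to every pixel trace and summarises the
recovered rate constants per ground-truth region; the rate map itself
can be thresholded to segment the fastest-bleaching region.
"""

import numpy as np

from bleachdmd import SimConfig, fit_stack, jaccard, simulate_stack, threshold_map

stack, truth = simulate_stack(SimConfig(seed=0))
maps = fit_stack(stack, model="mono")

print(f"fitted pixels: {int(maps.fitted_mask.sum())} of {maps.rate_map.size}"
      f" (convergence fraction {maps.convergence_fraction:.3f})")
for label, true_rate in [("rectangle", 0.01), ("circle", 0.05), ("ellipse", 0.15)]:
    med = np.median(maps.rate_map[truth.masks[label]])
    print(f"  {label:10s} median rate {med:.4f} /s (true {true_rate})")

seg = threshold_map(maps.rate_map, method="minimum")
j = jaccard(seg.mask, truth.masks["ellipse"])
print(f"Minimum-threshold of the rate map vs ellipse: J = {j:.3f}")
print(
    "Rate medians land within a few percent of the simulated constants;"
    " the rate-map histogram separates the fastest (elliptical) region"
    " almost perfectly, but unlike DMD a single map cannot isolate all"
    " three regions at once."
)
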