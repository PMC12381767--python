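"""Telegraph distance series: occupancy calibration and r_id profiles.

Generates one bound/unbound switching distance series, measures its
occupancy below the 0.6 nm selection cutoff and the 0.4 nm hydrogen-bond
proxy, and bins it into an r_id profile. The empirical occupancy should sit
within a few corrected standard errors of the planted stationary value.
"""

import numpy as np

from chargenet import (PairSpec, bin_distances, generate_pair_series,
                       hbond_fraction, occupancy_fraction)

pair = PairSpec.from_occupancy(0.30, switch_rate=0.05)
n = 100_000
series = generate_pair_series(pair, n, seed=42)

occ = occupancy_fraction(series, 0.6)
se = pair.stationary_stderr(n)
print(f"planted p_bound = {pair.p_bound:.3f} "
      f"(p_on = {pair.p_on:.4f}, p_off = {pair.p_off:.4f})")
print(f"occupancy below 0.6 nm over {n} frames: {occ:.4f} "
      f"(corrected standard error {se:.4f})")
print(f"hydrogen-bond proximity fraction (<0.4 nm): {hbond_fraction(series):.4f}")

profile = bin_distances(series, bin_width=0.02, max_range=2.0)
peak_bins = np.argsort(profile.counts)[-2:][::-1]
for b in peak_bins:
    lo, hi = profile.bin_edges[b], profile.bin_edges[b + 1]
    print(f"profile mode near [{lo:.2f}, {hi:.2f}) nm: {profile.counts[b]} frames")
# The two modes sit at the bound (~0.35 nm) and unbound (~1.20 nm) state
# means -- the bimodal signature of a transient charge pairing.
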