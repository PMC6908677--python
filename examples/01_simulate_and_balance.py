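"""Simulate a senescent-cell contact map and remove per-bin biases with ICE.

Generates one 40 Mb chromosome at 40 kb resolution with planted compartments
and log-normal bin biases, balances it, and reports how well the balanced
map matches a bias-free simulation of the same architecture.
"""

import numpy as np

from senhic import (
    SyntheticConfig,
    ice_normalize,
    plant_architecture,
    simulate_contacts,
)
from senhic.matrix import row_sum_spread

config = SyntheticConfig(seed=42)
truth = plant_architecture(config)

raw = simulate_contacts(truth, "senescent", "chr1")
iced = ice_normalize(raw, n_iter=30)

free = simulate_contacts(truth, "senescent", "chr1", with_biases=False)
iu, ju = np.triu_indices(raw.n_bins, k=1)
keep = ~iced.mask_array()
ok = keep[iu] & keep[ju]
r = np.corrcoef(iced.counts[iu, ju][ok], free.counts[iu, ju][ok])[0, 1]

print(f"bins: {raw.n_bins}, raw counts: {raw.counts.sum():.3g}")
print(f"row-sum relative spread after ICE: {row_sum_spread(iced):.2e}")
print(f"Pearson r vs bias-free simulation: {r:.4f}")
print("A spread below 1e-3 means the multiplicative biases are gone; the")
print("correlation shows the balanced map recovers the planted structure.")
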