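"""Detect SAHF-like regions and quantify their long-range contact signature.

Senescence-associated heterochromatic foci (SAHF) appear in the contact map
as heterochromatic blocks whose mutual contacts beyond 2 Mb are enhanced.
They are flagged by strongly negative compartment scores; the long-versus-
short (LVS) score — the fraction of a bin's cis contacts reaching beyond
2 Mb — independently marks the same bins.
"""

import numpy as np

from senhic import (
    SyntheticConfig,
    detect_sahf,
    ice_normalize,
    lvs_scores,
    pca_scores,
    plant_architecture,
    sahf_threshold_from_scores,
    simulate_contacts,
    simulate_expression_and_tracks,
)

config = SyntheticConfig(seed=42)
truth = plant_architecture(config)
_, tracks = simulate_expression_and_tracks(truth)

m = ice_normalize(simulate_contacts(truth, "senescent", "chr1"))
pca = pca_scores(m, tracks["gene_density"]["chr1"])

threshold = sahf_threshold_from_scores(pca.score)
regions = detect_sahf(pca, threshold)
planted = truth.sahf_bin_mask("chr1")
print(f"scale-free threshold: {threshold:.1f}")
print(f"flagged {regions.flagged.sum()} bins in "
      f"{len(regions.regions())} regions "
      f"(planted: {planted.sum()} bins in "
      f"{len(truth.sahf_blocks['chr1'])} blocks)")
print(f"recall of planted SAHF bins: {regions.flagged[planted].mean():.2f}")

lvs = lvs_scores(m, distance_cutoff=2_000_000).lvs
lab = np.asarray(truth.labels["chr1"]["senescent"])
print(f"median LVS — SAHF: {np.nanmedian(lvs[planted]):.3f}, "
      f"other B: {np.nanmedian(lvs[(lab == 'B') & ~planted]):.3f}, "
      f"A: {np.nanmedian(lvs[lab == 'A']):.3f}")
print("SAHF bins devote the largest share of their contacts to partners")
print("more than 2 Mb away — the defining long-range signature.")
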