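"""Relative abundance: the pool-scoped ratio statistic, merging and clipping.

RA(hPTM) = intensities of peptidoforms carrying it / total pool intensity.
Merging is done on intensities, never by averaging ratios: merging the
H3.1/H3.2 and H3.3 K27me3 keys below yields 12/100 = 0.12, not the
mean of 0.10 and 0.20.
"""

import pandas as pd

from hptmkit import AbundanceMatrix, HPTMKey, compute_ra, merge_keys, ra_matrix
from hptmkit.quantify import enumerate_keys, quantify_clipping

table = pd.DataFrame(
    {"P0_R1": [72.0, 8.0, 16.0, 4.0, 3.0]},
    index=[
        "H3 H31/H32 27-40 unmod",
        "H3 H31/H32 27-40 K27me3",
        "H3 H33 27-40 unmod",
        "H3 H33 27-40 K27me3",
        "H3 H31/H32 c28-40 unmod",  # clipped N-terminus at K27
    ],
)
matrix = AbundanceMatrix.from_wide(table)

for vg in ("H31/H32", "H33"):
    ra = compute_ra(matrix, HPTMKey(vg, "K27", "me3")).iloc[0]
    print(f"RA({vg} K27me3) = {ra:.3f}")

ra = ra_matrix(matrix, enumerate_keys(matrix))
merged = merge_keys(
    ra,
    [(
        HPTMKey("H3", "K27", "me3"),
        [HPTMKey("H31/H32", "K27", "me3"), HPTMKey("H33", "K27", "me3")],
    )],
)
print(f"merged RA(H3 K27me3) = {merged.values.loc['H3 K27me3'].iloc[0]:.3f} "
      "(intensity-weighted 12/100, not mean(0.10, 0.20) = 0.15)")

clip = quantify_clipping(matrix, clip_site=27, variant_group="H31/H32").iloc[0]
print(f"clipping RA at K27 = {clip:.4f} "
      "(clipped forms over clipped + intact pool)")
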