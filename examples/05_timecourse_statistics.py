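"""Time-course and endpoint statistics on a simulated conversion.

The default synthetic design plants a K27me3-like step at P9 (a naive
marker), a transient K36me2 excursion at P3 (time-significant but back to
baseline by P12) and constant null keys.  The marker table recovers each.
"""

from hptmkit import call_markers, default_simulation_config, simulate_ra_dataset
from hptmkit.quantify import enumerate_keys, ra_matrix

matrix, truth = simulate_ra_dataset(default_simulation_config(seed=1))
ra = ra_matrix(matrix, enumerate_keys(matrix))
markers = call_markers(ra.values, matrix.sample_passages())

cols = ["anova_p", "endpoint_p", "log2fc", "time_significant", "marker"]
show = ["H31/H32 K27me3", "H31/H32 K36me2", "H3 K18ac", "H3 K9ac"]
print(markers.loc[show, cols].round(4).to_string())
print(f"\n{int(markers['marker'].sum())} of {markers.shape[0]} hPTM keys called "
      "as endpoint markers (P0 vs P12 t-test p < 0.01); "
      f"{int(markers['time_significant'].sum())} change over time (ANOVA p < 0.05).")
print("The transient key is time-significant but not a marker - exactly the"
      " planted behaviour.")
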