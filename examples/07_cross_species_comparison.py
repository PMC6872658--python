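"""Cross-study comparison of naive/primed fold changes.

Two marker tables (e.g. a human primed->naive conversion and a mouse
naive->primed conversion, both re-oriented naive-over-primed) are joined on
a merged key vocabulary: H3.1/H3.2 and H3.3 fold into H3, K36 and K37 into
K36/37.  Shared keys land in the scatter table; study-specific keys are
reported unmatched.
"""

import numpy as np

from hptmkit import call_markers, compare_studies, default_simulation_config, simulate_ra_dataset
from hptmkit.pipeline import apply_standard_merges
from hptmkit.quantify import enumerate_keys, ra_matrix


def marker_table(seed):
    matrix, _ = simulate_ra_dataset(default_simulation_config(seed=seed))
    ra = ra_matrix(matrix, enumerate_keys(matrix))
    ra = apply_standard_merges(ra, merge_h3_variants=True, merge_k36_k37=True)
    return call_markers(ra.values, matrix.sample_passages())


human = marker_table(seed=1)
mouse = marker_table(seed=2)   # an independent replicate standing in for mouse
comparison = compare_studies(human, mouse, merge_label=None)

table = comparison.table
print(table.round(3).to_string())
both_sig = table[table["sig_human"] & table["sig_mouse"]]
concordant = both_sig[np.sign(both_sig["log2fc_human"]) == np.sign(both_sig["log2fc_mouse"])]
print(f"\n{table.shape[0]} shared keys; {both_sig.shape[0]} significant in both, "
      f"{concordant.shape[0]} with concordant direction - conserved marker candidates.")
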