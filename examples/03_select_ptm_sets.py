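"""Sequential variable-modification set selection with comprehensiveness.

A search engine cannot carry every modification at once, so sets of
modifications are chosen sequentially: each round picks the set explaining
the most not-yet-covered candidate matches (greedy maximum coverage).  The
comprehensiveness is the fraction of all MS1 candidate explanations the
chosen sets cover.
"""

from hptmkit import (
    default_registry,
    digest,
    enumerate_peptidoforms,
    load_packaged_variants,
    match_features,
    select_ptm_sets,
    simulate_feature_list,
)

registry = default_registry()
forms = []
for v in sorted(load_packaged_variants("h3")):
    for pep in digest(v, 1, 4, 30):
        forms.extend(enumerate_peptidoforms(pep, registry, max_mods=2))

features, _ = simulate_feature_list(forms, ppm_sd=3.0, decoy_count=100, seed=3)
matches = match_features(features, forms, tol_ppm=10.0)
selection = select_ptm_sets(matches, set_size=6, n_rounds=5)

print(f"{selection.total_candidates} candidate matches to cover")
for i, (names, covered, cum) in enumerate(
    zip(selection.rounds, selection.covered_per_round,
        selection.comprehensiveness_by_round),
    start=1,
):
    print(f"  round {i}: {{{', '.join(sorted(names))}}}  "
          f"covers {covered}  cumulative {100 * cum:.1f}%")
print(f"comprehensiveness after {len(selection.rounds)} rounds: "
      f"{100 * selection.comprehensiveness:.1f}% of all candidate explanations")
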