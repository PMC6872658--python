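"""ArgC digestion of histone H3.1 and the propionylation state of a peptide.

Trypsin on propionylated histones cleaves only after arginine, so the
digest below is the ArgC peptide universe.  The K27-K40 stretch
(KSAPATGGVKKPHR) hosts K27, K36 and K37; with K27 trimethylated, only the
N-terminus and the two free lysines receive a propionyl group.
"""

from hptmkit import default_registry, derivatize, digest, load_packaged_variants

h31 = next(v for v in load_packaged_variants("h3") if v.name == "H31")
products = digest(h31, max_missed_cleavages=0)
print(f"ArgC digest of {h31.name} ({len(h31)} mature residues): "
      f"{len(products)} zero-missed-cleavage peptides")
for p in products[:6]:
    print(f"  {p.start:>3}-{p.end:<3} {p.sequence}")

stretch = next(p for p in products if p.span == (27, 40))
print(f"\nK27 stretch: {stretch.sequence} (span {stretch.start}-{stretch.end})")

registry = default_registry()
state = derivatize(stretch, ((27, registry["me3"]),))
print(f"with K27me3 -> propionylated lysines: {sorted(state.propionylated_lysines)}, "
      f"N-terminal propionyl: {state.n_term_propionyl}")
print("K27 carries no propionyl because trimethylation blocks the epsilon-amine;"
      " K36/K37 stay derivatizable.")
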