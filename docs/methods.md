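# Methods

This note documents the models, conventions and parameter choices behind
hptmkit, and what its synthetic-data tests do and do not establish.

## Sequence model and coordinates

Histone variants are stored as mature chains: the initiator methionine is
stripped on FASTA import (`strip_init_met=True` by default), so community
nomenclature holds (H3K27 is residue 27 of the mature chain). Packaged
fixtures are UniProt canonical sequences with accessions recorded in the
headers (`NAME|FAMILY|ACCESSION`): H3.1 P68431, H3.2 Q71DI3, H3.3 P84243,
H4 P62805, plus H2A entries used only at the protein level.

Distinguishing positions are computed from the sequences, never hard-coded:
a column is distinguishing when at least two variants differ there (for the
packaged H3 set: 31, 87, 89, 90, 96). A peptide's variant group is the set
of variants consistent with every distinguishing residue its span covers;
spans covering none are reported at the family level ("H3"). Labels are
deterministic — members sorted and "/"-joined ("H31/H32"), collapsing to the
family name for the full set. Variants of unequal length are compared on the
shared prefix. Group calling is monotone: enlarging a span can only shrink
the candidate set.

## Derivatization and digestion model

Propionylation is modelled as an end state, not a kinetic process: the
peptide N-terminus always carries a propionyl; a lysine carries one exactly
when its biological modification leaves the epsilon-amine free (none or
monomethyl — monomethyl-lysine stacks methyl and propionyl); S/T/Y carry
none because aspecific over-propionylation is chemically reversed. The
propionyl count is therefore 1 + |{K : mod ∈ {none, me}}|, and derivatization
is idempotent by construction.

Digestion is ArgC-specific (cleavage C-terminal of R only), with
`max_missed_cleavages = 1` as the default search-style setting.
Zero-missed-cleavage products tile the sequence exactly. For the observable
peptide universe a 4–30 residue length window is the default — a typical
bottom-up detectability range, applied after cleavage and fully
configurable.

Histone clipping at residue c is modelled as cleavage C-terminal of c: the
clipped peptide starts at c+1 and ends at an enzymatic boundary
(`n_term_kind = clipped`). The alternative reading (cleavage N-terminal of
the residue) is a one-parameter change at the call site; the C-terminal
convention was chosen because it yields a detectable semi-ArgC peptide
covering the same pool region as the intact 27–40 peptide.

## Modification registry and masses

The registry maps names to elemental formulas (me CH2, me2 C2H4, me3 C3H6,
ac C2H2O, cr C4H4O, hib C4H6O2, ph HPO3; propionyl C3H4O as derivatization,
not biology). Monoisotopic deltas are always computed from the formulas via
pyteomics — a single source of truth that the test suite cross-checks
against an independent element-mass table, including the near-isobaric
trimethyl/acetyl gap (0.03638 Da) that an error in either delta would break.
Peptidoform mass = backbone + water + biological deltas + one propionyl per
derivatized site. me/me2 also target arginine (R40 methylation is observed
on H3); ph targets S/T/Y.

## MS1 matching and set selection

Features are (id, neutral mass) pairs; decharging is the caller's concern.
Matching uses a symmetric signed-ppm window (default 10 ppm, the usual
high-resolution search tolerance) over a sorted candidate index, equivalent
to the quadratic scan the tests compare against. `max_mods = 3` biological
modifications per peptide bounds the combinatorics of the K27–R40 backbone
while still covering multiply-modified forms.

Set selection is greedy maximum coverage: per round, the modification-name
set of size ≤ `set_size` covering the most not-yet-covered candidates wins;
ties prefer the smaller set, then lexicographic order. The counting unit is
the candidate match (feature, peptidoform pair), i.e. "possible explanations
of the MS1 precursor masses". Greedy round 1 is provably optimal (verified
against exhaustive subset search on random instances); later rounds are the
standard (1 − 1/e) max-coverage heuristic. Defaults `set_size = 6`,
`n_rounds = 5` mirror a five-search, six-modification-set workflow; both are
plain parameters because workflows differ. An empty candidate list yields a
vacuous comprehensiveness of 1.0 with a warning rather than 0/0.

Annotation classes: `unannotated` (no records), `non_curated` (nothing
curated above the score threshold), `ambiguous` (>1 distinct curated
candidate above threshold), `curated_reproducible` (one curated candidate on
>1 MSMS spectrum), else `curated_single_support`. The score threshold itself
is a parameter with no claimed default.

## Relative abundance

RA denominators are pool-scoped: all non-clipped peptidoforms of one variant
group whose span covers the residue. Variant-specific keys therefore use
variant-group-specific denominators by default (H31/H32 K27me3 over the
H31/H32 27–40 pool); family-wide denominators are obtained by merging.
A zero or missing pool total yields a missing RA (never 0/0 → 0), and
missing values propagate pairwise into the statistics.

Merging re-aggregates intensities, never ratios. The RA matrix retains each
key's supporting (carrier) and pool row sets, so residue merges (shared
pool — union of carriers de-duplicates doubly-modified forms) and variant
merges (disjoint pools — intensity-weighted combination) are exact, merging
is idempotent, and co-detection groups (keys with identical carrier sets,
hence provably identical RA) fall out of the same bookkeeping. Per residue
and sample, the modified-state RAs plus the unmodified share sum to one to
1e-9.

Input tables are accepted as already normalized (the tag is recorded); an
optional median-of-ratios column normalization is available for raw tables.

## Statistics

Time-course inference is a one-way fixed-effects ANOVA per key over passage
groups; all-equal observations give p = 1 by convention, and groups with
fewer than two values are dropped with a warning. Pairwise passage t-tests
are two-sided and unadjusted (they localize an effect the ANOVA already
tested globally). The endpoint contrast (default P0 vs P12) with fold change
of replicate means calls markers.

t-tests default to the classical pooled-variance Student form, with Welch
via `equal_var=False`. Pooled is the package default because the classical
"standard ANOVA / t-test" pair is what this analysis tradition uses, the
two-group identity F = t² holds only for pooled, and at the design's n = 4
with a five-fold RA change the pooled test retains the power the Welch
correction gives up (measured ≈ 0.97 vs ≈ 0.84 for the planted 0.05 → 0.15
endpoint shift at p < 0.01, CV 20%). hPTM p-values are reported raw;
Benjamini–Hochberg Q-values are applied to protein-level ANOVA (and
available as `bh_qvalues` elsewhere).

Protein profile clustering: per-passage means, per-protein standardization,
distance 1 − Pearson r, average linkage, cut at a distance threshold
(default 0.5). Constant or incomplete profiles cannot be correlated and
become singletons (a relative tolerance treats float-level jitter on a
constant profile as constant). PCA is a centered (optionally unit-variance)
SVD; each component's sign is fixed by making its largest-magnitude loading
positive, so scores are fully deterministic. Explained variances sum to the
total variance of the analysed matrix.

Cross-study comparison joins marker tables on a merged vocabulary
(H31/H32, H33 → H3; K36, K37 → K36/37) with both axes oriented
naive-over-primed. Colliding labels after mapping are an error by design:
merging must happen at the intensity level upstream.

## Synthetic-data generator

The generator emulates the study design it tests: five passages
(P0/P3/P6/P9/P12) × four biological replicates. Per backbone pool and
sample, the pool total is lognormal (sigma 0.25, a typical between-sample
loading spread); peptidoform proportions are products of independent
per-residue state probabilities given by the planted RA trajectories
(exactly renormalized via the unmodified remainder); each peptidoform then
receives independent mean-one multiplicative lognormal noise at the
configured replicate CV (default 0.20, a common label-free replicate CV).
Residue independence is the default (no planted co-occurrence); a joint
peptidoform can be written directly into a table to exercise co-detection.
Clipping intensity is planted so the clipped fraction matches the trajectory
(peaking at 3% at P3 by default).

Default trajectories encode the emulated biology: K27me3 stepping
0.05 → 0.15 at P9 on both H3.1/H3.2 and H3.3 pools; K27me2 drifting up;
acetylation on K18/K23/H33K27/H4K12/H4K16 dipping at P3 with partial
recovery (a net endpoint decrease); a transient K36me2 excursion at P3
returning to baseline; co-rising H4K5me/H4K8cr; constant null keys. The
protein generator plants a 64-member step-up cluster (×2.5 between P3 and
P6), two transient-spike-then-absent proteins and one late-onset protein
(missingness encoded structurally as absent values, not zeros), over a null
background. Feature lists perturb theoretical masses by Normal(0, ppm_sd)
ppm and add uniform mass decoys.

What passing tests show: the estimators are exact in the noise-free limit,
calibrated (null ANOVA false-positive rate 5% within Monte-Carlo error) and
powered (≥ 90% at p < 0.01 for the planted endpoint shift) under this
generative model, and the pipeline recovers planted markers, transients,
clipping and ordination structure. What they do not show: robustness to
retention-time misalignment, isotope-pattern or co-elution artefacts,
partial derivatization, or non-lognormal batch structure — none of which
the generator emulates; real exports also carry annotation errors upstream
of this package's scope.

## Problem sizes and numerical conventions

The acceptance script and test suite use sizes chosen to make Monte-Carlo
error small relative to the assertions: 500 simulated datasets each for
calibration (3 null keys → n = 1500 tests, 3-SD band ≈ ±0.017) and power;
200 random instances for greedy-vs-exhaustive selection; full H3 peptidoform
spaces (~10⁵ candidate matches) for comprehensiveness. Determinism: every
generator draws from one `numpy` Generator seeded from the single configured
seed; identical seeds give byte-identical tables and identical pipeline
bundles (config-hash manifests). Degenerate inputs follow the conventions
stated above (p = 1 for no-variance tests, missing rather than zero for
empty denominators, singletons for constant profiles, vacuous 1.0 for empty
selection).

## Known limitations

MS2-level localization is not modelled; positional ambiguity is handled by
merged reporting, which is the analysis-level convention, not a spectral
re-scoring. Quantification is relative, not stoichiometric — no spike-in
calibration. The clipping convention (C-terminal of the named residue) is an
assumption, flagged above. H2A/H2B peptidoforms are out of scope; H2A
variants appear only as proteins in the acid-extractome table.
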