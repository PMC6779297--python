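# Methods

## Curation model

A raw activity table is a list of assay rows `(compound_id, smiles,
cell_line_id, assay_type, value, units, relation)`. Curation applies, in
order:

1. **Endpoint filter.** Only IC50, GI50 and CC50 rows are admitted; these
   three median-effect endpoints are pooled into one classification rule.
2. **Relation filter.** Only `=` (or empty) relations are used. A censored
   value (`>` or `<`) cannot be placed against the 10 µM threshold, so such
   rows are dropped and logged. An opt-in flag
   (`--admit-censored-resistant`) keeps `>` rows whose reported value is
   already above 10 µM as resistant, which is sound because the true value
   can only be larger; `>` rows at or below the threshold remain unusable.
3. **Structure normalization.** Each SMILES is reduced to the fragment with
   the most heavy atoms (salts/mixtures → parent), canonicalized with
   RDKit. Ties break by molecular weight, then lexicographic canonical
   SMILES, so output never depends on input order. Unparseable structures
   are dropped and logged.
4. **Identity merge.** Two input ids with the same canonical
   largest-fragment SMILES are one compound (the lexicographically smallest
   id survives; the merge map goes to the audit report). Replicate
   agreement must operate on structures — duplicate structures under
   different ids would otherwise smuggle a compound into both sides of a
   validation split.
5. **Unit conversion and labeling.** Values convert to mol/L (pM…M
   accepted; unknown units drop the row). A pair is *sensitive* iff the
   concentration is ≤ 1e-5 M — the boundary is inclusive.
6. **Replicate resolution.** All rows for one (structure, cell line) pair,
   across assay types, must agree on the label; otherwise the pair is
   discarded (counted in the audit). Agreement is evaluated on the pooled
   set, not per assay type.
7. **Cell-line floor.** Cell lines sensitive to fewer than `min_sensitive`
   (default 10) compounds are removed with all their pairs; orphaned
   compounds leave the compound map.

The pipeline is idempotent (curating its own output is a no-op) and
order-invariant; both properties are tested.

## Similarity predictor

Fingerprints are hashed, folded circular Morgan fingerprints. Defaults:
radius 8 (ECFP16), 1024 bits, used consistently for scoring, balancing and
SVM features; radius and width are configurable everywhere (radii 2/4/8 are
the values the evaluation drivers sweep). Similarity is the Tanimoto
coefficient over bit sets, with Tc ≡ 0 when both vectors are empty (cannot
occur for a real molecule; avoids 0/0).

The score of query q against cell line j is the mean of the n_top = 3
largest similarities to j's known sensitive compounds. If fewer than n_top
references exist (possible only in edge-case inputs, since curation
guarantees ≥10), the mean runs over what is available rather than refusing
to predict. The decision rule is `score ≥ cutoff` — inclusive, fixed for
determinism. The per-cell label for a below-cutoff score is *resistant*, so
a full confusion matrix exists; *coverage* is the separate compound-level
flag "at least one sensitive call". Ties at the top-n boundary are
irrelevant to a mean of interchangeable values.

Self-exclusion during validation removes reference entries whose canonical
largest-fragment SMILES equals the query's — structural, not id-based, for
the same anti-leakage reason as the identity merge.

The top-n mean is averaged in descending sorted order, making the fast
partition-based path bit-identical to a naive sort-everything oracle.

## Class balancing and SVM

A cell line's training set is unbalanced when the majority class exceeds
1.2× the minority (the boundary 1.2× exactly counts as balanced). The
majority class is then reduced to the minority size Nm:

* Ward's minimum-variance agglomeration runs on the Tanimoto distance
  matrix of the majority compounds, cut at height 4.5 (scipy's Ward
  criterion scale for 0–1 distances; the height is configurable because
  linkage conventions rescale it).
* If the cut yields Nc < Nm clusters, each cluster contributes
  proportionally to its size (largest-remainder apportionment; leftover
  seats go to the largest fractional parts, ties to larger clusters, then
  lower index), taking its most central compounds first.
* If Nc > Nm, the set is re-clustered to exactly Nm groups and each
  contributes its medoid. At Nc = Nm each existing cluster contributes its
  medoid, which is what both branches degenerate to.

"Most central" means the medoid — the member minimizing summed Tanimoto
distance to its cluster, ties by lexicographic id. A mean bit vector is not
a compound, so a true centroid is not usable. Ward formally assumes
Euclidean geometry and Tanimoto distance is not Euclidean; the procedure is
applied to the Tanimoto matrix anyway, a standard pragmatic usage in
cheminformatics, and no correction is attempted.

Cell lines need ≥ 20 compounds in *each* class to be modeled. One RBF-SVM
per cell line is grid-searched (default C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, steps of
2²; accuracy criterion, stratified internal 5-fold CV, shuffled with a
fixed seed) and refit on all balanced rows. The cross-validation driver and
the acceptance script use a coarse 3×3 grid (C ∈ {1, 2⁵, 2¹⁰},
γ ∈ {2⁻⁷, 2⁻³, 2}) so a ten-fold, per-cell-line re-training loop stays
cheap; the full grid remains the default for single training runs and is
selectable everywhere.

## Validation

`make_folds` draws one global compound-level partition (seeded permutation,
k contiguous chunks) shared by both methods and all cell lines, so both
methods are judged on identical held-out compounds. Per fold, similarity
reference lists and SVM training sets are rebuilt from training compounds
only; an id audit of this hygiene is part of the test suite. Confusion
counts accumulate across folds per cell line and are macro-averaged; a cell
with a zero denominator in one ratio is excluded from that ratio's mean
only. Cells lacking test compounds in some fold simply contribute what they
have.

Because a cutoff sweep only re-thresholds the same held-out scores, the
monotone trends (sensitive-call sets shrink as the cutoff rises, so ⟨TP⟩ is
non-increasing and ⟨TN⟩ non-decreasing) are exact subset properties on any
fixed dataset, and the tests assert them exactly rather than statistically.

External validation takes pairs of compounds absent from the reference
(checked by canonical SMILES; overlap is an error listing offenders) and
weights every interaction equally (micro). TP_C/TN_C are the same micro
rates restricted to covered compounds, also interaction-weighted. The
combined strategy routes covered compounds to the similarity predictions
and uncovered ones to the SVMs. Well-modeled-cell summaries compare both
methods at an accuracy floor using ACU ≥ threshold.

## Synthetic data

The generator emulates exactly the regime the similarity principle assumes:

* **Library**: `n_scaffolds` core templates (benzenes, azines, five-ring
  heterocycles, amides, esters, sulfonamides, diaryl ethers, …) decorated
  with substituent pairs from a fixed whitelist. Every SMILES is valid by
  construction; within-family Tanimoto similarity exceeds between-family
  similarity on average (tested). `scaffold_offset` builds query libraries
  on cores the reference never used, emulating new chemical series.
* **Truth**: each (scaffold, cell line) is sensitive-prone with probability
  `p_scaffold_active` (default 0.35); members inherit the tendency, flipped
  with `label_noise` (default 0.05). Cells in `guaranteed_fraction`
  (default all) re-activate scaffolds until they reach
  `min_guaranteed_sensitive` = 10 sensitive compounds, so curation retains
  them.
* **Raw table**: sensitive pairs draw endpoints log-uniformly in [10 nM,
  10 µM], resistant in (10 µM, 1 mM], reported in nM or µM; consistent
  replicates appear at `replicate_rate` (0.2), contradicting replicates at
  `conflict_rate` (0 by default), counter-ion salts at `salt_rate` (0.1)
  and off-type EC50 rows at `off_type_rate` (0.02).

Default sizes are 12 scaffolds × 10 compounds × 15 cell lines (1 800
pairs), which gives every stage realistic imbalance while a full 10-fold
dual-method evaluation completes in seconds. What the generator does *not*
emulate: realistic medicinal-chemistry property distributions, activity
cliffs (similar structures with opposing labels beyond independent label
noise), inter-cell-line correlation structure, or ChEMBL-scale sparsity —
passing tests demonstrate that the machinery is correct and that the
methods recover a planted similarity signal, not that they will reach any
particular accuracy on real panels.

The chance-level baseline test permutes labels within each cell line on an
exactly class-balanced variant of the fixture. With unequal class sizes a
label permutation does not center accuracy at 0.5 (a predictor calling a
fraction p sensitive against a true fraction q has expected accuracy
1 − p − q + 2pq), so the 1:1 design is what makes "indistinguishable from
0.5" the correct null.

## Numerical and degenerate-input conventions

* Inclusive comparisons throughout: sensitivity at exactly 1e-5 M, decision
  at exactly the cutoff, balance at exactly 1.2×, accuracy floors at
  exactly the threshold.
* Deterministic tie-breaks: fragment ties by weight then string; medoid and
  pick-order ties by id; quota ties by fractional part, size, index.
* Seeded randomness only: fold permutation, SVM internal CV shuffling and
  all generators take explicit seeds; repeated runs are bit-identical.
* Degenerate inputs: empty reference sets raise instead of guessing;
  single-class training raises; an all-zero fingerprint predicts without
  crashing; a 1-compound distance matrix is a 1×1 zero.

## Known limitations

* The Ward cut height is linkage-convention-dependent; with other toolkits
  the same 4.5 produces different cluster counts, hence the
  proportional/centroid branch ratio is not portable bit-for-bit.
* Macro averages treat a 20-compound cell line and a 2 000-compound cell
  line equally; that is the intended reading, but it makes results
  sensitive to which small cell lines survive curation.
* The similarity method cannot, by construction, cover scaffolds with no
  sensitive analogue in the reference — external-validation coverage drops
  steeply with the cutoff on new-scaffold queries, and the SVM fallback is
  the designed mitigation.
* Grid-search selection uses accuracy on balanced training data; no
  probability calibration is attempted and SVM decision values are only
  rank-comparable within one cell line.
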