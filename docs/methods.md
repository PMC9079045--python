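# Methods

This note documents the models, rules and numerical choices behind
`eraqsar`, and what the synthetic studies do and do not demonstrate.

## Curation model

A raw activity table is a list of (structure, IC50, relation, assay
metadata) records. Curation applies rules in a fixed order so every removed
row carries the first rule that removed it: unknown relation symbol →
confidence score ≠ 9 → assay type ≠ B → missing value. Rows with relation
`<` or `>` that pass the confidence/assay filters are *diverted* to censored
qualification sets; they are unusable for regression (the likelihood of a
bound is not a point) but support directional validation later.

**Desalting** keeps the fragment with the most heavy atoms; ties break by
molecular weight, then by lexicographically smallest canonical SMILES, so the
operation is deterministic. Stereochemistry is preserved through
canonicalization because chirality is itself a ranked descriptor
(`ChiralCenterSpecified`).

**pIC50** = −log₁₀(IC50 in mol/L); for nanomolar input this is
9 − log₁₀(IC50/nM). Strict mode rejects any unit other than nM — silent unit
mix-ups are the dominant curation failure mode — while
`convert_known_units` handles pM/nM/µM/mM/M by power-of-ten scaling.

**Deduplication** groups records by exact desalted canonical SMILES. The
rule for reconciling replicate values is genuinely underdetermined in common
practice ("2 SD" rules rarely say 2 SD *of what*), so the package adopts an
explicit, order-free reading: compute the replicate group's pIC50 sample
standard deviation; if it is at most `dedup_sd_threshold` (default 1.0 pIC50
unit, configurable) the group collapses to its **median**, otherwise the
whole group is removed as a value disagreement. Statistics are computed on
the log (pIC50) scale, where assay replicates scatter approximately
symmetrically; a multiplicative error on the concentration scale is additive
here.

## Fingerprints

A pattern set is an ordered list of (name, SMARTS) pairs loaded from
two-column text. The count of a pattern in a molecule is the number of
**unique atom sets** matched, not the number of raw symmetry mappings — a
benzene ring contributes 1 to `BenzeneRing`, not 12. Presence fingerprints
are the indicator count > 0. Before matching, polar hydrogens (on N/O/S) are
made explicit and tautomers can optionally be mapped to RDKit's canonical
tautomer; both normalizations are off-by-default no-ops elsewhere.

The bundled 45-pattern set covers the functional-group classes that dominate
Gini rankings of ERα substructure-count models (phenol, catechol, amines,
aromatic systems, carboxylic-acid derivatives, ethers, tautomerizable
motifs, halogens, carbon environments). Full-size published pattern
collections (e.g. the 307-descriptor functional-group classification) load
through the same file format. Two graph descriptors with no SMARTS
expression — specified chiral centers and rotatable bonds — are registered
under `@builtin:` names. Fingerprint families computed by external software
import from CSV with validation (duplicate ids, non-numeric cells rejected
with their location).

**Rule of five**: MW < 500 Da (exact mass), Crippen logP < 5, Lipinski
acceptors (N+O count) < 10, donors (N–H/O–H count) ≤ 5. The donor rule is
applied in its canonical ≤ 5 form; violations are the number of failed
rules (0–4).

## Preprocessing

Zero-variance columns are removed first (a constant descriptor carries no
information and breaks autoscaling). The correlation filter then runs in two
stages, 0.95 and 0.7: within a stage, while any retained pair has
|Pearson r| above the threshold, the member of the worst pair with the
larger mean absolute correlation to the remaining descriptors is dropped
(ties drop the later column). This greedy rule is deterministic, order-stable
and guarantees the post-condition max |r| ≤ threshold, which the tests
verify by brute force. The second stage can be disabled when only the 0.95
pruning is wanted.

Scaling is mean centering and unit variance with the sample (n−1) SD. Both
the scaler and the PCA of the applicability domain are fitted on the
internal (training) rows of each split only and applied unchanged to
external rows — external validation must not leak distributional
information. Pearson correlation is scale-invariant, so running the filter
before or after scaling is equivalent.

Splits are independent uniform 70/30 partitions (|internal| = round(0.7·n)),
seeded as `base_seed + split_index`; 10 splits with mean ± SD reporting is
the default, since a single split's external estimate is itself a random
variable.

## Random-forest model

The response (pIC50) is continuous, so the learner is a regression forest:
bootstrap-sampled trees with a random feature subset per split. Defaults:
500 trees, `sqrt(p)` features per split, leaves of 1; the tuning grid
{100, 500} × {√p, p/3} × {1, 5} is searched exhaustively by 10-fold CV Q²
with deterministic tie-breaking (fewer trees, then smaller feature subsets).
In the orchestrated pipeline tuning runs once, on the first split's internal
set, and the winning configuration is reused across splits and for
Y-scrambling.

R² and Q² are squared Pearson correlations between observed and predicted
values — on training predictions, pooled out-of-fold CV predictions, or
external predictions respectively. The predictive-residual form
1 − SSres/SStot is available (`q2_form="press"`) but Pearson-squared is the
default, matching how the thresholds below are usually quoted. RMSE is
reported alongside, since a correlation says nothing about calibration.

Gini importances (mean decrease in impurity) are normalized to sum to 1.
The Occam refit retrains on the top-20 ranked features, preserving their
original column order so that k = p reproduces the full model bit-for-bit
(tree growth is sensitive to column order).

## Validation battery

* **Acceptability**: R² > 0.6 and Q²_CV > 0.5, strict inequalities.
* **Eriksson margin**: R²_Tr − Q²_Ext ≤ 0.2 is `ok`, 0.2–0.3 `warn`, above
  0.3 `chance_correlation_or_outliers`. Band edges carry a 1e−9 tolerance so
  two-decimal reported values (0.93 − 0.73 = 0.20) do not tip a band through
  float subtraction error.
* **Y-scrambling**: n (default 100) label permutations, each retraining the
  forest with the *same fixed* hyperparameters and recording
  (R²_train, Q²_CV). No re-tuning per permutation: that isolates label
  permutation as the only varying factor and is ~100× cheaper. The verdict
  is `robust` iff the real point clears both acceptability thresholds and
  every scrambled Q²_CV falls below the Q² threshold. Scrambled *training*
  R² is reported but not thresholded — deep forests can memorize permuted
  labels, which is precisely why the null is built on cross-validated Q².
* **Applicability domain**: PCA is fitted on the scaled training matrix;
  per-component bounds are the min/max training scores, and an external
  compound is inside iff it is within bounds on every retained component
  (default 2 components — a scores-plot box; configurable upward). Both
  sets are projected through the same transform path so a training row used
  as an external compound lands exactly on, not epsilon outside, its bound.
* **Censored accuracy**: on the pIC50 scale, an IC50 `>` bound record (less
  potent than the bound) is predicted correctly iff predicted pIC50 <
  bound, and a `<` record iff predicted pIC50 > bound; equality counts as
  incorrect, and an empty set leaves its accuracy absent rather than zero.

## Synthetic data: what it emulates, and what it does not

`generate_activity_table` emulates the *bookkeeping* hazards of a public
bioactivity extract: censored records, counter-ion-bearing SMILES
(chloride/sodium/bromide — one heavy atom each, so the largest-fragment rule
is unambiguous), replicate rows with multiplicative concentration noise
(value·10^±ε, ε ~ N(0, sd)), missing values, and off-target confidence/assay
codes. Activities are drawn N(6.5, 1.2) clipped to [4, 9] pIC50 — the range
typical of IC50 panels. Each generated table carries a ledger naming, per
row, the first curation rule that should fire and the exact expected
surviving compound set, computed from the generator's own assignments; the
ledger is the oracle the curation tests and acceptance studies compare
against. Structures come from a bundled pool of 50 verified drug-like SMILES,
extended programmatically with unique substituted benzamides when more
unique base structures are needed. The generator does **not** emulate
structure–activity coupling (activities are random given the structure),
scaffold series, or assay-format heterogeneity beyond the assay-type code —
so pipeline runs on these tables correctly report near-zero Q², and passing
curation tests say nothing about model quality on real extracts.

`generate_planted_dataset` provides the complementary piece: iid
Poisson(rate) count or Bernoulli(0.5) bit features with a known linear
activity signal on a chosen feature subset plus Gaussian noise. It validates
the *learning* machinery — signal recovery, ranking, scrambling separation —
under exactly known ground truth. Real fingerprints are correlated and
sparse in structured ways; planted features are iid, so these studies bound
what the model machinery can do under ideal identifiability, not what any
real ERα extract will yield.

## Reference study conditions

The canned studies in `eraqsar.studies` fix one set of conditions each:

* **Curation ledger study**: 50 random corruption specs, 20–200 compounds,
  moderate corruption fractions (censoring ≤ 15% per sign, salts ≤ 30%,
  duplicates ≤ 20% with 2–3 replicates).
* **Planted regression study**: 600 compounds × 120 count features, 15
  informative with effects 0.4–0.8 pIC50/count, noise SD 0.4 — a
  high-signal regime where an acceptable model is achievable but not
  trivial; 70/30 split, 10-fold CV.
* **Scrambling null**: 100 permutations on the study's 420-row training set.
* **AD study**: 40 descriptors with two latent factors loading on feature
  blocks (so the first two PCs are aligned with interpretable directions),
  300 training / 100 external rows; the shifted set moves +5 SD on the first
  factor's 10 features. With iid isotropic descriptors a 2-component box
  cannot see such a shift — the shift vector projects onto an arbitrary
  plane — which is itself a documented limitation of scores-plot ADs.
* **Censored study**: presence-bit dataset (600 × 50, 5 effects of 0.8,
  noise SD 0.2) where the forest's error (RMSE ≈ 0.3 versus truth) is well
  under the 1-unit bound offset, so directional accuracy measures the
  decision rule rather than raw model error; 100 records per sign.
* **Forests throughout**: 100 trees, √p features, leaves of 1 — the
  scrambling null retrains 100 × (1 + 10 CV) forests, and 100 trees keeps
  that tractable without changing any conclusion reached at 500.

## Known limitations

* The curated-set size and headline performance of any real ERα extract
  depend on the database snapshot; this package reproduces the *procedure*,
  and its studies quantify behaviour on synthetic ground truth only.
* The correlation filter's greedy drop rule is one of several defensible
  readings of a two-threshold prune; both thresholds and the second stage
  are configurable.
* The PCA bounding box is a coarse AD: it ignores density inside the box and
  is blind to shifts orthogonal to the retained components (see above).
* Canonical-tautomer standardization follows RDKit's enumerator; other
  toolkits choose different canonical forms, which can shift tautomer-
  sensitive counts.
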