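# Methods

This note records the model behind `oncopair`, its assumptions, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test-bench does and does not
demonstrate.

## Model

### Pair features and why they travel across platforms

All classification features are binarized gene pairs: `g1_g2 = 1` iff gene
g₁ is strictly more expressed than g₂ within the sample, ties encoding 0.
If f is any strictly increasing function applied per sample (a platform
change, a library-size rescaling, a log transform), then
e(g₁) > e(g₂) ⇔ f(e(g₁)) > f(e(g₂)), so the binary feature vector — and
therefore every downstream score — is unchanged bit for bit. The same
argument covers the per-sample ascending rank transform used by the GRN
status (ranks are the canonical maximal invariant of monotone
transformations). This invariance is a theorem about the code, not an
empirical observation, and the test suite asserts it as exact equality
under log, power and positive-affine distortions.

What the invariance does *not* cover: distortions that differ per gene
(probe effects), missing genes, and cross-species queries beyond what a
one-to-one ortholog map captures. Those enter only through the gene-space
intersection step.

### Training pipeline

1. **Depth normalization.** Each training sample is downsampled to a fixed
   total (default 500,000 counts) by a seeded multinomial draw with
   probabilities proportional to observed counts. Samples below the target
   pass through with a warning — upsampling would fabricate counts. A
   deterministic rescaling mode (`mode="scale"`) exists for exact
   reproducibility experiments; whether the original procedure was
   stochastic or deterministic is not knowable from its description, so
   both are provided and the multinomial is the default.
2. **Template matching.** Per class, each gene's Pearson r against the 1/0
   class-membership vector. Zero-variance genes (or templates) score r = 0
   by convention rather than NaN. The n largest-r, n most-negative-r and n
   smallest-|r| genes are taken sequentially from disjoint remainders, so
   the three lists can never overlap; all correlation ties break by gene id
   lexicographically, making selection order-independent.
3. **Pair selection.** All k(k−1)/2 candidate pairs over a class's 3n genes
   (canonical orientation: lexicographically smaller gene first), ranked by
   |r| of the binarized feature against the same template, accepted
   greedily while no gene exceeds 3 appearances within the class's list.
   |r| is quantized to 12 decimals before ranking so mathematically tied
   pairs order by name regardless of floating-point summation order. The
   cap is enforced **per class**: a gene may appear in several classes'
   lists (global totals can exceed 3), matching the per-tumor-type wording
   it implements.
4. **Unknown pseudo-class.** The full binary training matrix is shuffled —
   an independent permutation within each row, then within each column —
   and k columns (default 70) are sampled without replacement. Shuffling
   conserves the multiset of entries while destroying the class structure;
   the sampled profiles train an explicit "Unknown" category so that
   out-of-distribution queries have somewhere to go.
5. **Forest.** A random forest where every tree is grown on a balanced
   bootstrap: `strat_size` samples (default 60) drawn with replacement from
   each class, sqrt(p) features per split. Stock random-forest
   implementations do not expose per-class per-tree sample sizes, so the
   ensemble is built directly from decision trees; a query's score for a
   class is the fraction of trees voting it, so score rows are exact
   distributions (sum to 1 by construction, not by normalization).
   Feature importances are the tree-averaged impurity importances,
   renormalized to sum to 1.

Defaults follow the published procedure (n = 30, m = 75, cap 3, 2000
trees, 60 per class per tree, 70 unknown profiles, 500k counts); the test
suite and acceptance script run 200–500 trees because vote fractions
stabilize well below 2000 trees at bench scale and the properties tested
are insensitive to ensemble size.

### Query scoring

Queries are never depth-normalized (the pair transform is scale-free).
A query must cover ≥ 90% of the genes used by the model's pairs; below that
the call errors. Between 90% and 100%, the default is still a hard error
listing the missing genes, because silently scoring missing pairs as 0
biases toward the 0-encoded orientation; passing `allow_missing=True`
accepts the bias explicitly, 0-encodes the affected pairs and warns.

### Cross-validation and threshold calibration

Each repeat draws a stratified 2/3 training fold, re-runs the *entire*
feature selection inside the fold (the leakage guard the repeated design
exists for), scores a balanced held-out draw plus freshly shuffled Unknown
queries, and records the profile. The decision threshold is the most common
macro-F1-maximizing grid value (grid 0–1, step 0.01) above a floor of 0.2
across repeats. Two details were genuinely open:

- **Unknown in macro F1.** The Unknown pseudo-class is excluded from the
  F1 average (mirroring its exclusion from headline AUPRC summaries);
  `include_unknown=True` reverses this.
- **Plateaus.** When a repeat's F1 curve attains its maximum on a plateau,
  the default contributes the smallest maximizer ("smallest" tie rule,
  conservative). For near-perfect classifiers the smallest maximizer sits
  below the floor in *every* repeat and calibration refuses with a
  diagnostic. The `tie_rule="plateau"` mode instead lets each repeat
  contribute its full maximizer set before the floor-and-mode step — the
  sensible reading when the curve plateaus — and is what the CLI and the
  acceptance run use. On the synthetic bench it calibrates to 0.21, the
  smallest grid value above the floor, exactly because separation is
  near-perfect.

### Category calls

With S the set of real classes scoring strictly above the threshold
("higher than" read as strict; threshold equality does not trigger):
correct (S = {nominal}), mixed (nominal ∈ S, |S| > 1), other (S ≠ ∅,
nominal ∉ S), none (S = ∅ **or** the top score overall lands on Unknown —
the Unknown-top condition takes precedence over simultaneous above-threshold
real classes). The truth table is total and mutually exclusive and is tested
exhaustively. Subtype calls return every subtype above threshold (several =
a mixed subtype) or "Unknown".

### Subtype classifiers

Samples of the parent tumor type carry subtype (or normal-tissue) labels;
all other samples are relabeled "Unknown" — real foreign tumors, not
shuffled profiles, train the subtype-level Unknown. The feature vector is
the subtype pair bits concatenated with the general classifier's score
profile of the sample, giving the forest a coarse-identity prior before the
fine split; its length is |subtype pairs| + |general classes| by
construction.

### GRN status

A balanced subsample (default 80 per class, with replacement and a warning
when a class is smaller) is depth-normalized and rank-transformed. Mutual
information between gene pairs is estimated by equal-width binning with
⌈√n_samples⌉ bins per gene (no estimator settings are published for this
step; equal-width on ranks is the simplest choice that is itself
rank-invariant). CLR scores are sqrt(z_i² + z_j²) with each z the edge MI
z-scored against the gene's own background MI distribution and clipped at
0; degenerate (zero-variance) backgrounds contribute z = 0.

Per class, the subnetwork is the set of differential seed genes
(|template r| ≥ 0.3 by default — the published procedure names no DE
method, so the same template machinery is reused for consistency), with
direction up/down by the sign of r, and the positive CLR edges among them
retained for inspection. Pairwise MI is quadratic in genes, so the
model-level builder infers the network on the union of seed genes only;
`build_clr_grn` itself accepts any matrix. Per-gene training rank means and
SDs are learned from the class-of-interest subsample on the full gene
space (so query ranks, computed on the shared gene space, are comparable);
zero-SD genes are dropped.

Scoring: z = (query rank − μ)/σ per subnetwork gene; deviations in the
expected direction (z ≥ 0 for up, z ≤ 0 for down) score a modified Z of 0,
otherwise |z|. The raw status is Σ(1000 − Z_mod)·w / Σw with C = 1000 an
arbitrary large constant and w the gene's summed classifier pair
importances (genes outside any pair receive the smallest positive summed
weight, so no weight is 0; the status is invariant to rescaling all
weights). Normalization is affine against two empirical references stored
at build time: the mean raw status of the class-of-interest training
samples (maps to 1) and of the training class with the lowest mean status
for that network (maps to 0). Values outside [0, 1] are possible and are
not clipped.

## The synthetic test-bench

`generate_cohort` draws negative-binomial counts (variance μ + φμ², shared
dispersion φ) around log-normal gene baselines and plants, per class,
disjoint blocks of up- and down-regulated genes whose means are multiplied
or divided by 2^effect. Reference conditions: 5 classes × 40 samples, 2000
genes, 30 up + 30 down per class at log2 effect 2, φ = 0.1, baselines
log-normal with median 300 and sdlog 1.5 (sample depths ≈ 1–2 M counts, so
downsampling to 500k engages). Query simulators blend a class's mean
profile with background (the per-gene median over class profiles, which
recovers the unperturbed baseline) or with a second class, then NB-resample
— emulating low-fidelity and mixed-identity cancer models; a platform-shift
simulator applies random per-sample monotone distortions; a subtyped
variant plants three extra signature blocks inside one parent class.

What passing on this bench shows: the pipeline recovers planted monotone
class signatures, its scores behave as distributions, its invariances hold
exactly, and its selection/calibration/metric code agrees with brute-force
reimplementation. What it does not show: performance on real tumors — the
generator has independent genes (no covariance structure), no batch
effects, no stromal/immune contamination, no subclonal mixtures, and its
classes are far better separated than, say, squamous cancers of
neighboring tissues. Reported AUPRCs of 1.0 on the bench are a property of
these easy study conditions, not a claim about real data.

## Numerical choices and degenerate inputs

- Ties in the pair transform encode 0 (strictness chosen for determinism).
- All correlation ties break lexicographically; |r| quantized at 1e-12
  before ranking.
- Duplicate gene rows on input collapse by sum for counts (preserves
  library size for downsampling) and by mean for intensities, with a
  warning; collapse is idempotent.
- Ortholog maps are filtered to strict one-to-one pairs before use; any
  remaining ambiguity is an error, and dropped-gene counts are reported.
- Zero-variance genes: r = 0 in template matching; dropped from GRN
  subnetworks (no z-score exists); MI bins collapse to one (MI 0).
- Thresholds compare strictly (score > threshold) everywhere.
- All randomness flows through seeded numpy generators; per-repeat and
  per-tree seeds derive from the configured seed via `SeedSequence`, and
  every artifact (model bundle, CV repeat) records the seed that produced
  it. Model bundles are single joblib files with a format-version field;
  loading rejects unknown versions and corrupted files.

## Known limitations

- The balanced-bootstrap forest is a from-scratch ensemble of sklearn
  decision trees; it exposes exactly what the method needs (per-class
  sample sizes, vote fractions, importances) but none of sklearn's other
  forest conveniences.
- `predict` requires near-complete pair-gene coverage; there is no
  imputation path by design.
- GRN status assumes the query shares the model's rank space; large gene
  losses shift the rank scale and only produce a warning.
- The citation-normalization and ESTIMATE-purity formulas are provided as
  computations on user-supplied inputs; the package does not fetch
  citation counts or compute ESTIMATE scores.
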