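# Methods

## The annotation problem and the model

`hybridgo` annotates genes with Gene Ontology (GO) terms — e.g. *mitochondrion*,
*transmembrane transporter activity*, *glutathione metabolic process* — by
training binary classifiers on per-gene feature vectors that combine:

* **expression principal components**: each gene's coordinates on the leading
  principal components of a z-score-normalized gene × sample expression
  matrix (genes are the observations, samples the variables);
* **metabolite-correlation features**: the Fisher-transformed Spearman
  correlation between a gene's expression and a metabolite profile (e.g. GSH
  or GSSG) over shared samples, zeroed when not significant;
* **knowledge scores**: categorical {1, 0, −1} calls from curated or
  predictive resources (MitoCarta-style localization calls, TrSSP-style
  transporter calls), one-hot encoded into two Boolean columns
  (1 → (1,0), 0 → (0,1), −1 → (0,0); the third column would be redundant).

Because GO gives positives but no certified negatives, training is
positive–unlabeled: for each of `n_bootstrap` (default 100) iterations an
equal-sized negative set is drawn uniformly without replacement from the
unannotated remainder, and a stratified `n_folds` (default 5)
cross-validation is run inside the iteration. Out-of-fold probabilities give
the evaluation; final annotations for unlabeled genes come from models
retrained on each iteration's full balanced set, averaged over iterations
within each PC-count variant, then reported as mean ± SE across the variants
(default PC counts 5/14/30/50; SE = sd of the variant means / √#variants).
Candidates for a composite phenotype are nominated by the **triple gate**: a
gene passes only if three classifiers (localization, transport, target
process) all assign it a probability strictly above `gate_threshold`
(default 0.80), with genes already annotated to a term overridden to
probability 1.0 on that axis.

## Preprocessing

* **Filtering** drops samples, then genes/metabolites, with more than
  `max_missing` (default 30%) missing values or zero standard deviation over
  observed entries. The two passes repeat to a fixed point: removing a row
  can raise a surviving column's missing fraction, and a single pass would
  then not be idempotent. The fixed-point loop preserves the samples-first
  order while guaranteeing `filter(filter(m)) = filter(m)`.
* **Imputation** is k-nearest-neighbour (default k = 5) under a NaN-aware
  Euclidean distance (squared differences over mutually observed
  coordinates, rescaled by the fraction of usable coordinates). A missing
  cell takes the unweighted mean of the observed values among the k nearest
  rows; if none of those rows is observed in the column, the column mean is
  used and the fallback is logged. Observed entries are never altered.
  This donor rule (k nearest rows overall, not k nearest rows *with* a
  value) is implemented directly rather than through a library imputer,
  whose donor selection differs.
* **Normalization** is per-gene z-scoring across samples before PCA, so
  components capture co-expression pattern rather than abundance scale; the
  alternative per-sample axis is available via `scale_axis="sample"`. PCA is
  SVD-based with a deterministic sign convention (each component's
  largest-magnitude loading is positive). When a variance target is given
  (defaults 0.93/0.95/0.97/0.98), the component count is the smallest whose
  cumulative explained variance reaches it; on any particular dataset the
  resulting counts are reported, not assumed.

## Correlation features — numerical choices

Spearman rho uses average ranks for ties. Significance uses the t
approximation `t = rho·√((n−2)/(1−rho²))` referred to a Student-t with n−2
degrees of freedom; correlations with p ≥ `alpha` (default 0.05, no
multiple-testing correction) are set to 0 before the Fisher transform
z = arctanh(rho). |rho| is clamped to 1 − 1e−12 first so perfect monotone
relationships yield a large finite feature (≈ 13.9) instead of infinity.
A `dof` switch allows referring the statistic to a fixed 2 degrees of
freedom for compatibility with a stricter literal reading of some published
descriptions; the n−2 default is the standard test. Constant gene rows have
undefined rho and contribute a 0 feature (logged).

## Training regime

* Negative pools exclude only the target term's positives; genes positive
  for other terms remain eligible (term overlaps are typically tiny).
* Fold assignment shuffles positives and deals them round-robin over folds;
  negatives continue the deal where the positives stopped. Per fold this
  bounds |#positives − #negatives| by 1 while total fold sizes differ by at
  most 1.
* One master seed spawns all per-bootstrap and per-model seeds through
  NumPy's `SeedSequence`, so the entire run — including prediction-table
  bytes — is reproducible, and any single bootstrap can be regenerated in
  isolation.
* Classifier families are scikit-learn's RandomForest (100 trees,
  √p features per split), DecisionTree (unlimited depth), GaussianNB, and an
  RBF SVM wrapped in sigmoid (Platt-style) calibration with internal 3-fold
  CV so it emits genuine probabilities. Hyperparameters are deliberately
  library-conventional and overridable: the framework's claims concern the
  bootstrap/ensemble *regime*, not tuned settings.
* A leakage audit (`audit_no_leakage`) replays the recorded training/test
  memberships and proves every out-of-fold probability came from a model
  that never saw that gene.

## Evaluation

AUROC (trapezoidal, rank-based tie handling) and AUPRC (step-integrated
average precision) come from scikit-learn; precision, recall, accuracy, F1
and MCC are computed from the confusion counts at a given threshold
(predicted positive ⇔ prob ≥ threshold; the candidate gate, by contrast, is
strict >). MCC is defined as 0 when any marginal is 0. Metrics are computed
per bootstrap iteration and averaged — the headline numbers — and also once
on the pooled predictions, labeled separately, since the two differ.
Confusion matrices default to threshold 0.75; TPR-vs-threshold curves
support mean sensitivity over a threshold band (e.g. 0.3–0.5) for comparing
against external prediction tables. Inter-classifier agreement is the
Pearson r over genes confidently annotated (> 0.6 or < 0.4) in **both**
tables; requiring confidence in both is the stricter reading of an ambiguous
convention and is the declared choice here.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs so the full
pipeline is testable offline:

* expression = loadings · factors + Gaussian noise (`noise_sd`, default 1.0),
  with `n_factors` (default 3) latent factors whose scales decay
  geometrically (`factor_decay`, default 0.7). The decaying spectrum mirrors
  real expression panels, where a handful of leading components carry most
  variance; with equal scales the eigenvalues would be nearly degenerate and
  the leading components unidentifiable under resampling.
* positives (`n_positive`, default 50 of 400 genes) get their factor-1
  loading shifted by `signal_strength` (default 2.0) if they are in the
  metabolite-associated fraction (`metabolite_assoc_frac`, default 0.5), and
  their factor-2 loading shifted otherwise — so all positives are separable
  through the leading PCs but only the associated ones correlate with the
  metabolite, which is generated as factor-1 scores plus noise (a second,
  paired metabolite row mirroring an oxidized/reduced pair is optional).
* knowledge scores equal the true label with probability
  `knowledge_accuracy` (default 0.9) and are flipped otherwise — symmetric
  errors, since no better error model is established — then withheld (−1)
  with probability 1 − `knowledge_coverage` (default 0.9).
* `missing_frac` (default 5%) of expression entries are masked completely at
  random.

The defaults are the study conditions used by the tests and the acceptance
script: 400 genes × 60 samples keeps a full bootstrap × CV run at seconds to
minutes while leaving every estimated quantity (AUROC bands, gate rates,
component cosines) well away from small-sample degeneracy. What the
generator does **not** emulate: RSEM/TPM marginal distributions, batch or
tissue structure, realistic missingness mechanisms (missingness is MCAR),
or annotation noise that correlates with expression level. Passing tests
therefore demonstrate the correctness and calibration of the *procedure*,
not expected performance on any real compendium.

## Known limitations

* Evidence-code filtering treats annotations as a flat table; no GO-graph
  ancestor propagation is performed.
* The negative-sampling regime assumes unannotated genes are mostly true
  negatives; for very incomplete ontology terms the estimated probabilities
  are conservative.
* The SVM wrapper's calibrated probabilities depend on the internal CV split
  and are the least stable of the four families on very small gene sets.
* Component counts matched to variance targets are data-dependent; the
  5/14/30/50 defaults are sensible for large cell-line panels but any other
  matrix will map targets to different counts, which the PC model reports.
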