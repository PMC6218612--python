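# Methods

## Problem setting

Resting-state BOLD time series are non-stationary and strongly
autocorrelated, which inflates zero-lag cross-correlations between voxels
and between regions. A classification pipeline built on correlation
graphs therefore risks discovering "biomarkers" that reflect
autocorrelation structure or selection overfitting rather than group
differences. This package implements the full discovery pipeline —
prewhitening, functional parcellation, graph-measure extraction, nested
cross-validated feature selection, and a selection-frequency null — with
a synthetic generator that makes every stage falsifiable.

## Synthetic cohorts

The generator starts at the "preprocessed voxel time series" level. A
cohort is parameterized by `SyntheticConfig`:

- **Grid and regions.** Voxels fill a full 3D grid (default 6×6×6).
  Ground-truth regions are grown by competitive breadth-first accretion
  from randomly seeded voxels under 6-connectivity, which guarantees
  contiguity under the same adjacency the parcellation module uses.
- **Latent signals.** Each region carries one latent signal: a
  unit-variance stationary AR(1) process (default lag-1 autocorrelation
  φ = 0.5, a representative value for band-passed BOLD at TR = 2 s).
  Cross-region lag-zero correlations are imposed by multiplying the
  independent AR columns by the symmetric PSD square root of the coupling
  matrix; this preserves φ exactly and gives the target correlations in
  expectation. The default coupling is a uniform weak positive background
  (r = 0.2) standing in for globally shared signal.
- **Group difference.** `planted_effects` adds deltas to chosen coupling
  entries for the patient group only. Deltas that break positive
  semidefiniteness raise an error naming the offending pair — silent
  projection would distort the planted effect size.
- **Voxels and sessions.** Voxel series are the region latent plus iid
  Gaussian noise (default SD 1.0, i.e. noise as strong as signal). A
  second session redraws the latent signals and perturbs the coupling
  matrix with symmetric Gaussian state noise (default SD 0.1), projected
  back to a valid correlation matrix by eigenvalue clipping; this
  emulates the session-to-session state variability that limits
  within-subject reproducibility. The magnitude is a free knob, not an
  estimate — no published value quantifies it.
- **Scale and defaults.** 177 time points at TR = 2 s per scan (matching
  the acquisition the pipeline was designed around) and 10 + 10 subjects
  by default; tests and examples choose explicit cohort sizes per
  question. Band-limiting is not applied: the AR coefficient is the
  autocorrelation control, and the pipeline's properties are tested
  against autocorrelation, not a specific frequency band.

What the generator does **not** emulate: scanner physics, motion,
physiological noise, preprocessing artifacts, spatial noise correlation,
hemodynamic response shape, or heterogeneous per-region dynamics. Passing
tests therefore demonstrate the pipeline's statistical machinery under
its own assumptions, not performance on real scans.

## Prewhitening

The DFT of each series (length exactly T, no padding or taper) is divided
by its modulus and inverted. Conventions:

- The DC bin is always zeroed: band-passed data are mean-free, and a
  zero-mean output makes downstream cosine similarity equal Pearson *r*.
  Consequently the circular autocorrelation of a full-support output is
  an impulse up to a constant −1/T (flat unit spectrum on T−1 bins).
- Bins with modulus ≤ `zero_tol` (relative, default 1e−12) are set to 0,
  not to unit magnitude: no energy is injected at absent frequencies.
  This also makes the transform idempotent on its retained support.
- The transform is a-causal and circular by design.

## Parcellation

Correlation is computed on mean-centered columns (a no-op after
prewhitening), clipped to [−1, 1]; zero-variance columns are an error
naming the voxel. The clustering applies the Lance–Williams Ward update
to squared supplied distances — the standard "pre-computed distance"
convention; with a fully connected adjacency it reproduces an independent
Ward implementation exactly (verified against scipy on small instances).

Open choices made here:

- **Adjacency** defaults to 6-connectivity (strictest standard notion of
  "spatially neighboring"); 18/26 available. A disconnected voxel graph
  is rejected before clustering.
- **Tie-breaks** on equal Ward criteria go to the lexicographically
  smallest cluster-id pair, for determinism.
- **Merge heights** are recorded as-is; the spatial constraint can invert
  them, and no monotonicity is asserted.
- **Memory guardrail**: the dense N×N machinery refuses above a
  configurable voxel limit (default 4000) with guidance to downsample;
  full-brain voxel counts are out of desk scope.
- Cut labels are renumbered 1..K by smallest member voxel index.

## Graphs and measures

Edges are Pearson correlations between region-mean series with negatives
zeroed (negative correlations are rare — a few percent — and have no
agreed interpretation). Binarization keeps exactly
⌊density·K(K−1)/2⌋ strongest weights (rank thresholding; a scalar weight
threshold cannot achieve an exact density under ties), ties at the cut
broken by (i, j) order. Louvain runs on the weighted graph with a fixed
seed; binary-only measures use the binarized graph.

The measure registry implements named node, pair, and global measures
(see `RegistryConfig`). Two conventions worth noting:

- **Matching index** defaults to the Jaccard form on neighbor sets
  excluding the pair itself, with a degree-normalized variant behind a
  flag; both agree at the 0 and 1 extremes and are oracle-tested.
- **GTOM** uses m-step reachability sets N_m (self excluded) with
  `(|N_m(i) ∩ N_m(j)| + a_ij) / (min(|N_m(i)|, |N_m(j)|) + 1 − a_ij)`;
  under full reachability this is exactly 1 for adjacent pairs and
  (k−2)/k for non-adjacent ones. Default m = 2.

Feature assembly adds mean and SD across nodes/pairs per measure,
aggregating over finite values only; any feature non-finite for at least
one subject (e.g. a disconnected pair's distance) is dropped table-wide
and recorded.

## Double cross-validation

5 outer folds (equal sizes, remainders round-robin) per random partition,
N_perm partitions; the non-test subjects rotate through a 4-fold
train/validation scheme. The screen keeps features with mean validation
accuracy strictly above 60%; SFS starts from the best screened feature
(reusing the screen accuracies — identical definition, same folds) and
greedily adds the candidate maximizing mean validation accuracy, ties to
catalog order, up to the configured maximum. The selected prefix
maximizing mean inner accuracy (earliest on ties) defines each fold's
prediction for misclassification counting; the paper-style curves report
accuracy at every prefix length.

Design choices where the procedure is underdetermined:

- Features are standardized with non-test-subject statistics only;
  margin classifiers are scale-sensitive and leakage must be avoided.
- The inner scheme is a 4-fold rotation (each chunk validates once)
  rather than 4 independent redraws.
- If the screen retains nothing (routine under shuffled labels), the
  single best feature by screen accuracy is used so the fold still
  yields predictions; a constant majority-class fallback was measured to
  be systematically anti-predictive on held-out folds and rejected.
- Degenerate folds (one class absent) trigger a warning at plan time.

Chance level is estimated by repeating the entire process on shuffled
labels. Comparators: independent top-k selection by screen accuracy,
Fisher-LDA ranking with pseudo-inverted within-class scatter (defined for
singular scatter), and discrete Adaboost over 10 linear-SVM weak learners
(normalized sample weights; degenerate rounds end boosting with a logged
notice). Cross-session evaluation freezes the feature set and model on
session 1 and scores session 2.

## Selection-frequency null

Inclusion of a marked feature in one S-subset of F screened features has
probability S/F (hypergeometric h(1|F,S,1)); across N_fold sets the count
is Binomial(N_fold, S/F) and p-values are exact upper tails. The null
inherits two approximations: the sets are treated as independent despite
fold overlap, and F is taken as the mean screened count across folds
(the screen output varies per fold). Default α = 0.001. For the null to
have power the selected-set size must be well below the screened pool
(S ≪ F); the end-to-end test therefore selects small sets (S = 4) from a
multi-region feature space.

## Problem sizes in the test suite

Chosen to exercise every contract at desk scale: parcellation recovery
uses a 6×6×6 grid (216 voxels), 4 regions, 20 subjects at low noise;
measure oracles run over every 6-node graph (all 32,768) for the pair
measures, a deterministic 1-in-37 subsample of them plus 50 random 8-node
graphs for the path-enumeration betweenness/clustering oracles; CV
integrity checks use 60-subject Gaussian feature cohorts; the end-to-end
recovery run uses 100 subjects, 8 regions, and a planted coupling delta
of −0.2, which produces |d′| ≈ 2 on the region-pair correlation (measured
by direct simulation at n = 300). The Monte-Carlo check of the binomial
tail uses 10⁶ replicates of the two-stage draw.

## Known limitations

- The functional atlas is built from controls only (enforced), so
  region definitions carry no patient information — but also cannot
  adapt to patient-specific topography.
- Group concatenation introduces boundary discontinuities between
  subjects; they are accepted, as is standard, with no cross-fade.
- The measure registry is a documented set of standard graph measures,
  not a reproduction of any specific published measure list.
- Real-cohort accuracies are not reproducible here: no scan data ship
  with the package, and the generator's idealized structure makes
  synthetic accuracies incomparable to clinical ones.
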