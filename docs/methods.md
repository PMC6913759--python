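# Methods

`painvol` implements an end-to-end procedure for defining *pain volatility*
from app-recorded pain diaries and predicting a user's future volatility
class from their first month of records. This note documents the model, the
synthetic cohort that stands in for real diary data, and the numerical
choices made where the design was genuinely open.

## The volatility statistic and class definition

For a user's date-ordered severity ratings r_1 … r_n (0–10 visual-analogue
scale) within a 30-day observation window, volatility is the mean absolute
consecutive change

    v = (1 / (n − 1)) · Σ_{i=2}^{n} | r_i − r_{i−1} |.

Two windows are used per user: the **predictor window** (days 0–29 from the
first record; the first record anchors day 0) and the **outcome window**
(days 150–179, i.e. the sixth 30-day block). Only users with at least
`min_records = 5` records in *both* windows enter the analysis; two records
are the mathematical minimum for v, but five gives a usable estimate.

Volatility values from both windows are pooled (two points per user) and
split into **low** and **high** classes by one-dimensional 2-means
(25 restarts). The class boundary is the midpoint between the largest value
of the low cluster and the smallest value of the high cluster, so
thresholding at it reproduces the cluster assignment exactly; the boundary
midpoint (rather than the centroid midpoint) yields a single clean
separating value. `validate_threshold` re-derives the threshold on random
subsamples to check its stability. The prediction target is the
outcome-window class; everything else is computed from the predictor window.

## The 132-feature representation

Eight categories: demographics (gender code, age; 2), app usage (record
count, distinct record days; 2), pain statistics (mean/SD of ratings,
mean/SD of |Δ|, the rise of an OLS trend line over the window and its
absolute value, plus dichotomised severity and volatility levels; 8), pain
descriptors (locations 24, symptoms 20, characteristics 13, environments 7),
factors (aggravating 15, alleviating 14, ineffective 14), pain conditions
(6), medications (5) and mental-health conditions (2). Descriptor, factor,
condition, medication and mental-health features are binary *presence*
indicators — reported in at least one record of the window, or present in
the profile — the minimal encoding that stays comparable across users with
different record counts.

Open encodings were resolved as follows: the volatility-level feature
thresholds the user's predictor-window volatility at the pooled 2-means
boundary; the severity-level feature applies the same 1-D 2-means procedure
to the pooled window mean severities (symmetry with the volatility level);
gender is a small integer code with an explicit `unknown` category; missing
ages are imputed with the median age of eligible users. Same-day records are
kept as separate consecutive ratings (no aggregation), with file order
breaking date ties. Trend features use ordinary least squares on
(day, rating); a window whose records all fall on one day has no trend and
contributes 0.

## Cross-validation, class imbalance, and consolidation

Evaluation uses stratified 5-fold cross-validation over users. Because the
low-volatility class is roughly three times the size of the high class, each
fold's *training* portion is balanced by random under-sampling of the
majority class — all minority users plus an equal-size uniform random subset
of majority users — repeated 5 times, giving 5 folds × 5 subsamples = 25
balanced training sets. Under-sampling happens strictly after the CV split,
so test folds keep their full, imbalanced class sizes; this is the only
ordering under which per-class accuracy denominators equal the full class
sizes. A leakage guard verifies every training set is disjoint from its
fold's test set.

For each subsample id, the 5 fold-models pool their held-out predictions
into one prediction per user, scored as specificity (low-class accuracy),
sensitivity (high-class accuracy) and overall accuracy. The five subsample
predictions per user are then consolidated by **majority vote**: a user is
called high-volatility when at least 3 of the 5 subsample models vote high.
Vote counts are validated to be odd, so ties cannot occur.

## Models

* **Random forest** — 100 bootstrap trees, Gini splitting,
  floor(√p) candidate features per node; prediction is the majority of
  trees (the vote fraction is the predicted probability). Tree fitting is
  delegated to scikit-learn; per-node class counts and impurities stay
  accessible because the importance machinery consumes them.
* **Logistic regression (ridge / lasso)** — internally standardised,
  penalty strength chosen by 5-fold cross-validation on the training set
  only (deviance scoring) over a 19-point log-spaced grid, λ ∈ [10⁻², 10⁴]
  on the standardised scale; weaker penalties are never selected and make
  the l1 solver crawl on near-separable training sets. Decision threshold
  0.5, appropriate for balanced training sets. Solvers: lbfgs (ridge) and
  liblinear (lasso; exact zeros in the coefficient vector).

## Feature selection and the consensus rule

Three routes score features on every one of the 25 balanced training sets:

* **Gini importance**: mean decrease in impurity accumulated from the node
  statistics of a 100-tree forest; per split, the parent's weighted Gini
  impurity minus the children's, normalised by the root sample count, summed
  over a feature's splits and averaged over trees. The per-forest total
  equals the telescoped root-minus-leaves impurity decrease (a conservation
  identity used as a test).
* **Information gain**: H(Y) − H(Y|X) in bits; continuous features are
  discretised into 10 equal-frequency bins (robust to the heavy-tailed count
  features), binary features left untouched.
* **Boruta**: each feature competes against a freshly permuted shadow copy;
  a hit is scored when the feature's importance exceeds the best shadow's.
  Two-sided binomial tests (hit probability ½, Bonferroni-corrected over the
  currently undecided features) promote or demote features each iteration;
  rejected features leave the design together with their shadows, confirmed
  features stay in it (they keep absorbing signal) but are no longer tested,
  and whatever is undecided after `max_iter` iterations remains tentative.
  The importance statistic is the **Z-scored out-of-bag permutation
  accuracy drop** (mean over trees / its standard error). Impurity-based
  importance was deliberately rejected here: a feature's chance correlation
  with the labels is fixed across iterations and systematically inflates
  impurity importance over freshly permuted shadows, producing spurious
  confirmations on pure-noise inputs, whereas out-of-bag accuracy
  contributions do not generalise.

Per ranking method a top set is taken per training set — defaults 11 (Gini)
and 8 (information gain), matching where the score curves flatten on
representative runs; an automatic largest-relative-drop elbow rule is
available — and intersected across all 25 sets. Boruta contributes the
intersection of its per-set confirmed features. The final consensus list is
the union of the three per-method sets.

## Synthetic cohorts

Real diary data of this kind is private, so a seeded generator produces
cohorts with the structure the analysis assumes. Defaults describe the
target population: 879 users, 21% planted high-volatility, per-class
predictor/outcome classes linked by a persistence probability of 0.8
(chosen once as consistent with the ~70% accuracies such models reach;
higher persistence would make the prediction task unrealistically easy),
record counts per window Poisson with mean 20 (floored at `min_records`,
capped at one record per day plus same-window repeats excluded), and
severities from a **clipped Gaussian random walk** on [0, 10] with step SD
`step_scale · √(π/2)`, so the expected mean absolute step equals
`step_scale` (0.8 low / 2.8 high by default, which puts the pooled 2-means
boundary near 1.6). A configurable number of descriptor tokens (default 9)
is class-informative: their per-record occurrence probability is shifted by
`descriptor_effect` (default 0.25) for high-volatility windows, on a 0.10
baseline.

What the generator does *not* emulate: within-user severity autocorrelation
beyond the random walk, engagement drift over months, correlated descriptor
co-occurrence, and real medication/condition ontologies. Tests that pass on
these cohorts therefore validate the pipeline's mechanics and its ability to
recover planted structure — not claims about real diary data.

Calibration note: because the walk is clipped to [0, 10], the realised mean
absolute step of high-volatility users falls below the nominal step scale
(about 1.8 for a nominal 2.5); class-conditional volatility means and the
persistence parameter are recovered within Monte-Carlo error in the test
suite.

## Problem sizes and numerical choices

The cohort-scale acceptance checks run 10 seeded cohorts of 2,000 users
with step scales 0.5/2.5 through full consensus selection (25 training sets
× 3 methods each). At that scale the Boruta stage uses 25 trees of depth 6
per iteration, half-size bootstrap draws, at most 120 out-of-bag rows per
tree for the permutation importance, and at most 25 iterations — sizes
chosen so a full run remains comfortable on a single CPU while leaving the
decision statistics ample (a confirmation at Bonferroni-corrected α = 0.05
over 132 features needs 13 consecutive hits, well inside the iteration
budget). The standalone `boruta()` defaults are larger (40 trees, depth 7,
30 iterations). Ties in importance rankings break by schema order;
`kmeans_threshold` refuses inputs with fewer than two distinct values;
degenerate trend fits (all records on one day) raise a dedicated error at
the statistic level and contribute zeros at the feature level.

## Known limitations

* The consensus top-set sizes (11 / 8) encode where importance-score curves
  flatten on representative runs; there is no principled universal cutoff,
  and the elbow rule is an approximation, not a substitute for inspecting
  the curves.
* Boruta decisions on weakly informative features are sensitive to the
  iteration budget; features genuinely but marginally correlated with the
  outcome in a given sample can be confirmed — this is a property of the
  shadow-comparison construction, not a bug.
* The severity-level feature re-uses the volatility thresholding procedure
  for its cutoff; this is a symmetry choice, and other dichotomisations of
  mean severity are defensible.
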