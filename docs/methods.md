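# Methods

## The prediction problem

In LC-MS/MS proteomics, a peptide's retention time (RT) on a reversed-phase
column is highly reproducible under fixed chromatographic conditions, and
an accurate RT prediction lets a scheduled SRM or SWATH method monitor each
target only inside a narrow extraction window, multiplying the number of
targets per run. Classic predictors regress RT on amino-acid *composition*
(counts weighted by a hydrophobicity index); `locusrt` instead regresses on
amino-acid *locus* — which residue occupies which sequence position — so
that positional effects (e.g. the distinct retention contribution of a
residue adjacent to a terminus) are visible to the model.

## Locus-vector encoding

A peptide is placed on a fixed grid of 25 positions × 20 residue channels
(500 binary features, flattened position-major, channels in alphabetical
one-letter order). Residues are anchored from both termini inward: a
peptide of length L ≤ 25 fills grid positions 1..⌈L/2⌉ with its leading
residues and the last ⌊L/2⌋ positions with its trailing residues; the grid
middle stays zero. A 7-mer therefore occupies positions 1–4 and 23–25.
Peptides longer than 25 residues are encoded from their first 13 and last
12 residues; the overhang is invisible to the model. Terminal anchoring
reflects the chemistry: terminal neighbourhoods dominate the positional
component of retention, while the interior contributes mainly through
composition.

For L ≤ 25 the encoding is injective (the occupied positions always form a
prefix-plus-suffix pattern that determines L), so no information is lost
relative to the sequence itself. The ⌈L/2⌉/⌊L/2⌋ split generalizes the
4 + 3 anchoring of a 7-mer and is consistent with the 13 + 12 rule for long
peptides. The channel ordering and flattening order are serialized with
every model; prediction refuses to run when they disagree with the
encoder's (a silent mismatch would permute features).

## ε-SVR with RBF kernel

The regression function is f(x) = Σᵢ βᵢ K(sᵢ, x) + b with
K(u, v) = exp(−γ‖u − v‖²), trained by minimizing the regularized risk
C·Σ L_ε(yᵢ − f(xᵢ)) + ½‖w‖², where the ε-insensitive loss ignores
residuals inside a tube of half-width ε (minutes). On binary locus vectors
‖u − v‖² is the count of differing entries, so the kernel measures shared
(position, residue) loci. Features are not scaled (already {0, 1}).

Hyperparameters are selected by exhaustive grid search with 3-fold internal
cross-validation on the training set: C ∈ {2⁻⁸..2⁸}, γ ∈ {2⁻⁸..2⁸},
ε ∈ {10⁻³, 10⁻², 10⁻¹} (867 points) by default. The CV criterion is mean
squared error on held-out folds; folds are drawn once from `cv_seed` and
reused for every grid point so all points face identical splits; ties break
to the smallest C, then γ, then ε (the smoother model). A coarse sub-grid
(`HyperparamGrid.coarse`: C ∈ {2⁴, 2⁶, 2⁸}, γ ∈ {2⁻⁸, 2⁻⁶, 2⁻⁴},
ε ∈ {10⁻², 10⁻¹}) is provided for interactive and desk-scale work; on the
synthetic benchmark it selects the same region of the grid that the full
search does, at 1/50 the cost. The solver is libsvm (via scikit-learn) at
stopping tolerance 1e-3, recorded in the model file. Models are saved as
self-describing JSON (support vectors as one-indices, since they are
binary; floats at full round-trip precision), so a loaded model predicts
bit-identically.

## Calibration across chromatographic conditions

Predictions are specific to the gradient the model was trained under. For
a new condition, a set of peptides observed under that condition
("calibration peptides", chosen as the top-n by a caller-supplied rank
score standing in for identification reliability/abundance) is predicted
with the pre-trained model and fitted by ordinary least squares:

    observed RT = A × predicted RT + B.

All other predictions are then mapped through (A, B). No outlier rejection
is applied by default (an optional single trimming pass exists behind a
flag). Note the estimator property: because the regression runs observed on
*predicted*, any shrinkage in the predictions (predictions under-dispersed
relative to truth) inflates Â above the true gradient ratio by the
reciprocal of the same-condition obs-on-pred slope, and B̂ absorbs
−(Â − A)·mean(predicted). With a well-fitted model this bias is a few
percent; it vanishes when the calibrants are peptides the model fits
tightly (e.g. the same sample re-run under a new gradient). The
calibration-recovery experiment uses exactly that same-peptides scenario,
so its near-zero post-calibration window is an upper bound on what
disjoint-peptide transfer achieves.

## Evaluation statistics

Signed error is predicted − observed (minutes). The report contains
Pearson's r, error mean and sample SD (n−1), Δt95%, and a capacity curve.

Δt95% is the width of the narrowest extraction window centered on the
predicted RT that contains at least 95% of the errors: twice the
⌈0.95·n⌉-th smallest |error| (numpy's `inverted_cdf` quantile). This exact
covering order statistic — rather than an interpolated percentile — is
used so the value is literally the minimal covering window; interpolated
percentiles are available via `percentile_method="linear"`. A narrowest
possibly-asymmetric interval of signed errors is available via
`method="minimal"`; the symmetric default matches how scheduled
acquisition centers windows on predictions. Below 20 points the 95%
quantile is poorly determined and a warning is emitted.

The capacity curve reports, for each window width w, the fraction of
peptides with |error| ≤ w/2 — the fraction of targets a scheduler with
w-minute windows would actually catch.

## Synthetic ground truth

The generator emulates an identification list from a tryptic digest:

* **Sequences** — C-terminal K or R, no internal K/R (fully cleaved),
  lengths 7–25 from a truncated-geometric distribution (median ≈ 10),
  matching the short-skewed length profile of tryptic peptides.
* **Retention model** — RT = intercept + Σᵢ coef(aaᵢ)·w(i) +
  length_coef·L + N(0, noise_sd), clipped to [0, gradient]. Defaults:
  Kyte–Doolittle hydropathy at 2.0 min per unit (giving an RT spread of
  ≈ 20 min SD on the 120-min default gradient, i.e. peptides elute across
  most of the gradient), terminal multipliers 1.5/1.3/1.1 (N-side) and
  1.4/1.2/1.1 (C-side) applied to the first/last three positions (both for
  peptides shorter than 6), length coefficient 0.7 min/residue, intercept
  50 min, noise SD 1 min. The clipped fraction is logged.

The ground truth is additive-linear with positional weights — deliberately
*not* an SVR — so recovery experiments are non-circular; and because the
positional weights break pure additivity in composition, a
composition-only linear baseline demonstrably underperforms the
locus-vector model when terminal effects are strong.

What the generator does **not** emulate: modification heterogeneity,
missed cleavages in the observed list, heteroscedastic or drifting noise,
peak-shape/loading effects, inter-run nonlinear warping, and
identification FDR structure. Passing the synthetic benchmarks therefore
shows the pipeline recovers a learnable additive-positional retention map
under realistic sampling and noise — not that it attains any particular
accuracy on real LC-MS/MS data.

## Desk-scale benchmark sizes

The shipped benchmark runs (tests and `scripts/acceptance.py`) use 1000
training / 1000 held-out peptides for the headline evaluation, 10 × 300
training peptides for the small-training check, and a 500-peptide
same-sample gradient transfer (slope 1.3, offset +5 min) with 200
calibrants, all on the coarse grid. These sizes were chosen so a complete
run finishes in well under a half hour on one CPU while leaving the
qualitative conclusions (r ≈ 0.99 at n = 1000, mean r ≈ 0.93 at n = 300,
near-exact calibration recovery) stable across seeds.

## Known limitations

* Positional resolution is fixed at 25 grid positions; longer peptides
  lose their middle residues (empirically benign, since termini dominate).
* Modified residues have no channel; modified and unmodified forms of a
  sequence are indistinguishable to the model.
* The observed-on-predicted calibration regression carries the shrinkage
  bias described above when calibrants are peptides the model has never
  fitted; robust or errors-in-variables alternatives are out of scope.
* Grid-search cost is cubic-ish in training size per point; the full
  867-point grid at n ≈ 5000 is an overnight job on one core, which is why
  the coarse grid exists.
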