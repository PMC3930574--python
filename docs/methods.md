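# Methods

This note documents the statistical model, the selection procedures, the
default parameters and the numerical conventions implemented by the
`dysphonia` package, together with what the synthetic evaluation data do and
do not emulate.

## Problem setting

Input is a table of N voice records, each a vector of real-valued vocal
measures (fundamental-frequency statistics, jitter and shimmer perturbation
families, noise/harmonics ratios, and nonlinear measures such as RPDE, DFA,
spread1/spread2, D2 and PPE) with a binary label: healthy control (CO) or
Parkinson's disease (PD). Records are grouped by subject — several
sustained-vowel phonations per person — so record-level cross-validation
and subject-grouped cross-validation are both supported and reported
distinctly, since the former leaks subject identity across folds.

Reference problem size: 195 records (48 CO, 147 PD), 22 measures, roughly
31 subjects with ~6 records each. All defaults below were chosen for this
scale.

## Pipeline stages

### 1. Correlation screening (`correlation`)

Pearson correlation matrix over all measures (`numpy.corrcoef`).
Zero-variance columns get correlation 0 off-diagonal (with a warning) and 1
on the diagonal. `filter_collinear` examines all pairs with |r| above a
threshold (default 0.95), sorted by descending |r|, and drops the member
with the later column index; ties in |r| resolve by pair order. The jitter
family (Jitter(%), Jitter(Abs), RAP, PPQ, DDP) and shimmer family are the
intended targets: `Jitter:DDP = 3·MDVP:RAP` and `Shimmer:DDA =
3·Shimmer:APQ3` are exact linear identities (r = 1) in the standard layout.

### 2. Sequential forward selection (`feature_selection`)

Greedy wrapper search starting from the empty set; at each step the
candidate measure maximizing the criterion jointly with the already-selected
set is appended. Criterion: stratified k-fold (default 5) cross-validated
accuracy of a near-unpenalized logistic regression (L2 with C = 10⁶, i.e.
effectively maximum likelihood but numerically stable under separation).
Ties break by measure column order; the search stops at `max_features`
(default 4) or as soon as no candidate strictly improves the criterion. The
full criterion trace is returned for inspection.

`fit_logistic` proper uses Newton/IRLS maximum likelihood (statsmodels
`Logit`, up to 100 iterations, tolerance 1e-8). Complete or quasi-complete
separation (non-finite or > 10⁶ coefficients, or non-convergence) triggers a
ridge fallback with penalty λ = 1e-6 and the model is flagged
(`separation_flag`), since the MLE does not exist under separation.

### 3. Kernel PCA (`kpca`)

Polynomial kernel k(x, y) = (xᵀy + c)^d on the raw (unstandardized)
selected measures. The Gram matrix is double-centered,
K_c = K − 1·rowmeans − colmeans·1 + grandmean, and the top two eigenpairs
are taken (`scipy.linalg.eigh` with `subset_by_index`). Dual coefficients
are scaled α_k = v_k / √λ_k so projections have feature-space unit-norm
axes; the score variance along component k is then λ_k/(n−1), which the
linear-kernel case (d = 1, c = 0) verifies against ordinary PCA exactly.

Numerical conventions:

- Eigenvalues must exceed max|K_c|·1e-12; otherwise the fit raises
  `KPCADegeneracyError` rather than silently dividing by ~0.
- Eigenvector sign is arbitrary; it is fixed so that the PD score centroid
  minus the CO score centroid is non-negative on each component (falling
  back to making the largest-|score| entry positive when labels are absent).
- Out-of-sample transform re-applies the stored centering statistics:
  K_c(test) = K(test) − mean over training columns − stored row means +
  stored grand mean.

Kernel-parameter selection (`select_kernel_params`) grid-searches
d ∈ {1,…,10} and c ∈ {1,…,10} and maximizes a scale-free separation
criterion: the Euclidean distance between class centroids in the score
plane divided by √(trace of the pooled within-class covariance / (n−2)).
The normalization matters: with unstandardized measures of magnitude ~10²,
raw score distances grow monotonically with d (kernel values scale like
(xᵀy)^d), so an unnormalized criterion would always pick the grid corner.
Ties resolve to the smallest d, then the smallest c.

### 4. Parzen density estimation and MAP rule (`density_map`)

Each class-conditional density on the 2-D score plane is a Parzen estimate
with a shared bivariate Gaussian kernel of diagonal covariance
Σ = h·diag(σ₁², σ₂²), where σ₁², σ₂² are pooled (ddof = 1) variances of the
two score components over all training records and h ∈ (0, 1] is a single
scaling factor. All densities are computed in log space with `logsumexp`;
this matters because score magnitudes from high-degree kernels make naive
exponentials underflow.

Bandwidth selection (`select_bandwidth`): h is searched on the grid 0.01,
0.02, …, 1.00 maximizing the leave-one-out log-likelihood of the training
scores under their own class density (the diagonal of each class's
pairwise-kernel matrix is excluded). Ties resolve to the smaller h.

Classification is MAP: posteriors P(ω|z) ∝ p(z|ω)P(ω) with priors taken as
empirical class frequencies by default ("equal" or an explicit dict are
accepted). Decisions are made on the log-posterior scale; exact ties go to
PD (the screening-oriented choice: a false negative is costlier than a
false positive). If both class log-densities underflow to −∞ the posterior
falls back to the priors, and the record is flagged.

### 5. Baselines (`baselines`)

- **FLDA**: closed form w ∝ S_W⁻¹(m_PD − m_CO) with the midpoint
  ½·wᵀ(m_PD + m_CO) as threshold. `regularize=True` (default) adds 1e-8·I
  to S_W before solving; a singular unregularized S_W raises with a message
  suggesting regularization. The decision function is affine-invariant up
  to the documented transformation, which the tests verify.
- **RBF SVM**: `sklearn.svm.SVC` (C-SVM, RBF kernel), decision values
  oriented so PD is positive. `tune_svm` grid-searches
  C ∈ {2⁻⁵, …, 2⁵} and, by default, gamma values expressed as multipliers
  of the scale heuristic γ₀ = 1/(n_features · Var(Z)) rather than as
  absolute values — on KPCA scores whose variance depends strongly on the
  kernel degree, absolute gamma grids are meaningless (every value is
  effectively 0 or ∞). Selection is by stratified CV accuracy inside the
  training data; ties resolve to the smallest C, then smallest gamma.
  `kkt_residual` exposes the maximum KKT violation of a fitted model for
  verification.

### 6. Evaluation (`evaluation`)

`make_folds` supports two strategies: `stratified_record`
(`StratifiedKFold`, shuffled with the given seed) and `grouped_subject`
(subjects shuffled by seed, then assigned largest-first to the lightest
fold, keeping every record of a subject in one fold). `run_cv` performs
k-fold CV (default 5) with **all** model selection nested in each training
fold — kernel-parameter grid, bandwidth search, SVM tuning — unless
`global_fit=True` is requested explicitly (reported in the output so the
two modes cannot be confused). Outputs: pooled confusion counts, accuracy,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), ROC curve and
trapezoidal AUC (via `sklearn.metrics.roc_curve`/`auc`; AUC equals the
normalized Mann–Whitney U statistic, which the tests assert to 1e-12), and
per-subject misclassification counts. Constant score vectors yield a
warning and AUC 0.5.

## Synthetic data (`synthetic_data`)

The package is evaluated on generated tables because the reference
phonation recordings are not redistributable with it. Everything produced
by this module is synthetic and labelled as such in record manifests.

`synthetic_uci_table(seed)` emulates, at the level the generator can
support:

- the 22-measure UCI column layout, record naming (`phon_R01_S<nn>_<k>`)
  and subject grouping (48 CO records over 8 subjects, 147 PD over 23);
- the published per-class means and standard deviations of the four
  informative measures (Fo, Jitter(%), DFA, spread2), enforced exactly by
  affine moment matching after sampling;
- the exact collinear identities DDA = 3·APQ3 and DDP = 3·RAP, plus
  plausible within-family correlations for the remaining measures.

It does **not** emulate the joint dependence structure of real phonation
measures: within each class the informative measures are independent
Gaussians. Real voice data are neither independent nor Gaussian (the CO
group in particular is multimodal in several measures), and those joint
features are precisely what a nonlinear KPCA + Parzen pipeline exploits.
Consequently the attainable accuracy on the stand-in (~83%) is lower than
on real data, and a linear rule (FLDA) is near Bayes-optimal on it — the
class-conditional Gaussian structure with unequal diagonal covariances
gives an almost-linear optimal boundary. Headline-accuracy comparisons on
the stand-in therefore show that the pipeline is correctly implemented and
well-behaved, not that it attains any particular published figure;
`recovery_suite` complements this with planted-structure checks (SFS
recovers the informative measure; MAP CV accuracy ≥ 0.95 on a well-separated
two-class problem; empirical priors recovered).

## Defaults summary

| Parameter | Default | Rationale |
|---|---|---|
| Collinearity threshold | 0.95 | drops exact/near-exact family duplicates only |
| SFS max features / folds | 4 / 5 | small dominant set; stable CV at N≈200 |
| Logistic ridge fallback λ | 1e-6 | finite coefficients under separation, negligible bias otherwise |
| Kernel grid | d, c ∈ {1,…,10} | covers linear through strongly nonlinear maps |
| Kernel criterion | centroid distance / pooled within-class spread | scale-free across degrees |
| Bandwidth grid | h ∈ (0, 1], step 0.01 | LOO log-likelihood is unimodal-ish here; fine enough at N≈200 |
| Priors | empirical | matches the deployment base rate of the table |
| Tie at P(PD\|z) = P(CO\|z) | call PD | screening asymmetry |
| SVM C grid | 2⁻⁵ … 2⁵ | standard coarse log grid |
| SVM gamma grid | same grid × 1/(p·Var(Z)) | scale-adapted to the score plane |
| CV folds | 5 | reference protocol; ≈39 records per fold |

## Limitations

- Record-level stratified CV leaks subject identity across folds; the
  subject-grouped strategy is provided and should be preferred for any
  claim about generalization to new speakers.
- The MAP rule under a 147:48 prior sacrifices specificity; applications
  with balanced costs should pass explicit priors.
- The KPCA eigen-decomposition is O(N³) in records; fine for N in the
  hundreds, not intended for large corpora.
- All quantitative results shipped with the package are computed on
  synthetic tables with the caveats above.
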