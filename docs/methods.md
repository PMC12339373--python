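# Methods

This note records the modelling choices, defaults and known limitations
of `neurofuse`, in the spirit of a model-description appendix.

## Connectivity construction

**fMRI.** Functional connectivity is the Pearson correlation between ROI
time series (`compute_fmri_fc`). Columns with zero variance are an
error naming the ROI, because a constant regional signal indicates an
upstream extraction fault rather than something to impute.

**EEG.** Power-envelope connectivity (`compute_pec`) follows the
standard analytic-signal construction: zero-phase band-pass (4th-order
Butterworth run forward and backward; the filter family is a free
choice, pinned by pass/stop behavior — a 10 Hz tone passes the alpha
band with ≥95% amplitude, a 40 Hz tone with ≤5%), Hilbert transform,
pairwise orthogonalization removing the instantaneous zero-lag component
of the reference signal, squared-magnitude envelopes, natural log with a
1e−12 floor, Pearson correlation of log envelopes. The two directed
values per pair are averaged; orthogonalization is asymmetric and no
convention dominates in the literature, so the symmetric mean is used.
When orthogonalization annihilates the target signal entirely (exactly
shared zero-lag signal, e.g. identical channels), the directed value is
defined as 0 — full removal means no envelope co-fluctuation survives —
while a constant *input* envelope is an error. No envelope downsampling
is applied.

**Normalization.** Both measures pass through: Fisher r-to-z (atanh) on
off-diagonal entries (|r| = 1 clipped to 1 − 1e−7 with a warning), zero
diagonal, then z-scoring of the N(N−1)/2 upper-triangle edges within
subject, mirrored back. atanh must precede z-scoring because atanh is
only defined on (−1, 1); z-scoring first would push values outside its
domain. Within-subject (rather than across-subject per-edge) z-scoring
is chosen so that no statistic of the training cohort leaks into test
subjects. Edge vectorization is always the strict upper triangle in
row-major order.

## COBE and augmentation

Common Orthogonal Basis Extraction treats each subject's normalized
connectivity matrix as a block whose columns are ROI profiles, and finds
an orthonormal basis lying (nearly) in every block's column space by
greedy alternating projection with deflation: project the candidate onto
each block's span, average, renormalize, repeat to convergence (1e−6,
max 1000 iterations); accept while the mean per-block residual
‖w − P_s w‖² stays below `tol` (default 0.01), then deflate the accepted
direction out of every block.

A square full-rank block spans all of R^N, which would make "common"
vacuous; for such blocks the search is restricted to each block's top
`block_rank` principal directions (augmentation uses max(2, N/4)), so
the common basis captures the dominant group-shared structure (the group
template). Augmentation removes the top-C components for each C in the
schedule (default [1, 2], i.e. rate 2), re-symmetrizes the residual as
(M + Mᵀ)/2, and tags each sample with its source subject's outcome. The
cross-validation harness applies augmentation strictly inside training
folds; the early-stopping validation split is drawn from non-augmented
subjects only.

## Fusion model

All learnable components are numpy arrays with hand-derived gradients
(verified against central finite differences to ~1e−6 relative error in
the test suite) and an Adam optimizer.

Forward pass per modality: operator P = rownorm(A ⊙ sym(S_m)) with A the
ReLU-clamped cosine similarity of connectivity profiles (unit diagonal)
and S_m the learnable edge scaling initialized at 1 and symmetrized each
pass; row sums are floored at 1e−6 in magnitude, sign-preserving. Two
rounds of Z ← tanh(P Z W + b); node activations h = feature-axis mean of
the final embedding; latent z = W_mᵀ h. The correlation penalty is
−(1/d) Σ_j corr(z_fmri[:,j], z_eeg[:,j]) with 1e−4 ridge on the
variances (per-dimension CCA-style rather than trace correlation — the
per-dimension form is what makes the aggregation-weighted column
read-out interpretable). Softmax weights α multiply latent dimensions
before the MLP head (two tanh hidden layers, linear output on the
standardized outcome scale).

Defaults (standard / fast mode for N = 20 ROI cohorts): hidden width
64/32, latent d 32/8, MLP 64→32 / 32→16, λ = 0.5, lr 1e−3 / 3e−3, ≤200 /
≤150 epochs with patience-20 early stopping on a 10% validation split,
batch 32. The fast-mode learning rate is higher because the loss surface
at N = 20 is small and well-conditioned.

Three choices serve interpretability of S_m specifically: a 10× learning
rate multiplier (S_m sits behind a row normalization and moves slowly
otherwise), an L2 pull toward its initialization (1e−3) so only edges
with persistent predictive gradient retain large deviations, and a
30-epoch warm-up during which S_m is frozen so its updates reflect
trained-pathway sensitivities rather than the initial random network.
Edge scores are reported as the fold-averaged symmetrized S_m minus its
initialization value — signed, ranked by magnitude — and averaging over
the fold models of several runs (the read-out used in the acceptance
checks pools three runs) substantially reduces optimizer noise.

## Evaluation protocol

Cross-validation is 10-fold, stratified by outcome quantile (sorted
outcomes cut into blocks of 10, fold labels shuffled within block), with
pooled out-of-fold R² = 1 − SSres/SStot and Pearson r; pooling rather
than per-fold averaging stabilizes 12-subject test folds. Permutation
tests permute labels before the full CV and use the add-one estimator
p = (1 + #{perm ≥ obs})/(1 + B); permuted refits may use a reduced
configuration (12 epochs, no augmentation) — a chance-level null needs
no convergence, and the reduced null is empirically centered at R² ≈ 0.
The harness accepts a ridge-regression backend on vectorized edges
through the identical code path; calibration checks of the permutation
machinery use it because they need tens of thousands of refits.

Band comparison is a paired t-test on per-seed R² against the alpha
band with Benjamini–Hochberg correction; a zero-variance nonzero
difference is reported as p = 0. The transfer path trains an MLP with
half-width hidden layers on the union of both modalities' training
latents and scores new subjects from a single branch's latent. Clinical
scales are predicted from latents (reduced to ≤5 principal components to
keep the spline design well-posed) by a generalized additive model with
5-df cubic B-spline smooths per feature and out-of-fold Pearson r,
FDR-corrected across scales. Correlations are compared with the
independent-samples Fisher z-test. Stratification assigns each patient
the arm with the larger predicted improvement (ties → sertraline),
cross-tabulates preference alignment against responder status (strictly
more than 50% HAMD₁₇ reduction) within each actual arm, and tests with
the Yates-continuity-corrected chi-square (degenerate margins reported
as NaN rather than an error at this level) plus a pooled-variance t-test
on reduction rates.

## Synthetic cohorts

The generator emulates the statistical skeleton the method relies on,
not biophysics. Connectivity-level cohorts: a group correlation template
(random factor structure, moderate off-diagonals), per-subject symmetric
deviations composed of a rank-3 nuisance field (scale 0.08), dense
symmetric noise (sd 0.03), and the planted signature — a per-subject
expression score multiplying fixed per-edge loadings (0.5–1.5) over all
pairs of the 10 planted ROIs (sd 0.12), with 30% idiosyncratic per-edge
jitter. Every latent factor mixes a shared subject component (weight
√ρ, default ρ = 0.7) with modality-private components (√(1−ρ)). The
outcome is effect size × standardized planted-edge sum + Gaussian noise
(defaults 1.0 and 0.5, i.e. a best-possible predictor explains ~80% of
outcome variance, in the range of a strong but noisy biomarker), mapped
onto a clinical HAMD₁₇ scale (baseline ≈ 18 ± 3, ΔHAMD ≈ 6 ± 4,
integer-rounded). A subnetwork mode was chosen over independent
per-edge factors because coherent connectivity modes are how predictive
signatures present in measured connectomes, and because at n = 120 the
per-edge information of 45 independent factors would be below the
sampling noise floor — unrecoverable by any method.

Time-series cohorts: fMRI-like data are AR(1) Gaussian series (a = 0.3)
with the subject's target matrix as stationary cross-correlation
(nearest-positive-definite repair with eigenvalue flooring when
needed); EEG-like data are carrier oscillators (frequency jittered
within the band, independent phases) modulated by slow log-normal
envelopes (<1 Hz latent dynamics) whose latent correlations follow the
same target, plus 2% sensor noise. Measured PEC therefore recovers the
planted structure up to a monotone rescaling, not as an identity — the
log-normal/envelope chain is nonlinear.

What passing tests on these cohorts do **not** show: robustness to
scanner/site effects, motion and physiological artifacts, parcellation
misalignment between modalities, non-linear outcome dependence, missing
data, or cohort shift; the planted signature is also cleaner-rank than
real treatment-response biology is likely to be.

## Problem sizes and numerical choices

Desk-scale defaults: N = 20 ROIs, n = 120 subjects, 10 folds,
3-run read-outs, 200-permutation nulls at the reduced configuration —
sizes chosen so the full test battery completes in minutes while every
statistic stays estimable. Determinism: every entry point takes a seed
and threads it through numpy Generators; identical seeds reproduce runs
bit-for-bit (training parameters to 1e−6 after float accumulation).
Degenerate inputs have pinned behavior: |r| = 1 clipping before atanh,
sign-preserving row-sum floors in the operator, ridge in the correlation
loss, epsilon floors under logs, chi-square zero margins as errors at
the statistic level.

## Known limitations

ROI importance shares mass across correlated profiles, so at top-10
granularity (on 20-ROI cohorts) typically 4–8 of the 10 signature ROIs
surface per modality; at the top-20 read-out used for reporting the
signature is fully covered. Edge-level recovery through the scaling
matrices is real but noisy: the model can fit the outcome through node
features alone, so S_m receives only part of the signal; the measured
rank correlation between |edge score| and planted effect is ~0.25–0.45
depending on the cohort draw. The GAM association step reduces latents
to principal components and will miss structure orthogonal to the top
components. COBE's common basis is only identifiable up to rotation
within near-degenerate shared subspaces.
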