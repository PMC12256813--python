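# Methods

## Model

Each recording is modelled as a linear time-varying dynamic network: the
channels × samples matrix is split into non-overlapping windows of
duration T = 125 ms, and within each window the one-step model
x(t+1) = A x(t) + e(t) is fitted by least squares. The window-wise A
matrices are treated as locally time-invariant snapshots of inter-channel
influence; nonstationarity is handled purely by the windowing, not by any
smoothness constraint across windows. e(t) is assumed white and
state-independent; no input term is modelled (resting-state assumption).

At the working rate of 250 Hz a 125 ms window is floor(31.25) = 31
samples, i.e. 30 one-step regression pairs for N = 19 unknowns per row.
That is barely overdetermined, so `fit_dnm` defaults to a relative ridge
of 1e-6 × mean(diag(X₁X₁ᵀ)) per window — small enough not to move
well-conditioned fits (the scale-equivariance and exact-recovery tests run
with ridge = 0) while keeping near-singular windows finite. Degenerate
(all-zero) windows are flagged and excluded from downstream averages
rather than zero-filled.

## Sink index

For each window's A, row and column 2-norms (diagonal included) are ranked
across channels — rank 1 smallest, rank N largest, ties broken by stable
first-occurrence order — and normalized by N. The sink index is

SI_i = c − ‖(rr_i, cr_i) − (1, 1/N)‖₂,  c = √2 by default,

which ranges over [c − √2(1 − 1/N), c]; for N = 19 and c = √2 that is
[0.0744, 1.4142]. The additive constant is configurable (`eq2_constant`):
with c = 2 the same geometry shifts to [0.66, 2.00]. The default √2 is the
value consistent with a unit-diagonal range anchored at zero-ish minima
and with cohort-level FT means near 1.34 reported for this marker family;
both constants are supported and none of the rank geometry changes.
Ranking raw squared sums instead of square-rooted norms would be
monotone-equivalent and cannot change any SI value.

Sink indices are averaged over all valid windows of the whole recording,
then averaged (unweighted) within the FT group (Fp1, Fp2, F3, F4, F7, F8,
T3, T4) and the CPO group (O1, T5, O2, T6, Cz, Pz, P3, Fz, P4, C3, C4).
Fz is kept in the CPO group despite being a frontal-midline electrode, for
fidelity to the grouping convention this marker uses. The subject marker
is SI_FT / SI_CPO.

## Preprocessing

Order: downsample to 250 Hz (polyphase resampling with its own anti-alias
low-pass), 0.5–48 Hz Butterworth band-pass, notch at 50 Hz and each
harmonic below Nyquist ({50, 100} Hz at 250 Hz) with a 2 Hz stopband.
All filters are 4th-order Butterworth applied forward-backward
(zero-phase); the order and the zero-phase choice are this package's
defaults, documented rather than inherited — zero-phase filtering avoids
phase distortion that would bias the one-step regression. Channels are
demeaned before filtering (a large DC offset would otherwise leak through
the high-pass as edge transients) and the residual sample mean is removed
after. Heavy artefact removal (ASR, ICA) is deliberately out of scope; the
`artefact_hook` config slot accepts an external cleaning callable and
defaults to identity, so reproductions on clinical data can plug in
published tools.

## Baseline features

* Band powers: Welch periodogram averaging (8 s Hann windows, 50%
  overlap), integrated over delta 1–4, theta 4–8, alpha 8–12, beta
  12–30 Hz; FT and CPO group means and their ratio. Powers are absolute;
  the classification feature is the alpha-band FT/CPO ratio.
* Hjorth parameters: activity = var(x), mobility = sqrt(var(Δx)/var(x))
  (the RMS angular frequency, rad/sample), complexity =
  mobility(Δx)/mobility(x) ≥ 1, → 1 for a pure tone.
* Time-frequency: per 8 s window (50% hop) and channel, a 5-level dyadic
  wavelet decomposition (db4 default; sym4, coif2, haar selectable); the
  Hjorth triplet on each of the 5 detail subbands, averaged over windows:
  19 × 5 × 3 = 285 features. This channel × subband × parameter
  composition is the only one consistent with the stated ingredient count
  and is flagged as our reconstruction. PCA to 5 components is fitted
  inside each training fold only (leakage control).

## Classification

One-vs-rest multiclass evaluation under leave-one-out cross-validation:
per-fold continuous class scores (probabilities or margins, never hard
labels) are pooled across folds; per-class ROC curves and a
micro-averaged curve are built from the pooled scores, with micro TPR/FPR
pooling per-class confusion counts at each threshold. AUCs are trapezoidal
integrals of the stored curve points (all thresholds retained). Eight
classifier families sit behind one interface (LDA, QDA, kNN, naive Bayes,
decision tree, random forest, logistic regression, SVM) with library
default hyperparameters and a recorded seed; `k_neighbors` defaults to 2.
Per-cohort AUC distributions are produced by repeating LOOCV with
incremented seeds (default 8 repetitions; only stochastic families vary).
Constant feature matrices short-circuit to chance-level output (AUC 0.5)
with a warning instead of fitting ill-posed models.

## Group statistics

Mann–Whitney U is reported as min(U_a, U_b) (complete separation gives
U = 0) with two-sided p: exact by enumeration/closed-form when both
samples have n ≤ 12, tie-corrected normal approximation otherwise. The
approximation deliberately omits the continuity correction so that the
two-group identity H = z² with the tie-corrected Kruskal–Wallis statistic
holds exactly. Kruskal–Wallis p comes from chi-square with k − 1 df;
Dunn's post hoc z uses mean-rank differences with tie correction and
Bonferroni adjustment by the number of pairwise comparisons, capped at 1.
Significance tiers: *** p < 0.001, ** p < 0.01, * p ≤ 0.05 (boundary
inclusive), n.s. otherwise.

## Synthetic cohorts

The generator simulates x(t+1) = A x(t) + e(t) at 250 Hz with unit
Gaussian process noise, a 2 s discarded burn-in, and optional additive
white measurement noise (`obs_noise_sd`, default 0.3 in cohorts relative
to the unit-process-noise signal scale — a pure process-noise "noise
level" would be a no-op, since least squares and ranking are both
scale-invariant). Base matrices are sparse (density 0.4, Gaussian
weights), with constant self-loops of 0.3 and per-column incoming mass
normalized to 0.4 with 3% lognormal jitter, so that planted structure —
not base-matrix heterogeneity — controls the norm rankings. A channel
planted as a sink with strength s has its off-diagonal column entries
scaled by (1 − s) and its off-diagonal row rescaled so the row norm
interpolates toward 1.3× the maximum base row norm; at s = 1 it is
unambiguously the most-driven, least-driving node. Matrices are uniformly
rescaled to spectral radius ≤ 0.95 (rank-preserving).

Cohorts: FTD-like subjects get sinks at all 8 FT electrodes, AD-like at
all 11 CPO electrodes, HC-like none; planted strength is the effect size
(default 0.8) plus per-subject Gaussian jitter (sd 0.05, clipped to
[0, 1]). Default cohort sizes are 10/10/10. The default recording length
is 60 s — chosen once as a desk-scale length at which the group ordering
of median ratios is already stable; clinical-scale 12-minute recordings
are a config change (`duration_s=720`), and the planted-sink fidelity
study uses 240 s recordings where the Spearman correlation between
planted strength and recovered sink index exceeds 0.9 under observation
noise 0.5.

What the generator does *not* emulate: 1/f spectral shape, alpha rhythms,
eye/jaw artefacts, volume conduction, electrode drift, or inter-subject
montage variation. Passing tests therefore demonstrate that the pipeline
recovers planted linear network structure under noise — not that any
clinical effect size is reproduced. Cohort-level numeric agreement with
published clinical datasets additionally depends on artefact-cleaning
choices outside this package's scope and is reported, not asserted.

## Numerical choices and edge cases

* Windowing: window length floor(T·fs/1000) samples; trailing partial
  window dropped; recording shorter than one window is an error.
* Underdetermined ridgeless windows (L − 1 < N) fall back to the
  minimum-norm pseudo-inverse solution and are flagged.
* Rank ties are measure-zero for real fits; the stable tie rule makes
  degenerate inputs deterministic.
* EDF export quantizes to 16 bits over the per-channel data range and
  stores the record duration in an 8-character header field; round-trips
  are exact to those precisions.
* All randomness flows through `numpy.random.default_rng` seeds recorded
  in provenance output; reruns with identical config are byte-identical.

## Known limitations

Scalp-level transition matrices mix volume conduction with genuine
inter-regional influence; the sink geometry is rank-based, hence invariant
to global scaling but insensitive to absolute coupling strength. The
125 ms / 19-channel regime leaves single-window estimates noisy by design;
all inference rests on averaging thousands of windows. The source index
(the symmetric notion for the opposite corner) is intentionally not
implemented.
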