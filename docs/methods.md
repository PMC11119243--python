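# Methods

This note documents the models and numerical choices behind `entrocsp`: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Pipeline model

The package classifies two-class motor-imagery (MI) EEG. The physiological
contrast is event-related desynchronization (ERD): imagery suppresses
band-limited power in mu (8–13 Hz) and beta (13–35 Hz) rhythms over the
involved sensorimotor area. Every stage is built around variance structure,
not mean structure, because ERD is a variance phenomenon.

Stages, in execution order:

1. **Epoching.** Trials are cut relative to cue markers with a half-open
   window `[start, end)` seconds, `N = round((end−start)·fs)` samples, 0-based
   indexing. This makes trial lengths exact (a 4-s window at 100 Hz is 400
   samples, a 3.5-s window 350). Window offsets are configuration: paradigms
   with 3.5-s cues typically use `[0.5, 3.0)` (discarding pre/post-imagery
   half-seconds), 4-s cue paradigms `[0, 4)`. Published descriptions of cue
   timing are sometimes internally inconsistent, so nothing is hard-coded.
2. **Broadband filtering.** 5th-order Butterworth bandpass, 8–35 Hz,
   applied as second-order sections forward and backward (`sosfiltfilt`,
   odd-extension padding). Zero-phase filtering cancels group delay at the
   cost of squaring the magnitude response; the same engine and phase
   convention is used for the broadband stage and the sub-band bank so that
   narrowband latencies stay aligned across bands.
3. **Entropy channel scoring.** Per trial and channel, amplitudes are binned
   into `B` equal-width bins over `[min, max]` of that trial/channel and
   scored `−Σ_b p_b ln p_b` (nats). The channel score is the mean over
   trials; channels are ranked descending, ties broken by ascending channel
   index, and the top `k` kept. Because bin edges track the data range, the
   score is invariant to affine amplitude scaling and the ranking is
   invariant to the log base. Scoring happens *after* broadband filtering
   (the pipeline's block order); this matters — out-of-band noise masks the
   narrowband structure the score detects, and recovery of planted channels
   on synthetic data degrades visibly when ranking raw signals.
   Default `B = 256`. With trial lengths of a few hundred samples this puts
   the estimator in the sparse-histogram regime, where the score is driven
   by bin-collision statistics: channels dominated by narrowband
   (few-degrees-of-freedom) sources spread occupancy more evenly and score
   higher than broadband-noise channels of any amplitude. An alternative
   per-sample-sum reading of the score (`entropy_literal_sample_sum`) is
   provided for comparison; it is not Shannon entropy and is off by default.
4. **Filter bank.** Mu (8–13), low beta (13–22), high beta (22–35) and full
   band (8–35 Hz); shared edges and the redundant full band are deliberate.
   Sub-band order defaults to 5, the same as the broadband stage (one filter
   order governs the whole pipeline unless overridden).
5. **CSP.** Per band, trial covariances are trace-normalized
   (`C_m = XXᵀ/tr(XXᵀ)`) and averaged per class into `B₁, B₂`. The variance-
   ratio objective is solved as the generalized symmetric eigenproblem
   `B₁w = λ(B₁+B₂)w` — same extremal directions as the raw ratio, but the
   composite right-hand side keeps the problem well-conditioned, and the
   eigenvalues land in `[0, 1]` with the convenient complement property
   (swapping classes maps λ to 1−λ). The `V` eigenvectors from each end are
   kept (default `V = 2`, so 4 filters/band, 16 features total). Columns are
   scaled to `wᵀ(B₁+B₂)w = 1` and sign-fixed (first nonzero entry positive)
   so fitted models are deterministic. Before decomposition each class
   covariance is shrunk, `B ← (1−γ)B + γ(tr B/L)I` with `γ = 1e−6`, guarding
   rank deficiency (duplicated channels, `k` approaching `N`).
6. **Features.** `f_v = ln var(w_vᵀx)` per trial, sample variance with
   `ddof = 1`. The log of the *raw* variance is the default;
   `normalized_variance=True` switches to the conventional `var/Σvar`
   variant. Both are exposed because the literature uses both and they differ
   by a per-trial constant shift that matters to linear classifiers.
   Zero-variance projections are floored at `1e−12` before the log.
7. **Classification and evaluation.** Stratified 5-fold cross-validation
   over trials with a fixed shuffle seed; when the fold count exceeds the
   minority-class size (e.g. leave-one-out) plain k-fold is used, and a fold
   whose training partition loses a class raises an error rather than
   silently degrading. Channel ranking, CSP filters and the classifier are
   refit inside every training fold; the held-out fold is only transformed
   and scored. A `leaky_selection` switch reproduces whole-dataset channel
   selection for comparison with protocols that rank once on all data.
   Metrics come from the confusion matrix with class 1 positive; zero
   denominators report 0 and are flagged rather than raising.

   Classifiers: RBF-SVM with `C = 1` and kernel width from the median
   pairwise training-feature distance (`γ = 1/(2·median²)`), a robust
   scale-free default; LDA with pooled covariance and `1e−6` shrinkage;
   and a one-hidden-layer network (10 sigmoid units, 2 linear outputs)
   trained full-batch by L-BFGS, at most 500 iterations, seeded. On
   16-dimensional log-variance features all three are deterministic given
   the seed.

When a channel-count sweep asks for `k < 2V`, the per-band pair count is
clamped to `⌊k/2⌋` (at least one pair; `k = 1` is rejected), since `2V`
filters cannot exceed the channel count. Sweep rows are therefore
self-contained pipelines of possibly different feature width; the best `k`
is the accuracy argmax, smallest on ties.

## Synthetic data

`simulate_mi_eeg` emulates the variance contrast the pipeline detects, and
only that. Per trial, `n_sources` Gaussian white-noise series are band-pass
filtered into the source band (default 8–13 Hz, the same zero-phase engine
as the analysis filters, 1 s of padding discarded on each side),
standardized, scaled by the class amplitude, mixed into the informative
channels, and buried in independent broadband Gaussian noise on all
channels. Class 1 sources have amplitude `source_amplitude` (default 2.0,
in units of the noise standard deviation — a strong but realistic
sensorimotor-rhythm SNR); class 2 sources are scaled by `erd_ratio ∈ (0,1]`,
so `erd_ratio = 1` is an exact null and smaller values mean stronger ERD
contrast. The default mixing draws one source per informative channel and a
random orthonormal mixing matrix: orthonormal rows guarantee each
informative channel receives exactly the full source variance while the
spatial structure stays non-trivial. Passing an explicit mixing vector
instead plants a known discriminative direction, which the CSP tests compare
against a dense random-search maximizer of the class-variance ratio.

Defaults mirror a typical two-class competition recording: 100 Hz, 4-s
trials (400 samples), 100 trials/class, 16 channels of which 4 informative.
Everything derives from one seed; identical configs give identical tensors.

What the generator does **not** emulate: volume conduction from deep
sources, artifacts (EOG/EMG), non-Gaussian amplitude distributions,
session-to-session nonstationarity, and channel correlations in the noise.
Passing tests therefore demonstrate correctness of the algorithms under the
stated variance model — not expected accuracy on real recordings, where
SNRs are lower and the entropy ranking faces structured noise.

`make_fixture_suite` writes five canonical fixtures (separable, null,
rank-deficient via a duplicated channel, single-trial-per-class,
constant-channel) as CSV containers with ground truth; the suite is
byte-reproducible.

## File formats

The native container is a directory with `manifest.json` plus either one
CSV per trial (small, human-diffable) or one HDF5 tensor (large runs);
labels are normalized to `{1, 2}` with the original coding preserved in
`label_map`, and channel order is authoritative from the file. The
competition MAT reader assumes the documented public layout (`cnt` in 0.1 µV
steps, `nfo.fs`, `nfo.clab`, `mrk.pos`, `mrk.y`; IV-I's −1/+1 coding mapped
to 1/2, NaN to unknown) and fails loudly, naming the missing field, on
anything else.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
modest sizes chosen to make the measured properties stable: 60 trials/class
for end-to-end discrimination and channel-recovery rates (matching the
separable fixture's geometry), 30 trials/class for the channel-count sweep,
20 simulation seeds for rates, 2×10⁵ candidates for the dense
ratio-search oracle on 4-channel problems. Published subject-level
accuracies on competition datasets depend on the original recordings and
are outside what synthetic checks can or should reproduce.

## Known limitations

- Entropy scoring assumes informative channels differ from noise channels
  in amplitude-distribution shape after broadband filtering; a source with
  the same effective bandwidth as the noise is invisible to it.
- The histogram estimator's absolute value depends on `B` and trial length;
  only the ranking is meant to be interpreted.
- CSP is two-class by design here; no multiclass extension is provided.
- The ANN is a small fixed architecture; no early stopping beyond the
  optimizer's own convergence test.
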