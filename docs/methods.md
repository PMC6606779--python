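# Methods

## The generative model and its two coders

All analyses treat data as draws from a linear generative model
`x = Σₘ aₘ Φₘ + n`, with the dictionary elements Φₘ unit-norm rows of a
K × D matrix and `n` isotropic Gaussian noise. Two inference/learning
schemes are compared on the same data:

**LCA + SGD.** MAP inference under a factorial Laplace prior minimizes
`E(a) = ½‖x − aΦ‖² + λ‖a‖₁`. The locally competitive algorithm integrates
`u̇ = Φx − u − (ΦΦᵀ − I)a`, `a = T_λ(u)`, by explicit Euler (step 0.1,
200 iterations by default; both configurable). These values are not part of
the model — they only need to be small/large enough for convergence, which
the energy-monotonicity test checks at small step size. Dictionary learning
takes one gradient step `ΔΦ ∝ aᵀ(x − aΦ)/B` per minibatch (B = 100) and
renormalizes every row to unit norm afterwards; MAP inference would
otherwise drive ‖Φₘ‖ → ∞ against aₘ → 0.

**The λ controller.** Rather than fixing λ, training holds the
reconstruction quality at a target SNR (default 15 dB): after each
minibatch, `λ ← λ·(1 + g·(SNR − SNR*)/SNR*)` with gain g = 0.05, the
factor clamped to [0.5, 2] so one catastrophic minibatch cannot zero the
controller out (a multiplicative update cannot recover from λ = 0). The
fixed point is SNR = SNR*; whether to adapt per minibatch or per epoch was
an open choice and per-minibatch was taken for faster settling. Perfect
reconstructions report a capped 300 dB sentinel so histories stay finite.

**SAILnet.** The spiking coder optimizes the Lagrange function

    L = ½ Σₘᵢ (xᵢ − Φₘᵢ aₘ)² + Σₘ θₘ (aₘ − p) + ½ Σₘₙ Wₘₙ (aₘ aₙ − p²)

whose first term is the *per-connection* squared error — an approximation
to the true reconstruction error valid when activities are sparse and
uncorrelated, and the reason every gradient is synaptically local
(ΔWₘₙ needs only aₘaₙ; Δθₘ only aₘ; ΔΦₘᵢ only aₘ, xᵢ and Φₘᵢ itself).
Activities are spike counts of discrete-time leaky integrate-and-fire
units (50 steps per stimulus, dt = 0.1, leak 1.0, reset to zero, unit
spikes); W is kept symmetric, non-negative and zero-diagonal (inhibitory
couplings). The dictionary is *not* renormalized — that would be a
non-local operation — so homeostasis comes entirely from θ and the decay
term in the Φ rule. Learning rates default to (α_Φ, α_W, α_θ) =
(0.01, 0.1, 0.02), with the multiplier rates larger than the dictionary
rate so the constraints hold throughout learning. The target rate is
p = 0.05 spikes per stimulus window. The thresholds chase the slowly
moving equilibrium of Φ, so the rate constraint is only satisfied after a
few thousand updates; the training tests allow for this.

**Signed spikes.** The signed variant fires ±1 spikes at ±θ crossings so a
single unit can code a sign-symmetric feature. Its multiplier updates use
spike-event magnitudes |aₘ| (a signed sum would average to zero and the
rate constraint would be meaningless); the Φ rule keeps the signed
activities, since it must know the direction of drive.

## Preprocessing

Waveforms are DC-removed and scaled by 1/(10·var) (a std-based convention
is available as a switch; the scale is irrelevant after whitening), then
framed into Hamming-windowed 256-sample windows with hop 128. Power is
sampled at 256 log-spaced frequencies between 100 Hz and 4 kHz by
nearest-DFT-bin lookup — no interpolation is invented, so several adjacent
log bins can share one DFT bin at low frequencies. The log is taken after
adding a floor of 1e−12 × median frame power (absolute fallback 1e−30 for
all-silent input) so silence maps to a finite value. Frames with total
power below 0.01 × the median are trimmed as silence; segments of 25
frames (hop 5) are flattened into rows. Both thresholds and the segment
hop are conventions, not measurements; results are insensitive to the hop
given enough segments.

PCA whitening keeps the top `n_components` principal axes and divides each
projection by its standard deviation, so the whitened fitting set has
identity covariance exactly. Components with (numerically) zero variance
raise an error rather than being clamped — they indicate a degenerate
fitting set. `unwhiten(whiten(x))` reconstructs the projection of `x` onto
the retained subspace plus the mean.

## Synthetic ensembles: what they emulate, and what they do not

The generator draws coefficients per element from Laplace, exponential, or
spike-and-slab distributions, so one ensemble can mix symmetric and skewed
features. Two named ensembles define the study conditions (D = 64, K = 64,
2 × 10⁴ samples):

* **symmetric** (image-like): random orthonormal dictionary,
  spike-and-slab coefficients (p_active = 0.1) with a Laplace slab —
  sparse, sign-symmetric, homogeneous across elements.
* **skewed** (speech-like): half harmonic stacks (non-negative energy at
  integer multiples of a base frequency index, 1/k roll-off), half onset
  profiles (sharp rise, exponential decay); spike-and-slab coefficients
  with an exponential slab and activation probabilities log-uniform in
  [0.02, 0.3] — non-negative, skewed, heterogeneous.

Both ensembles are PCA-whitened before any coder sees them, exactly as the
preprocessing stage whitens spectrogram segments and image patches; all
projection statistics and random-direction controls live in that whitened
space. Auxiliary generators provide raw test signals: harmonic-stack
waveforms with abrupt onsets and 50 ms exponential decays (a fixed
convention — any decay much longer than the 16 ms analysis window
behaves the same), and image-patch surrogates with 1/f² power spectra
plus sparse oriented edges.

These ensembles reproduce the *statistical contrasts* the analysis is
about — symmetric vs skewed marginals, homogeneous vs heterogeneous
sparseness, feature classes with distinct statistics — but not the rich
phonetic, temporal or photometric structure of real corpora. Passing tests
therefore demonstrate that the pipeline detects these contrasts when they
are present by construction, not that any particular natural dataset
exhibits them at a particular effect size; dataset-specific quantities
(median control scores, correlations, Cohen's d values on speech/image
corpora) are out of scope.

## Statistics and conventions

* Sparseness score `S[y] = √(2/π) − ⟨|y|⟩/√⟨y²⟩`, bounded in
  [√(2/π) − 1, √(2/π)] by Cauchy–Schwarz. An all-zero sample set returns
  the supremum and is flagged `degenerate` — needed for overcomplete units
  that never activate.
* Skewness magnitude mean-centers internally; callers pass raw samples.
* Kurtosis is reported as *excess* (normal → 0).
* L0 statistics count `|y| ≤ zero_tol` as zero. LCA codes contain exact
  zeros (zero_tol = 0); projections and spike counts use 1e−12.
* Dictionary matching minimizes the angle `arccos |cos|` — sign-invariant,
  because sparse-coding elements are defined only up to sign.
* GMM clustering of the (sparseness, |skewness|) plane selects the number
  of components by BIC over k = 1..5 (no selection rule was prescribed;
  BIC is the standard conservative choice).
* Effect sizes: Cohen's d with the pooled standard deviation; the
  normalized median difference substitutes medians in the numerator only.

## Problem sizes and determinism

Study runs use D = 64, K = 64, 2 × 10⁴ samples, 15 training epochs for LCA
and 20 for SAILnet — sizes at which every experiment finishes in seconds to
a few minutes on one CPU while the qualitative results (controller
convergence, dictionary recovery, null separation, modality contrast) are
stable across seeds. The full-scale configuration (D = 200, 10× overcomplete
K = 2000, ≈3 × 10⁵ samples) remains available through the same interfaces.
Dictionary-recovery checks use a 20 × 20 orthonormal ground truth with pure
Laplace coefficients, where SGD recovery is near-exact (mean max
|cos| > 0.99).

Every stochastic stage takes an explicit seed; the pipeline derives named
per-stage substreams from one root seed by hashing, so adding a stage never
perturbs another stage's stream. Reruns with the same config and seed
produce field-for-field identical summaries.

## Known limitations

* The LIF simulation is coarse (50 steps, unit spikes); spike counts are
  small integers, so SAILnet activation statistics are strongly quantized.
  The analysis therefore prefers projection statistics for SAILnet
  dictionaries, which are continuous.
* The skewed ensemble's onset features overlap heavily (neighboring onset
  indices are highly correlated), so element-for-element recovery on that
  ensemble is not expected, and some learned elements legitimately sit
  below the random-direction sparseness band there; strict null separation
  is asserted on the symmetric ensemble.
* Waveform ingestion expects PCM WAV at the configured rate; resampling is
  out of scope.
* ICA and SPARSENET baselines, cochlear front-ends, and reconstruction of
  audio from log spectrograms are out of scope.
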