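# Methods

## Signal model

An FID of a multi-component solid is modelled as a sum of exponentially
decaying complex sinusoids plus complex Gaussian thermal noise:

    s(t) = Σ_j a_j · exp(i φ_j) · exp(i 2π f_j t) · exp(−t / T2*_j) + ε(t)

Each line j is a Lorentzian of absorption-mode full width at half maximum
1/(π·T2\*_j). The magnitude lineshape of the same decay is wider by a
factor √3, so all width measurements in this package (tests, acceptance
script) are made on the real part of the spectrum; `fourier_transform`
exposes `mode="real"` for exactly this purpose.

## STFT

`compute_stft` frames the FID as `signal[j·hop : j·hop+segment_length]`,
applies a periodic window (hann default) and takes a two-sided DFT with the
frequency axis in ascending (fftshift) order. Frame time stamps are frame
*centers*, `(j·hop + segment_length/2)·dwell_time`; this matters because
decay constants are read off the frame-magnitude decay, and a consistent
origin makes those fits deterministic. Magnitude (not power or complex)
spectrograms feed the factorizations, which require non-negativity.
Defaults: `segment_length = n_points/8` rounded to a power of two, 50%
overlap. The degradation fixtures use shorter segments (128 points, hop 32)
so that the fastest-decaying component is still sampled by several frames —
the segment must be a compromise between frequency resolution (bin width
1/(segment·dwell)) and decay resolution (frame spacing hop·dwell).

## Non-negative factorization

All three solvers minimize the Frobenius reconstruction error with
classical multiplicative updates (denominators guarded by 1e−12), which
preserve non-negativity exactly and never increase the objective.

* **NMF**: V(t, f) ≈ W H, W (frames × k) the decay patterns, H (k × freq)
  the component spectra.
* **NTD**: X ≈ G ×₁ A ×₂ B ×₃ C with a non-negative core G; A carries
  sample compositions, B frame decays, C spectra. The per-factor updates
  share the contraction `X ×_m (other factors, core)` in numerator and
  denominator (computed by `einsum`), i.e. the standard majorize–minimize
  generalization of the NMF rules.
* **NCPD**: X ≈ Σ_c a_c ∘ b_c ∘ c_c, the core-free special case.

**Initialization.** The first start is deterministic: absolute values of
the truncated SVD factors (NMF) or HOSVD mode factors with the matching
core contraction (NTD/NCPD). Remaining restarts (default 5 in total) are
seeded uniform-random. Multiplicative updates started from random factors
converge slowly and, at the default tolerance, can stall before separating
a fast-decaying minority component; the SVD start puts the iteration inside
the right basin and makes the default run reproducible without sacrificing
the random-restart safety net. The best restart by final error is reported.

**Convergence.** Relative change of the objective below `tol` (default
0.001), evaluated across 10-iteration windows rather than consecutive
iterations so that the slow-start plateau of multiplicative updates is not
mistaken for convergence; `max_iter` (default 2000) caps the run.

**Identifiability.** NMF/NTF solutions are scale- and permutation-
ambiguous. Frequency profiles are normalized to unit maximum with the
absorbed scale pushed into the time profiles (NMF) or the core and sample
factors (NTD/NCPD); components are reported sorted by decreasing energy.
Rank is user-specified (no automatic selection); `rank_scan` reports the
error-vs-rank curve, and a noise floor is captured by over-specifying the
rank by one, as in the 4-component analysis of a 3-component series.

**Composition read-out.** For NTD with equal mode ranks the frequency-mode
components need not pair one-to-one with sample-mode columns. Rather than
trusting a diagonal-dominant core (`core_pairing`, provided but fragile),
`spectral_sample_profiles` contracts the core with the sample and time
factors to get the total amount of each *spectral* component in each
sample, and `spectral_time_profiles` the corresponding frame decay. These
contractions are well defined for any core and are what the recovery tests
score. `sample_fractions` additionally renormalizes compositions per sample
to fractions, since raw loadings and fractions answer different questions.

**Decay constants.** `fit_decay_constant` fits a least-squares line to
log(profile) vs frame time over points above 5% of the profile maximum and
returns −1/slope; non-decaying profiles yield `inf` as a "no decay"
sentinel. Only relative T2\* values (orderings, ratios) should be
interpreted: window tapering biases the absolute scale slightly.

## GTM / GTMR

The generative topographic map places K nodes on a regular 2-D lattice in
[−1, 1]², maps them through an RBF network y(z) = Wᵀφ(z) (M Gaussian bases
on a sub-lattice plus a bias) into data space, and models data as an
equal-weight mixture of isotropic Gaussians of precision β at the node
images. Fitting is EM with a ridge prior on W: the M-step solves
(Φᵀ G Φ + (λ/β) I) W = Φᵀ R X and then updates β in closed form.
`loglik_trace` records the *penalized* log-likelihood — the quantity this
MAP-EM provably never decreases — and the monotonicity test asserts exactly
that. On noiseless data β diverges as nodes land on the data; the update is
clamped at `beta_max` (default 1e10 on autoscaled data) and hitting the
clamp terminates EM before round-off can corrupt the trace.

Defaults: 20×20 grid, 7×7 RBFs, RBF width 2× the center spacing, λ = 1e−3,
tol 1e−5 on the relative objective change, 300 iterations. Initialization
is deterministic from the first two principal axes of the autoscaled data
(a seeded random init is available). All inputs are autoscaled per column;
a zero-variance column is an error (for flattened spectrograms,
`flatten_spectrograms` drops empty bins and records the mask so inverse
predictions can be un-flattened by `profile_to_spectrum`).

**Regression.** `fit_gtmr` fits one joint GTM on the column-concatenation
[X_scaled | Y_scaled] with equal block weight after autoscaling (no extra
rebalancing). Prediction conditions the node responsibilities on one block
only — a Gaussian likelihood with the model's β restricted to those
dimensions — and returns both the responsibility-weighted mean of the other
block's node means (default) and the argmax-node ("mode") prediction, both
de-scaled to original units. Forward and inverse prediction are the same
operation with the blocks swapped; a single joint model with Dy = 3 serves
multi-property targets rather than three separate per-property maps.

## GMM pseudodata

`fit_gmm` fits a full-covariance Gaussian mixture by EM (scikit-learn
backend, diagonal regularization 1e−6, 3 EM initializations); "means and
covariances" of the data distribution imply full second moments, hence full
covariances. `sample_pseudodata` draws component labels from the weights
and then multivariate normals, using one numpy Generator so a seed fixes
the output bitwise. Component count is user-specified; `bic_scan` assists.

## Synthetic fixtures: what they emulate and what they do not

The degradation scenario emulates a 16-timepoint series over 0–120 h:
a "cellulose"-like component (2 lines, T2\* = 5 ms) whose amplitude decays
exponentially (τ = 40 h), a "protein"-like transient (3 lines, 15 ms, bell
around 50 h) and a "lipid"-like accumulating product (2 lines, 50 ms,
logistic rise at 60 h), plus complex Gaussian noise (σ = 0.01 of the unit
line amplitude). The T2\* ordering cellulose < protein < lipid encodes the
physics that rigid crystalline material decays fastest and mobile lipids
slowest — this ordering, not the arbitrary line positions, is the testable
claim. The catabolic-product table follows first-order chain kinetics
A → B → C with k₁ = 1/25 h⁻¹, k₂ = 1/45 h⁻¹, chosen so the
propionate-analogue A is strictly monotone over the window; B and C are
then single-valued functions of A and a regression from A is well posed.
Pseudo-thermal properties (Tg/Tm/Td, °C) are linear functions of
composition fractions.

Not emulated: cross-polarization dynamics, chemical-shift anisotropy powder
patterns, MAS sidebands, baseline/phase artifacts, B₀ drift across a
series. Passing tests therefore demonstrate that the algorithms recover
known T2\*-separable structure from additive Lorentzian data at realistic
noise, not that any particular real material will separate as cleanly.
The two-line rigid/mobile fixture (broad 0.3 ms + narrow 20 ms) is
noiseless by construction: with rank equal to the number of physical
components there is no factor left to absorb a noise floor — on noisy data
one over-specifies the rank instead, as the degradation analysis does.

## Numerical choices and edge cases

* Identically-zero factorization inputs are rejected (no scale).
* Multiplicative-update denominators and cosine-similarity norms are
  guarded by 1e−12.
* `align_components` solves the Hungarian assignment maximizing total
  cosine similarity; with unequal component counts only min(n₁, n₂) pairs
  are assigned.
* Fourier interpolation of an FID is zero-filling (integer factor
  preserves every original bin exactly); of a sampled spectrum it is
  FFT-based resampling. Linear/spline interpolation operate on the sampled
  intensities and deviate near sharp peaks and in the extrapolated tail.
* JCAMP-DX support is a minimal uncompressed AFFN `(XY..XY)` dialect
  sufficient for lossless round-trips of files this package writes;
  vendor formats and compressed JCAMP encodings are out of scope.
* The acceptance script runs every fixture at its default size (16 samples
  × 61 frames × 128 bins for the tensor; n = 100–10,000 elsewhere), chosen
  so the full recomputation finishes in well under a minute on one CPU.

## Known limitations

* No sparsity/smoothness regularizers or probabilistic factorizations; no
  automatic rank selection.
* GTM latent maps of strongly clustered data pile many nodes onto each
  cluster, so a cluster occupies a latent *region*; per-point mean and mode
  coordinates can then differ by more than one lattice cell. Map
  smoothness (RBF count/width, λ) should be matched to the expected
  manifold complexity.
* T2\* estimates from STFT frame decays carry a window-dependent bias;
  compare them only within one STFT configuration.
* Phase/baseline correction and solvent suppression are out of scope; the
  deconvolution assumes magnitude spectrograms of reasonably phased FIDs.
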