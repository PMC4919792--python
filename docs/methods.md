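# Methods

`selsort` recovers per-neuron spike trains from a single extracellular
voltage channel. This note records the model, the estimation procedures,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Generative model

The channel voltage is

    v(t) = Σ_n (δ_n ⊛ w_n)(t) + b(t) + η(t)

with `δ_n` a binary impulse train for neuron `n` (Bernoulli per sample,
thinned by an absolute refractory period), `w_n` a distinct spike
waveform of τ ≈ 60 samples (2.5 ms at 24 kHz) whose positive peak marks
the spike time, `b(t)` low-amplitude activity from distant "neighbour"
neurons, and `η` white Gaussian noise whose SD is quoted as a fraction
of the unit template peak. All indices are 0-based sample positions.

Simulator defaults (the study conditions used by the acceptance script
and the heavier tests):

| parameter | default | rationale |
|---|---|---|
| sampling rate | 24 kHz | standard for the public simulated benchmark |
| duration | 60 s (1.44 M samples) | benchmark-scale recordings |
| firing rate | 0.0008 /sample ≈ 19 Hz per neuron | reproduces the benchmark's ≈1,100 spikes per neuron per minute |
| refractory | 60 samples (2.5 ms) | one template span |
| noise level | 0.05–0.2 of peak | the benchmark's quoted range |
| neighbour activity | amplitude 0.1, two extra units at 0.002 /sample | correlated background from distant neurons |
| forced overlap rate | 0.05 | guarantees near-coincident cross-neuron pairs |

Templates are sum-of-Gaussians biphasic shapes (sharp depolarisation
peak, slower repolarisation trough, optional pre-dip), peak-normalised
to 1. Widths are drawn from a narrow band so the classes have
comparable energy — as recorded spike classes on one channel do — and
draws are rejected until all pairwise shape correlations are below
0.92. Correlations of 0.8–0.9 still occur routinely, which is the
"difficult" regime of the public benchmark.

## Detection: cepstrum of bispectrum (CoB)

For a skewed impulse process driven through a linear filter, the
bispectrum factorises as `B(n, m) = ξ F(n) F(m) F*(n+m)` while Gaussian
noise contributes nothing in expectation. `B` is estimated by averaging
the FFT triple product over Hann-tapered segments (length 1024, 50%
overlap, at most 256 segments — more segments stopped improving the
estimate well before this cap at the trace lengths used here).

The transfer function is reconstructed in two parts:

- **log-magnitude** from the q = 0 slice of the bicepstrum (2-D inverse
  FFT of log |B|); the unknown `ξ` only shifts the zeroth cepstral bin,
  which is set to 0 (pure scale ambiguity).
- **phase** from the factorisation `arg B(k, s−k) = φ(k) + φ(s−k) −
  φ(s)`: each split `k` of frequency `s` yields an estimate of `φ(s)`
  and the estimates are combined by |B|-weighted circular averaging.
  A single-slice recursion (using only `B(1, n)`) accumulates error as
  a random walk and fails at realistic noise levels; averaging over all
  splits keeps the phase usable. The remaining linear-phase ambiguity
  is removed by rolling the impulse response so its dominant peak sits
  at lag 0, matching the peak-marking time convention (the sign is
  fixed so the peak is positive; the driving process is assumed
  positively skewed, which holds for positive-peak templates).

The inverse filter is Tikhonov-regularised, `F̄ /(|F|² + (ε max|F|)²)`
with ε = 0.05, and applied with an exactly zero-delay FIR convolution.
The filtered trace is denoised with a stationary (undecimated) coiflet-3
wavelet transform at level 4, soft-thresholding details at the universal
threshold with σ from the MAD of the finest level.

Events are local maxima above `k` robust standard deviations
(MAD-based) of the denoised output; the study conditions use k = 3.
When the background is essentially silent the MAD collapses to the
deconvolution-ripple scale, so if the peak-to-MAD ratio exceeds 200 the
threshold is floored at 0.15 of the largest sample (ripple stays below
~10% of a spike's response). Distinct events need only be 3 samples
apart — near-synchronous overlapping spikes must both survive
detection; per-neuron refractory constraints are enforced later, at the
sorting stage, where neuron identity is known. Each event is finally
snapped to the raw-trace local maximum within ±3 samples, since the
inverse filter equalises a compromise of several templates and can
shift individual classes by a sample or two, and must clear 2.5 robust
noise SDs on the raw channel: the regularised inverse rings slightly
around strong spikes, and those echoes have no raw-trace support (the
same amplitude test the conventional detectors apply).

Known limitation: the deconvolved peak height scales with a template's
energy, so at high noise (≥0.15 of peak) a low-energy class loses
recall first. This mirrors the behaviour of the conventional detectors,
only later in noise.

## Features: Haar + Kolmogorov–Smirnov selection

Extracted windows (61 samples, peak at index 20, cubic-spline
sub-sample alignment at 2× resolution) are decomposed with a full
orthonormal Haar transform. For each coefficient position, values
beyond 3 SD are discarded and the remainder standardised and compared
to the standard normal CDF; the KS distance ranks coefficients and the
10 best form the feature matrix. The 3-SD trim is essential in
practice: without it, coefficients contaminated by overlaps and
neighbour spikes score high through their tails alone and crowd out
the genuinely multimodal coefficients — with the trim the selected
set's class separation improved enough to resolve 0.86-correlated
classes at noise 0.15. Sub-sample alignment matters for the same
reason: at integer alignment the ±0.5-sample peak jitter splits each
class into several feature-space lobes.

Per-feature Gaussian kernel densities (bandwidth σ(4/3M)^{1/5}) make
the selection auditable; a feature that separates classes shows more
than one mode.

## Clustering: super-paramagnetic (Potts) dynamics

Waveform features become q = 20 Potts spins on a mutual 11-nearest-
neighbour graph with couplings `J_ij = (1/K̂) exp(−e_ij²/(2a²))` (K̂ =
mean degree, a = mean edge length). Swendsen–Wang dynamics (500 sweeps,
100 burn-in, independent seeded stream per temperature) estimate the
thermal same-spin correlation `G_ij` on a grid T = 0 … 0.25 step 0.01.
Clusters at a given T are connected components of edges with G > 0.5.
Three demotion rules route non-class structure into the unassigned
pool: components below max(60, 3% of M); components below 25% of the
largest cluster; and clusters whose mean feature-space radius exceeds
5× the tightest cluster's — a genuine spike class is compact at the
noise scale (radius ≈ √d·σ), while a group of overlapped waveforms is
a wide mixture of collision shapes (measured 9–11× the class radius).
The pool is exactly the benchmark tables' starred overlap group.

Temperature selection: Potts domains only ever split as T rises, so the
grid point with the most non-trivial clusters marks the phase where all
separable structure has come apart; ties are broken toward the largest
assigned membership, then toward lower T. Two regimes occur in
practice. When classes are well separated the mutual-KNN graph is
already disconnected and the full structure exists at T = 0; when
classes touch (similar templates, high noise) the split appears only in
a narrow band near the melting point, and membership there is eroded —
the matching stage recovers the eroded spikes afterwards. With
0.85–0.9-correlated templates at noise 0.15 the three-cluster window
can close entirely for unlucky template draws (roughly one draw in
four); the pipeline then reports two clusters, a genuine resolution
limit of the method at that noise.

OPTICS is available as the alternative ("no feature engineering")
route, cut at the 90th percentile of finite reachabilities by default.

## Overlap resolution: templates, noise model, likelihood matching

Putative templates solve the joint least-squares convolution model: the
normal equations are block-Toeplitz in the trains' auto- and
cross-correlations and are solved with a pseudo-inverse (minimum-norm
under rank deficiency, with a warning). Joint — rather than per-neuron —
solving is what makes the estimates unbiased when trains correlate
through overlaps; it reduces to segment averaging for isolated spikes.

Subtracting the fitted templates at their clustered indices leaves a
residual of noise plus the unclustered spikes. Its biased sample
autocovariance (31 lags) defines, through the centre column of its
Toeplitz matrix, a symmetric unit-norm filter: white residual gives an
identity, spike-contaminated residual a wavelet-like matched smoother
that lifts spike peaks over white noise. The voltage is filtered
(zero-phase) and templates re-estimated on the filtered trace.

Before matching, the filtered templates are subtracted from the
filtered trace at all clustered indices: already-claimed spikes are
explained, and a target near a clustered spike must not be able to
score against that neighbour's waveform. Each detected-but-unclustered
index is then scored per neuron with the Gaussian matched-filter
log-likelihood ratio plus a Bernoulli rate prior:

    L_n = (w̃_n·ṽ_win − ‖w̃_n‖²/2) / σ² + log(p_n/(1−p_n))

σ² (robust MAD-based variance of the filtered trace) sets the scale of
the evidence against the prior; without it the prior term dominates and
nearly everything is rejected. Acceptance is globally greedy across
targets with a lag search of ±3 samples, and before each commit the
best *joint pair* of templates over the nearby candidate positions is
compared against the single best match (the pair score is the exact
two-template likelihood, validated against explicit residual energies).
This pairwise step is what resolves small-lag collisions of correlated
templates, where a single-template match prefers a compromise position
between the two true spikes. Accepted spikes are recorded at the
nearest detected index, respect per-neuron refractory intervals, are
subtracted from the working trace, and trigger re-scoring of every
candidate whose window the subtraction touched; each event accepts at
most two neurons (triple overlaps are rare at these rates).

## Evaluation

Accepted and true spikes are matched one-to-one within ±24 samples
(1 ms); the neuron correspondence is fixed by Hungarian assignment over
the match-count confusion matrix, so scoring is invariant to
relabelling. Overlap spikes are true spikes within one template span of
a spike from another neuron. Reconstruction places each neuron's
template at its accepted indices; the coefficient of determination is
the squared Pearson correlation between the reconstruction sum and the
recorded trace, in percent. Note an intrinsic ceiling: against a noisy
trace even a perfect reconstruction reaches only
var(signal)/var(signal+noise) — about 86–88% at noise 0.05 under the
default rates — so reported values should be read against that bound,
not against 100%.

## What the synthetic tests do and do not show

The simulator reproduces the benchmark's structure: distinct biphasic
classes, Bernoulli spiking with refractory gaps, near-coincident
overlaps, correlated neighbour background, white Gaussian noise. It
does not model electrode drift, bursting amplitude adaptation,
non-stationary noise, or multi-channel geometry. Passing the synthetic
suite therefore demonstrates correct estimation under the stated
generative assumptions, not robustness to those real-data effects; the
benchmark MAT dialect reader exists so the same pipeline can be run
unchanged on the public simulated datasets when they are available
locally.

## Problem sizes

Heavy tests and the acceptance script use 60 s at 24 kHz (≈3,400 true
spikes, ≈3,000 clustered waveforms) per noise level — the scale of one
benchmark file — and 200 randomised trials for the constructed-overlap
recovery rate. Unit tests use 5–10 s renders of the same process.
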