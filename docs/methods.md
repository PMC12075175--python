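# Methods

This note documents the models, conventions and design choices behind
`emgband`, in the spirit of the model documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
where the genuinely open choices were made.

## Synthetic session model

Surface EMG is modelled phenomenologically, not physiologically: during a
contraction, the signal on channel *c* is

    x[t, c] = n[t, c] + A · g[γ(t), c] · e(t) · w[t, c]

where `n` is white Gaussian baseline noise (sd `noise_floor_sd`, default
1.0 in arbitrary units), `w` is a unit-variance Gaussian carrier band-pass
filtered to 30–350 Hz (the useful surface-EMG band), `e(t)` is a 0→1
contraction envelope with 100 ms raised-cosine onset/offset ramps, `γ(t)`
the cued gesture, and `g` the per-gesture per-channel activation gain in
[0, 1].  The carrier amplitude `A = noise_floor_sd · 10^(SNR/20)` is chosen
so a gain-1 channel attains exactly the target ON/OFF variance-ratio SNR,
`10·log10(σ²_on/σ²_off − 1)` dB; the default target of 12 dB sits in the
range a quality dry-electrode armband reports (maxima around 20 dB).
Channels within one 3-channel node share a pre-filter noise component
(pairwise correlation 0.6), reproducing the visually similar but
non-identical traces of closely spaced contacts.

The default spatial model (`GestureSpatialModel.forearm_default`) gives
each of the five active gestures a raised-cosine arc of 9 channels,
with centres spread evenly around the 21-channel ring.  All arcs have the
same shape and energy, so gestures differ in *where* activity sits rather
than in how much there is — the discriminative information is deliberately
spatial, which is the property the density comparison probes.  Two
variability terms make repeated trials realistically non-identical: a
lognormal gain multiplier per trial and channel (σ = 0.25,
contraction-intensity/recruitment variability) and a rounded Gaussian
rotation of the whole pattern per trial (σ = 0.6 channels, slight
armband/muscle displacement).  Without them every decoder saturates and
paired comparisons degenerate; with them, accuracies on the reduced-scale
default fall in the 70–100 % range typical of real cued-gesture sessions.

The protocol is block-randomized: each repetition block contains every
gesture once in a seed-dependent order.  "Rest" is a sixth class whose
movement interval carries no activity; together with the inter-trial rest
periods this makes rest over-represented by design, as in a real cued
protocol.  Identical seeds give bit-identical sessions.

What the generator does **not** model: motor-unit dynamics, electrode-skin
impedance, fatigue, limb-position effects, or crosstalk beyond the
node-correlation term.  Passing tests on this generator therefore show
that the pipeline recovers planted spatio-temporal structure under
realistic noise and variability — not that any particular accuracy level
transfers to recorded human data.

## Conditioning and windowing

The acquisition chain is emulated as a second-order Butterworth band-pass
(30–350 Hz) followed by a notch (default 50 Hz, Q = 30 ≈ 1.7 Hz stopband;
the hardware's notch bandwidth is unspecified, so Q is config-exposed).
Offline pipelines use forward-backward (zero-phase) filtering by default;
a causal mode exists for streaming parity with hardware.

Windows are specified in milliseconds (281.1 ms length, 9.3 ms step) and
converted via `round(ms·fs/1000)`, giving exactly 300-sample windows and a
10-sample step at 1,067 Hz; 300/1067 = 281.2 ms and 10/1067 = 9.37 ms, so
these are taken as the intended sample counts.  The window count over an
N-sample recording is `floor((N − L)/S) + 1`.

## Activity detection and SNR

Detection follows the classical double-threshold scheme.  Baseline
statistics (μₙ, σₙ) come from a known rest interval (the first
sufficiently long rest-labelled run, or the first `baseline_s` seconds);
thresholds are LT = μₙ + k₁σₙ and UT = μₙ + k₂σₙ with defaults k₁ = 3,
k₂ = 5, m = 30 samples (≈ 28 ms).  One deliberate deviation from a naive
reading: raw rectified broadband EMG crosses zero every few samples, so no
supra-LT run of 30 consecutive raw samples ever survives.  The detector
therefore thresholds a 25 ms moving-average *envelope* of the rectified,
baseline-mean-subtracted signal — standard practice for this detector
family; `smooth_ms=0` restores bare-sample thresholding.  A candidate
activation must dwell above LT for ≥ m samples and contain an excursion
above UT; sub-m gaps between activations are rejected (merged).  State
variances entering the SNR are computed on the **raw** segments (the
rectified envelope is used only for detection), and the SNR uses the mean
of per-state variances, returning −∞ (flagged, not raised) when
σ²_on ≤ σ²_off.

## Descriptor features

Six per-window, per-channel descriptors (with DD₁ and DD₂ the first and
second differences):

1. `∑ x²` — integral square descriptor (power);
2. `∑ x² − (1/θ)·∑ DD₁²`;
3. `∑ x² − (1/θ)·∑ DD₂²`;
4. `|exp(mean log(|x| + ε))|` — geometric-mean magnitude (log-detector
   variant, a contraction-force proxy);
5. `mean |x|^½`;
6. `mean DD₂`.

Conventions that had to be fixed: θ is nowhere defined in the source
material, so it defaults to the window length n and is prominently
config-exposed; logarithm and square root of signed samples are undefined,
so the magnitude convention |x| is used with ε = 10⁻⁸ guarding zeros;
derivative sums run over their natural lengths (n−1, n−2) while mean
divisors stay n as printed.  Extraction over a session uses cumulative-sum
moving windows (O(N) per channel per descriptor); the test suite verifies
this against literal per-window summation to 10⁻¹⁰ relative.

Consecutive windows are tiled into non-overlapping blocks of 60 time
steps (≈ 0.83 s per model sample); a block becomes a sample only if all
its windows carry the same majority label, so samples never straddle a
gesture boundary, and each sample records its originating trial for
leakage-free splits.  Non-overlapping tiling (rather than sliding
sequences) was chosen for sample independence.  Features are z-scored per
channel-feature pair with statistics from the training split only.

## Decoders

**LDA.**  Each time step of a sample is one training row (channels ×
features flattened); classification is shrinkage-regularized
(`lsqr`/`auto`), and a sample's prediction is the majority vote of its 60
window-level decisions.

**Vanilla TCN.**  Blocks of causal dilated 1-D convolutions along time
(kernel 3; dilations 1, 2, 4), each followed by batch normalisation, ReLU
and dropout (p = 0.3).  By default channels × features are stacked into
the feature axis (the standard stacked-TCN formulation); a
per-channel-independent mode (shared weights, no cross-channel mixing)
exists for capacity-matched comparisons.

**Spatio-temporal network.**  Each block runs two branches on the same
input *in parallel*: the causal dilated temporal convolution (per channel,
shared weights across channels) and a spatial convolution across the
channel axis at each time step (kernel 3).  The spatial convolution wraps
circularly, because the electrode nodes form a closed ring around the
forearm.  Branch outputs are concatenated per feature map (a summation
merge is available), then batch-norm/ReLU/dropout.

**Head.**  Activations are average-pooled over time only, then channels ×
maps are flattened into a dense softmax layer.  This is a load-bearing
choice: circular spatial convolutions are rotation-equivariant around the
ring, so a head that also pooled over channels would make the network
blind to *where* on the ring a pattern sits — precisely the information
that distinguishes gestures with rotated activation patterns.

The source material fixes none of the architecture's depths, widths,
kernel sizes, merge rule, optimizer or split protocol; the defaults here
(3 blocks, 32 filters — 8 in the reduced-scale studies — Adam at 1e-3,
batch 32, ≤ 100 epochs with patience 10 on a 15 % validation split,
cross-entropy) are documented choices, not claims of fidelity.  The
networks are implemented directly in NumPy with explicit backward passes;
finite-difference tests verify every parameter and input gradient, and
training is bit-reproducible under a fixed seed.

## Saliency

For class c with pre-softmax score S_c, the raw saliency of a sample is
|∂S_c/∂I|, shape [60, 21, 6]; averaging over the feature axis gives the
[60, 21] per-gesture map.  The logit (not the softmax output) is used
because softmax saturation flattens gradients.  Per-gesture aggregates
average over correctly classified samples (falling back to all samples of
the class if none are correct); cross-subject aggregation is an
elementwise mean.  For the linear LDA baseline the analogous closed form
|w| is exposed separately, mirroring the first-order Taylor view
S_c(I) ≈ wᵀi + b in which the gradient *is* w.

## Evaluation and statistics

Cross-validation is trial-wise and stratified: all samples of one trial
repetition stay in one fold (`StratifiedGroupKFold`), eliminating
window-level leakage.  The density comparison is fully paired — the
low-density condition is the exact 7-middle-channel subset (within-node
position 2 of 1..3, global indices 1, 4, 7, …) of the same recordings.

Paired statistics: Wilcoxon signed-rank with zero-differences dropped,
exact null for n ≤ 12 and normal approximation with continuity correction
above; Friedman with average ranks and tie correction (all-tied tables
give χ² = 0, p = 1, df = k−1); Nemenyi post-hoc p-values from the
studentized range distribution with k groups and ∞ df, gated on Friedman
significance at α = 0.05.  Tests verify Wilcoxon against full 2ⁿ sign-
pattern enumeration, Friedman against the literal rank formula on all
3-condition × 4-subject rank tables and against scipy, and Nemenyi against
the published k = 3 critical value (2.343 at α = 0.05).

## Reduced-scale study sizes

The packaged studies (`emgband.study`, also used by the acceptance script
and tests) keep the full recording geometry — 21 channels, 1,067 Hz, 6 s
movement + 6 s rest, six classes, 300/10-sample windows, 60 time steps —
and reduce only the statistical scale: 2 repetitions per gesture per
synthetic subject, 8 network filters, 12 training epochs, 2-fold
trial-wise CV, 10 subjects (density comparison) and 10 independent
training runs (saliency channel recovery).  These sizes were chosen so a
full study completes in minutes on one CPU while the paired tests retain
enough resolution; scaling up is a matter of configuration.

## Known limitations

* The generator's spatial patterns are smooth single arcs; real forearm
  synergies are multimodal and subject-specific.
* The vanilla TCN in its default flattened mode has *more* parameters
  than the spatio-temporal network at matched width — comparisons of the
  two are about inductive bias, not capacity.
* Nemenyi p-values use the asymptotic studentized-range reference, as is
  conventional, even at small subject counts.
* The loader for externally recorded datasets supports only the HDF5/CSV
  schemas documented in `emgband.io`; no EDF/BDF or streaming input.
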