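# Methods

## Forward model

A fringe is the real detector signal of a swept-source interferometer
sampled uniformly in wavenumber k (cm⁻¹). A scatterer at depth z (µm)
with complex reflectivity a contributes

    |a| · G(k) · cos(2π·(2z·10⁻⁴)·k + φ(k) + arg a),

where G is the Gaussian source amplitude envelope and
φ(k) = a₂(k−k₀)² + a₃(k−k₀)³ the polynomial dispersion phase. The default
axis matches a 1290 nm / 110 nm source: centre 7752 cm⁻¹ (= 10⁷/1290),
source FWHM 661 cm⁻¹ (= 10⁷·110/1290²), span 1000 cm⁻¹, 2048 samples.
With the 2× zero-padded FFT (length 4096) this gives a depth pitch of
2.5 µm, 2048 depth pixels and a 5.12 mm unambiguous range. Reflectors
beyond that range are rejected rather than aliased.

Speckle is generated physically, not as multiplicative noise: phantom
layers are filled with Poisson-distributed sub-resolution scatterers
(default several per 5 × 13 µm resolution cell) carrying circular complex
Gaussian amplitudes, so the reconstructed intensity in homogeneous regions
shows fully developed speckle. Detection noise is additive white Gaussian
on the fringe (default σ = 0.05 detector units, which places the noise
floor ≈ 50 dB below a unit reflector and makes speckle clearly visible in
a 40 dB display window). A Gaussian beam of 13 µm FWHM weights the
scatterers each A-scan sees.

Out-of-plane frame stepping redraws a fraction of the speckle scatterers
per micrometre of offset (6 %/µm, discrete reflectors persist), so
inter-frame speckle correlation decays with separation while layer
geometry is preserved — the mechanism that makes multi-frame averaging
despeckle. The rate was fixed once so that a 7-frame stack at the 2 µm
interval shows a measurable contrast reduction without washing out
structure; real out-of-plane decorrelation additionally depends on beam
profile and tissue microstructure the generator does not model.

## Reconstruction chain

Background removal → k-linearization (identity for the simulator's
already-linear axis; a resampling-table hook covers real, nonlinear
sweeps) → analytic signal via Hilbert transform → multiplication by
exp(−iφ_comp(k)) → FFT (4096) → positive-half magnitude → log compression
(20·log₁₀, amplitudes clamped at 10⁻⁶ of the image maximum) →
normalization of a dB window onto [−1, 1] (default window: 5th percentile
to maximum of the optimal image, stored per record and shared by the
degraded partner). The first 5 depth pixels are excluded from peak
searches to keep DC remnants out of resolution measurements.

The spectrogram slices the fringe into Hann-weighted windows of
325 cm⁻¹ with 275 cm⁻¹ overlap (converted to samples by rounding; band
count computed on sample units), zero-padded to the common FFT length:
14 bands on the default axis. Hann was chosen for its leakage/width
compromise; the band count is unchanged by any window shape.

Resolution is the full width at 3 dB below the peak of a log-amplitude
profile, with linearly interpolated crossings. Because the depth pitch
(2.5 µm) is coarse relative to the PSF (≈5 µm), PSF measurements
(`measure_psf_fwhm`) reconstruct at 16× zero padding; the standard image
chain stays at 2×.

One deliberate physical consequence of the default axis: the 661 cm⁻¹
Gaussian envelope is clipped by the 1000 cm⁻¹ sweep at ±1.8σ, so the
optimal PSF is a few tens of percent wider than the pure-Gaussian
transform pair predicts (5.56 µm vs 4.71 µm) and ideal closed-form laws
hold only approximately there. The test-suite therefore verifies the
Gaussian laws (bandwidth–resolution reciprocity, analytic PSF width) on a
wide-span axis (2800 cm⁻¹) where the envelope is untruncated, and all
quantitative degradation bounds on the default axis are defined through
*measured* widths (below), which makes them exact by construction.

## Degradations

**Axial (NetA).** The dispersion-mismatch envelope is calibrated
numerically: for each coefficient separately, bisection on the measured
mirror-PSF broadening until it reaches the ×2 target (tolerance 10⁻³,
≤100 iterations). Joint draws are uniform in the per-coefficient box and
shrunk onto the L1 simplex (|u₂|+|u₃| ≤ 1 in bound units), which keeps
every combined draw at or below the target (worst observed ≈ 1.995 over
500 draws; a 5 % tolerance absorbs discretization). Bandwidth truncation
multiplies the fringe by a Gaussian window whose σ is chosen so the
*effective* (product) bandwidth equals `truncation_factor` × the source
bandwidth — hence broadening is exactly 1/factor and a factor of 1 is a
strict identity. The factor is uniform in [0.5, 1].

**Lateral (NetB).** Truncation factor uniform in [0.8, 1] (mild, to vary
the noise pattern), lateral-only Gaussian blur (odd size 5–15 px, σ 1–5)
applied to the linear amplitude (a wider illumination spot adds field
amplitudes; blurring the dB image would under-broaden point targets), and
SNR deterioration of up to 3 dB: "attenuate" subtracts the drawn dB from
pixels above the noise floor (floor = 25th percentile of the dB image);
"amplify" adds white noise sized to raise that floor by the drawn dB.
Mode is a fair coin. The 7-frame ground-truth average uses Gaussian
frame weights with σ = 1.5 frames (edge frames ≈ 14 % of the centre
weight), normalized to sum to one.

## Networks

Torch-free by design: `fringeoct.nn` is a ~500-line reverse-mode autodiff
over numpy arrays (conv2d via shift-and-matmul, batch norm, PReLU,
pooling, concat), with every backward rule checked against numerical
differentiation in the test-suite, plus Adam. Float dtype follows the
data: networks run float32, metric evaluation float64 through the same
ops.

NetA's generator (13 blocks) = conv head, 4 residual-in-residual dense
blocks (3 dense conv layers each, residual scaling 0.2), conv, one
long-skip-connection block, 4 conv blocks, conv, and a tanh output head
that collapses the band axis by averaging. Its four input channels are
the two spectrograms and the two A-scans broadcast along the band axis;
the output corresponds to the first fringe of the pair. NetB's generator
(12 blocks) = head, 8 RRDBs, two conv blocks, tanh head, fully
convolutional so it trains on patches and infers on full frames. Both
discriminators have 11 blocks (stride 2 on every other block, global
average pool, sigmoid). Every block carries 2-D batch norm and PReLU.
Channel width defaults to 32 but every test and example runs at 2–8
channels; block counts are width-invariant. Checkpoints are single `.npz`
archives holding weights, batch-norm buffers and the network spec.

## Training and inference

Alternating optimization: one generator Adam step and one discriminator
Adam step per batch (1:1), lr 10⁻⁴ default, batch 8 (NetA) / 2 (NetB).
Loss weights as in the README. Non-finite losses abort with a
diagnostic. A master seed fans out to simulator, samplers, augmentation,
shuffling and weight initialisation through labelled `SeedSequence`
streams (`derive_seeds`), so runs are bit-reproducible and checkpoints
reload to identical outputs.

Augmentation picks one uniformly random adjacent A-scan pair per B-scan
and flips the pair order with probability ½. Dataset splitting assigns
whole acquisition sets to train/test at the 8:2 ratio per sample
(fractional counts round the train side down), which reproduces the
60,000 = 12 × 5 × 1000 / 48,000 / 12,000 arithmetic and guarantees no set
straddles the split.

Inference runs NetA over all adjacent pairs (the last column pairs with
its left neighbour so all 1024 columns get an output), assembles the
B-scan, and applies NetB once, in eval mode with the stored normalization
window — deterministic given the checkpoints.

## Desk-scale problem sizes

The package's own experiments are sized for a single CPU: the training
sanity/parameter-recovery experiment uses a 256-sample axis (same
1000 cm⁻¹ span, so 14 bands are preserved), 48 bead fringes, an
8-channel NetA and 30 epochs, after which the enhanced axial FWHM of
held-out truncation-degraded beads (factor 0.55) drops from 8.3 µm to
≈6.4–6.5 µm against a 5.4 µm optimum. NetB training demonstrations use
48–176 px patches with the MS-SSIM scale count reduced to fit the patch
(5 scales need ≥176 px). These sizes demonstrate that the losses,
samplers and optimization interact correctly; they say nothing about
enhancement quality achievable with full-scale training on real tissue
data, which is out of scope here.

## Metrics

SSIM uses the 11×11 Gaussian window (σ 1.5), standard stabilizers
C₁=(0.01L)², C₂=(0.03L)², covariance via windowed moments, and the mean
over the valid (fully overlapped) region. MS-SSIM uses 5 dyadic scales
with the conventional weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333),
contrast-structure means at the finer scales, full SSIM at the coarsest,
negative means clipped at zero. Both agree with independent
implementations to <10⁻⁴ in the test-suite and are differentiable through
the autodiff for the NetB loss (the x^w gradient is routed to zero at
x = 0, where it is undefined). PSNR uses peak = reference maximum; the
`mode` flag records whether the reference is ground truth or the
unenhanced input (the vs-input convention is what despeckling studies
tabulate). β is the zero-mean normalized correlation of 3×3
Laplacian-filtered pairs; EPF averages local correlations of
3×3-mean-filter residuals over 16×16 tiles, skipping structureless
tiles. The exact window sizes for β/EPF vary across the despeckling
literature; these defaults are declared here and kept fixed.

## Known limitations

* No confocal/DOF rolloff, polarization, sensitivity rolloff with depth,
  catheter scan distortion, or tissue attenuation in the simulator;
  phantom realism is heuristic.
* The fringe model is single-scattering; autocorrelation and DC terms are
  reduced to a separable background.
* The reconstruction assumes the stated normalization window transfers
  between optimal and degraded partners; strongly saturated images would
  need per-image windows.
* Desk-scale network widths/epochs demonstrate mechanism, not clinical
  image quality.
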