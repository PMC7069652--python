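# Methods

## The correction model

A hyperspectral measurement is modelled as I(x,y,λ) = B(x,y,λ)·ρ(x,y,λ) on
top of a dark signal, with B the illumination ("background") and ρ the sample
reflectance. Reflectance and absorbance estimates divide the dark-subtracted
measurement by a background estimate:

    R = (I − I_dark) / (B̂ − I_dark),    A = −log₁₀ R.

Three background estimates are implemented. **GT** (ground truth) is a white
reference taken under exactly the sample's illumination; **SB** (single
background) reuses one white reference everywhere; **RB** (retrieved
background) is estimated from the sample data. For any positive scalar error
ω in B̂ the algebra is exact: R picks up a factor 1/ω and A an offset
+log₁₀ω. These two laws are the backbone of the test suite and hold to
floating-point precision.

The retrieval assumes the illumination is spectrally uniform,
B(x,y,λ) = M(x,y)·S(λ), and that the sample absorbs negligibly at a reference
wavelength λ_ref (default 800 nm — central in the NIR tissue optical window
and an isosbestic point of haemoglobin, so blood oxygenation does not bias
it). Then I(·,·,λ_ref) ≈ M·S(λ_ref), and

    RM(x,y,λ) = (C_s(x,y) / C_b) · NS(λ),

with NS the min-max normalised source spectrum, C_s the dark-subtracted
intensity at the channel nearest λ_ref and C_b = NS(λ_ref), recovers M·S up
to the sample's residual reflectance at λ_ref. The identity the
implementation satisfies (tested): when NS is proportional to S, RB
absorbance equals A_GT(λ) − A_GT(λ_ref) for every pixel, independent of M.
Consequences: the spectral *shape* is always preserved, while the magnitude
is underestimated exactly by the sample's absorbance at λ_ref — negligible
for methylene blue, a few percent for blood, ~30% for nigrosin, which
reproduces the reported qualitative behaviour of the method.

Numerical policies (all declared, all tested): under-dark pixels clamp to 0;
reflectance ratios ≤ 0 are floored at 1e−6 with a warning mask rather than
aborting a whole-cube correction; NS values below a 1% floor are clamped
before division (channels there are flagged unreliable); C_s ≤ 0 pixels are
flagged invalid and retrieve a zero field; the cosine argument of the
spectral angle is clamped to [−1, 1]. An optional ±k-channel band average
for C_s exists but is off by default — the single-channel value is the
method as specified.

## The synthetic study

The generator emulates the conditions under which the correction methods are
compared, with every random draw seeded and recorded.

**Illumination.** M(x,y) is an isotropic bivariate Gaussian density with a
uniformly random centre, scaled to unit maximum and floored at ε_M = 0.05
(default σ = 0.35·min(n_x, n_y)). The floor keeps every correction
well-posed; as σ → ∞ the field tends to uniform illumination.

**Source.** S(λ) is a 3200 K Planck curve (halogen lamp) on the 450–900 nm
grid times a blue-edge rolloff window emulating the spectral throughput of a
dispersive system. Dark-subtracted counts of real spectrographs fall to ≈0
at the band edge; the rolloff makes min-max normalisation nearly
proportional to S, confining the retrieval distortion to the few bluest
channels (≤ 0.2 absorbance units at the edge, < 1% beyond ~520 nm). This is
the one place where RB and GT genuinely differ in-band, and it is visible as
occasional sub-100% cross-condition SVM cells.

**Stand-in sample spectra.** The four phantom classes (muscle, oxygenated
blood, methylene blue, nigrosin; deoxygenated blood is in the library for
the noise study) are defined in absorbance as neutral baselines plus
amplitudes on two shared Gaussian band templates — a haemoglobin-like
540/560 nm double band with a blue rise and a small NIR tail, and a dye-like
664 nm band — then converted to reflectance via 10^(−A). Real measured
reflectance spectra are strongly inter-correlated; building all classes from
a shared low-dimensional template basis reproduces that property, and with
it the reported structure that the first two principal components capture
>99% of the variance after per-pixel centring (constant baselines vanish
under row centring, so the class spectra span exactly two dimensions plus
noise). Peak positions and reference-channel absorptions are fixed so the
stated features hold on-grid: oxy maxima at 540/560 nm, deoxy at 550 nm,
methylene blue A(800) < 0.01, nigrosin small but finite A(800) (~30% of its
peak). These are stand-ins, not the unreleased instrument measurements, so
magnitudes that depend on the measured spectra (e.g. exact error
percentages) are not reproduced — only their structure and ordering.

**Phantom and noise.** The label image is a 256×512 canvas (scaled versions
keep proportions; circle radius 28 px at full size) with four clusters of
three circles each in one horizontal row per class; the background region
carries the muscle spectrum, giving exactly four classes for k = 4. Pixel
noise is GT = ρ_class·(1 + α·N) with α ~ U(0, 0.1) and N a smooth
colour-chart-like spectrum drawn per pixel from a pool of six — the relative
form keeps the perturbation below 10% of the signal at every wavelength.
Train and test cubes draw from disjoint seed streams; each cube gets an
independent illumination field.

**SB and RB cubes.** The emulated raw signal is BG·GT with
BG = M·S. SB divides it by the unit-power source spectrum (so SB = M·GT
algebraically); RB runs the actual retrieval on the raw signal through the
same code path as the correction tool, so the two cannot drift apart
(verified bit-for-bit). Absorbance triplets are elementwise −log₁₀ with the
floor above.

**Noise robustness.** Multiplicative zero-mean Gaussian noise at relative
levels 1/5/10/20% is applied channel-wise to the raw oxygenated-blood
spectrum; the percent error is the channel-mean |ΔA| of the RB absorbance
over the channel-mean |A|, summarised over ≥100 replicates. Because the
retrieval anchors on one noisy channel, the mean error grows monotonically
with the level (asserted); absolute values depend on the stand-in spectra.

## Analysis and classification harness

**PCA** vectorises the cube to (pixels × channels), centres each pixel
spectrum by its own mean — exactly as specified, although column centring is
the usual convention (offered behind `center="channel"`) — and
eigendecomposes the channel covariance (1/(n−1)) via SVD; loadings are
sign-fixed by making each one's largest-magnitude element positive. Row
centring makes the result invariant to per-pixel additive offsets (the SB
absorbance error) but not to per-pixel scalings (the SB reflectance error);
both directions are tested. **SAM** is the arccosine of cosine similarity,
scale-invariant but offset-sensitive — the mirror image of PCA's
sensitivities. Cluster references are same-cube class means.

**Classifiers.** k-means is scikit-learn's MiniBatchKMeans (k = 4), fed one
hypercube per partial fit, stopping after 21 epochs without inertia
improvement on a fixed evaluation sample (max 100 epochs); clusters are
mapped to classes by exhaustive optimal matching over the 4! permutations.
The SVM is an incremental one-vs-all hinge-loss SGD classifier (ℓ2
regularisation 1e−4, 5 passes over the cubes). The CNN is a six-weight-layer
numpy network — three strided 1D convolutions (kernel 7, channels 8/16/32),
dense layers of 64 and 32, softmax over 4 classes — trained with plain SGD
(lr 0.01, 200-spectrum batches, ≤ 20 epochs, stopping once training accuracy
reaches 100%); optional 5-fold cross-validation reports fold accuracies. Its
input layer standardises each spectrum (zero mean, unit variance), which
makes it provably invariant to per-spectrum offsets and scalings — a
mechanistic account of why a well-trained CNN is insensitive to the
background condition. Gradients are verified against finite differences.

**Scaling modes.** The per-spectrum min-max map to [−1, 1] is an affine map
per row, so it cancels *any* per-row affine distortion — offsets and
scalings alike. That cancellation is itself one of the effects under study
(it is why supervised classifiers score identically on GT and SB absorbance
after per-spectrum scaling, tested as an identity), but under it the three
background conditions become bitwise indistinguishable, so no degradation
can be observed. The harness therefore also provides cube-level scaling (one
global min/max per hypercube), under which SB genuinely degrades: that mode
drives the qualitative ordering result (single-background k-means far below
GT/RB) and the `paper-experiment` driver. The per-spectrum mode is the
default and is what the acceptance experiments use.

## Problem sizes and determinism

The synthetic study in the tests and the acceptance script runs at
64×128 pixels × 100 channels with 10 training and 3 test cubes per
condition — sizes chosen so the full grid (three classifiers, both data
kinds) completes in minutes while every claim under test (exact laws,
ordering, variance capture, 100%-accuracy plateaus) is already stable at
this scale. All experiments derive every random stream from a single seed
via `numpy.random.SeedSequence`; identical seeds reproduce cubes, models and
reports exactly.

## Known limitations

- The retrieval requires spectrally uniform illumination; multi-source,
  spectrally heterogeneous lighting violates the model and is out of scope.
- Samples with non-negligible absorption at the reference wavelength are
  systematically underestimated in magnitude (shape is preserved).
- Min-max normalisation of a source that does not fall to ~0 in-band
  distorts the bluest channels; the NS floor bounds but does not remove
  this.
- The generator does not emulate fibre-bundle artefacts, spectrograph
  smile/keystone, or detector shot/read noise beyond the stated models, and
  its stand-in spectra are smoother and better separated than real tissue
  measurements — passing grids here demonstrate the mechanism, not clinical
  performance.
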