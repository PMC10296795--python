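# Methods

## Imaging model

The simulator and the AMD computation assume the absorption
intensity-fluctuation-modulation picture of full-field optical angiography:
erythrocytes absorb far more than the surrounding tissue and move through
vessels discontinuously, so a vessel pixel's intensity time series carries a
fluctuating component while tissue contributes only a quasi-DC signal. The
separation is performed per pixel in the temporal Fourier domain with an
*ideal* mask: bins with |f| > cutoff form the dynamic signal, bins at or
below it (DC included) the static one. Hard masks keep the two components
exactly complementary (`dynamic + static == stack` to round-off) and
orthogonal, which windowed filters would not. The cutoff is a free
parameter (default 1.0 Hz at 42 frames/s, both configurable); the
concentration estimate `sigma = I_r / I_b` is valid in the dilute limit
where moving scatterers are far outnumbered by static ones (at a 1:100
ratio the approximation is off by ~1%). AMD uses a 1e-12 guard in the
denominator, so zero-background pixels return finite values.

## Transform

The NSCT here is a Laplacian-style nonsubsampled bank. The pyramid stage
convolves with an a-trous-upsampled 2-D lowpass kernel (upsampling factor
`2^(u-1)` at scale `u`) and takes the detail as the difference of successive
approximations; the directional stage splits each detail band with a fan
filter (a McClellan diamond built from a 7-tap Lagrange halfband, modulated
by pi along one frequency axis) and, at the second tree level, its
quincunx-upsampled version. In both stages the second channel is
`delta - first channel` and synthesis is summation, so perfect
reconstruction holds to machine precision for *any* boundary handling, every
bandpass channel has exactly zero DC gain, and the transform is linear and
(with wrap padding) exactly shift-covariant. The kernel tables are shipped
as plain-text files registered under the conventional toolbox names
("pyrexc" pyramid, "vk" directional); any PR-satisfying pair can be added
alongside them. Directional depth per scale is supported up to 2 (four
subbands); deeper trees would need parallelogram upsampling and are
rejected with a configuration error. Convolution runs in the spatial domain
for kernels up to 32x32 and via FFT products above that; the two paths agree
to 1e-8 and are covered by a test.

Boundary handling is mirror (reflect-without-edge) padding everywhere;
circular padding is available and is what the shift-invariance guarantee is
stated for.

## Sparse coding and dictionary

OMP is a vectorised batch implementation (precomputed Gram matrix, batched
normal-equation solves on the active sets). Selection ties go to the lowest
atom index; a signal stops when its residual 2-norm drops below delta
(default 0.01 for unit-range 8x8 patches) or at `max_nonzeros` (default 8)
atoms. K-SVD alternates that coding stage with sequential exact rank-1 SVD
atom updates. Two guards make the logged mean-residual sequence provably
non-increasing: the coding stage keeps a signal's previous code whenever it
beats the fresh OMP code, and only *unused* atoms are re-initialised (from
the currently worst-coded signals, seeded). Initial atoms are drawn from
the training patches; duplicates (e.g. flat background blocks) are jittered
apart so the dictionary never contains coincident columns.

The default dictionary (256 atoms, 30 iterations, 20 000 patches) is
trained at run time on a corpus of seeded vessel phantoms plus their
blurred versions — smooth defocused patches need representation too — so no
external image collection is involved and retraining is fully
reproducible. The test suite and the acceptance script use a reduced
dictionary (128 atoms, 8 iterations, 5000 patches), which trains in seconds
and codes phantom low-pass content well below the delta tolerance. Patches
are coded raw (no mean removal), matching the literal three-step low-pass
rule; patch stride defaults to 1 (maximum overlap) and overlapping decoded
blocks are averaged by per-pixel coverage.

## Decision maps

The spatial-frequency saliency mirrors the printed formulas literally: RF
is the windowed *mean of squared* horizontal first differences (no inner
square root), CF likewise vertically, and `S = sqrt(RF^2 + CF^2)` squares
them again. Differences are taken between pixels of the mirror-padded
window, and differences whose left/upper pixel falls outside the window are
excluded (the printed summation limits start at the second column/row).
The conventional root-mean-square variant sits behind
`literal_formulas=False`. The CSF comparison is strict
(`S_A > local mean of S_B`; ties select B). Area opening removes
8-connected components *strictly* smaller than `ceil(r*C)` (C = image
area) and, by default, applies the same opening to the background so small
holes and bumps are corrected; foreground-only behaviour is selectable.
Consistency verification is a strict majority over an N x N window — the
printed comparison omits its threshold, and majority filtering is the
standard reading in the decision-map literature; the window (default 59) is
configurable. Each (scale, direction) pair gets its own independent map.

## Synthetic data: what it does and does not emulate

Phantoms are smooth seeded random walks (with occasional branches) rendered
with Gaussian cross-sections (width 1-3 px) and combined by maximum over a
constant dark background; `texture_amplitude` optionally adds multi-scale
Gaussian-correlated tissue texture (correlation lengths 1.5/5/12 px). The
fusion experiments use dense phantoms (20 vessels at 256x256) *with*
texture 0.03, because real angiograms carry weak tissue structure
everywhere and a perfectly flat background holds no focus information —
both subbands tie exactly there, and no decision rule could recover the
focus mask. Multi-focus pairs blur the out-of-focus side with a sigma = 3
Gaussian and blend across an 8-px distance-transform transition band (hard
focus edges are unphysical). Temporal stacks put unit-RMS band-limited
fluctuations (Gaussian spectral window, default 2 Hz bandwidth around 8 Hz
at 42 fps) inside vessels over a constant background, plus seeded sensor
noise; a zero-bandwidth mode produces pure random-phase sinusoids, for
which AMD has the closed form `(2a/pi)/d`.

Not emulated: physical speckle statistics (Rayleigh/negative-exponential
amplitudes), realistic optical PSFs beyond Gaussian blur, misregistration,
or depth-continuous defocus. Passing tests therefore demonstrate the
correctness and selectivity of the *method* under controlled conditions,
not end-to-end performance on a physical instrument.

## Quality metrics

All three metrics quantise intensities to 256 levels and use unsmoothed
joint histograms. Q^MI is the normalised form
`2 [ I(A;F)/(H(A)+H(F)) + I(B;F)/(H(B)+H(F)) ]`, exactly 2 when F = A = B;
a constant image's zero-entropy term contributes 0 with a warning. Q^TE is
the same construction with order-q Tsallis divergence and entropies
(q = 1.85, the customary value in this metric family) and converges to Q^MI
as q -> 1. Q^NCIE builds the 3x3 matrix of pairwise nonlinear correlation
coefficients — each `H_b(X) + H_b(Y) - H_b(X,Y)` on rank-transformed,
equal-frequency-binned pixels, entropies in log base b = 256 — and returns
`1 + sum (lam_i/3) log_b(lam_i/3)` over its eigenvalues; it is exactly 1
for identical images whenever the pixel count divides evenly into the bins
(e.g. 64x64). Histogram MI estimators carry a positive small-sample bias,
so trend checks (noise degrades all metrics) are run on smooth
angiogram-like content where the joint histograms are well sampled.

## Problem sizes and known limitations

The suite runs the transform checks at 64x64 (50 random images), fusion
recovery on ten 256x256 phantom pairs, self-fusion on five 128x128
phantoms, and K-SVD recovery on 2000 patches / 80 atoms / 30 iterations;
these sizes keep the full suite to a few CPU-minutes while leaving every
property comfortably away from its threshold.

Known limitations:

* At the coarsest scale (32-64 px wavelengths) a sigma = 3 blur changes
  subband amplitudes by only ~10-15%, so fourth-scale decision maps are
  intrinsically the least reliable (occasionally ~92% agreement against
  ground truth while all finer maps sit at ~100%); map accuracy is
  accordingly assessed over the pooled decision pixels of a pair.
* The CSF rule is asymmetric by construction (A's saliency is compared to
  the local mean of B's), so swapping the inputs can flip decisions in
  ambiguous regions (~5-10% of pixels near the focus boundary); fusion
  quality is unaffected.
* Q^TE's magnitude depends strongly on the image entropy through the
  q = 1.85 Tsallis normalisation; compare values only across methods on the
  same inputs, not across datasets.
* The consistency window (59 px) assumes images of a few hundred pixels per
  side; shrink it for smaller inputs (it must fit inside the image).
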