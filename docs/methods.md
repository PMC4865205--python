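# Methods

## Signal model and assumptions

A fingerprint image is modeled as a bounded 2-D signal f : D → [0, 1] whose
foreground is an oscillatory texture: locally a plane wave with spatial
wavelength (inter-ridge distance) between about 3 and 25 px at 500 DPI and a
smoothly varying orientation. In the frequency plane this texture occupies a
ring of radial frequencies — here called the valid band — while background
structure splits into low frequencies (homogeneous regions, illumination)
below the band and small-scale noise above it. The method's premise is that
foreground/background separation is a band-and-orientation selection
problem, not an intensity one; all thresholds in the pipeline are therefore
relative (scale-invariant), and the output ROI is unchanged under positive
rescaling of the input intensities (tested).

Images are read as 8-bit grayscale and divided by 255. No resizing is
performed by default; inputs are assumed to be near 500 DPI adult prints so
that the fixed cutoffs apply.

## Filter bank

**Radial selection.** The 1-D Butterworth bandpass power response is
evaluated in the pole-free form

    b̂(ω) = (ωΔ)^{2γ} / [(ωΔ)^{2γ} + (ω² − p²)^{2γ}],

Δ = ω_H − ω_L, p² = ω_H·ω_L, which is algebraically identical to the
rational form with the removable singularity at ω = 0 eliminated; b̂(0) = 0
is assigned as the limit. b̂ has its unique maximum 1 at p, and approaches
the ideal (brick-wall) bandpass as γ → ∞; moderate γ is preferred precisely
because the ideal filter rings (Gibbs effect). The overflow-safe ratio form
1/(1 + r^{2γ}), r = (ω² − p²)/(ωΔ), keeps γ = 50 evaluations finite.

The default *discrete* response (`variant="bilinear"`) factorizes the analog
transfer function over the nodes t_k = e^{πj(γ+2k−1)/2γ} (whose negative
squares are the γ-th roots of −1) and maps each factor through the bilinear
substitution jω ≈ 2(e^{jω} − 1)/(e^{jω} + 1). This warps the frequency axis
(ω_analog = 2 tan(ω/2)) and slightly narrows the passband; it also forces a
zero at the Nyquist frequency, which is desirable here (pixel-level noise).
The analog magnitude response is retained as `variant="original"`; it is
real and convenient for exactness tests. Which variant produced published
benchmark figures is not derivable from the description; the bilinear form
is the one the derivation actually constructs, so it is the default.

**2-D extension.** Rather than a polar tiling, each frequency (ω₁, ω₂)
receives the 1-D response along exactly one axis: the horizontal branch
where b|ω₁| ≥ a|ω₂| and the vertical branch otherwise, with a, b the
half-widths of the padded spatial domain (for square images: |ω₁| ≥ |ω₂|).
Both printed indicator functions are 1 on the diagonal; ties are assigned to
the horizontal branch so the two indicators partition the plane (verified
exhaustively) and diagonal frequencies are not double-weighted.

**Orientation selection.** The n-th order directional Hilbert transform
along u = (cos θ, sin θ) has spectrum (−j)ⁿ (⟨u, ω⟩/‖ω‖)ⁿ =
(−j)ⁿ cosⁿ(∠ω − θ). It is bounded by 1, real for even n, and undefined at
DC, where it is set to 0 — harmless because the bandpass vanishes there
anyway. With θ_l = πl/L, l = 0..L−1, and the default n = 20, L = 16, the
worst-case ridge orientation (midway between two θ_l) still passes
cos²⁰(π/32) ≈ 0.908 of the bandpass gain, so no orientation falls into a
gap. The constant (−j)ⁿ is +1 for n = 20.

The subband filters are built directly on the unshifted DFT frequency grid
of the padded image (2π·fftfreq), so image spectra are never fftshifted and
off-by-one layout bugs are structurally excluded.

## Factorized transform

Analysis correlates the padded image with the argument-reversed kernels:
c_l = IDFT(DFT(f)·φ̂_l^∨) with φ̂_l^∨(ω) = φ̂_l(−ω), realized as an exact
index reversal on the DFT grid. All filtering is circular; the 15 px mirror
pad (reflect-101, edge sample not duplicated, so cropping is an exact
inverse) absorbs the wrap-around. Coefficients are kept complex throughout;
for even n they are real up to round-off.

The shrinkage level is β = C·max_{l,m}|c_l[m]|, the *magnitude* maximum —
coefficients are signed/complex, and a signed maximum would make β depend on
pattern polarity, which has no bearing on its role as a noise floor.
Soft-thresholding is applied per coefficient (x/|x| defined as 0 at 0);
hard, semi-soft and garrote rules are implemented in their conventional
textbook forms as comparison operators only, with the semi-soft upper knee
β₂ defaulting to 2β.

Synthesis filters the thresholded coefficients with the non-reversed
kernels, sums over subbands and takes the real part (exactly real in the
β = 0 limit, where the whole transform reduces to linear filtering by
Σ_l φ̂_l^∨ φ̂_l — an identity the tests verify to 1e−10). The max/sum
reconstruction operators (signed max across subbands; plain sum; each with
or without shrinkage) skip the second filter pass and are provided solely
for the comparison study.

## Segmentation

Binarization keeps pixels with f̃ ≥ C·max f̃ (the same trained C as the
shrinkage, as the method prescribes). A feature image whose maximum does not
exceed 1e−9 is treated as degenerate and yields an empty ROI: an exactly
zero feature image would otherwise binarize to all-ones (0 ≥ 0), and a
numerically-zero one (FFT round-off of a blank image, magnitudes ~1e−16 on
[0,1] inputs) would binarize pure noise. The floor is ten million times
below any real texture response, so it cannot clip genuine signal.

The two-scale morphology votes over nine s×s cells at offsets {−s, 0, s}²:
a cell passes with at least s²/t foreground pixels (not rounded, ≥ as
stated), and the pixel becomes foreground with at least b passing cells.
Pixels outside the image count as background, but cells *centered* outside
the image still exist and count their in-image pixels — the box-sum
implementation therefore evaluates cell occupancy on an s-extended
zero-padded domain and matches a per-pixel loop oracle bit-exactly. Near
borders this erodes (a corner pixel has at most four cells overlapping the
image), which is the conservative behaviour wanted at scan margins. The
literal index expression for the cell offsets would produce only the three
diagonal neighbours and the occupancy threshold reads "s²t", which is
unreachable (it exceeds s² for the trained t); the nine-cell neighbourhood
and s²/t are the only readings consistent with the accompanying description
and the trained parameter ranges.

Components use 8-connectivity. The ROI is the filled convex hull of the
largest component: hull vertices from `scipy.spatial.ConvexHull`, rasterized
by half-plane tests on pixel centers with boundary pixels included
(tolerance 1e−9, far below the minimum distance of an off-facet lattice
point). Degenerate (collinear) components are returned as-is. A separate
hole-filling step is unnecessary since the hull contains every hole. The
hull makes the ROI convex by construction — adequate for plain-to-roll
fingerprint impressions, wrong for genuinely non-convex foregrounds (e.g.
latents), which are out of scope.

## Evaluation and training

Err = (M_f + M_b)/(N₁·N₂) per image; dataset scores are the unweighted mean
of per-image Err (images of differing sizes are not pixel-pooled). Training
is an exhaustive grid search over C ∈ {0.03..0.09}, γ ∈ {1..4}, t ∈ {4..7}
(the ranges spanning all trained per-sensor values) minimizing mean training
Err, ties broken to the lexicographically smallest (C, γ, t). Since t only
enters the morphology, the search computes each feature image once per
(C, γ) and re-runs only the cheap morphological tail per t; exhaustiveness
is unaffected. Package defaults (C, γ, t) = (0.05, 2, 5) sit at the centre
of the trained ranges and are intended as a sensible untrained operating
point, not a substitute for training.

Ground-truth masks are accepted in either polarity; by default the polarity
is chosen so that foreground dominates the central window of the mask, with
an explicit override for unusual layouts.

## Synthetic data

The generator renders 0.5 + (A/2)·cos(2π·phase/λ) inside a known ellipse
(the exact ground truth) on a 0.5 background, with three orientation
fields: constant direction, concentric arcs around a core above the ROI
centre, and a smoothly rotating direction (±0.35 rad across the width —
small enough that the local wavelength stays in band). Defaults: 192×192
images, ridge contrast A = 0.5, ellipse axes ~0.40/0.32 of the image
(foreground fraction ≈ 0.4, typical of plain impressions).

Wavelengths cycle through {4, 8, 12, 20} px. Note that λ = 4 px
(ω ≈ 1.57) lies above the upper cutoff and is passed only at reduced gain;
it is retained deliberately: because all pipeline thresholds are relative,
a uniformly attenuated clean pattern still segments, and the fixture
exercises exactly the "treat all realistic frequencies alike" requirement.
Such images are the hardest in the clean tier once any noise is present,
since in-band noise is *not* attenuated alongside the pattern.

Difficulty tiers are nested so that difficulty is monotone by construction:
clean adds sensor noise σ = 0.02 (a good-quality capture, ~5 gray levels at
8 bit); noisy raises it to σ = 0.08 (a poor capture, SNR ≈ 3 against the
ridge contrast); artifacts keeps σ = 0.08 and adds the degradations that
plague real sensors — a 60%-attenuated ghost print offset outside the true
ROI, large-scale smooth structure-noise blobs (amplitude 0.15), and patchy
ridge dropout emulating a dry finger (30% contrast loss). An early draft
used a harsher, non-nested noise ladder (σ up to 0.15 with *less* noise in
the artifacts tier); it was replaced by the nested ladder above both for
realism and because non-nested tiers do not define a difficulty ordering at
all. All randomness derives from the single suite seed, and regenerated
suites are byte-identical.

**What the synthetic fixtures do not show.** The patterns are locally pure
cosines: real ridge texture has harmonics, minutiae, pores and amplitude
modulation, i.e. a much richer in-band spectrum. One measured consequence:
the advantage of the factorized synthesis over the naive subband sum *with*
shrinkage — which on real texture comes from re-filtering away the
frequencies that thresholding scatters — is small on these fixtures
(fractions of a percentage point of Err), and the two are statistically
tied across seeds, while both no-shrinkage variants and the max operator
are clearly worse. Passing tests therefore demonstrate correctness of the
machinery and the qualitative orderings, not the full effect sizes expected
on real scans.

## Problem sizes and numerical choices

The test suite and examples use 192×192 images (222×222 padded), 16-subband
banks, training suites of 4–6 images with the full 112-point default grid,
and 20-image evaluation suites per tier — sizes chosen so a complete run
takes about a minute on one core while still exercising every code path at
realistic foreground fractions. Oracle comparisons (spatial correlation,
per-pixel morphology loop, dense prox grids, 50-digit symbolic evaluation of
the transfer function) run on reduced sizes (16×16 images, 64×64 masks)
where brute force is exact and fast.

Determinism: the pipeline contains no randomness; fixed inputs give
bit-identical feature images, masks and CSV reports. Generator determinism
flows from `numpy.random.default_rng(seed)` exclusively.

Known limitations: convex ROIs only; single fixed frequency band (no
per-image band estimation, so heavily scaled or adolescent prints need
resizing first); the bilinear variant's complex subbands make the feature
image mildly sensitive to the phase of high-frequency content near Nyquist;
border cells erode the outermost ~s px of genuinely foreground texture
touching the image edge (the convex hull usually recovers it).
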