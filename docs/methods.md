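# Methods

## The imaging model

All simulations and reconstructions in `classim` rest on one assumption:
within an isoplanatic patch (the optical memory-effect range), a thin
scattering layer acts on the image as a single shift-invariant convolution.
A *static* scatterer under varying illumination and a *dynamic* scatterer in
front of a static object then produce the same data, with the roles of the
two factors exchanged:

    I_m(r) = P_m(r) * O(r) = O(r) * P_m(r),        m = 1 … M,

where `O` is the hidden object (intensity in incoherent mode, complex
reflectivity times a fixed illumination — the *effective object* — in
coherent mode) and `P_m` the PSF of the m-th scatterer realization.
Because convolution commutes, the matrix machinery developed for random
illuminations applies verbatim to random media: arranging the centred 2-D
Fourier transforms of the frames as columns of a matrix **A**, the frame
spectra factor as `A[:,m] = diag(Õ) · P̃_m`, and for PSF realizations whose
centred pixels are mutually uncorrelated

    Cov(A) = diag(Õ) · T · diag(Õ)*,

with `T(k1,k2) = t(k1−k2)` a (circulant) Toeplitz kernel — the Fourier
transform of the per-pixel PSF variance map.  The object's Fourier phase
and amplitude are recovered from this factorisation; the per-frame PSFs
follow by frame-wise Wiener deconvolution with the reconstructed object.

Convolution is **circular** throughout, implemented as products of centred
FFTs, so the forward model and the covariance factorisation agree exactly
(a `linear=True` flag zero-pads when linear convolution is wanted for
realism checks).  Spatial and frequency origins sit at the centre sample
`(N//2, N//2)` in both domains.

## Phase retrieval

`class_phase_retrieval` pins down the closed-loop accumulation scheme as
the normative algorithm.  With `ψ` the current phase estimate, each
iteration forms

    kernel:  t(q)    = Σ_k  C(k+q, k) e^{−iψ(k+q)} e^{+iψ(k)}
    phase:   ψ(k1) ← arg( Σ_{k2} C(k1,k2) e^{+iψ(k2)} t*(k1−k2) )

with all frequency differences circular.  Both sums are evaluated through
frame-domain FFT correlations, so the dense `N_k × N_k` covariance is never
materialised (`class_phase_retrieval_dense` applies the same updates
literally and serves as the test oracle; the two agree to ~1e−8 on small
instances).  The kernel weighting concentrates the accumulation on the
frequency offsets at which the PSF ensemble actually carries phase
information — `|t(q)|` is large only within the inverse PSF-envelope
width — and is what makes the update robust at realistic M.

Design choices a user should know:

- **Initialisation** is ψ ≡ 0; the iteration is fully deterministic (no
  randomness enters the reconstruction).
- **Gauge.**  The retrieved phase is defined only up to a constant and a
  linear ramp (an unobservable cyclic shift).  After convergence the ramp
  is removed by the amplitude-weighted mean phase increment between
  neighbouring frequency samples (exact for a pure ramp) and the DC phase
  is zeroed.  `arg(0)` is defined as 0.
- **Convergence** is declared when the mean absolute wrapped phase update
  drops below `tol` (default 1e−6 rad) within `n_iter` (default 1000).
  Non-convergence produces a warning status in the trace, never an
  exception.  On exact-model (noise-free) covariances the update decays
  monotonically after a burn-in window declared as the first quarter of
  iterations; on finite-M empirical covariances the trace is noisy and
  only the trend is meaningful.
- **Amplitude** starts from the covariance diagonal,
  `|Õ(k)| = sqrt(max(C(k,k), 0))` — the moment estimator consistent with
  the factorised model, with the unknown constant `t(0)` absorbed into the
  global scale.  The diagonal, however, estimates `|Õ(k)|² · s(k)` with
  `s(k)` the PSF-ensemble spectral power, which for physical speckle PSFs
  is far from flat (zero at DC for energy-conserving media, an
  aperture-autocorrelation decay at high frequency).  Because `s(k)` is a
  property of the data, one self-consistent refinement step removes it:
  Wiener-deconvolve each frame by the initial reconstruction to recover
  the per-frame PSFs (the reconstruction's unknown shift cancels in their
  power spectra), measure `ŝ(k)` as their centred mean spectral power, and
  Wiener-divide the amplitude by `sqrt(ŝ)` (regularizer `amp_refine_eps`,
  default 0.05).  Enabled by default; `amp_refine=False` restores the
  plain diagonal estimator.
- **Precision.**  The iterative loop in the full pipeline runs in single
  precision (`work_dtype=complex64`), halving FFT memory traffic; the
  per-iteration phase rounding (~1e−6 rad) is far below the statistical
  error of realistic ensembles.  `class_phase_retrieval` defaults to
  double precision, where it matches the dense oracle to ~1e−14.
- **DC restoration (incoherent mode).**  Mean-frame subtraction removes
  the DC component of the spectrum.  It is restored from the temporal-mean
  frame, whose total intensity equals the object's (unit-sum PSFs); the AC
  part is first rescaled by matching the lowest nonzero frequencies of the
  mean-frame spectrum, where the PSF-envelope transfer is close to unity.
  The DC/AC relative scale is fundamentally unidentifiable without priors
  on the PSF statistics, which is why all quantitative metrics in the
  package (registered correlation, haze) are offset- and scale-invariant.
  The final incoherent image is the real part of the inverse transform
  clipped at zero (the clipped fraction is recorded in the result
  metadata).
- **Static-medium fallback.**  If the frames show no frame-to-frame
  variation (no scattering, or a frozen medium), the covariance carries no
  information and the temporal mean frame is returned as the
  reconstruction, flagged `static_fallback` in the metadata.

## Intensity modulation

Phase-only screens conserve energy, so every raw frame has exactly the
same total intensity.  This pins `P̃_m(0)` to a constant across the
ensemble and induces residual correlations between PSF realizations that
bias the covariance near DC.  `apply_intensity_modulation` multiplies
frame m by the deterministic scalar `s_min + (s_max−s_min)(m−1)/(M−1)`
(default 1 → 2), restoring frame-to-frame energy variance before the
covariance is formed.  It is off by default and should be enabled whenever
the medium is energy-conserving (it is enabled in the incoherent
experiment configurations shipped with the package).

## The synthetic scatterer

`generate_phase_screen` draws white Gaussian noise, filters it with a
Gaussian kernel in the Fourier domain, and rescales to the exact sample
RMS.  `corr_len_px` is defined as the correlation length of the complex
transmission `exp(iφ)` — the quantity that controls the speckle-PSF
envelope and the one diffuser vendors quote — so the underlying phase
correlation length is internally stretched by `max(rms, 1)`.  Consequences
worth knowing:

- The PSF envelope occupies roughly `N/(π·corr_len_px)` samples, so with
  the default `corr_len_px = 4` the scattered blur fills a central blob of
  the field of view rather than the whole frame.  This is the isoplanatic
  imaging regime the method addresses: the Toeplitz kernel `t(q)` is then
  a few samples wide and the covariance genuinely carries phase
  information.  Screens much rougher than this (envelope filling the whole
  frame) drive `t(q)` toward a delta and starve the retrieval; screens much
  smoother degenerate into low-order aberrations.
- For deep screens the per-realization fields are not strictly Gaussian
  speckle (the smooth deep phase produces caustic-like structure); the
  fully developed exponential-intensity limit is reached when the phase is
  pixelwise independent.
- `frame_correlation = c` mixes the underlying Gaussians as an AR(1)
  process (`g_m = c·g_{m−1} + sqrt(1−c²)·w_m`) before RMS renormalisation,
  so adjacent screens correlate with coefficient ~c and `c = 0` gives
  mutually independent realizations.
- The optional pupil (default: a circular aperture at the full Nyquist
  radius) sets the diffraction limit.  Unit-sum PSF normalisation makes
  every frame conserve energy exactly regardless of the pupil.
- Detection noise is optional and off by default: Poisson shot noise at a
  `photons_per_frame` budget plus additive Gaussian read noise.  (The
  defaults are declared choices, not fits to any dataset.)

What the generator does **not** emulate: volumetric (thick-medium)
scattering, anisoplanatism, polarisation, ballistic components, detector
nonlinearity, or reference-arm phase drift in holography.  Tests passing
on these synthetics therefore demonstrate correctness of the algorithmic
chain under the stated model, not performance on any particular physical
system.

## Coherent mode and holography

In coherent mode the frames are complex fields
`E_m = P^coh_m * (O · E_ill)` with `P^coh_m = F{pupil · e^{iφ_m}}`
energy-normalised, and the illumination fixed across realizations (the
focused-spot condition: the beam waist on the scatterer is smaller than
its correlation length).  Speckle fields are zero-mean, so no mean
subtraction is applied before building **A**.  The reconstruction returns
the complex effective object at the scattering-layer plane; when the
physical object sits a distance `dz` away, `fresnel_propagate` moves the
field between planes using the transfer function

    H(fx, fy; Δz) = exp(i·2πΔz/λ) · exp(−iπλΔz(fx²+fy²)),

evaluated on centred frequency grids in cycles/µm.  The constant phase
factor is retained so `H(Δz1)·H(Δz2) = H(Δz1+Δz2)` holds exactly; |H| ≡ 1
makes propagation unitary and invertible by flipping the sign of Δz.  A
guard warns when `λ|Δz|/(N·pitch²) > 0.5` (badly sampled quadratic phase).

Off-axis holograms are `|E + A·e^{−i2π c·r}|²`; demodulation transforms,
crops a disk (`crop_radius_frac` of Nyquist, hard-edged by default) around
the sideband carrying `E`, recentres and inverse-transforms, recovering
the field up to the constant reference amplitude.  The carrier must exceed
the field bandwidth and stay below Nyquist so the sidebands separate; a
warning is emitted when energy is detected midway between sideband and DC.

Per-frame APSF estimation divides each frame spectrum by the reconstructed
object spectrum on the support where the latter is significant
(`support_thresh`, default 1e−3 of the peak): at the scattering-layer
plane the measurement is the object field multiplied by `e^{iφ_m}`, so the
ratio isolates the diffuser phase of that realization, and the APSF is the
centred transform of `e^{iφ̂}` on that support, energy-normalised.  The
ratio magnitude is bimodal when a band-limiting pupil is present
(passband level vs ~0 stop band), so the support additionally excludes
pixels whose ratio magnitude falls below 10% of the upper-tail (99.5th
percentile) level — stop-band noise otherwise masquerades as phase.

The reference coherent experiment uses a 128×128 grid with a 0.25-Nyquist
pupil and an off-axis carrier of 0.28125 cycles/pixel on both axes (36/128
— an exact DFT sample).  The pupil's band limit is what makes single-frame
off-axis holography physically meaningful on a finite grid: the sideband
(radius 0.125 cycles/px), the DC autocorrelation term (radius 0.25) and
the conjugate sideband then separate cleanly below Nyquist.  Full-band
speckle fields cannot be off-axis-multiplexed on the same grid — real
systems always oversample the speckle at the camera, and the pupil models
exactly that.

## Evaluation

Reconstructions are compared to ground truth with
`registered_correlation`: Pearson correlation maximised over all cyclic
shifts and over the point-reflected twin (Fourier-phase methods are
defined only up to these transforms).  Background haze is the median of
the registered, floored and support-normalised reconstruction outside the
object support.  `psf_diagonality` scores how diagonal the PSF-ensemble
pixel covariance is (1 = perfectly uncorrelated pixels); note it carries a
finite-M sampling floor of order `N_pix/√M`, so only comparisons at
matched M are meaningful.

## Problem sizes and ensemble fluctuations

The shipped experiment configurations use a 64×64 grid with M = 150
realizations (incoherent) and a 128×128 grid with M = 180 (coherent,
where the pupil band limit demands more pixels per resolution cell), both
with the standard 1000-iteration retrieval budget — ensemble sizes
matching the regime the method is designed for, at grid sizes chosen so a
full experiment runs in minutes on one CPU core.  The
covariance-convergence study uses 16×16 grids with M up to 8000, where
the dense covariance is still tiny.

Reconstruction fidelity at small M fluctuates strongly from realization
to realization (at M = 10 the registered correlation ranges over ~0.4
across seeds, partly because the deterministic intensity ramp itself
carries a rank-one blurred-object component that dominates when speckle
statistics are poor).  Fidelity-vs-M statements are therefore properties
of the seed mean, and the tests evaluate them as such.

## Known limitations

- The Fourier-amplitude estimator (covariance diagonal) differs from
  iterative amplitude refinement; under strong noise it inherits the
  diagonal's bias.
- Monotone convergence is guaranteed only on exact-model covariances;
  empirical covariances can show transient plateaus and escapes.
- `psf_diagonality` materialises an `N_pix × N_pix` covariance and is
  intended for grids up to ~64×64.
- No SVD filtering of the covariance, no anisoplanatic mosaicking, no
  thick-medium corrections.
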