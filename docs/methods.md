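# Methods

This note documents the model, the numerical choices, and what the
synthetic study design does and does not establish.

## Photon transport model

Photon packets follow the standard multilayer Monte-Carlo random walk:
exponential free paths with s = −ln(u)/μt, Henyey–Greenstein (HG)
deflection cosines from the closed-form inverse CDF, uniform azimuth, and
unpolarized Fresnel reflection/refraction at layer boundaries.  The HG
phase function is parameterized solely by the anisotropy factor g, which is
the only angular-shape parameter varied in the look-up map; it is the
standard single-parameter surrogate for Mie-type scattering in tissue
transport codes.

Choices that depart from, or specialize, the textbook algorithm:

- **Probabilistic boundaries.** At an interface the packet wholly reflects
  or wholly transmits by comparing one uniform draw to the Fresnel
  reflectance, instead of splitting its weight.  With μa = 0 (the corneal
  default — stromal absorption at 850 nm is ~0.01 mm⁻¹, two orders below
  scattering) every packet then carries weight exactly 1, so the phasor
  amplitudes entering the speckle sum are homogeneous.  The absorption
  drop and Russian roulette (threshold 10⁻⁴, survival 1/10) are
  implemented but inert at μa = 0.
- **Launch.** An infinitely thin beam enters at (0, 0) pointing straight
  down, starting just inside the tissue; there is no specular launch event.
  A specular launch reflection would return ~2.5% of packets straight into
  the detector and swamp the ~0.03% tissue backscatter signal, which is
  inconsistent with the detection fractions the transport model reproduces.
- **Detection.** A packet exiting the top surface is backscattered; it is
  detected iff the straight-line continuation of its refracted direction
  reaches the plane 100 µm above the surface within a disc of radius
  0.2 cm.  No additional angular cut is applied: the low system NA is
  already normalized into this disc geometry.
- **Units and coordinates.** Geometry is in µm internally (coefficients
  enter in mm⁻¹ and are converted at the module boundary); z grows
  downward from the surface, the detector plane is z = −100 µm.  Optical
  pathlength accumulates geometric length × local refractive index, so a
  packet's record is directly the sample-arm interferometric delay.

The transport core reproduces, with no free parameters, the operating
points the acceptance script recomputes: backscattered fraction ≈ 0.031%,
detected fraction ≈ 0.031%, and ≈ 4.6 × 10³ detections per 15 × 10⁶
launched packets at μs = 0.1 mm⁻¹, g = 0.99.

## OCT signal synthesis

For depth pixel j the reference delay is L_ref(j) = 2 n z_j with n = 1.376
and z_j = (j + 1) × 2.7 µm; the air gap above the sample is common to both
interferometer arms and cancels.  The complex amplitude is the phasor sum
over detected packets,

    U(j) = Σ_i √W_i · exp(−4 ln2 (ΔL_ij / l_c)²) · exp(i 2π ΔL_ij / λ0),

with ΔL_ij the packet-minus-reference optical path difference.  The
Gaussian gate with FWHM equal to the coherence length l_c is the standard
choice for a Gaussian-spectrum source; the reference-arm amplitude is 1
(any constant is removed by the downstream normalization).  The envelope
is |U(j)| — equivalent to demodulating Re U(j) since all phasors share one
carrier frequency, and numerically cleaner.  The deepest ~30 rows of the
223-pixel scan contain the bright stroma–aqueous interface reflection;
the 193-row (≈ 521 µm) ROI excludes them.

## Speckle statistics and matching

- **Contrast ratio.** CR = sample standard deviation (n−1) / mean.  The
  definition is centralized in one function; CR is exactly invariant under
  the simulated-ROI normalization.
- **Kernel density.** Gaussian kernel with Silverman's rule-of-thumb
  bandwidth (as implemented by `scipy.stats.gaussian_kde`), evaluated on a
  512-point grid spanning [0, 1.05 × max] over *all* blocks compared in an
  analysis — one shared grid per analysis, as the density distances
  require.  Because speckle amplitudes cluster near zero, part of the
  kernel mass falls below 0; the evaluated density is renormalized to unit
  trapezoid mass on the grid so that densities are proper before the
  distances are formed.
- **Distances.** D_RMS is computed as the integrated squared difference
  (no square root): the minimizer is unchanged by the monotone root, and
  the integral form is what the matching uses.  D_KL floors both densities
  at 10⁻¹² and renormalizes to unit sum before the discrete divergence
  (natural log), keeping it finite and non-negative.  Argmin ties take the
  first (lowest-index) reference and are logged.
- **Ensemble.** The estimate is the arithmetic mean of the three
  per-distance (μs, g) minimizers; it always lies inside the grid's hull.

## Look-up map and reproducibility

The default grid is μs ∈ {0.10 … 0.20} mm⁻¹ step 0.01 (11 values) and
g ∈ {0.85 … 0.99} step 0.01 (15 values): 165 references, one simulated
B-scan ROI each.  Entry k is built from sub-seed SeedSequence((master, k)),
so any entry can be rebuilt in isolation and the map content is
independent of build order; within a B-scan, each of the 40 A-scans gets
its own substream so columns are independent realizations.  The HDF5 map
file carries the full grid, seeds, photon budget, source and detector
specifications, and refuses to load across schema versions — a map cannot
silently be matched against a sample simulated under different system
assumptions.

## Study scale and photon budgets

The reference operating budget is 15 × 10⁶ packets per A-scan.  The
package's own test and benchmark runs scale this down so the whole suite
completes on one CPU:

- transport benchmarks run the full 15 × 10⁶-packet budget (seconds with
  the jitted core);
- the speckle-contrast plateau is probed on a doubling ladder capped at
  30 × 10⁶ packets per A-scan, stopping once successive contrast ratios
  change by < 0.02.  The contrast ratio decreases monotonically toward
  ≈ 0.59 at the cap, consistent with a fully-developed-speckle floor just
  above the Rayleigh-amplitude value 0.52;
- the recovery studies (map + fresh samples) use 10⁵ packets per A-scan
  with the full 165-entry map.  At that budget the speckle is sparser and
  contrast ratios sit well above their converged values, but map and
  samples share the budget, so matching remains consistent; measured mean
  recovery errors are ≈ 0.03 mm⁻¹ in μs and ≈ 0.01 in g over 12 trials.

## Synthetic fixtures and their limits

No public image dataset accompanies the method, so `corneal_io` generates
*synthetic* device-like frames: a simulated envelope ROI is log10
compressed over 2.5 decades, affinely mapped to 8 bits, embedded at its
native 40-column width below a synthetic curved surface (bright 2-px
specular line) in a 733 × 1538 frame with Poisson background noise, with
ground truth in a JSON sidecar.  Surface/apex detection is deliberately
simple — axial smoothing, fixed intensity threshold, apex at the center of
the minimal-surface-row plateau of the central third — and can be bypassed
with an explicit ROI rectangle.

What passing the fixture tests shows: the full experimental pipeline
(8-bit image → ROI → 10^x normalization → matching) is wired correctly,
the display transform is invertible in rank (Spearman ρ > 0.95 at a
developed-speckle budget), and ground-truth parameters are recovered
within the recovery tolerance.  What it does not show: robustness to real
acquisition effects — lateral beam width, corneal curvature, motion,
detector noise spectra, vendor-specific display mappings — none of which
the generator emulates.  A structural caveat inherent to the method's
normalizations: experimental values 10^x are ≥ 1 while simulated
normalized amplitudes are mostly < 1, so the two density distances carry a
support offset for device images; the contrast-ratio distance is immune
(CR is scale-invariant), which is why the ensemble over three distances,
rather than any single density distance, is the estimator.

## Known limitations

- Single flat layer; no epithelium, no corneal curvature, no Gaussian
  beam/lateral resolution, no polarization, no spectral-domain artifacts,
  no shot noise.
- μa is accepted but the study default is 0; with μa > 0 detected weights
  are < 1 and the speckle amplitude distribution changes accordingly.
- The matcher returns grid nodes only; no interpolation between (μs, g)
  grid points.
- The (μs, g) pair is partially confounded along iso-detection-count
  curves (counts rise with μs and fall with g); at sparse budgets the
  density shape carries limited extra information, which bounds recovery
  accuracy at the grid-step scale.
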