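# Methods

## The physical problem

Functional near-infrared spectroscopy (fNIRS) measures attenuation changes
of NIR light between an emitter and a detector placed ~3 cm apart on the
scalp. Neural activity changes the absorption coefficient of gray matter
(via oxy-/deoxyhemoglobin), so the technique is only sensitive to the part
of the detected light that actually traversed gray matter. How much gray
matter that is depends on individual anatomy: the scalp-cortex distance
(SCD), the thickness of the low-scattering CSF layer, air-filled frontal
sinuses, and cortical folding. `nirsim` quantifies these effects with a
voxel Monte Carlo simulation of photon migration through segmented head
volumes, plus the derived sensitivity analyses.

## Transport model

Photon *packages* carry a continuous weight `W` (initialised to 1) and
perform a random walk through a grid of labelled voxels (air, scalp,
skull, CSF, gray, white), launched perpendicular to the scalp under the
emitter. The model follows the standard weighted-photon convention of
layered-tissue Monte Carlo codes:

* **Free paths.** The distance to the next interaction in a medium with
  total interaction coefficient `mu_t = mu_a + mu_s` is exponential:
  `s = -ln(xi)/mu_t`. Heterogeneity is handled by sampling a dimensionless
  optical depth `-ln(xi)` and consuming it voxel by voxel at each voxel's
  own `mu_t`, checking interfaces at every voxel-face crossing. This is
  exact in homogeneous regions and introduces no step truncation. Voxels
  with `mu_t = 0` (air) are crossed in free flight.
* **Absorption.** At each interaction the package deposits
  `dW = W mu_a / mu_t` in the current voxel (albedo weighting) and
  continues with the remainder.
* **Scattering.** The deflection cosine is drawn from the
  Henyey-Greenstein phase function with tissue anisotropy `g` (inverse
  CDF; isotropic for `g = 0`), the azimuth uniformly on [0, 2pi). The
  direction update uses the standard local-frame rotation; for
  near-vertical directions (|e_z| > 0.99999) the vertical special case is
  used, which fixes the azimuth convention: a straight-up photon deflected
  by 90 degrees at phi = 0 continues along +x.
* **Refractive interfaces.** Where the tissue label changes across a
  voxel face *and* the refractive index differs, the local surface normal
  is estimated from the 5x5x5 label neighbourhood (the vector sum of
  offsets pointing into the far tissue; exact for axis-aligned planes,
  about 10 degrees worst-case error on a digitised sphere). The photon is
  reflected specularly with the unpolarised Fresnel probability —
  including total internal reflection — or refracted by Snell's law.
* **Detection.** A photon refracting out through the top (scalp-air)
  surface within the detector radius of the detector position counts as
  *detected*; any other exit escapes. Channel tallies (absorption map,
  tissue energies, partial pathlengths) accumulate **detected photons
  only**, because only light reaching the detector contributes to the
  measurement; per-photon deposits are buffered sparsely until the fate
  is known.
* **Termination.** Below a weight of 1e-4 a package plays Russian
  roulette with survival probability 0.1 (survivors are boosted by 10x,
  keeping the estimator unbiased); a hard cap of 1e6 events per photon
  guards against pathological trajectories. Per-photon weight accounting
  (deposits + exit weight + roulette residual = 1) closes to float
  roundoff and is asserted in the tests.

### Reduced-isotropic mode

Scattering with `g` near 1 is strongly forward-peaked and expensive: most
interactions barely change the direction. The similarity transform
replaces `mu_s` by the reduced coefficient `mu_s' = mu_s (1 - g)` with
isotropic scattering, reproducing the diffuse light distribution with
roughly `1/(1-g)` = 6x fewer interactions for `g = 0.9`. Both modes are
implemented; their detected-photon absorption maps overlap to within the
replicate-to-replicate Monte Carlo noise at equal photon counts (the
suite checks overlap >= 0.8 at scaled counts, where the same-mode
replicate overlap is at the same level). The reduced-isotropic mode is
the default for all studies.

### Optical coefficients

The bundled per-tissue table (mm^-1; dimensionless g, n) is the standard
literature set for adult head tissue at NIR wavelengths (roughly
700-900 nm), treated as wavelength-fixed:

| tissue | mu_a | mu_s | g | n |
|--------|------|------|-----|------|
| air | 0 | 0 | 0 | 1.00 |
| scalp | 0.016 | 19.0 | 0.9 | 1.60 |
| skull | 0.018 | 16.0 | 0.9 | 1.56 |
| CSF | 0.004 | 0.3 | 0 | 1.33 |
| gray | 0.090 | 21.5 | 0.9 | 1.40 |
| white | 0.090 | 38.4 | 0.9 | 1.47 |

## Boundary and aperture choices

* **Detector aperture.** Real fNIRS fibre tips are ~1 mm; simulating that
  aperture faithfully would require ~10^9 launched packages per channel
  for 10^4 detections. The default detector radius is 5 mm — still small
  against the 30 mm separation — which raises the detection rate to
  ~2e-4 and makes desk-scale studies practical. Distance-quantile
  metrics (penetration depths) are insensitive to the aperture at the
  few-percent level; absolute detection rates are not, and should not be
  compared against instrument throughputs.
* **Lateral boundaries.** A channel cube cut from a head is surrounded by
  more tissue, not vacuum. The cube's side and bottom faces therefore
  default to specular ("mirror") boundaries, the image-source
  approximation of laterally extended tissue; fully open (absorbing)
  boundaries are available via `lateral_boundary="open"`.
* **Launch coupling.** The emitter is assumed index-coupled: the package
  starts just inside the scalp voxel under the emitter with no initial
  specular loss.

## Synthetic phantoms

No segmented MRI accompanies this package, so studies run on synthetic
label volumes that emulate the relevant forehead anatomy:

* **Layer slab** — planar scalp/skull/CSF/gray/white layers (defaults
  4/7/2 mm, an adult forehead; gray thickness 5 mm ~ cortical thickness,
  resolvable at 1 mm voxels), 60 mm cube, 1 mm isotropic voxels, scalp
  surface at the z=0 face. Thicknesses are rounded half-up to voxels so
  phantoms are deterministic.
* **Frontal sinus** — an air ellipsoid carved out of the skull layer only.
* **Gyrification** — the CSF-gray boundary displaced column-wise by a 2D
  sinusoid (product of sines, amplitude/wavelength in mm); the gray-white
  offset rides along so cortical thickness is preserved. Folds may rise
  into the CSF but not past its top.

What the phantoms do **not** emulate: curved head surface, continuous
thickness gradients, real sulcal geometry, segmentation noise,
probabilistic tissue maps, vasculature. Passing tests therefore show that
the *transport physics and the derived metrics* behave correctly and
reproduce the direction of anatomy effects on idealised geometry — not
that the package predicts absolute sensitivities for a particular human
head.

## Derived metrics

* **Cumulative absorption profile** `P(r)`: energy-weighted cumulative
  distribution of absorbing-voxel distances to the surface reference
  point midway between the optodes (1 mm bins).
* **Penetration depth**: the (1 - tail) quantile of `P(r)`, linearly
  interpolated between bins; tails 0.05/0.03/0.01 are reported side by
  side. An alternative "mean distance of the most distal tail" reading is
  exposed as `distal_mean_depth`. On the default slab the 0.97-quantile
  radius lands at ~2 cm, the lower edge of the 2-3 cm range generally
  reported for 3 cm optode spacing.
* **SCD and layer thicknesses**: radius around the reference point at
  which the cumulative volume of a tissue first reaches 1 per mille of
  that tissue's volume in the cube (robust to isolated mislabelled
  voxels); skull/CSF/gray surfaces give scalp thickness, scalp+skull and
  SCD; differences give the layer thicknesses. A "mean of the nearest
  per-mille voxels" variant is available (`method="mean"`). On slabs the
  construction is within one voxel of the analytic layer sum.
* **V_GM**: volume of gray-matter voxels with absorbed weight above a
  floor (default 0: any deposit counts) from detected photons — the
  anatomy-dependent sensitivity proxy.
* **Ellipsoid calotte model**: the absorption cloud is modelled as a
  rotational half-ellipsoid with lateral semi-axis `a` (half the optode
  distance, 15 mm) and depth semi-axis `b`; the gray volume it predicts
  is the cap below the SCD,
  `V(scd) = pi a^2 ((2/3) b - scd + scd^3/(3 b^2))` for `0 <= scd <= b`,
  zero beyond. `b` is fitted to observed (SCD, V_GM) pairs by bounded 1-D
  least squares; the closed form is verified against numerical
  integration in the tests.
* **Gyrification estimate**: the Euclidean length of the per-component
  standard deviation of gray-surface unit normals (toward CSF) inside an
  ellipsoid anchored at the reference point (`b` from the channel's own
  profile when transport is run, 20 mm fallback otherwise). Zero for a
  flat cortex, larger for folds.
* **CSF-ratio deviation**: `simulated - analytic V_GM` against
  `d_csf / (d_scalp + d_skull)`, with Pearson correlation; a positive
  correlation means the calotte model underestimates V_GM where the
  light-guiding CSF layer is relatively thick.

## Numerical choices

* Isotropic voxels only; anisotropic NIfTI grids are rejected at load.
* `xi = 0` draws are clamped to avoid `log(0)`.
* Degenerate Henyey-Greenstein (`g = 0`) uses the exact isotropic inverse
  CDF; sampled cosines are clamped to [-1, 1].
* `deposit_weight` recomputes the deposited fraction as the complement of
  the updated weight so conservation is exact in floating point.
* A package whose weight reaches exactly zero (albedo-1 media) terminates
  immediately instead of entering roulette.
* The ellipsoid-calotte fit uses bounded Brent minimisation
  (`xatol = 1e-4` mm) on b in [0.5, 200] mm.
* Point masses in cumulative profiles are resolved to the bin width; the
  profile's last value is pinned to 1 against roundoff.
* Same seed, same mode, same build: bit-identical results
  (single-threaded kernel with one seeded RNG stream per run). No
  cross-implementation reproducibility is promised.

## Problem sizes

Studies are run at desk scale, chosen once as the package's defaults:
200-1200 detected photons per channel for sweeps and suite checks, 4000
for the reproduction script, 1200/800 for the mode-equivalence check.
At these sizes the monotone anatomy effects (Spearman rho = -1.0 across
the scalp sweep), the sinus effect signs, and the penetration-depth
quantiles (stable to a few tenths of a millimetre) are well resolved.

## Known limitations

* Coefficients are wavelength-fixed; no spectra, no time-of-flight, no
  polarisation.
* The detector aperture and mirror boundaries (above) trade absolute
  detection rates for runtime; relative and geometric quantities are the
  intended outputs.
* The gyrification fold is a stationary sinusoid, far milder than real
  sulci; the estimate is a relative index, not a validated gyrification
  index.
* Group-level inferential statistics beyond Pearson/Spearman helpers are
  out of scope.
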