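# nirsim

Voxel-based Monte Carlo simulation of near-infrared photon migration
through segmented head tissue, with the sensitivity analyses used in
optical neuroimaging (fNIRS).

## The problem

fNIRS infers cortical activity from changes in near-infrared light
attenuation between an emitter and a detector ~3 cm apart on the scalp.
Only the light that traversed *gray matter* carries the functional
signal, and how much does depends on the head in front of the optodes:
the scalp–cortex distance (SCD), the low-scattering CSF layer, air-filled
frontal sinuses, cortical folding. `nirsim` is for researchers who want
to quantify these anatomy-driven sensitivity effects by simulation: it
transports weighted photon packages through 3D tissue-label volumes
(NIfTI), tallies where detected light was absorbed, and derives the
standard sensitivity metrics.

## Model

Photon packages with weight `W` random-walk through labelled voxels
(air, scalp, skull, CSF, gray, white matter):

* free paths `s = −ln ξ / μ_t`, consumed voxel-by-voxel through
  heterogeneous tissue;
* absorption by albedo weighting, `ΔW = W μ_a/μ_t` per interaction;
* Henyey–Greenstein scattering with tissue anisotropy `g` (or the
  similarity-transformed isotropic mode at `μ_s′ = μ_s(1−g)`, ~6× faster
  for `g = 0.9`);
* unpolarised Fresnel reflection / Snell refraction at refractive-index
  boundaries, with surface normals estimated from the voxel labels;
* detected-photon-only tallies: a package refracting out of the scalp
  within the detector aperture contributes its absorption history to the
  channel's sensitivity map.

From a channel's map the package computes the cumulative absorption
profile `P(r)` around the surface midpoint, penetration depths (the
`1−tail` quantiles of `P`), the absorbing gray-matter volume `V_GM`, the
SCD (closest per-mille construction), and the rotational-ellipsoid
calotte model `V_GM(SCD) = π a² ((2/3)b − SCD + SCD³/3b²)` with its
least-squares depth parameter `b`. A phantom generator provides layered
forehead slabs with optional frontal-sinus cavities and sinusoidal
gyrification, and a workbench runs the standard sweeps. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from nirsim import (PhantomSpec, make_layer_phantom, OpticalCoefficientSet,
                    run_channel, compute_layer_thicknesses,
                    cumulative_profile, penetration_depth,
                    gray_matter_sensitivity, EllipsoidModel,
                    ellipsoid_calotte_volume)
from nirsim.probe_geometry import reference_point_on_scalp

# adult-forehead slab: scalp 4 mm, skull 7 mm, CSF 2 mm, 1 mm voxels
volume = make_layer_phantom(PhantomSpec())
emitter, detector = np.array([15.0, 30.0, 0.0]), np.array([45.0, 30.0, 0.0])

result = run_channel(volume, OpticalCoefficientSet.default(),
                     emitter, detector, n_detected_target=500, seed=1)
ref = reference_point_on_scalp(volume, emitter, detector)
thick = compute_layer_thicknesses(volume, ref)
summary = gray_matter_sensitivity(result, volume, reference_point=ref)
profile = cumulative_profile(result, ref)
d97 = penetration_depth(profile, 0.03)
```

Output (about a minute on one CPU):

```text
detected 500/2119473 photons (rate 2.4e-04)
SCD = 13.2 mm  (scalp 5.0, skull 6.1, CSF 2.1 mm)
V_GM = 1796 mm^3
energy fractions: scalp 0.48, skull 0.45, CSF 0.007, gray 0.057
97% of detected-photon absorption lies within 19.8 mm of the surface midpoint
calotte-model V_GM at this SCD: 1397 mm^3
```

Reading it: only ~1 in 4000 launched packages reaches the detector 30 mm
away; of the energy those packages deposited, scalp and skull absorb the
overwhelming share (~93%) and gray matter ~6% — which is why superficial
anatomy dominates fNIRS sensitivity. The absorption cloud reaches ~2 cm
from the channel midpoint, and the simulated absorbing gray volume is in
the range the half-ellipsoid cap model predicts from the SCD alone.

## Command line

Every step is also a CLI subcommand:

```sh
nirsim phantom --scalp 4 --skull 7 --csf 2 --out slab.nii.gz
nirsim simulate --volume slab.nii.gz --emitter 15,30,0 --detector 45,30,0 \
    --n-detected 1000 --seed 1 --out channel
nirsim geometry --volume slab.nii.gz --emitter 15,30,0 --detector 45,30,0 \
    --out thickness.csv
nirsim analyze --result channel --volume slab.nii.gz --out-prefix channel
nirsim sweep-scd --out sweep.csv      # and sweep-sinus, sweep-gyri,
nirsim stability --out stab.csv       # stability, mode-equivalence
```

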