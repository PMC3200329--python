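"""Derived fNIRS-sensitivity quantities.

From a channel's detected-photon absorption map this module computes:

* the cumulative absorption profile P(r) — the fraction of absorbed energy
  within radius r of the surface reference point;
* penetration depths — the radius capturing all but a small tail fraction
  of the absorbed energy ("relevant" penetration depth);
* V_GM — the gray-matter volume receiving energy from detected photons,
  the anatomy-dependent sensitivity proxy;
* the rotational-ellipsoid calotte model V_GM(SCD) and the least-squares
  fit of its depth parameter b;
* a gyrification estimate — the length of the per-component standard
  deviation vector of cortical surface normals in an ellipsoid region;
* the CSF-ratio deviation analysis relating the calotte model's error to
  the relative thickness of the low-scattering CSF layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .head_model import TissueLabelVolume
from .optics import CSF, GRAY, TISSUES
from .transport import ChannelResult, estimate_surface_normal

__all__ = [
    "CumulativeProfile",
    "EllipsoidModel",
    "SensitivitySummary",
    "CsfRatioResult",
    "cumulative_profile",
    "penetration_depth",
    "distal_mean_depth",
    "gray_matter_sensitivity",
    "ellipsoid_calotte_volume",
    "fit_depth_parameter",
    "gyrification_estimate",
    "csf_ratio_deviation",
]

#: Tail fractions reported side by side for penetration depths.
TAIL_FRACTIONS = (0.05, 0.03, 0.01)

#: Half the standard 30 mm optode separation, mm.
DEFAULT_A = 15.0


@dataclass
class CumulativeProfile:
    """Energy-weighted cumulative distribution of voxel distances to the
    reference point: ``cumulative_fraction[i]`` is the fraction of total
    absorbed energy within ``radii[i]`` mm."""

    radii: np.ndarray
    cumulative_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.cumulative_fraction = np.asarray(self.cumulative_fraction,
                                              dtype=float)
        if self.radii.shape != self.cumulative_fraction.shape:
            raise ValueError("radii and fractions must have equal length")
        if np.any(np.diff(self.cumulative_fraction) < -1e-12):
            raise ValueError("cumulative fraction must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_mm": self.radii,
                             "cumulative_fraction": self.cumulative_fraction})


@dataclass
class EllipsoidModel:
    """Rotational ellipsoid of NIR-light absorption between the optodes.

    ``a`` is the lateral semi-axis (half the optode distance, default
    15 mm); ``b`` the depth semi-axis, a measure of light penetration.
    """

    a: float = DEFAULT_A
    b: float = 20.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")


@dataclass
class SensitivitySummary:
    """Channel-level sensitivity metrics."""

    v_gm_mm3: float
    tissue_energy_fractions: np.ndarray
    penetration_depths: dict = field(default_factory=dict)
    gyrification: float | None = None


def cumulative_profile(result: ChannelResult, reference_point,
                       bin_width: float = 1.0) -> CumulativeProfile:
    """Cumulative absorbed-energy distribution around the reference point.

    Distances are from each absorbing voxel's centre to the reference
    point; the profile is tabulated on a radius grid of ``bin_width`` mm
    starting at 0 and ends at 1 by construction.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    amap = result.absorption_map
    mask = amap > 0
    if not np.any(mask):
        raise ValueError("absorption map is identically zero")
    idx = np.argwhere(mask)
    weights = amap[mask]
    centers = idx * result.voxel_size + result.origin
    d = np.linalg.norm(centers - np.asarray(reference_point, float), axis=1)
    n_bins = int(math.ceil(d.max() / bin_width)) + 1
    radii = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(d, bins=radii, weights=weights)
    cum = np.concatenate([[0.0], np.cumsum(hist)]) / weights.sum()
    cum[-1] = 1.0  # guard against roundoff in the last bin
    return CumulativeProfile(radii=radii, cumulative_fraction=cum)


def penetration_depth(profile: CumulativeProfile,
                      tail_fraction: float) -> float:
    """Smallest radius beyond which at most ``tail_fraction`` of the
    absorbed energy lies, i.e. the (1 - tail) quantile of P(r).

    Linearly interpolated between profile bins; point masses are resolved
    to the bin resolution.
    """
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must lie in (0, 1)")
    c = profile.cumulative_fraction
    r = profile.radii
    if c.size < 2 or c[-1] <= 0:
        raise ValueError("profile is degenerate")
    target = 1.0 - tail_fraction
    i = int(np.searchsorted(c, target, side="left"))
    if i == 0:
        return float(r[0])
    i = min(i, c.size - 1)
    if c[i] == c[i - 1]:
        return float(r[i])
    frac = (target - c[i - 1]) / (c[i] - c[i - 1])
    return float(r[i - 1] + frac * (r[i] - r[i - 1]))


def distal_mean_depth(result: ChannelResult, reference_point,
                      tail_fraction: float) -> float:
    """Energy-weighted mean distance of the most distal ``tail_fraction``
    of absorbed energy — the alternative reading of a "deepest fraction"
    penetration measure."""
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must lie in (0, 1)")
    amap = result.absorption_map
    mask = amap > 0
    if not np.any(mask):
        raise ValueError("absorption map is identically zero")
    idx = np.argwhere(mask)
    weights = amap[mask]
    centers = idx * result.voxel_size + result.origin
    d = np.linalg.norm(centers - np.asarray(reference_point, float), axis=1)
    order = np.argsort(d)[::-1]  # most distal first
    w_sorted = weights[order]
    cum = np.cumsum(w_sorted)
    target = tail_fraction * weights.sum()
    n_take = int(np.searchsorted(cum, target, side="left")) + 1
    sel = order[:n_take]
    return float(np.average(d[sel], weights=weights[sel]))


def gray_matter_sensitivity(result: ChannelResult,
                            volume: TissueLabelVolume,
                            reference_point=None,
                            tail_fractions=TAIL_FRACTIONS,
                            floor: float = 0.0,
                            bin_width: float = 1.0) -> SensitivitySummary:
    """V_GM, tissue energy fractions and (optionally) penetration depths.

    V_GM is the volume of gray-matter voxels whose absorbed weight exceeds
    ``floor`` (default 0: any deposit counts). Tissue energy fractions are
    normalised by the total energy absorbed from detected photons.
    """
    if result.absorption_map.shape != volume.shape:
        raise ValueError("result and volume grids do not match")
    gray_mask = (volume.labels == GRAY) & (result.absorption_map > floor)
    v_gm = float(np.count_nonzero(gray_mask)) * volume.voxel_size ** 3
    total = result.tissue_energy.sum()
    fractions = (result.tissue_energy / total if total > 0
                 else np.zeros(len(TISSUES)))
    depths = {}
    if reference_point is not None:
        profile = cumulative_profile(result, reference_point, bin_width)
        depths = {tail: penetration_depth(profile, tail)
                  for tail in tail_fractions}
    return SensitivitySummary(v_gm_mm3=v_gm,
                              tissue_energy_fractions=fractions,
                              penetration_depths=depths)


def ellipsoid_calotte_volume(scd: float, model: EllipsoidModel) -> float:
    """Volume of the rotational-ellipsoid calotte deeper than the SCD.

    The absorption ellipsoid has lateral semi-axis ``a`` (both lateral
    directions) and depth semi-axis ``b``, anchored with its equator at
    the scalp surface. Gray matter starts at depth ``scd``, so the
    traversed gray volume is the ellipsoid cap below that depth:

        V(scd) = pi a^2 [ (2/3) b - scd + scd^3 / (3 b^2) ],  0 <= scd <= b

    which is (2/3) pi a^2 b (the half ellipsoid) at scd = 0 and 0 for
    scd >= b.
    """
    if scd < 0:
        raise ValueError("scd must be nonnegative")
    a, b = model.a, model.b
    if scd >= b:
        return 0.0
    return math.pi * a * a * (2.0 * b / 3.0 - scd + scd ** 3 / (3.0 * b * b))


def fit_depth_parameter(pairs, a: float = DEFAULT_A,
                        b_bounds: tuple[float, float] = (0.5, 200.0)) -> float:
    """Least-squares fit of the calotte depth parameter b to observed
    (SCD, V_GM) pairs, by bounded 1-D minimisation.

    Requires at least two pairs with distinct SCD values.
    """
    pairs = [(float(s), float(v)) for s, v in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least two (scd, v_gm) pairs")
    scds = np.array([p[0] for p in pairs])
    vgms = np.array([p[1] for p in pairs])
    if np.allclose(scds, scds[0]):
        raise ValueError("all SCD values identical; depth parameter is "
                         "unidentifiable")

    def sse(b: float) -> float:
        model = EllipsoidModel(a=a, b=b)
        pred = np.array([ellipsoid_calotte_volume(s, model) for s in scds])
        return float(np.sum((pred - vgms) ** 2))

    res = optimize.minimize_scalar(sse, bounds=b_bounds, method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x)


def gyrification_estimate(volume: TissueLabelVolume, reference_point,
                          model: EllipsoidModel) -> float:
    """Magnitude of cortical folding within the channel's ellipsoid.

    Collects the unit normals of the gray-matter boundary to CSF inside
    the ellipsoid (semi-axes ``a`` lateral, ``b`` in depth, anchored at
    the reference point on the surface) and returns the Euclidean length
    of the vector of per-component standard deviations: 0 for a flat
    boundary, larger for folded cortex.
    """
    ref = np.asarray(reference_point, dtype=float)
    labels = volume.labels
    nx, ny, nz = labels.shape
    gray_idx = np.argwhere(labels == GRAY)
    if gray_idx.size == 0:
        raise ValueError("volume contains no gray matter")
    centers = volume.voxel_centers_mm(gray_idx)
    rel = centers - ref
    inside = ((rel[:, 0] ** 2 + rel[:, 1] ** 2) / model.a ** 2
              + rel[:, 2] ** 2 / model.b ** 2) <= 1.0
    normals = []
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 1], [0, 0, -1]])
    for ijk in gray_idx[inside]:
        nb = ijk + offsets
        ok = np.all((nb >= 0) & (nb < [nx, ny, nz]), axis=1)
        if not np.any(labels[nb[ok, 0], nb[ok, 1], nb[ok, 2]] == CSF):
            continue
        normals.append(estimate_surface_normal(volume, ijk, other_label=CSF))
    if not normals:
        raise ValueError("no gray-surface voxels bordering CSF inside the "
                         "ellipsoid region")
    normals = np.asarray(normals)
    return float(np.linalg.norm(normals.std(axis=0, ddof=0)))


@dataclass
class CsfRatioResult:
    """Per-channel calotte-model deviation vs relative CSF thickness."""

    deviation: np.ndarray  # simulated - analytic V_GM, mm^3
    csf_ratio: np.ndarray  # d_csf / (d_scalp + d_skull)
    pearson_r: float
    pearson_p: float
    correlation_defined: bool


def csf_ratio_deviation(simulated_v_gm, analytic_v_gm,
                        thicknesses) -> CsfRatioResult:
    """Deviation of simulated from analytic V_GM against the CSF ratio.

    A positive correlation indicates the simple calotte model
    underestimates V_GM where the low-scattering CSF layer is thick
    relative to the superficial scalp+skull layer. ``thicknesses`` is a
    sequence of :class:`~nirsim.probe_geometry.LayerThicknesses`.
    """
    sim = np.asarray(simulated_v_gm, dtype=float)
    ana = np.asarray(analytic_v_gm, dtype=float)
    if sim.shape != ana.shape or len(sim) != len(thicknesses):
        raise ValueError("simulated, analytic and thickness records must "
                         "be matched")
    ratios = []
    for t in thicknesses:
        superficial = t.d_scalp + t.d_skull
        if superficial <= 0:
            raise ValueError("zero superficial (scalp+skull) thickness")
        ratios.append(t.d_csf / superficial)
    ratios = np.array(ratios)
    deviation = sim - ana
    if np.allclose(ratios, ratios[0]) or np.allclose(deviation, deviation[0]):
        return CsfRatioResult(deviation, ratios, math.nan, math.nan, False)
    r, p = stats.pearsonr(deviation, ratios)
    return CsfRatioResult(deviation, ratios, float(r), float(p), True)
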