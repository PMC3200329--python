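"""Voxelised Monte Carlo photon transport.

Photon packages carry a continuous weight, start at the emitter travelling
perpendicular to the scalp surface (the ``z = 0`` face of the grid), and
alternate exponentially sampled free paths with interaction events. At each
interaction a fraction ``mu_a / mu_t`` of the weight is deposited in the
current voxel and the package is scattered into a new direction
(Henyey-Greenstein for anisotropic tissue, isotropic for ``g = 0``). The
free path is sampled as a dimensionless optical depth ``-ln(xi)`` consumed
voxel by voxel at each voxel's own ``mu_t``, which is exact in homogeneous
regions and handles tissue heterogeneity without step truncation.

At voxel-face crossings where the refractive index changes, the local
surface normal is estimated from the surrounding label neighbourhood and the
photon is specularly reflected with the unpolarised Fresnel probability
(including total internal reflection) or refracted by Snell's law.

A photon refracting out through the top surface within the detector radius
of the detector position is *detected*; any other exit is an *escape*.
Photon weight is terminated by Russian roulette below a weight threshold
(unbiased: survivors are boosted by the inverse survival probability) or by
a hard event cap. Absorption maps accumulate deposits of detected photons
only, so the map is the channel's sensitivity volume.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .head_model import TissueLabelVolume
from .optics import AIR, GRAY, TISSUES, OpticalCoefficientSet

__all__ = [
    "PhotonState",
    "PhotonOutcome",
    "ChannelResult",
    "estimate_surface_normal",
    "propagate_photon",
    "run_channel",
    "absorption_overlap",
    "ZeroDetectionError",
]

#: Default termination parameters: roulette below this weight with 10%
#: survival, and a hard cap on events per photon.
WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
MAX_EVENTS = 1_000_000

#: Default detector aperture radius in mm. Chosen large enough (still small
#: against the 30 mm optode separation) for desk-scale detection statistics.
DETECTOR_RADIUS = 5.0

_STATUS = ("detected", "escaped", "terminated")

log = logging.getLogger(__name__)


class ZeroDetectionError(RuntimeError):
    """No photon reached the detector within the launch budget."""


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _boundary_normal(labels, i, j, k, other_lab, fx, fy, fz):
    """Unit normal at the face of voxel (i,j,k), pointing toward the tissue
    ``other_lab``, estimated from the 5x5x5 label neighbourhood (exact for
    axis-aligned planes, ~10 deg worst case on a digitised sphere); falls
    back to the face normal (fx, fy, fz) when the neighbourhood is
    degenerate."""
    nx, ny, nz = labels.shape
    mx = 0.0
    my = 0.0
    mz = 0.0
    for di in range(-2, 3):
        ii = i + di
        if ii < 0 or ii >= nx:
            continue
        for dj in range(-2, 3):
            jj = j + dj
            if jj < 0 or jj >= ny:
                continue
            for dk in range(-2, 3):
                kk = k + dk
                if kk < 0 or kk >= nz:
                    continue
                if labels[ii, jj, kk] == other_lab:
                    mx += di
                    my += dj
                    mz += dk
    norm = math.sqrt(mx * mx + my * my + mz * mz)
    if norm < 1e-12:
        return fx, fy, fz
    return mx / norm, my / norm, mz / norm


@njit(cache=True, fastmath=True)
def _fresnel_ci(n1, n2, ci):
    """Unpolarised Fresnel reflectance from the incidence cosine."""
    if n1 == n2:
        return 0.0
    si2 = 1.0 - ci * ci
    if si2 < 0.0:
        si2 = 0.0
    st2 = (n1 / n2) * (n1 / n2) * si2
    if st2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _rotate(dx, dy, dz, ct, phi):
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(dz) > 0.99999:
        sign = 1.0 if dz > 0.0 else -1.0
        ox = st * cp
        oy = st * sp
        oz = ct * sign
    else:
        denom = math.sqrt(1.0 - dz * dz)
        ox = st * (dx * dz * cp - dy * sp) / denom + dx * ct
        oy = st * (dy * dz * cp + dx * sp) / denom + dy * ct
        oz = -st * cp * denom + dz * ct
    norm = math.sqrt(ox * ox + oy * oy + oz * oz)
    return ox / norm, oy / norm, oz / norm


@njit(cache=True, fastmath=True)
def _trace(labels, voxel, mu_a, mu_t, g_arr, n_arr,
           px, py, pz, det_x, det_y, det_r2,
           w_thresh, r_surv, max_events, mirror_sides,
           dep_idx, dep_w, path_t):
    """Trace one photon package from the given launch position.

    Returns (status, n_deposits, exit weight, roulette residual, exit
    position xyz, exit direction xyz, n_events). The identity
    ``sum(deposits) + exit_weight + residual == 1`` holds exactly.
    """
    nx, ny, nz = labels.shape
    for t in range(6):
        path_t[t] = 0.0
    dx = 0.0
    dy = 0.0
    dz = 1.0
    w = 1.0
    resid = 0.0
    ndep = 0
    events = 0
    i = min(max(int(px / voxel), 0), nx - 1)
    j = min(max(int(py / voxel), 0), ny - 1)
    k = min(max(int(pz / voxel), 0), nz - 1)
    xi = np.random.random()
    if xi <= 0.0:
        xi = 1e-300
    tau = -math.log(xi)
    status = 1
    exw = 0.0
    # inverse direction components, refreshed whenever the direction changes
    ivx = 1.0 / dx if abs(dx) > 1e-12 else 0.0
    ivy = 1.0 / dy if abs(dy) > 1e-12 else 0.0
    ivz = 1.0 / dz if abs(dz) > 1e-12 else 0.0
    while True:
        lab = labels[i, j, k]
        mt = mu_t[lab]
        # distance to the voxel faces along the current direction
        if dx > 1e-12:
            sx = ((i + 1) * voxel - px) * ivx
        elif dx < -1e-12:
            sx = (i * voxel - px) * ivx
        else:
            sx = 1e30
        if dy > 1e-12:
            sy = ((j + 1) * voxel - py) * ivy
        elif dy < -1e-12:
            sy = (j * voxel - py) * ivy
        else:
            sy = 1e30
        if dz > 1e-12:
            sz = ((k + 1) * voxel - pz) * ivz
        elif dz < -1e-12:
            sz = (k * voxel - pz) * ivz
        else:
            sz = 1e30
        s_face = sx
        axis = 0
        if sy < s_face:
            s_face = sy
            axis = 1
        if sz < s_face:
            s_face = sz
            axis = 2
        if s_face < 0.0:
            s_face = 0.0
        if mt > 0.0 and tau <= s_face * mt:
            # interaction inside this voxel
            s = tau / mt
            px += dx * s
            py += dy * s
            pz += dz * s
            path_t[lab] += s
            dw = w * mu_a[lab] / mt
            if dw > 0.0 and ndep < max_events:
                w -= dw
                dep_idx[ndep] = (i * ny + j) * nz + k
                dep_w[ndep] = dw
                ndep += 1
            events += 1
            if events >= max_events:
                status = 2
                resid += w
                w = 0.0
                break
            if w <= 0.0:
                # fully absorbed (albedo-1 media deposit all weight at once)
                status = 2
                break
            if w < w_thresh:
                if np.random.random() < r_surv:
                    resid += w - w / r_surv
                    w = w / r_surv
                else:
                    resid += w
                    w = 0.0
                    status = 2
                    break
            gg = g_arr[lab]
            xi = np.random.random()
            if gg > 0.0:
                frac = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * xi)
                ct = (1.0 + gg * gg - frac * frac) / (2.0 * gg)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            else:
                ct = 2.0 * xi - 1.0
            phi = 2.0 * math.pi * np.random.random()
            dx, dy, dz = _rotate(dx, dy, dz, ct, phi)
            ivx = 1.0 / dx if abs(dx) > 1e-12 else 0.0
            ivy = 1.0 / dy if abs(dy) > 1e-12 else 0.0
            ivz = 1.0 / dz if abs(dz) > 1e-12 else 0.0
            xi = np.random.random()
            if xi <= 0.0:
                xi = 1e-300
            tau = -math.log(xi)
        else:
            # advance to the nearest voxel face
            px += dx * s_face
            py += dy * s_face
            pz += dz * s_face
            path_t[lab] += s_face
            tau -= s_face * mt
            events += 1
            if events >= max_events:
                status = 2
                resid += w
                w = 0.0
                break
            ni = i
            nj = j
            nk = k
            fx = 0.0
            fy = 0.0
            fz = 0.0
            if axis == 0:
                if dx > 0.0:
                    ni += 1
                    fx = 1.0
                else:
                    ni -= 1
                    fx = -1.0
            elif axis == 1:
                if dy > 0.0:
                    nj += 1
                    fy = 1.0
                else:
                    nj -= 1
                    fy = -1.0
            else:
                if dz > 0.0:
                    nk += 1
                    fz = 1.0
                else:
                    nk -= 1
                    fz = -1.0
            if nk < 0:
                # top surface: interface with exterior air
                n1 = n_arr[lab]
                ci = -dz
                R = _fresnel_ci(n1, 1.0, ci)
                if np.random.random() < R:
                    dz = -dz
                    ivz = -ivz
                else:
                    r = n1
                    st2 = r * r * (1.0 - ci * ci)
                    ct2 = math.sqrt(max(0.0, 1.0 - st2))
                    dx = r * dx
                    dy = r * dy
                    dz = -ct2
                    norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                    dx /= norm
                    dy /= norm
                    dz /= norm
                    ddx = px - det_x
                    ddy = py - det_y
                    if ddx * ddx + ddy * ddy <= det_r2:
                        status = 0
                    else:
                        status = 1
                    exw = w
                    break
            elif ni < 0 or ni >= nx or nj < 0 or nj >= ny or nk >= nz:
                if mirror_sides:
                    # specular image boundary: approximates tissue extending
                    # laterally (and below) beyond the channel cube
                    if axis == 0:
                        dx = -dx
                        ivx = -ivx
                    elif axis == 1:
                        dy = -dy
                        ivy = -ivy
                    else:
                        dz = -dz
                        ivz = -ivz
                else:
                    # open boundary: photon leaves the cube
                    status = 1
                    exw = w
                    break
            else:
                nlab = labels[ni, nj, nk]
                if nlab != lab and n_arr[nlab] != n_arr[lab]:
                    mx, my, mz = _boundary_normal(labels, i, j, k, nlab,
                                                  fx, fy, fz)
                    ci = dx * mx + dy * my + dz * mz
                    if ci <= 1e-9:
                        mx = fx
                        my = fy
                        mz = fz
                        ci = dx * mx + dy * my + dz * mz
                    R = _fresnel_ci(n_arr[lab], n_arr[nlab], ci)
                    if np.random.random() < R:
                        dx -= 2.0 * ci * mx
                        dy -= 2.0 * ci * my
                        dz -= 2.0 * ci * mz
                        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                        dx /= norm
                        dy /= norm
                        dz /= norm
                        ivx = 1.0 / dx if abs(dx) > 1e-12 else 0.0
                        ivy = 1.0 / dy if abs(dy) > 1e-12 else 0.0
                        ivz = 1.0 / dz if abs(dz) > 1e-12 else 0.0
                    else:
                        r = n_arr[lab] / n_arr[nlab]
                        st2 = r * r * (1.0 - ci * ci)
                        ct2 = math.sqrt(max(0.0, 1.0 - st2))
                        c = ct2 - r * ci
                        dx = r * dx + c * mx
                        dy = r * dy + c * my
                        dz = r * dz + c * mz
                        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                        dx /= norm
                        dy /= norm
                        dz /= norm
                        ivx = 1.0 / dx if abs(dx) > 1e-12 else 0.0
                        ivy = 1.0 / dy if abs(dy) > 1e-12 else 0.0
                        ivz = 1.0 / dz if abs(dz) > 1e-12 else 0.0
                        i = ni
                        j = nj
                        k = nk
                else:
                    i = ni
                    j = nj
                    k = nk
    return status, ndep, exw, resid, px, py, pz, dx, dy, dz, events


@njit(cache=True, fastmath=True)
def _run_channel_kernel(labels, voxel, mu_a, mu_t, g_arr, n_arr,
                        ex, ey, ez, det_x, det_y, det_r2,
                        n_target, max_launch, seed,
                        w_thresh, r_surv, max_events, mirror_sides):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    flat = labels.reshape(nx * ny * nz)
    amap = np.zeros(nx * ny * nz)
    tissue_energy = np.zeros(6)
    path_sum = np.zeros(6)
    gm_paths = np.zeros(n_target)
    total_paths = np.zeros(n_target)
    dep_idx = np.empty(max_events, np.int64)
    dep_w = np.empty(max_events)
    path_t = np.zeros(6)
    n_det = 0
    n_launch = 0
    dep_all = 0.0
    escaped_w = 0.0
    detected_w = 0.0
    resid_all = 0.0
    total_events = 0
    while n_det < n_target and n_launch < max_launch:
        n_launch += 1
        status, ndep, exw, resid, _, _, _, _, _, _, ev = _trace(
            labels, voxel, mu_a, mu_t, g_arr, n_arr,
            ex, ey, ez, det_x, det_y, det_r2,
            w_thresh, r_surv, max_events, mirror_sides,
            dep_idx, dep_w, path_t)
        resid_all += resid
        total_events += ev
        for t in range(ndep):
            dep_all += dep_w[t]
        if status == 0:
            detected_w += exw
            for t in range(ndep):
                amap[dep_idx[t]] += dep_w[t]
                tissue_energy[flat[dep_idx[t]]] += dep_w[t]
            for t in range(6):
                path_sum[t] += path_t[t]
            gm_paths[n_det] = path_t[4]
            total_paths[n_det] = (path_t[0] + path_t[1] + path_t[2]
                                  + path_t[3] + path_t[4] + path_t[5])
            n_det += 1
        elif status == 1:
            escaped_w += exw
    return (amap, tissue_energy, path_sum, gm_paths, total_paths, n_det,
            n_launch, dep_all, escaped_w, detected_w, resid_all,
            total_events)


# ---------------------------------------------------------------------------
# Python-facing API
# ---------------------------------------------------------------------------


@dataclass
class PhotonState:
    """Position (mm), unit direction and weight of one photon package."""

    r: np.ndarray
    e: np.ndarray
    W: float = 1.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        norm = np.linalg.norm(self.e)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 <= self.W <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass
class PhotonOutcome:
    """Fate of a single photon package."""

    status: str
    deposits: list  # [(voxel index triple, delta_w), ...]
    partial_pathlengths: np.ndarray  # per tissue, mm
    exit_weight: float
    roulette_residual: float
    exit_position: np.ndarray | None = None
    exit_direction: np.ndarray | None = None
    n_events: int = 0

    @property
    def weight_balance(self) -> float:
        """sum(deposits) + exit weight + roulette residual; equals the
        launched weight (1) up to float roundoff."""
        return (sum(dw for _, dw in self.deposits)
                + self.exit_weight + self.roulette_residual)


@dataclass
class ChannelResult:
    """Tallies of one emitter-detector channel simulation."""

    absorption_map: np.ndarray  # detected-photon deposits per voxel
    tissue_energy: np.ndarray  # per-tissue absorbed weight (detected only)
    tissue_voxel_counts: np.ndarray  # voxels per tissue with any absorption
    tissue_pathlengths: np.ndarray  # summed partial pathlengths, detected
    gm_pathlengths: np.ndarray  # per-detected-photon gray-matter path, mm
    total_pathlengths: np.ndarray  # per-detected-photon total path, mm
    n_launched: int
    n_detected: int
    seed: int
    mode: str
    emitter: np.ndarray
    detector: np.ndarray
    detector_radius: float
    voxel_size: float
    origin: np.ndarray
    total_deposited: float = 0.0  # all photons, not just detected
    escaped_weight: float = 0.0
    detected_weight: float = 0.0
    roulette_residual: float = 0.0
    total_events: int = 0

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_launched if self.n_launched else 0.0

    @property
    def energy_balance(self) -> float:
        """Launched weight accounted for per launched photon (should be 1)."""
        if not self.n_launched:
            return 0.0
        return (self.total_deposited + self.escaped_weight
                + self.detected_weight + self.roulette_residual) / self.n_launched

    def mean_partial_pathlengths(self) -> np.ndarray:
        """Mean per-tissue pathlength of detected photons, mm."""
        if self.n_detected == 0:
            return np.zeros(len(TISSUES))
        return self.tissue_pathlengths / self.n_detected

    def save(self, stem: str | Path) -> None:
        """Write the absorption map as NIfTI plus a JSON tally sidecar."""
        import nibabel as nib

        stem = Path(stem)
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.absorption_map.astype(np.float32),
                                 affine), str(stem.with_suffix(".nii.gz")))
        meta = {
            "tissue_energy": self.tissue_energy.tolist(),
            "tissue_voxel_counts": self.tissue_voxel_counts.tolist(),
            "tissue_pathlengths": self.tissue_pathlengths.tolist(),
            "gm_pathlengths": self.gm_pathlengths.tolist(),
            "total_pathlengths": self.total_pathlengths.tolist(),
            "n_launched": int(self.n_launched),
            "n_detected": int(self.n_detected),
            "seed": int(self.seed),
            "mode": self.mode,
            "emitter": self.emitter.tolist(),
            "detector": self.detector.tolist(),
            "detector_radius": self.detector_radius,
            "voxel_size": self.voxel_size,
            "origin": self.origin.tolist(),
            "total_deposited": self.total_deposited,
            "escaped_weight": self.escaped_weight,
            "detected_weight": self.detected_weight,
            "roulette_residual": self.roulette_residual,
            "total_events": int(self.total_events),
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "ChannelResult":
        """Read a result written by :meth:`save`."""
        import nibabel as nib

        stem = Path(stem)
        img = nib.load(str(stem.with_suffix(".nii.gz")))
        meta = json.loads(stem.with_suffix(".json").read_text())
        return cls(
            absorption_map=np.asanyarray(img.dataobj).astype(float),
            tissue_energy=np.array(meta["tissue_energy"]),
            tissue_voxel_counts=np.array(meta["tissue_voxel_counts"],
                                         dtype=np.int64),
            tissue_pathlengths=np.array(meta["tissue_pathlengths"]),
            gm_pathlengths=np.array(meta["gm_pathlengths"]),
            total_pathlengths=np.array(meta["total_pathlengths"]),
            n_launched=meta["n_launched"],
            n_detected=meta["n_detected"],
            seed=meta["seed"],
            mode=meta["mode"],
            emitter=np.array(meta["emitter"]),
            detector=np.array(meta["detector"]),
            detector_radius=meta["detector_radius"],
            voxel_size=meta["voxel_size"],
            origin=np.array(meta["origin"]),
            total_deposited=meta["total_deposited"],
            escaped_weight=meta["escaped_weight"],
            detected_weight=meta["detected_weight"],
            roulette_residual=meta["roulette_residual"],
            total_events=meta["total_events"],
        )


def _mirror_flag(lateral_boundary: str) -> bool:
    if lateral_boundary not in ("open", "mirror"):
        raise ValueError("lateral_boundary must be 'open' or 'mirror'")
    return lateral_boundary == "mirror"


def _coef_arrays(coefficients: OpticalCoefficientSet, mode: str):
    if mode == "reduced-isotropic":
        coefficients = coefficients.reduced()
    elif mode != "anisotropic":
        raise ValueError("mode must be 'reduced-isotropic' or 'anisotropic'")
    return (coefficients.mu_a, coefficients.mu_t, coefficients.g,
            coefficients.n)


def _local_frame(volume: TissueLabelVolume):
    """Corner of voxel (0,0,0) in world mm; kernel positions are relative
    to it so voxel index = floor(p / voxel)."""
    return volume.origin - volume.voxel_size / 2.0


def _check_emitter(volume: TissueLabelVolume, emitter_local: np.ndarray) -> None:
    nx, ny, nz = volume.shape
    i = int(emitter_local[0] // volume.voxel_size)
    j = int(emitter_local[1] // volume.voxel_size)
    if not (0 <= i < nx and 0 <= j < ny):
        raise ValueError("emitter lies outside the volume")
    if abs(emitter_local[2]) > volume.voxel_size:
        raise ValueError("emitter must sit on the scalp (z = 0) surface")
    if volume.labels[i, j, 0] == AIR:
        raise ValueError("emitter is not adjacent to an air/scalp interface")


def estimate_surface_normal(volume: TissueLabelVolume, boundary_voxel,
                            other_label: int | None = None) -> np.ndarray:
    """Unit normal of the local tissue interface at ``boundary_voxel``.

    The normal is estimated from the 5x5x5 label neighbourhood and points
    from the voxel's own tissue toward ``other_label`` (inferred as the most
    common differing neighbour label when omitted). Raises when the voxel
    has no neighbours of another tissue.
    """
    i, j, k = (int(v) for v in boundary_voxel)
    labels = volume.labels
    own = labels[i, j, k]
    if other_label is None:
        counts = np.zeros(len(TISSUES), dtype=int)
        nx, ny, nz = labels.shape
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                        lab = labels[ii, jj, kk]
                        if lab != own:
                            counts[lab] += 1
        if counts.sum() == 0:
            raise ValueError("voxel has no neighbours of a different tissue")
        other_label = int(np.argmax(counts))
    mx, my, mz = _boundary_normal(labels, i, j, k, other_label, 0.0, 0.0, 0.0)
    norm = math.sqrt(mx * mx + my * my + mz * mz)
    if norm < 1e-12:
        raise ValueError("no surface neighbours of the requested tissue")
    return np.array([mx, my, mz]) / norm


def propagate_photon(volume: TissueLabelVolume,
                     coefficients: OpticalCoefficientSet,
                     emitter,
                     rng: int | np.random.Generator = 0,
                     detector=None,
                     detector_radius: float = DETECTOR_RADIUS,
                     mode: str = "anisotropic",
                     weight_threshold: float = WEIGHT_THRESHOLD,
                     roulette_survival: float = ROULETTE_SURVIVAL,
                     max_events: int = MAX_EVENTS,
                     lateral_boundary: str = "open") -> PhotonOutcome:
    """Trace a single photon package and report its full fate.

    ``rng`` is an integer seed or a numpy Generator (used to derive one).
    Without a ``detector`` any top-surface exit is classified as escaped.
    """
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2 ** 31 - 1))
    else:
        seed = int(rng)
    mu_a, mu_t, g_arr, n_arr = _coef_arrays(coefficients, mode)
    corner = _local_frame(volume)
    e_loc = np.asarray(emitter, dtype=float) - corner
    _check_emitter(volume, e_loc)
    if detector is None:
        det_x, det_y, det_r2 = -1e9, -1e9, 0.0
    else:
        d_loc = np.asarray(detector, dtype=float) - corner
        det_x, det_y, det_r2 = d_loc[0], d_loc[1], detector_radius ** 2
    dep_idx = np.empty(max_events, np.int64)
    dep_w = np.empty(max_events)
    path_t = np.zeros(6)
    _seed_kernel(seed)
    (status, ndep, exw, resid, px, py, pz,
     dx, dy, dz, ev) = _trace(volume.labels, volume.voxel_size,
                              mu_a, mu_t, g_arr, n_arr,
                              e_loc[0], e_loc[1], max(e_loc[2], 1e-9),
                              det_x, det_y, det_r2,
                              weight_threshold, roulette_survival,
                              max_events, _mirror_flag(lateral_boundary),
                              dep_idx, dep_w, path_t)
    ny_, nz_ = volume.shape[1], volume.shape[2]
    deposits = []
    for t in range(ndep):
        idx = dep_idx[t]
        k = idx % nz_
        j = (idx // nz_) % ny_
        i = idx // (nz_ * ny_)
        deposits.append(((int(i), int(j), int(k)), float(dep_w[t])))
    exit_pos = np.array([px, py, pz]) + corner
    return PhotonOutcome(
        status=_STATUS[status],
        deposits=deposits,
        partial_pathlengths=path_t.copy(),
        exit_weight=float(exw),
        roulette_residual=float(resid),
        exit_position=exit_pos if status != 2 else None,
        exit_direction=np.array([dx, dy, dz]) if status != 2 else None,
        n_events=int(ev),
    )


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


def run_channel(volume: TissueLabelVolume,
                coefficients: OpticalCoefficientSet,
                emitter,
                detector,
                detector_radius: float = DETECTOR_RADIUS,
                n_detected_target: int = 1000,
                seed: int = 0,
                mode: str = "reduced-isotropic",
                max_launch: int | None = None,
                weight_threshold: float = WEIGHT_THRESHOLD,
                roulette_survival: float = ROULETTE_SURVIVAL,
                max_events: int = MAX_EVENTS,
                lateral_boundary: str = "mirror") -> ChannelResult:
    """Simulate one emitter-detector channel until ``n_detected_target``
    photons have been detected (or the launch budget runs out).

    The absorption map accumulates the voxel-wise deposits of detected
    photons only. ``mode`` selects anisotropic scattering at ``mu_s`` or
    the ~6x faster isotropic scattering at the reduced ``mu_s'``.
    """
    emitter = np.asarray(emitter, dtype=float)
    detector = np.asarray(detector, dtype=float)
    if np.linalg.norm(detector - emitter) <= 0:
        raise ValueError("emitter and detector must be separated")
    mu_a, mu_t, g_arr, n_arr = _coef_arrays(coefficients, mode)
    corner = _local_frame(volume)
    e_loc = emitter - corner
    d_loc = detector - corner
    _check_emitter(volume, e_loc)
    _check_emitter(volume, d_loc)
    if max_launch is None:
        max_launch = max(1_000_000, 20_000 * n_detected_target)
    (amap, tissue_energy, path_sum, gm_paths, total_paths, n_det,
     n_launch, dep_all, escaped_w, detected_w, resid_all, total_events) = \
        _run_channel_kernel(volume.labels, volume.voxel_size,
                            mu_a, mu_t, g_arr, n_arr,
                            e_loc[0], e_loc[1], 1e-9,
                            d_loc[0], d_loc[1], detector_radius ** 2,
                            n_detected_target, max_launch, seed,
                            weight_threshold, roulette_survival, max_events,
                            _mirror_flag(lateral_boundary))
    log.info("channel %s: launched %d, detected %d (rate %.3e), "
             "%d events", mode, n_launch, n_det,
             n_det / n_launch if n_launch else 0.0, total_events)
    if n_det == 0:
        raise ZeroDetectionError(
            f"0/{n_launch} photons detected within the launch budget; "
            f"check optode placement (separation "
            f"{np.linalg.norm(detector - emitter):.1f} mm) and detector "
            f"radius ({detector_radius} mm)")
    amap3 = amap.reshape(volume.shape)
    counts = np.zeros(len(TISSUES), dtype=np.int64)
    nonzero = amap3 > 0
    for lab in range(len(TISSUES)):
        counts[lab] = int(np.count_nonzero(nonzero & (volume.labels == lab)))
    return ChannelResult(
        absorption_map=amap3,
        tissue_energy=tissue_energy,
        tissue_voxel_counts=counts,
        tissue_pathlengths=path_sum,
        gm_pathlengths=gm_paths[:n_det],
        total_pathlengths=total_paths[:n_det],
        n_launched=int(n_launch),
        n_detected=int(n_det),
        seed=int(seed),
        mode=mode,
        emitter=emitter,
        detector=detector,
        detector_radius=float(detector_radius),
        voxel_size=volume.voxel_size,
        origin=volume.origin.copy(),
        total_deposited=float(dep_all),
        escaped_weight=float(escaped_w),
        detected_weight=float(detected_w),
        roulette_residual=float(resid_all),
        total_events=int(total_events),
    )


def absorption_overlap(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Overlap of two absorption maps normalised to unit sum.

    ``sum_v min(A_v, B_v)`` after normalisation: 1 for identical maps, 0
    for disjoint supports.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("absorption maps must have positive total")
    return float(np.minimum(a / sa, b / sb).sum())
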