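"""Synthetic segmented head phantoms.

Real fNIRS sensitivity studies run photon transport on tissue label volumes
segmented from structural MRI. This module synthesises comparable label
volumes directly: stacked planar layers (scalp, skull, CSF, gray, white)
emulating an adult forehead, optionally with an air-filled frontal-sinus
cavity carved out of the skull and a sinusoidally folded cortical surface
standing in for gyrification.

Grid conventions: isotropic voxels; the third array axis is depth, with the
scalp surface at index 0 (the plane ``z = 0`` in world mm borders exterior
air). ``origin`` is the world coordinate of the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .optics import AIR, CSF, GRAY, SCALP, SKULL, TISSUES, WHITE

__all__ = [
    "TissueLabelVolume",
    "PhantomSpec",
    "make_layer_phantom",
    "add_frontal_sinus",
    "add_gyrification",
    "read_volume",
    "write_volume",
]

_VALID_LABELS = frozenset(range(len(TISSUES)))


@dataclass
class TissueLabelVolume:
    """3D grid of tissue labels with isotropic voxel geometry.

    ``labels`` holds one integer label per voxel (0=air .. 5=white matter);
    ``voxel_size`` is the edge length in mm; ``origin`` the world-mm
    coordinate of the centre of voxel (0, 0, 0).
    """

    labels: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        bad = set(np.unique(self.labels)) - _VALID_LABELS
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.labels = self.labels.astype(np.uint8)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """World-mm centres for an (N, 3) array of voxel indices."""
        return np.asarray(indices, dtype=float) * self.voxel_size + self.origin

    def mm_to_index(self, xyz) -> np.ndarray:
        """Voxel index containing a world-mm point."""
        return np.floor((np.asarray(xyz, float) - self.origin)
                        / self.voxel_size + 0.5).astype(int)

    def tissue_volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_size ** 3

    def copy(self) -> "TissueLabelVolume":
        return TissueLabelVolume(self.labels.copy(), self.voxel_size,
                                 self.origin.copy())


@dataclass
class PhantomSpec:
    """Parameters of a layered forehead phantom.

    Layer thicknesses are in mm and are rounded half-up to whole voxels at
    construction time so phantoms are deterministic. Gray matter occupies
    ``d_gray`` mm below the CSF, white matter the remainder of the cube.
    """

    cube_edge: float = 60.0
    voxel_size: float = 1.0
    d_scalp: float = 4.0
    d_skull: float = 7.0
    d_csf: float = 2.0
    d_gray: float = 5.0
    sinus_center: tuple[float, float, float] | None = None
    sinus_semi_axes: tuple[float, float, float] | None = None
    gyrification_amplitude: float = 0.0
    gyrification_wavelength: float = 0.0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.cube_edge < self.voxel_size:
            raise ValueError("need voxel_size > 0 and cube_edge >= voxel_size")
        for name in ("d_scalp", "d_skull", "d_csf", "d_gray"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.d_scalp + self.d_skull + self.d_csf >= self.cube_edge:
            raise ValueError("superficial layers exceed the cube depth")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        data = json.loads(text)
        for key in ("sinus_center", "sinus_semi_axes"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _round_voxels(thickness_mm: float, voxel: float) -> int:
    """Round a thickness to whole voxels, half-up."""
    return int(math.floor(thickness_mm / voxel + 0.5))


def make_layer_phantom(spec: PhantomSpec) -> TissueLabelVolume:
    """Build a planar-layer slab phantom: scalp, skull, CSF, gray, white.

    The scalp surface is the depth-index-0 plane (adjacent to exterior
    air); layers stack downward along the third axis. Raises if the layer
    stack exceeds the cube depth.
    """
    n = _round_voxels(spec.cube_edge, spec.voxel_size)
    ns = _round_voxels(spec.d_scalp, spec.voxel_size)
    nk = _round_voxels(spec.d_skull, spec.voxel_size)
    nc = _round_voxels(spec.d_csf, spec.voxel_size)
    ng = _round_voxels(spec.d_gray, spec.voxel_size)
    if ns + nk + nc >= n:
        raise ValueError("layer thicknesses exceed cube depth")
    labels = np.full((n, n, n), WHITE, dtype=np.uint8)
    z = np.arange(n)
    depth_label = np.full(n, WHITE, dtype=np.uint8)
    depth_label[z < ns + nk + nc + ng] = GRAY
    depth_label[z < ns + nk + nc] = CSF
    depth_label[z < ns + nk] = SKULL
    depth_label[z < ns] = SCALP
    labels[:, :, :] = depth_label[np.newaxis, np.newaxis, :]
    # Voxel (i, j, k) spans [i v, (i+1) v) in world mm: centre at (i+1/2) v,
    # so the scalp surface is exactly the z = 0 plane.
    vol = TissueLabelVolume(labels, spec.voxel_size,
                            np.full(3, spec.voxel_size / 2.0))
    if spec.sinus_semi_axes is not None:
        if spec.sinus_center is None:
            raise ValueError("sinus_center required with sinus_semi_axes")
        vol = add_frontal_sinus(vol, spec.sinus_center, spec.sinus_semi_axes)
    if spec.gyrification_amplitude:
        vol = add_gyrification(vol, spec.gyrification_amplitude,
                               spec.gyrification_wavelength)
    return vol


def add_frontal_sinus(volume: TissueLabelVolume, center, semi_axes
                      ) -> TissueLabelVolume:
    """Carve an air-filled ellipsoidal cavity out of the skull layer.

    Only voxels currently labelled skull and lying inside the ellipsoid
    become air; all other labels are untouched. Returns a new volume.
    """
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi < 0):
        raise ValueError("semi-axes must be nonnegative")
    out = volume.copy()
    if np.any(semi == 0):
        return out
    lo = volume.mm_to_index(center - semi)
    hi = volume.mm_to_index(center + semi)
    shape = np.array(volume.shape)
    if np.any(hi < 0) or np.any(lo >= shape):
        raise ValueError("sinus ellipsoid lies entirely outside the grid")
    lo = np.clip(lo, 0, shape - 1)
    hi = np.clip(hi, 0, shape - 1)
    ii, jj, kk = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    centers = np.stack([ii, jj, kk], axis=-1) * volume.voxel_size + volume.origin
    inside = np.sum(((centers - center) / semi) ** 2, axis=-1) <= 1.0
    block = out.labels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    block[inside & (block == SKULL)] = AIR
    return out


def add_gyrification(volume: TissueLabelVolume, amplitude: float,
                     wavelength: float) -> TissueLabelVolume:
    """Fold the CSF-gray interface with a 2D sinusoid.

    The gray-matter top surface at each (x, y) column is displaced by
    ``amplitude * sin(2 pi x / wavelength) * sin(2 pi y / wavelength)``
    (mm, rounded to voxels); the gray-white offset moves with it so gray
    thickness is preserved. Upward folds may rise into the CSF but not past
    the top of the CSF layer (that would push cortex into skull/scalp).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    out = volume.copy()
    if amplitude == 0:
        return out
    if wavelength <= 0:
        raise ValueError("wavelength must be positive for nonzero amplitude")
    labels = out.labels
    nx, ny, nz = labels.shape
    voxel = volume.voxel_size
    has_interface = False
    x = np.arange(nx) * voxel + out.origin[0]
    y = np.arange(ny) * voxel + out.origin[1]
    disp = amplitude * np.outer(np.sin(2 * np.pi * x / wavelength),
                                np.sin(2 * np.pi * y / wavelength))
    disp_vox = np.floor(disp / voxel + 0.5).astype(int)
    for i in range(nx):
        for j in range(ny):
            col = labels[i, j, :]
            csf_idx = np.flatnonzero(col == CSF)
            gray_idx = np.flatnonzero(col == GRAY)
            if gray_idx.size == 0 or csf_idx.size == 0:
                continue
            has_interface = True
            z_csf_top = csf_idx[0]
            z_gray = gray_idx[0]
            z_white = gray_idx[-1] + 1
            d = disp_vox[i, j]
            z_gray_new = z_gray + d
            z_white_new = z_white + d
            if z_gray_new < z_csf_top:
                raise ValueError("amplitude pushes gray matter above the CSF "
                                 "layer into skull/scalp")
            z_white_new = min(z_white_new, nz)
            z_gray_new = min(z_gray_new, nz)
            col[z_csf_top:z_gray_new] = CSF
            col[z_gray_new:z_white_new] = GRAY
            col[z_white_new:] = WHITE
    if not has_interface:
        raise ValueError("volume has no CSF/gray interface to fold")
    return out


def write_volume(volume: TissueLabelVolume, path: str | Path) -> None:
    """Serialise a label volume to NIfTI (.nii or .nii.gz)."""
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.labels.astype(np.uint8), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path: str | Path) -> TissueLabelVolume:
    """Load a label volume from NIfTI; rejects non-integer data, unknown
    labels and anisotropic voxel grids."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("volume contains non-integer label data")
        data = np.round(data).astype(np.int64)
    bad = set(np.unique(data)) - _VALID_LABELS
    if bad:
        raise ValueError(f"unknown tissue labels in file: {sorted(int(b) for b in bad)}")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise ValueError(f"anisotropic voxel sizes {tuple(zooms)} are not "
                         "supported; resample to an isotropic grid first")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return TissueLabelVolume(data.astype(np.uint8), float(zooms[0]), origin)
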