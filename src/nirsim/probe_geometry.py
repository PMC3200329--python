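"""Channel geometry: channel cubes, reference points, scalp-cortex distance.

An fNIRS channel is one emitter-detector pair on the scalp. Transport and
all tallies are computed inside a *channel cube*, an axis-aligned subvolume
laterally centred on the optode midpoint and starting at the head surface.
The *reference point* is the scalp-surface point centred between the
optodes; radial distances from it define the scalp-cortex distance (SCD)
and the superficial layer thicknesses.

The SCD is operationalised as the radius at which the cumulative
gray-matter voxel volume around the reference point first reaches a small
per-mille fraction of the cube's total gray matter — robust against
isolated mislabelled voxels. Scalp, skull and CSF thicknesses follow from
the same construction applied to the skull, CSF and gray surfaces.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .head_model import TissueLabelVolume
from .optics import AIR, CSF, GRAY, SCALP, SKULL

__all__ = [
    "ChannelGeometry",
    "LayerThicknesses",
    "surface_voxels",
    "reference_point_on_scalp",
    "extract_channel_cube",
    "compute_scd",
    "compute_layer_thicknesses",
    "read_probe_layout",
    "write_probe_layout",
]

#: Default fraction of tissue volume that defines the "closest" radius.
PER_MILLE = 0.001

#: Default channel-cube edge, mm; must exceed the 30 mm optode separation.
CUBE_EDGE = 60.0


@dataclass
class ChannelGeometry:
    """World-mm geometry of one emitter-detector channel."""

    emitter: np.ndarray
    detector: np.ndarray
    reference_point: np.ndarray
    cube_bounds: tuple  # ((i0, i1), (j0, j1), (k0, k1)) into the parent grid
    clipped: bool = False

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.detector - self.emitter))


@dataclass
class LayerThicknesses:
    """Superficial layer thicknesses and scalp-cortex distance, mm."""

    d_scalp: float
    d_skull: float
    d_csf: float
    scd: float


def surface_voxels(volume: TissueLabelVolume) -> np.ndarray:
    """(N, 3) indices of non-air voxels on the outer head surface.

    A voxel is on the surface when it sits on the ``z = 0`` face of the
    grid (which borders exterior air) or touches an air voxel directly
    above it. Air pockets deeper inside (frontal sinus) do not count.
    """
    labels = volume.labels
    mask = np.zeros(labels.shape, dtype=bool)
    mask[:, :, 0] = labels[:, :, 0] != AIR
    deeper = (labels[:, :, 1:] != AIR) & (labels[:, :, :-1] == AIR)
    # only via an air column open to the outside
    open_air = np.cumprod(labels == AIR, axis=2).astype(bool)
    mask[:, :, 1:] |= deeper & open_air[:, :, :-1]
    return np.argwhere(mask)


def reference_point_on_scalp(volume: TissueLabelVolume, emitter,
                             detector) -> np.ndarray:
    """Scalp-surface point centred between the optodes.

    The nearest surface-voxel centre to the 3D midpoint of emitter and
    detector; deterministic for a given volume.
    """
    mid = (np.asarray(emitter, float) + np.asarray(detector, float)) / 2.0
    surf = surface_voxels(volume)
    if surf.size == 0:
        raise ValueError("volume has no air/scalp surface")
    centers = volume.voxel_centers_mm(surf)
    return centers[np.argmin(np.linalg.norm(centers - mid, axis=1))]


def _on_surface(volume: TissueLabelVolume, point, tol_mm: float) -> bool:
    surf = surface_voxels(volume)
    centers = volume.voxel_centers_mm(surf)
    return bool(np.min(np.linalg.norm(centers - np.asarray(point, float),
                                      axis=1)) <= tol_mm)


def extract_channel_cube(volume: TissueLabelVolume, emitter, detector,
                         cube_edge: float = CUBE_EDGE
                         ) -> tuple[ChannelGeometry, TissueLabelVolume]:
    """Cut the channel cube around an optode pair.

    The cube is laterally centred on the optode midpoint, starts at the
    head surface, and has the requested edge length; it is clipped at the
    parent volume bounds with a warning. Both optodes must lie on the
    scalp surface.
    """
    emitter = np.asarray(emitter, dtype=float)
    detector = np.asarray(detector, dtype=float)
    tol = 1.5 * volume.voxel_size
    for name, p in (("emitter", emitter), ("detector", detector)):
        if not _on_surface(volume, p, tol):
            raise ValueError(f"{name} at {p} is not on the scalp surface")
    mid = (emitter + detector) / 2.0
    voxel = volume.voxel_size
    n_edge = int(round(cube_edge / voxel))
    ci = int(round((mid[0] - volume.origin[0]) / voxel))
    cj = int(round((mid[1] - volume.origin[1]) / voxel))
    i0, i1 = ci - n_edge // 2, ci - n_edge // 2 + n_edge
    j0, j1 = cj - n_edge // 2, cj - n_edge // 2 + n_edge
    k0, k1 = 0, n_edge
    nx, ny, nz = volume.shape
    clipped = i0 < 0 or j0 < 0 or i1 > nx or j1 > ny or k1 > nz
    if clipped:
        warnings.warn("channel cube clipped at volume bounds", stacklevel=2)
    i0, i1 = max(i0, 0), min(i1, nx)
    j0, j1 = max(j0, 0), min(j1, ny)
    k1 = min(k1, nz)
    cube = TissueLabelVolume(
        volume.labels[i0:i1, j0:j1, k0:k1].copy(),
        voxel,
        volume.origin + np.array([i0, j0, k0]) * voxel,
    )
    geom = ChannelGeometry(
        emitter=emitter,
        detector=detector,
        reference_point=reference_point_on_scalp(volume, emitter, detector),
        cube_bounds=((i0, i1), (j0, j1), (k0, k1)),
        clipped=clipped,
    )
    return geom, cube


def write_probe_layout(channels, path: str | Path) -> None:
    """Serialise a probe layout as a JSON list of channels, each a pair of
    world-mm optode coordinates: ``[{"emitter": [...], "detector": [...]}]``.

    ``channels`` is a sequence of (emitter, detector) coordinate pairs.
    """
    payload = [{"emitter": list(map(float, e)), "detector": list(map(float, d))}
               for e, d in channels]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_probe_layout(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read a probe layout written by :func:`write_probe_layout`."""
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload:
        e = np.asarray(entry["emitter"], dtype=float)
        d = np.asarray(entry["detector"], dtype=float)
        if e.shape != (3,) or d.shape != (3,):
            raise ValueError("optode coordinates must be 3-vectors")
        out.append((e, d))
    return out


def _per_mille_radius(cube: TissueLabelVolume, reference_point, label: int,
                      per_mille: float, method: str) -> float:
    """Radius around the reference point enclosing the closest
    ``per_mille`` fraction of the given tissue's volume."""
    if not 0 < per_mille <= 1:
        raise ValueError("per_mille must lie in (0, 1]")
    idx = np.argwhere(cube.labels == label)
    if idx.size == 0:
        raise ValueError(f"cube contains no voxels of tissue {label}")
    centers = cube.voxel_centers_mm(idx)
    d = np.sort(np.linalg.norm(centers - np.asarray(reference_point, float),
                               axis=1))
    k = max(1, math.ceil(per_mille * d.size))
    if method == "radius":
        return float(d[k - 1])
    if method == "mean":
        return float(d[:k].mean())
    raise ValueError("method must be 'radius' or 'mean'")


def compute_scd(cube: TissueLabelVolume, reference_point,
                per_mille: float = PER_MILLE,
                method: str = "radius") -> float:
    """Scalp-cortex distance: radial distance from the surface reference
    point to the closest per-mille of gray-matter volume in the cube.

    ``method='radius'`` (default) returns the enclosing radius;
    ``method='mean'`` the mean distance of the nearest per-mille voxels.
    Raises when the cube contains no gray matter.
    """
    try:
        return _per_mille_radius(cube, reference_point, GRAY, per_mille,
                                 method)
    except ValueError as err:
        if "no voxels" in str(err):
            raise ValueError("no gray matter in channel cube; SCD is "
                             "undefined") from err
        raise


def compute_layer_thicknesses(cube: TissueLabelVolume, reference_point,
                              per_mille: float = PER_MILLE,
                              method: str = "radius") -> LayerThicknesses:
    """Scalp, skull and CSF layer thicknesses plus SCD.

    Each tissue surface is located by the same per-mille radial
    construction as the SCD: the skull radius gives the scalp thickness,
    the CSF radius scalp+skull, the gray radius the SCD; differences give
    the individual thicknesses (clamped at 0 against discretisation
    jitter). A cube without CSF yields ``d_csf = 0``.
    """
    r_skull = _per_mille_radius(cube, reference_point, SKULL, per_mille,
                                method)
    scd = compute_scd(cube, reference_point, per_mille, method)
    try:
        r_csf = _per_mille_radius(cube, reference_point, CSF, per_mille,
                                  method)
    except ValueError:
        r_csf = scd  # no CSF layer present
    r_csf = min(r_csf, scd)
    return LayerThicknesses(
        d_scalp=r_skull,
        d_skull=max(0.0, r_csf - r_skull),
        d_csf=max(0.0, scd - r_csf),
        scd=scd,
    )
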