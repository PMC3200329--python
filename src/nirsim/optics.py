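"""Optical-physics primitives for NIR photon transport.

Conventions used throughout the package:

* absorption coefficient ``mu_a`` and scattering coefficient ``mu_s`` are
  rates per millimetre (mm^-1), so the scalp reduced scattering coefficient
  comes out at the physiological 1.9 mm^-1;
* the scattering anisotropy ``g`` is the mean cosine of the
  Henyey-Greenstein phase function, dimensionless, ``0 <= g < 1``;
* the refractive index ``n`` is dimensionless, ``n >= 1``;
* attenuation is the natural logarithm of the intensity ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TISSUES",
    "AIR",
    "SCALP",
    "SKULL",
    "CSF",
    "GRAY",
    "WHITE",
    "OpticalCoefficientSet",
    "AttenuationTerms",
    "reduced_scattering",
    "sample_step",
    "deposit_weight",
    "hg_phase",
    "sample_hg_costheta",
    "rotate_direction",
    "snell_angle",
    "fresnel_reflectance",
    "beer_lambert_attenuation",
    "attenuation_from_intensities",
    "differential_attenuation",
]

#: Tissue label order shared by every module: integer label == index here.
TISSUES = ("air", "scalp", "skull", "csf", "gray", "white")
AIR, SCALP, SKULL, CSF, GRAY, WHITE = range(6)

# Literature coefficients for adult head tissue between roughly 700 and
# 900 nm, treated as wavelength-fixed: (mu_a [mm^-1], mu_s [mm^-1], g, n).
_DEFAULTS = {
    "air": (0.0, 0.0, 0.0, 1.00),
    "scalp": (0.016, 19.0, 0.9, 1.60),
    "skull": (0.018, 16.0, 0.9, 1.56),
    "csf": (0.004, 0.3, 0.0, 1.33),
    "gray": (0.090, 21.5, 0.9, 1.40),
    "white": (0.090, 38.4, 0.9, 1.47),
}


@dataclass(frozen=True)
class OpticalCoefficientSet:
    """Per-tissue optical coefficients, indexed by the integer tissue label.

    Each field is a length-6 float array ordered as :data:`TISSUES`.
    """

    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s", "g", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(TISSUES),):
                raise ValueError(f"{name} must have one value per tissue "
                                 f"({len(TISSUES)}), got shape {arr.shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise ValueError("mu_a and mu_s must be nonnegative")
        if np.any(self.g < 0) or np.any(self.g >= 1):
            raise ValueError("anisotropy g must satisfy 0 <= g < 1")
        if np.any(self.n < 1):
            raise ValueError("refractive index must be >= 1")

    @classmethod
    def default(cls) -> "OpticalCoefficientSet":
        """Coefficient table used for all head simulations by default."""
        cols = list(zip(*(_DEFAULTS[t] for t in TISSUES)))
        return cls(*(np.array(c, dtype=float) for c in cols))

    @property
    def mu_t(self) -> np.ndarray:
        """Total interaction coefficient mu_a + mu_s per tissue."""
        return self.mu_a + self.mu_s

    def reduced(self) -> "OpticalCoefficientSet":
        """Similarity-transformed set: mu_s' = mu_s (1 - g) with g = 0.

        Isotropic scattering at the reduced coefficient reproduces the
        diffuse light distribution of the anisotropic medium while cutting
        the number of interactions by roughly 1/(1 - g).
        """
        return OpticalCoefficientSet(
            mu_a=self.mu_a.copy(),
            mu_s=reduced_scattering(self.mu_s, self.g),
            g=np.zeros_like(self.g),
            n=self.n.copy(),
        )

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tissue": TISSUES, "mu_a": self.mu_a, "mu_s": self.mu_s,
             "g": self.g, "n": self.n}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OpticalCoefficientSet":
        frame = frame.set_index("tissue").reindex(list(TISSUES))
        if frame.isna().any().any():
            missing = frame.index[frame.isna().any(axis=1)].tolist()
            raise ValueError(f"coefficient table missing tissues: {missing}")
        return cls(frame["mu_a"].to_numpy(float), frame["mu_s"].to_numpy(float),
                   frame["g"].to_numpy(float), frame["n"].to_numpy(float))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            payload = {t: dict(mu_a=self.mu_a[i], mu_s=self.mu_s[i],
                               g=self.g[i], n=self.n[i])
                       for i, t in enumerate(TISSUES)}
            path.write_text(json.dumps(payload, indent=2))
        else:
            self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "OpticalCoefficientSet":
        path = Path(path)
        if path.suffix == ".json":
            payload = json.loads(path.read_text())
            frame = pd.DataFrame(
                [{"tissue": t, **payload[t]} for t in TISSUES if t in payload]
            )
        else:
            frame = pd.read_csv(path)
        return cls.from_frame(frame)


def reduced_scattering(mu_s, g):
    """Reduced scattering coefficient mu_s' = mu_s (1 - g).

    The similarity relation from the diffusion approximation of radiative
    transport; valid for 0 <= g < 1.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g >= 1):
        raise ValueError("g must be < 1")
    out = np.asarray(mu_s, dtype=float) * (1.0 - g)
    return float(out) if out.ndim == 0 else out


def sample_step(mu_t: float, xi: float) -> float:
    """Free-path length s = -ln(xi)/mu_t for one uniform draw xi in (0, 1].

    The path length between interactions is exponentially distributed with
    mean 1/mu_t. ``mu_t == 0`` means free flight (no interaction ever); the
    caller must handle straight propagation itself, so we raise here.
    """
    if mu_t <= 0:
        raise ValueError("mu_t must be positive; mu_t == 0 is free flight")
    if not 0 < xi <= 1:
        xi = max(xi, np.finfo(float).tiny)
        if xi > 1:
            raise ValueError("xi must lie in (0, 1]")
    return -math.log(xi) / mu_t


def deposit_weight(w: float, mu_a: float, mu_t: float) -> tuple[float, float]:
    """Albedo weighting: split off deltaW = W mu_a/mu_t at an interaction.

    Returns ``(w_new, delta_w)`` with ``w_new + delta_w == w`` exactly.
    """
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    if mu_a > mu_t:
        raise ValueError("mu_a cannot exceed mu_t")
    delta = w * mu_a / mu_t
    w_new = w - delta
    # recompute the complement so w_new + delta == w holds exactly in
    # floating point (Fast2Sum: w - (w - delta) is representable)
    return w_new, w - w_new


def hg_phase(costheta, g: float):
    """Henyey-Greenstein phase function p(cos theta), normalised over
    cos theta in [-1, 1]."""
    costheta = np.asarray(costheta, dtype=float)
    return 0.5 * (1.0 - g * g) / (1.0 + g * g - 2.0 * g * costheta) ** 1.5


def sample_hg_costheta(g: float, xi: float) -> float:
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine.

    For g = 0 the phase function is isotropic and cos theta = 2 xi - 1.
    """
    if not 0 <= g < 1:
        raise ValueError("g must satisfy 0 <= g < 1")
    if not 0 <= xi <= 1:
        raise ValueError("xi must lie in [0, 1]")
    if g == 0.0:
        return 2.0 * xi - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


def rotate_direction(e: Sequence[float], costheta: float,
                     phi: float) -> np.ndarray:
    """Rotate unit vector ``e`` by polar angle acos(costheta) and azimuth phi.

    Azimuth convention: for the near-vertical special case (|e_z| ~ 1) the
    new direction is (sin theta cos phi, sin theta sin phi,
    cos theta * sign(e_z)), i.e. phi = 0 maps straight-up input deflected by
    90 degrees onto +x. The general case uses the standard local-frame
    rotation consistent with that convention.
    """
    e = np.asarray(e, dtype=float)
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ValueError("direction vector must be nonzero")
    ex, ey, ez = e / norm
    st = math.sqrt(max(0.0, 1.0 - costheta * costheta))
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(ez) > 0.99999:
        out = np.array([st * cp, st * sp, costheta * math.copysign(1.0, ez)])
    else:
        denom = math.sqrt(1.0 - ez * ez)
        out = np.array([
            st * (ex * ez * cp - ey * sp) / denom + ex * costheta,
            st * (ey * ez * cp + ex * sp) / denom + ey * costheta,
            -st * cp * denom + ez * costheta,
        ])
    return out / np.linalg.norm(out)


def snell_angle(n1: float, n2: float, alpha: float) -> tuple[float, bool]:
    """Refraction angle from Snell's law, n1 sin(alpha) = n2 sin(beta).

    Returns ``(beta, tir)``; under total internal reflection ``beta`` is NaN
    and ``tir`` is True.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    if not 0 <= alpha <= math.pi / 2:
        raise ValueError("incidence angle must lie in [0, pi/2]")
    s = n1 * math.sin(alpha) / n2
    if s > 1.0:
        return math.nan, True
    return math.asin(s), False


def fresnel_reflectance(n1: float, n2: float, alpha: float) -> float:
    """Unpolarised Fresnel reflectance at incidence angle ``alpha`` (rad).

    Average of the s- and p-polarised power reflectances, computed from the
    amplitude coefficients (well-behaved at normal incidence); returns 1
    under total internal reflection.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    if n1 == n2:
        return 0.0
    beta, tir = snell_angle(n1, n2, alpha)
    if tir:
        return 1.0
    ci, ct = math.cos(alpha), math.cos(beta)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@dataclass
class AttenuationTerms:
    """Terms of the modified Beer-Lambert relation for one channel.

    ``A = mu_a * L + G`` in a homogeneous medium, where ``L`` is the mean
    photon pathlength (mm) and ``G`` collects scattering losses that do not
    depend on absorption. ``I0``/``I`` are emitted/detected intensities.
    """

    I0: float | None = None
    I: float | None = None
    mu_a: float | None = None
    L: float | None = None
    G: float = 0.0
    partial_pathlengths: np.ndarray | None = None
    delta_mu_a: np.ndarray | None = None


def attenuation_from_intensities(I0: float, I: float) -> float:
    """A = ln(I0 / I); requires positive intensities."""
    if I <= 0 or I0 <= 0:
        raise ValueError("intensities must be positive")
    return math.log(I0 / I)


def beer_lambert_attenuation(terms: AttenuationTerms) -> float:
    """Attenuation of a homogeneous medium, A = mu_a * L + G.

    Falls back to the intensity log-ratio when pathlength terms are absent.
    """
    if terms.mu_a is not None and terms.L is not None:
        return terms.mu_a * terms.L + terms.G
    if terms.I0 is not None and terms.I is not None:
        return attenuation_from_intensities(terms.I0, terms.I)
    raise ValueError("need either (mu_a, L) or (I0, I)")


def differential_attenuation(partial_pathlengths, delta_mu_a) -> float:
    """Attenuation change dA = sum_i dmu_a,i * L_i over tissue types.

    This is the quantity an fNIRS measurement senses: the absorption change
    of each tissue weighted by the mean partial pathlength through it.
    """
    L = np.asarray(partial_pathlengths, dtype=float)
    d = np.asarray(delta_mu_a, dtype=float)
    if L.shape != d.shape:
        raise ValueError("partial pathlengths and delta mu_a must have the "
                         "same length")
    return float(np.dot(d, L))
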