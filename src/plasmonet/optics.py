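"""Transfer-matrix optics for surface-plasmon-resonance (SPR) sensing.

Simulates p- (and s-) polarised reflectivity of a planar multilayer in the
Kretschmann geometry: light is incident through a semi-infinite glass
substrate onto a thin gold film, beyond which lie the sample layers (cell
medium, membrane, cytosol — or just medium where no cell is present).
Surface plasmons appear as a sharp p-polarisation reflectivity minimum whose
angle shifts with the interfacial refractive index; a widefield microscope
operated at a fixed off-resonance angle converts those shifts into intensity
changes.

Conventions
-----------
* Complex refractive indices are written ``n + i*k`` with ``k >= 0`` for
  absorbing media, under the ``exp(-i*omega*t)`` time convention, so that
  absorbing layers attenuate propagating waves.
* Angles are in degrees, thicknesses and wavelengths in nanometres.
* The characteristic (Abeles) 2x2 matrix formalism is used; the outermost
  two layers of a stack are semi-infinite half-spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "OpticalLayer",
    "OpticalLayerStack",
    "SPRCurve",
    "build_interface_stacks",
    "reflection_coefficient",
    "spr_curve",
    "locate_minimum",
    "operating_angle",
    "two_media_sp_angle",
    "load_stack",
    "save_stack",
]

# Interface constants (indices at 690 nm)
WAVELENGTH_NM = 690.0
N_GLASS = 1.5133
N_GOLD = 0.13322 + 3.9722j
N_MEDIUM = 1.3350
N_MEMBRANE = 1.4985
N_CYTOSOL = 1.36
N_ITO = 1.85 + 0.01j  # sputtered ITO adhesion layer, optional
D_GOLD_NM = 50.0
D_GAP_NM = 50.0
D_MEMBRANE_NM = 7.5
D_ITO_NM = 50.0


@dataclass(frozen=True)
class OpticalLayer:
    """One layer of a planar stack.

    ``thickness_nm=None`` marks a semi-infinite half-space (only valid for
    the first and last layer of a stack).
    """

    name: str
    refractive_index: complex
    thickness_nm: float | None = None

    @property
    def semi_infinite(self) -> bool:
        return self.thickness_nm is None

    def __post_init__(self) -> None:
        n = complex(self.refractive_index)
        if n.real <= 0:
            raise ValueError(f"layer {self.name!r}: Re(n) must be > 0, got {n}")
        if self.thickness_nm is not None and self.thickness_nm < 0:
            raise ValueError(f"layer {self.name!r}: negative thickness")


@dataclass(frozen=True)
class OpticalLayerStack:
    """Ordered layers from the incidence side, plus the vacuum wavelength."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float = WAVELENGTH_NM

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 2:
            raise ValueError("a stack needs at least two layers")
        if not (layers[0].semi_infinite and layers[-1].semi_infinite):
            raise ValueError("first and last layers must be semi-infinite")
        for lyr in layers[1:-1]:
            if lyr.semi_infinite:
                raise ValueError(f"interior layer {lyr.name!r} must have a thickness")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def indices(self) -> np.ndarray:
        return np.array([complex(l.refractive_index) for l in self.layers])

    @property
    def thicknesses_nm(self) -> np.ndarray:
        return np.array([0.0 if l.semi_infinite else l.thickness_nm for l in self.layers])


@dataclass(frozen=True)
class SPRCurve:
    """Reflectivity versus angle of incidence on a uniform angle grid."""

    angles_deg: np.ndarray
    reflection: np.ndarray  # complex amplitude reflection coefficient
    reflectivity: np.ndarray  # |r|^2
    derivative: np.ndarray  # dR/dtheta per degree, central differences

    def __post_init__(self) -> None:
        n = len(self.angles_deg)
        if not (len(self.reflection) == len(self.reflectivity) == len(self.derivative) == n):
            raise ValueError("curve arrays must share length")


def cell_stack(include_ito: bool = False, wavelength_nm: float = WAVELENGTH_NM) -> OpticalLayerStack:
    """Glass | (ITO) | Au 50 nm | medium gap 50 nm | membrane 7.5 nm | cytosol."""
    layers = [OpticalLayer("glass", N_GLASS)]
    if include_ito:
        layers.append(OpticalLayer("ito", N_ITO, D_ITO_NM))
    layers += [
        OpticalLayer("gold", N_GOLD, D_GOLD_NM),
        OpticalLayer("medium_gap", N_MEDIUM, D_GAP_NM),
        OpticalLayer("membrane", N_MEMBRANE, D_MEMBRANE_NM),
        OpticalLayer("cytosol", N_CYTOSOL),
    ]
    return OpticalLayerStack(tuple(layers), wavelength_nm)


def background_stack(include_ito: bool = False, wavelength_nm: float = WAVELENGTH_NM) -> OpticalLayerStack:
    """Glass | (ITO) | Au 50 nm | semi-infinite cell medium (no cell)."""
    layers = [OpticalLayer("glass", N_GLASS)]
    if include_ito:
        layers.append(OpticalLayer("ito", N_ITO, D_ITO_NM))
    layers += [
        OpticalLayer("gold", N_GOLD, D_GOLD_NM),
        OpticalLayer("medium", N_MEDIUM),
    ]
    return OpticalLayerStack(tuple(layers), wavelength_nm)


def build_interface_stacks(include_ito: bool = False) -> tuple[OpticalLayerStack, OpticalLayerStack]:
    """Return the (cell, background) stacks of the sensor interface model."""
    return cell_stack(include_ito), background_stack(include_ito)


def _kz(n: np.ndarray, k0: float, kx: np.ndarray) -> np.ndarray:
    """Longitudinal wavevector with the decaying-evanescent branch (Im >= 0)."""
    kz = np.sqrt((n * k0) ** 2 - kx**2 + 0j)
    flip = kz.imag < 0
    return np.where(flip, -kz, kz)


def reflection_coefficient(
    stack: OpticalLayerStack,
    angle_deg: float | np.ndarray,
    polarization: str = "p",
) -> complex | np.ndarray:
    """Amplitude reflection coefficient r of the stack at the given angle(s).

    The 2x2 characteristic matrix of each interior layer is accumulated in
    order from the incidence side; r follows from the stack matrix and the
    admittances of the two bounding half-spaces. For p-polarisation the
    layer admittance is kz/(k0 n^2), for s-polarisation kz/k0.
    """
    if polarization not in ("p", "s"):
        raise ValueError("polarization must be 'p' or 's'")
    angles = np.asarray(angle_deg, dtype=float)
    scalar = angles.ndim == 0
    angles = np.atleast_1d(angles)
    if np.any((angles <= 0) | (angles >= 90)):
        raise ValueError("angle of incidence must lie in (0, 90) degrees")

    n = stack.indices
    d = stack.thicknesses_nm
    k0 = 2 * np.pi / stack.wavelength_nm
    n0 = n[0]
    if abs(n0.imag) > 1e-12:
        raise ValueError("incidence medium must be transparent")
    kx = k0 * n0.real * np.sin(np.deg2rad(angles))

    def admittance(ni: complex) -> np.ndarray:
        kz = _kz(ni, k0, kx)
        return kz / (k0 * ni**2) if polarization == "p" else kz / k0

    q0 = admittance(n[0])
    qN = admittance(n[-1])

    m00 = np.ones_like(kx, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for i in range(1, len(n) - 1):
        kz = _kz(n[i], k0, kx)
        q = admittance(n[i])
        beta = kz * d[i]
        c, s = np.cos(beta), np.sin(beta)
        a00, a01 = c, -1j * s / q
        a10, a11 = -1j * q * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )

    num = q0 * (m00 + m01 * qN) - (m10 + m11 * qN)
    den = q0 * (m00 + m01 * qN) + (m10 + m11 * qN)
    r = num / den
    return complex(r[0]) if scalar else r


def spr_curve(
    stack: OpticalLayerStack,
    angle_start: float = 65.0,
    angle_stop: float = 80.0,
    angle_step: float = 0.01,
    polarization: str = "p",
) -> SPRCurve:
    """Reflectivity curve on the closed grid [start, stop] with the given step.

    The angle derivative is estimated by second-order central differences
    (one-sided at the grid ends).
    """
    if angle_step <= 0:
        raise ValueError("angle_step must be positive")
    if angle_start >= angle_stop:
        raise ValueError("angle_start must be below angle_stop")
    n_pts = int(round((angle_stop - angle_start) / angle_step)) + 1
    angles = angle_start + angle_step * np.arange(n_pts)
    r = reflection_coefficient(stack, angles, polarization)
    refl = np.abs(r) ** 2
    deriv = np.gradient(refl, angles)
    return SPRCurve(angles, r, refl, deriv)


def locate_minimum(curve: SPRCurve) -> float:
    """Angle of the reflectivity minimum, with local quadratic refinement."""
    i = int(np.argmin(curve.reflectivity))
    if i == 0 or i == len(curve.angles_deg) - 1:
        return float(curve.angles_deg[i])
    x = curve.angles_deg[i - 1 : i + 2]
    y = curve.reflectivity[i - 1 : i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom <= 0:
        return float(curve.angles_deg[i])
    step = x[1] - x[0]
    return float(x[1] + 0.5 * step * (y[0] - y[2]) / denom)


def operating_angle(
    curve_cell: SPRCurve,
    curve_bg: SPRCurve,
    derivative_tol: float = 1e-4,
) -> float:
    """Angle where the two SPR curves cross between their minima.

    This is the functional operating point: both curves have nonzero (and
    opposite-sign) intensity gradients there, so a common resonance-angle
    shift moves cell and background intensities in opposite directions.
    """
    if len(curve_cell.angles_deg) != len(curve_bg.angles_deg) or not np.allclose(
        curve_cell.angles_deg, curve_bg.angles_deg
    ):
        raise ValueError("curves must share the angle grid")
    angles = curve_cell.angles_deg
    diff = curve_cell.reflectivity - curve_bg.reflectivity
    if np.max(np.abs(diff)) < 1e-12:
        raise ValueError("curves are identical; crossing undefined")

    lo, hi = sorted((locate_minimum(curve_cell), locate_minimum(curve_bg)))
    inside = (angles > lo) & (angles < hi)
    crosses = (np.sign(diff[:-1]) * np.sign(diff[1:]) < 0) | (
        (diff[:-1] == 0) & (diff[1:] != 0)
    )
    idx = np.where(inside[:-1] & crosses)[0]
    # require meaningful gradients on both curves at the crossing
    idx = [
        i
        for i in idx
        if abs(curve_cell.derivative[i]) > derivative_tol and abs(curve_bg.derivative[i]) > derivative_tol
    ]
    if not idx:
        raise ValueError("no reflectivity crossing between the two minima")
    mid = 0.5 * (lo + hi)
    i = min(idx, key=lambda k: abs(angles[k] - mid))
    # linear interpolation of the zero of diff between grid points
    a0, a1 = angles[i], angles[i + 1]
    d0, d1 = diff[i], diff[i + 1]
    if d0 == 0:
        return float(a0)
    return float(a0 + (a1 - a0) * d0 / (d0 - d1))


def two_media_sp_angle(
    n_metal: complex = N_GOLD,
    n_medium: float = N_MEDIUM,
    n_prism: float = N_GLASS,
) -> float:
    """Closed-form surface-plasmon resonance angle for a metal/dielectric pair.

    From the SP dispersion relation k_sp = k0*sqrt(eps_m*eps_d/(eps_m+eps_d))
    matched to the in-plane wavevector in the prism; ignores the finite metal
    thickness, so it approximates the thin-film minimum to a fraction of a
    degree.
    """
    eps_m = complex(n_metal) ** 2
    eps_d = complex(n_medium) ** 2
    n_eff = np.sqrt(eps_m * eps_d / (eps_m + eps_d)).real
    return float(np.rad2deg(np.arcsin(n_eff / n_prism)))


# ---------------------------------------------------------------------------
# stack config I/O (YAML)

def save_stack(stack: OpticalLayerStack, path) -> None:
    doc = {
        "wavelength_nm": float(stack.wavelength_nm),
        "layers": [
            {
                "name": l.name,
                "n_real": float(complex(l.refractive_index).real),
                "n_imag": float(complex(l.refractive_index).imag),
                "thickness_nm": "semi_infinite" if l.semi_infinite else float(l.thickness_nm),
            }
            for l in stack.layers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_stack(path) -> OpticalLayerStack:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    layers = []
    for entry in doc["layers"]:
        thick = entry["thickness_nm"]
        layers.append(
            OpticalLayer(
                entry["name"],
                complex(entry["n_real"], entry.get("n_imag", 0.0)),
                None if thick == "semi_infinite" else float(thick),
            )
        )
    return OpticalLayerStack(tuple(layers), float(doc["wavelength_nm"]))
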