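"""Measurement-side analysis: displacement estimation, two-angle
decomposition, elliptical-motion summaries, compliance/FWHM metrics,
deformation ratios and the stiffness felt by an outer hair cell.

Angle convention: all direction angles are measured from the transverse
axis, positive toward the lateral radial direction, and reported in
(-90, 90] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .assembly import AssembledSystem
from .materials import (DC_ROOTS, N_JOINT1, N_OHC1_APEX, N_OHC2_APEX,
                        N_TM_ATTACH, N_TM_HB2, element_stiffness)
from .solver import (DisplacementField, apply_ohc_force_couple,
                     solve_point_load)

__all__ = [
    "MotionVector", "DeflectionProfile", "EllipseAxis",
    "ncc_displacement", "decompose_two_angle", "compose_two_angle",
    "ellipse_major_axis", "hair_bundle_deflection", "volume_compliance",
    "fwhm_fraction", "contact_stiffness", "deformation_ratio_tm",
    "deformation_ratio_dc", "stiffness_felt_by_ohc", "bm_profile",
    "corner_frequency", "hf_slope_db_per_octave", "phase_accumulation_deg",
]


@dataclass(frozen=True)
class MotionVector:
    """Complex in-plane motion (radial, transverse components, meters)."""

    d_r: complex
    d_t: complex

    def __sub__(self, other: "MotionVector") -> "MotionVector":
        return MotionVector(self.d_r - other.d_r, self.d_t - other.d_t)

    @property
    def major_axis(self) -> "EllipseAxis":
        return ellipse_major_axis(self)


class EllipseAxis(NamedTuple):
    amplitude: float       # m
    theta_deg: float       # from the transverse axis, (-90, 90]
    degenerate: bool       # circular or zero motion: direction undefined


def decompose_two_angle(d1: complex, d2: complex, theta1: float,
                        theta2: float) -> MotionVector:
    """Radial/transverse components from displacements along two beam axes.

    Solves ``[d1, d2]^T = [[sin t1, cos t1], [sin t2, cos t2]] [d_r, d_t]^T``
    exactly; angles in degrees from the transverse axis.
    """
    t1, t2 = math.radians(theta1), math.radians(theta2)
    det = math.sin(t1) * math.cos(t2) - math.cos(t1) * math.sin(t2)
    if abs(det) < 1e-12:
        raise ValueError(
            f"singular measurement geometry: theta1={theta1}, theta2={theta2}")
    d_r = (d1 * math.cos(t2) - d2 * math.cos(t1)) / det
    d_t = (d2 * math.sin(t1) - d1 * math.sin(t2)) / det
    return MotionVector(d_r=d_r, d_t=d_t)


def compose_two_angle(v: MotionVector, theta: float) -> complex:
    """Displacement seen along a beam at ``theta`` degrees from transverse."""
    t = math.radians(theta)
    return math.sin(t) * v.d_r + math.cos(t) * v.d_t


def ellipse_major_axis(v: MotionVector) -> EllipseAxis:
    """Major axis of the ellipse traced by ``Re[(d_r, d_t) e^{i w t}]``.

    Computed analytically from the singular values of the 2x2 matrix whose
    columns are the real and imaginary parts of the motion vector.
    """
    m = np.array([[v.d_r.real, v.d_r.imag], [v.d_t.real, v.d_t.imag]])
    u, s, _ = np.linalg.svd(m)
    amp = float(s[0])
    if amp == 0.0:
        return EllipseAxis(0.0, 0.0, True)
    direction = u[:, 0]  # (radial, transverse)
    theta = math.degrees(math.atan2(direction[0], direction[1]))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    degenerate = s[1] > 0.999 * s[0]  # (near-)circular orbit
    return EllipseAxis(amp, theta, degenerate)


def hair_bundle_deflection(u_tm: MotionVector, u_rl: MotionVector) -> float:
    """Bundle deflection amplitude |u_TM - u_RL| via the major axis (m)."""
    return ellipse_major_axis(u_tm - u_rl).amplitude


# ---------------------------------------------------------------------------
# Image displacement estimation
# ---------------------------------------------------------------------------

@dataclass
class DisplacementEstimate:
    """Windowed subpixel displacement field between two images."""

    centers: np.ndarray       # (n, 2) row/col pixel centers
    shifts_px: np.ndarray     # (n, 2) displacement of image_b vs image_a
    valid: np.ndarray         # (n,) False where the window had no texture

    def mean_shift_px(self) -> np.ndarray:
        if not self.valid.any():
            raise ValueError("no valid windows")
        return self.shifts_px[self.valid].mean(axis=0)

    def shifts_nm(self, pixel_pitch_um) -> np.ndarray:
        pitch = np.broadcast_to(np.asarray(pixel_pitch_um, dtype=float), (2,))
        return self.shifts_px * pitch * 1e3


def ncc_displacement(image_a: np.ndarray, image_b: np.ndarray,
                     window: int = 64, upsample: int = 100,
                     stride: int | None = None) -> DisplacementEstimate:
    """Per-window subpixel displacement from cross-correlation peaks.

    Windows with (near-)zero variance are flagged invalid rather than
    raising.  ``upsample`` refines the correlation peak by local Fourier
    upsampling; displacements are the motion of features from ``image_a``
    to ``image_b`` in pixels.
    """
    from skimage.registration import phase_cross_correlation

    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    half = window // 2
    step = stride or max(half, 1)
    rows = np.arange(half, a.shape[0] - half, step)
    cols = np.arange(half, a.shape[1] - half, step)
    centers, shifts, valid = [], [], []
    for r in rows:
        for c in cols:
            wa = a[r - half:r + half + 1, c - half:c + half + 1]
            wb = b[r - half:r + half + 1, c - half:c + half + 1]
            centers.append((r, c))
            if wa.std() < 1e-12 * (abs(wa).max() + 1e-300) or wa.std() == 0:
                shifts.append((np.nan, np.nan))
                valid.append(False)
                continue
            shift, _, _ = phase_cross_correlation(
                wa, wb, upsample_factor=upsample, normalization=None)
            # phase_cross_correlation returns the registration shift of b
            # onto a; feature motion is its negative
            shifts.append(tuple(-shift))
            valid.append(True)
    return DisplacementEstimate(centers=np.asarray(centers, dtype=float),
                                shifts_px=np.asarray(shifts, dtype=float),
                                valid=np.asarray(valid, dtype=bool))


def align_rigid(src: np.ndarray, dst: np.ndarray):
    """Rigid (rotation + translation) alignment from matched landmark pairs."""
    from skimage.transform import EuclideanTransform

    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if hasattr(EuclideanTransform, "from_estimate"):
        tf = EuclideanTransform.from_estimate(src, dst)
        if not tf:
            raise ValueError("rigid alignment failed")
        return tf
    tf = EuclideanTransform()
    if not tf.estimate(src, dst):
        raise ValueError("rigid alignment failed")
    return tf


# ---------------------------------------------------------------------------
# Deflection-profile metrics
# ---------------------------------------------------------------------------

@dataclass
class DeflectionProfile:
    """BM deflection across the radial width under a known pressure."""

    positions_um: np.ndarray
    displacement_nm: np.ndarray
    pressure_pa: float
    bm_width_um: float

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")


def bm_profile(field: DisplacementField, section: int | None = None,
               pressure_pa: float = 1.0) -> DeflectionProfile:
    """Transverse BM deflection profile of one section of a solved field."""
    system = field.system
    s = section if section is not None else system.mid_section
    sec = system.sections[s]
    pos = sec.nodes[:13, 0]
    disp = np.array([field.values[system.dof(s, n, 1)] for n in range(13)])
    disp = np.real(disp) if field.frequency == 0 else np.abs(disp)
    return DeflectionProfile(positions_um=pos, displacement_nm=disp * 1e9,
                             pressure_pa=pressure_pa,
                             bm_width_um=sec.bm_width)


def volume_compliance(profile: DeflectionProfile) -> tuple[float, float]:
    """(peak compliance nm/Pa, volume compliance mm^4/N).

    Volume compliance is the area between the deformed and undeformed BM
    (trapezoid rule) divided by the applied pressure.
    """
    if profile.pressure_pa == 0:
        raise ValueError("pressure must be nonzero")
    peak = float(np.max(np.abs(profile.displacement_nm)) /
                 abs(profile.pressure_pa))
    area_m2 = abs(np.trapezoid(profile.displacement_nm * 1e-9,
                               profile.positions_um * 1e-6))
    volume = area_m2 / abs(profile.pressure_pa) / 1e-12  # -> mm^4/N
    return peak, volume


def fwhm_fraction(profile: DeflectionProfile) -> float:
    """Full width at half maximum of the deflection, over the BM width.

    Crossings are located by linear interpolation; if several disjoint
    half-max regions exist, the one containing the peak is used.
    """
    y = np.abs(profile.displacement_nm)
    x = profile.positions_um
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0
    if y[ipk] == 0:
        raise ValueError("profile is identically zero")

    def cross(i0: int, direction: int) -> float:
        i = i0
        while 0 <= i + direction < len(y):
            j = i + direction
            if y[j] < half <= y[i]:
                frac = (y[i] - half) / (y[i] - y[j])
                return x[i] + frac * (x[j] - x[i])
            i = j
        return x[0] if direction < 0 else x[-1]

    left = cross(ipk, -1)
    right = cross(ipk, +1)
    return float((right - left) / profile.bm_width_um)


# ---------------------------------------------------------------------------
# Model-probing metrics
# ---------------------------------------------------------------------------

def contact_stiffness(system: AssembledSystem, node: int | None = None,
                      section: int | None = None) -> float:
    """Point-force-to-local-displacement stiffness at a BM node, in mN/m.

    Applies a unit transverse point force at the node (default: the
    first-row Deiters-cell root, where the pressure-driven peak occurs) and
    returns force over co-located displacement.
    """
    s = section if section is not None else system.mid_section
    n = node if node is not None else DC_ROOTS[0]
    d = system.dof(s, n, 1)
    if system.fixed[d]:
        raise ValueError(f"BM node {n} is constrained")
    f = np.zeros(system.n_dofs)
    f[d] = 1e-9  # 1 nN, well within the linear regime
    field = solve_point_load(system, f, label="contact probe")
    return float(f[d] / field.values[d] * 1e3)


def _motion(field: DisplacementField, section: int, node: int) -> MotionVector:
    d_r, d_t = field.motion(section, node)
    return MotionVector(complex(d_r), complex(d_t))


def _axial_change(field: DisplacementField, section: int, n_from: int,
                  n_to: int) -> complex:
    """Complex end-to-end length change of the segment n_from -> n_to."""
    sec = field.system.sections[section]
    axis = sec.nodes[n_to] - sec.nodes[n_from]
    axis = axis / np.linalg.norm(axis)
    du = field.motion(section, n_to) - field.motion(section, n_from)
    return complex(du @ axis)


def deformation_ratio_tm(field: DisplacementField,
                         section: int | None = None
                         ) -> tuple[float, float]:
    """(Delta_TM / Delta_HB, theta_TM in degrees).

    Delta_TM is the radial elongation of the TM between the limbal
    attachment and the point above the second-row bundle (end-to-end);
    Delta_HB the bundle deflection from the TM-RL relative motion;
    theta_TM the major-axis direction of the TM point's motion.
    """
    s = section if section is not None else field.system.mid_section
    d_tm = abs(_axial_change(field, s, N_TM_ATTACH, N_TM_HB2))
    u_tm = _motion(field, s, N_TM_HB2)
    u_rl = _motion(field, s, N_OHC2_APEX)
    d_hb = hair_bundle_deflection(u_tm, u_rl)
    if d_hb == 0:
        raise ZeroDivisionError("hair-bundle deflection is zero")
    return d_tm / d_hb, u_tm.major_axis.theta_deg


def deformation_ratio_dc(field: DisplacementField,
                         section: int | None = None
                         ) -> tuple[float, float]:
    """(Delta_DC / Delta_OHC, theta_DC in degrees) at the first OHC row.

    Delta_OHC is the axial length change apex -> OHC/DC joint, Delta_DC the
    axial length change joint -> DC root; theta_DC the major-axis angle of
    the joint's motion.
    """
    s = section if section is not None else field.system.mid_section
    d_ohc = abs(_axial_change(field, s, N_OHC1_APEX, N_JOINT1))
    d_dc = abs(_axial_change(field, s, N_JOINT1, DC_ROOTS[0]))
    if d_ohc == 0:
        raise ZeroDivisionError("OHC deformation is zero")
    theta = _motion(field, s, N_JOINT1).major_axis.theta_deg
    return d_dc / d_ohc, theta


def stiffness_felt_by_ohc(system: AssembledSystem, section: int | None = None,
                          row: int = 1, f_ohc: float = 1e-9) -> float:
    """Scaffold stiffness felt by an actuating OHC: f/Delta_OHC - k_OHC (mN/m).

    A unit force couple contracts the selected OHC; the surrounding-structure
    stiffness is the couple force over the resulting cell shortening minus
    the cell's own axial stiffness.
    """
    s = section if section is not None else system.mid_section
    load = apply_ohc_force_couple(system, (s, s + 1), rows=(row,),
                                  f_ohc=f_ohc)
    field = solve_point_load(system, load, label="OHC force couple")
    d_ohc = abs(_axial_change(field, s, N_OHC1_APEX, N_JOINT1))
    if d_ohc == 0:
        raise ZeroDivisionError("OHC axial deformation is zero")
    sec = system.sections[s]
    ohc_el = next(el for el in sec.elements if el.role == "ohc-row1")
    k_ohc = element_stiffness(ohc_el, sec.nodes)[0]  # mN/m
    return f_ohc / d_ohc * 1e3 - k_ohc


# ---------------------------------------------------------------------------
# Frequency-response summaries
# ---------------------------------------------------------------------------

def corner_frequency(frequencies: np.ndarray, amplitudes: np.ndarray) -> float:
    """-3 dB point of the amplitude relative to the low-frequency asymptote.

    Returns the highest frequency at which the amplitude crosses
    ``A(f_min)/sqrt(2)`` from above, located by log-log interpolation.
    """
    f = np.asarray(frequencies, dtype=float)
    a = np.abs(np.asarray(amplitudes))
    target = a[0] / math.sqrt(2.0)
    above = a >= target
    if above.all():
        return float(f[-1])
    idx = np.nonzero(above)[0][-1]
    if idx == len(f) - 1:
        return float(f[-1])
    la = np.log(a[idx: idx + 2])
    lf = np.log(f[idx: idx + 2])
    frac = (math.log(target) - la[0]) / (la[1] - la[0])
    return float(np.exp(lf[0] + frac * (lf[1] - lf[0])))


def hf_slope_db_per_octave(frequencies: np.ndarray, amplitudes: np.ndarray,
                           band: tuple[float, float]) -> float:
    """Least-squares amplitude slope in dB/octave within ``band`` (Hz)."""
    f = np.asarray(frequencies, dtype=float)
    a = np.abs(np.asarray(amplitudes))
    sel = (f >= band[0]) & (f <= band[1])
    if sel.sum() < 2:
        raise ValueError("need at least two points in the fitting band")
    return float(np.polyfit(np.log2(f[sel]), 20 * np.log10(a[sel]), 1)[0])


def phase_accumulation_deg(frequencies: np.ndarray,
                           values: np.ndarray) -> float:
    """Unwrapped phase drop from the lowest to the highest frequency (deg)."""
    ph = np.unwrap(np.angle(np.asarray(values)))
    return float(np.degrees(ph[0] - ph[-1]))
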