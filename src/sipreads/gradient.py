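"""Isopycnic CsCl gradient physics.

This module implements the physical model of DNA banding in an equilibrium
cesium chloride density gradient spun in a fixed-angle rotor:

* buoyant density (BD) of a DNA fragment from its G+C content,
* the BD shift caused by heavy-isotope (13C/15N) incorporation,
* diffusive band broadening around the equilibrium BD,
* the mapping between BD and radial position in the spinning tube, and
* the range of tube-wall positions (and hence BDs) touched by a band,
  which determines where diffusive-boundary-layer (DBL) DNA ends up
  after the gradient reorients during deceleration.

The model gradient is analytic: BD as a function of radial distance from
the axis of rotation is the exact algebraic inverse of the equilibrium
position equation, so ``position_to_bd`` and ``equilibrium_position`` are
inverses to machine precision.  A tabulated variant
(:class:`ModelGradientTable`) is provided for parity checks against
interpolation-based pipelines.

Units: lengths in cm, densities in g/ml, temperature in K, angular
velocity in rad/s, angles in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DomainError, GeometryError, OutOfGradientError

__all__ = [
    "DELTA_BD",
    "GradientParams",
    "BDWindow",
    "DBLRange",
    "theoretical_bd",
    "labeled_bd",
    "diffusion_sigma",
    "isoconcentration_point",
    "equilibrium_position",
    "position_to_bd",
    "dbl_position_range",
    "ModelGradientTable",
]

#: Maximal BD increase (g/ml) at 100% atom % excess, by isotope.
DELTA_BD: dict[str, float] = {"13C": 0.036, "15N": 0.016}


@dataclass(frozen=True)
class GradientParams:
    """Physical constants, centrifugation conditions and tube geometry.

    Defaults describe a standard DNA-SIP setup: a TLA-110-like fixed-angle
    rotor (28 degrees from the axis of rotation) spun at 55,000 rpm at
    20 C with an average gradient density of 1.70 g/ml.

    Parameters
    ----------
    temperature : float
        Centrifugation temperature in kelvin.
    avg_density : float
        Average density of the gradient solution, g/ml.
    angular_velocity : float
        Rotor angular velocity, rad/s.
    r_min, r_max : float
        Minimum/maximum distance (cm) from the axis of rotation to the tube.
    tube_radius : float
        Internal radius of the ultracentrifuge tube, cm.
    tube_angle : float
        Angle of the tube relative to the axis of rotation, radians.
    beta : float
        Proportionality constant of aqueous CsCl.
    buoyancy_factor : float
        Buoyancy factor G of DNA in CsCl.
    base_pair_mass : float
        Mean molar mass of a nucleotide base pair in CsCl solution, g/mol.
    gas_constant : float
        Universal gas constant, J/(mol K).
    """

    temperature: float = 293.15
    avg_density: float = 1.70
    angular_velocity: float = 55000.0 * 2.0 * math.pi / 60.0
    r_min: float = 2.6
    r_max: float = 4.85
    tube_radius: float = 0.65
    tube_angle: float = math.radians(28.0)
    beta: float = 1.14e9
    buoyancy_factor: float = 7.87e-10
    base_pair_mass: float = 882.0
    gas_constant: float = 8.314

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ConfigurationError(
                f"require 0 < r_min < r_max, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.tube_radius <= 0:
            raise ConfigurationError(f"tube_radius must be positive, got {self.tube_radius}")
        if not (0 < self.tube_angle <= math.pi / 2):
            raise ConfigurationError(
                f"tube_angle must lie in (0, pi/2] radians, got {self.tube_angle}"
            )
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be positive, got {self.temperature}")
        if self.angular_velocity <= 0:
            raise ConfigurationError(
                f"angular_velocity must be positive, got {self.angular_velocity}"
            )
        if self.avg_density <= 1:
            raise ConfigurationError(
                f"avg_density must exceed 1 g/ml, got {self.avg_density}"
            )

    @property
    def isoconcentration(self) -> float:
        """Isoconcentration point I (cm) for this geometry."""
        return isoconcentration_point(self.r_min, self.r_max)


@dataclass(frozen=True)
class BDWindow:
    """A buoyant-density interval to be recovered/sequenced.

    Infinite bounds are permitted (the whole-gradient limit used in
    conservation checks).
    """

    rho_min: float
    rho_max: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.rho_min < self.rho_max:
            raise ConfigurationError(
                f"window requires rho_min < rho_max, got ({self.rho_min}, {self.rho_max})"
            )

    @property
    def width(self) -> float:
        return self.rho_max - self.rho_min

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.rho_min + self.rho_max)

    def contains(self, rho: float) -> bool:
        return self.rho_min <= rho < self.rho_max


@dataclass(frozen=True)
class DBLRange:
    """Range of tube positions and BDs contaminated by a fragment's DBL.

    ``x_min``/``x_max`` are positions along the tube wall measured from the
    bottom tip (cm); ``rho_dbl_min``/``rho_dbl_max`` are the corresponding
    model-gradient BD bounds after reorientation.
    """

    x_min: float
    x_max: float
    rho_dbl_min: float
    rho_dbl_max: float

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise GeometryError(f"DBL range requires x_min < x_max, got ({self.x_min}, {self.x_max})")
        if not self.rho_dbl_min < self.rho_dbl_max:
            raise GeometryError(
                f"DBL range requires rho_dbl_min < rho_dbl_max, "
                f"got ({self.rho_dbl_min}, {self.rho_dbl_max})"
            )

    @property
    def bd_width(self) -> float:
        return self.rho_dbl_max - self.rho_dbl_min


def theoretical_bd(gc):
    """Theoretical buoyant density (g/ml) of unlabeled DNA from G+C content.

    BD is linear in the G+C fraction: ``0.098 * gc + 1.66``.

    Parameters
    ----------
    gc : float or ndarray
        G+C content as a fraction in [0, 1].
    """
    gc = np.asarray(gc, dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise DomainError(f"G+C fraction must lie in [0, 1], got {gc}")
    out = 0.098 * gc + 1.66
    return float(out) if out.ndim == 0 else out


def labeled_bd(rho_t, atom_excess, isotope: str = "13C"):
    """Isotope-adjusted buoyant density: ``rho_t + A * delta``.

    ``delta`` is the BD increase at 100% atom % excess: 0.036 g/ml for 13C
    and 0.016 g/ml for 15N.

    Parameters
    ----------
    rho_t : float or ndarray
        Theoretical (unlabeled) BD, g/ml.
    atom_excess : float or ndarray
        Atom % excess as a fraction in [0, 1] (1.0 = fully labeled).
    isotope : {"13C", "15N"}
    """
    if isotope not in DELTA_BD:
        raise ConfigurationError(
            f"unknown isotope {isotope!r}; expected one of {sorted(DELTA_BD)}"
        )
    atom_excess = np.asarray(atom_excess, dtype=float)
    if np.any((atom_excess < 0) | (atom_excess > 1)):
        raise DomainError(f"atom excess fraction must lie in [0, 1], got {atom_excess}")
    out = np.asarray(rho_t, dtype=float) + atom_excess * DELTA_BD[isotope]
    return float(out) if out.ndim == 0 else out


def diffusion_sigma(rho, length_bp, params: GradientParams):
    """Standard deviation (g/ml) of a fragment's BD due to diffusion.

    ``sigma = sqrt(rho * R * T / (beta^2 * G * M_c * l))`` -- band width
    shrinks with the square root of fragment length ``l``.
    """
    rho = np.asarray(rho, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp < 1):
        raise DomainError(f"fragment length must be >= 1 bp, got {length_bp}")
    if np.any(rho <= 0):
        raise DomainError(f"buoyant density must be positive, got {rho}")
    out = np.sqrt(
        rho
        * params.gas_constant
        * params.temperature
        / (params.beta**2 * params.buoyancy_factor * params.base_pair_mass * length_bp)
    )
    return float(out) if out.ndim == 0 else out


def isoconcentration_point(r_min: float, r_max: float) -> float:
    """Isoconcentration point I (cm): the radius where solution density
    equals the average loading density.

    ``I = sqrt((r_min^2 + r_min*r_max + r_max^2) / 3)``.
    """
    if r_min <= 0 or r_max <= 0:
        raise DomainError(f"radii must be positive, got r_min={r_min}, r_max={r_max}")
    return math.sqrt((r_min**2 + r_min * r_max + r_max**2) / 3.0)


def equilibrium_position(rho, params: GradientParams):
    """Radial distance x (cm) from the axis of rotation where a fragment
    of buoyant density ``rho`` bands at equilibrium.

    ``x = sqrt(2*beta*(rho - D)/omega^2 + I^2)``; strictly increasing in rho.

    Raises
    ------
    OutOfGradientError
        If ``rho`` is so far below the average density that the radicand
        is negative (the fragment floats off-gradient).
    """
    rho_arr = np.asarray(rho, dtype=float)
    radicand = (
        2.0 * params.beta * (rho_arr - params.avg_density) / params.angular_velocity**2
        + params.isoconcentration**2
    )
    if np.any(radicand < 0):
        bad = float(np.min(rho_arr)) if rho_arr.ndim else float(rho_arr)
        raise OutOfGradientError(bad)
    out = np.sqrt(radicand)
    return float(out) if out.ndim == 0 else out


def position_to_bd(x, params: GradientParams):
    """Model-gradient BD (g/ml) at radial position ``x`` (cm).

    Algebraic inverse of :func:`equilibrium_position`:
    ``rho = D + omega^2 * (x^2 - I^2) / (2*beta)``; strictly increasing in x.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0):
        raise GeometryError(f"radial position must be positive, got {x}")
    out = (
        params.avg_density
        + params.angular_velocity**2
        * (x_arr**2 - params.isoconcentration**2)
        / (2.0 * params.beta)
    )
    return float(out) if out.ndim == 0 else out


def _tube_wall_contact(x: float, params: GradientParams) -> tuple[float, float]:
    """Tube-wall contact range [s_min, s_max] of the band at radius ``x``.

    Positions are measured along the tube axis from the bottom tip.  Each
    bound independently uses the cylindrical-section formula while its
    value stays above the cylinder/hemisphere junction at s = r_t, and the
    rounded-bottom formula below it; the two formulas agree exactly at the
    junction.
    """
    rt = params.tube_radius
    theta = params.tube_angle
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    r_axis_bottom = params.r_max - rt  # radius of the tube-axis point at the hemisphere center

    # s_min: near-wall (deep) contact.  Cylindrical while x <= r_axis_bottom - rt*cos(theta).
    if x <= r_axis_bottom - rt * cos_t:
        s_min = rt + (params.r_max - rt * cos_t - rt - x) / sin_t
    else:
        q = (x - params.r_max + rt) / rt
        s_min = rt - rt * math.cos(theta - math.asin(q))

    # s_max: far-wall (shallow) contact.  Cylindrical while x <= r_axis_bottom + rt*cos(theta).
    if x <= r_axis_bottom + rt * cos_t:
        s_max = rt + (params.r_max + rt * cos_t - rt - x) / sin_t
    else:
        q = (x - params.r_max + rt) / rt
        s_max = rt - rt * math.cos(theta - math.pi + math.asin(q))

    return s_min, s_max


def _tube_length(params: GradientParams) -> float:
    """Tube length (cm) from the bottom tip to the level where the tube
    axis reaches r_min."""
    return params.tube_radius + (
        params.r_max - params.tube_radius - params.r_min
    ) / math.sin(params.tube_angle)


def _level_radius_range(s: float, params: GradientParams) -> tuple[float, float]:
    """Extreme radial distances (shallow, deep) of lumen points at tube
    position ``s``.

    In the cylindrical section the lumen cross-section at level ``s`` spans
    radii ``c(s) +/- r_t*cos(theta)`` around the tube-axis radius ``c(s)``;
    in the rounded bottom the sphere cross-section gives the analogous
    extremes.  Mapping a wall-contact level through these extremes
    guarantees the resulting BD range brackets the BD of the band that
    produced the contact.
    """
    rt = params.tube_radius
    theta = params.tube_angle
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    c_bottom = params.r_max - rt
    if s >= rt:
        c = c_bottom - (s - rt) * sin_t
        lo, hi = c - rt * cos_t, c + rt * cos_t
    else:
        m = (rt - s) / rt
        half = math.sqrt(max(0.0, 1.0 - m * m)) * cos_t
        lo = c_bottom + rt * (m * sin_t - half)
        hi = c_bottom + rt * (m * sin_t + half)
    lo = min(max(lo, params.r_min), params.r_max)
    hi = min(max(hi, params.r_min), params.r_max)
    return lo, hi


def dbl_position_range(x: float, params: GradientParams) -> DBLRange:
    """Tube-position and BD range contaminated by the diffusive boundary
    layer of a band at radial position ``x``.

    The band at radius ``x`` touches the tube wall over a range of
    positions along the tube; DNA trapped there (the DBL) stays put while
    the gradient reorients, ending up spread over the BDs the model
    gradient assigns to those tube levels.

    Raises
    ------
    GeometryError
        If ``x`` lies outside the radial extent of the tube, naming the
        violated bound.
    """
    if x < params.r_min:
        raise GeometryError(
            f"position x={x:.6g} cm is above the tube top (violates r_min={params.r_min} cm)"
        )
    if x >= params.r_max:
        raise GeometryError(
            f"position x={x:.6g} cm is at/below the tube bottom (violates r_max={params.r_max} cm)"
        )
    s_min, s_max = _tube_wall_contact(x, params)
    length = _tube_length(params)
    s_min = min(max(s_min, 0.0), length)
    s_max = min(max(s_max, 0.0), length)
    # Radii decrease with tube position, so the deep contact (s_min) sets
    # the high-BD bound and the shallow contact (s_max) the low-BD bound.
    rho_hi = position_to_bd(_level_radius_range(s_min, params)[1], params)
    rho_lo = position_to_bd(_level_radius_range(s_max, params)[0], params)
    # The trapped layer at the contact point sits in solution of the band's
    # own density, so the DBL BD range always contains it.
    rho_band = position_to_bd(x, params)
    rho_hi = max(rho_hi, rho_band)
    rho_lo = min(rho_lo, rho_band)
    return DBLRange(x_min=s_min, x_max=s_max, rho_dbl_min=rho_lo, rho_dbl_max=rho_hi)


class ModelGradientTable:
    """Tabulated model gradient (BD vs radial position) for parity checks.

    Linearly interpolates a table built from the analytic gradient at a
    configurable radial step.  Intended for verifying that a lookup-table
    gradient reproduces the analytic mapping to within table resolution.
    """

    def __init__(self, params: GradientParams, step: float = 1e-3):
        if step <= 0:
            raise ConfigurationError(f"table step must be positive, got {step}")
        self.params = params
        self.step = step
        n = max(2, int(math.ceil((params.r_max - params.r_min) / step)) + 1)
        self.positions = np.linspace(params.r_min, params.r_max, n)
        self.densities = position_to_bd(self.positions, params)

    def bd_at(self, x) -> float:
        x_arr = np.asarray(x, dtype=float)
        if np.any((x_arr < self.positions[0]) | (x_arr > self.positions[-1])):
            raise GeometryError(f"position {x} outside tabulated range")
        out = np.interp(x_arr, self.positions, self.densities)
        return float(out) if out.ndim == 0 else out

    def position_at(self, rho) -> float:
        rho_arr = np.asarray(rho, dtype=float)
        if np.any((rho_arr < self.densities[0]) | (rho_arr > self.densities[-1])):
            raise OutOfGradientError(float(np.min(rho_arr)))
        out = np.interp(rho_arr, self.densities, self.positions)
        return float(out) if out.ndim == 0 else out
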