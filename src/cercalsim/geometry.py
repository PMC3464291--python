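"""Geometry of the modeled cercal segment: a right circular cone frustum.

The basal segment of a cricket cercus is modeled as a cone frustum, and all
plots and coordinates refer to its "filet" representation: the surface cut
along the medial lineage-restriction line and unrolled flat.  The flattened
sheet is a trapezoid whose x axis is the lateral restriction line (axial
position along the cercus, base at 0) and whose local height equals the local
circumference of the cone.

Surface coordinates are ``(axial, circum)`` with ``axial`` in mm and
``circum`` a signed circumferential fraction in (-1, 1]: 0 on the lateral
line, +-1 (the same physical line) on the medial line.  Distances between
surface points are geodesic distances on the cone, computed either by the
closed-form unrolling construction (:func:`geodesic_analytic`) or by chord
summation along a discretized path (:func:`geodesic_numeric`), mirroring the
numerical scheme used to generate the published simulations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ConeDomain",
    "SurfacePoint",
    "DomainError",
    "canonical_circum",
    "canonical_angle",
    "local_height",
    "to_3d",
    "geodesic_analytic",
    "geodesic_numeric",
]


class DomainError(ValueError):
    """A coordinate falls outside the modeled cercal segment."""


def canonical_circum(circum):
    """Wrap a circumferential fraction into the canonical range (-1, 1].

    -1 and +1 denote the same physical point (the medial line); the canonical
    representative is +1.
    """
    return 1.0 - np.mod(1.0 - np.asarray(circum, dtype=float), 2.0)


def canonical_angle(theta_deg):
    """Wrap an angle in degrees into (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(theta_deg, dtype=float), 360.0)


class SurfacePoint(NamedTuple):
    """A point on the cercal surface: axial position (mm) and signed
    circumferential fraction (0 = lateral line, +-1 = medial line)."""

    axial: float
    circum: float

    def canonical(self) -> "SurfacePoint":
        return SurfacePoint(float(self.axial), float(canonical_circum(self.circum)))


@dataclass(frozen=True)
class ConeDomain:
    """The modeled cercal segment.

    Defaults describe the basal 5.2 mm of an adult cercus: diameter 0.54 mm at
    the base tapering to 0.26 mm, with the flattened sheet's height tapering
    from 1.7 mm to 0.8 mm (the local circumference).

    All lengths in mm.
    """

    axial_length: float = 5.2
    base_radius: float = 0.27
    tip_radius: float = 0.13
    base_height_flat: float = 1.7
    tip_height_flat: float = 0.8

    def __post_init__(self):
        if not self.axial_length > 0:
            raise ValueError("axial_length must be positive")
        if not (self.base_radius > self.tip_radius > 0):
            raise ValueError("require base_radius > tip_radius > 0")
        for name, h, r in (
            ("base", self.base_height_flat, self.base_radius),
            ("tip", self.tip_height_flat, self.tip_radius),
        ):
            circ = 2.0 * math.pi * r
            if abs(h - circ) / circ > 0.03:
                warnings.warn(
                    f"{name}_height_flat={h} differs from the local circumference "
                    f"2*pi*r={circ:.4f} by more than 3%; the flattened trapezoid is "
                    "inconsistent with the cone radii",
                    stacklevel=3,
                )

    # --- derived cone constants -------------------------------------------
    @property
    def radius_slope(self) -> float:
        """dr/dx along the axis (negative: the cone narrows)."""
        return (self.tip_radius - self.base_radius) / self.axial_length

    @property
    def apex_axial(self) -> float:
        """Axial coordinate of the (virtual) cone apex, beyond the tip end."""
        return self.base_radius * self.axial_length / (self.base_radius - self.tip_radius)

    @property
    def slant_factor(self) -> float:
        """Slant length per unit axial length, sqrt(1 + (dr/dx)^2)."""
        return math.hypot(1.0, self.radius_slope)

    @property
    def sector_factor(self) -> float:
        """sin(half apex angle): ratio of unrolled-sector angle to azimuth."""
        return abs(self.radius_slope) / self.slant_factor

    @property
    def area(self) -> float:
        """Area of the flattened trapezoid, mm^2."""
        return 0.5 * (self.base_height_flat + self.tip_height_flat) * self.axial_length

    # --- coordinate helpers -----------------------------------------------
    def radius(self, axial):
        return self.base_radius + self.radius_slope * np.asarray(axial, dtype=float)

    def slant_rho(self, axial):
        """Distance from the apex along the surface (unrolling radius)."""
        return (self.apex_axial - np.asarray(axial, dtype=float)) * self.slant_factor

    def contains(self, axial, circum=0.0) -> bool:
        ax = np.asarray(axial, dtype=float)
        return bool(np.all((ax >= 0.0) & (ax <= self.axial_length)))

    def check_axial(self, axial):
        ax = np.asarray(axial, dtype=float)
        if np.any((ax < 0.0) | (ax > self.axial_length)):
            raise DomainError(
                f"axial coordinate outside [0, {self.axial_length}] mm"
            )
        return ax


def local_height(domain: ConeDomain, axial):
    """Height of the flattened sheet (local circumference) at ``axial``, mm.

    Linear taper from ``base_height_flat`` to ``tip_height_flat``.
    """
    ax = domain.check_axial(axial)
    t = ax / domain.axial_length
    return domain.base_height_flat + (domain.tip_height_flat - domain.base_height_flat) * t


def to_3d(domain: ConeDomain, p: SurfacePoint) -> np.ndarray:
    """Embed a surface point in 3-D: x along the cone axis (0 = base), the
    lateral line (circum = 0) in the x-y plane at +y, azimuth = pi * circum."""
    ax, ci = p
    domain.check_axial(ax)
    return np.asarray(embed_3d(domain, ax, ci), dtype=float)


def embed_3d(domain: ConeDomain, axial, circum):
    """Vectorized embedding; returns (x, y, z) arrays (no domain check)."""
    ax = np.asarray(axial, dtype=float)
    phi = np.pi * np.asarray(circum, dtype=float)
    r = domain.radius(ax)
    return ax, r * np.cos(phi), r * np.sin(phi)


def geodesic_analytic(domain: ConeDomain, p: SurfacePoint, q: SurfacePoint) -> float:
    """Exact geodesic distance on the cone by unrolling it into a planar
    annular sector about the apex; the geodesic is the chord in that plane,
    minimized over the two circumferential winding directions."""
    domain.check_axial(p[0])
    domain.check_axial(q[0])
    return float(geodesic_analytic_arrays(domain, p[0], p[1], q[0], q[1]))


def geodesic_analytic_arrays(domain: ConeDomain, ax1, ci1, ax2, ci2):
    """Vectorized closed-form geodesic distance (broadcasts; no domain check)."""
    rho1 = domain.slant_rho(ax1)
    rho2 = domain.slant_rho(ax2)
    dci = np.asarray(ci1, dtype=float) - np.asarray(ci2, dtype=float)
    c = domain.sector_factor
    # Two winding choices around the cone; the unrolled sector spans < pi of
    # planar angle, so the chord through the smaller |dci| always wins, but we
    # evaluate both explicitly.
    dci0 = dci - 2.0 * np.round(dci / 2.0)  # wrapped into [-1, 1]
    dci1 = dci0 - np.sign(dci0 + (dci0 == 0)) * 2.0  # the long way round
    out = None
    for d in (dci0, dci1):
        ang = np.pi * d * c
        chord = np.sqrt(
            np.maximum(rho1**2 + rho2**2 - 2.0 * rho1 * rho2 * np.cos(ang), 0.0)
        )
        out = chord if out is None else np.minimum(out, chord)
    return out


def geodesic_numeric(
    domain: ConeDomain, p: SurfacePoint, q: SurfacePoint, steps: int = 100
) -> float:
    """Geodesic distance approximated by chord summation.

    For each winding direction the straight segment from ``p`` to ``q`` in
    (axial, unwrapped circumferential fraction) parameter space is split into
    ``steps`` equal increments; the nodes are embedded in 3-D and Euclidean
    chord lengths summed.  Returns the shorter of the two windings.  100 steps
    match the published simulations' discretization and agree with
    :func:`geodesic_analytic` to better than 1%.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    ax1, ci1 = p
    ax2, ci2 = q
    domain.check_axial(ax1)
    domain.check_axial(ax2)
    dci = ci2 - ci1
    dci0 = dci - 2.0 * round(dci / 2.0)
    dci1 = dci0 - (2.0 if dci0 > 0 else -2.0) if dci0 != 0 else 2.0
    t = np.linspace(0.0, 1.0, steps + 1)
    best = math.inf
    for d in (dci0, dci1):
        ax = ax1 + t * (ax2 - ax1)
        ci = ci1 + t * d
        x, y, z = embed_3d(domain, ax, ci)
        length = float(
            np.sum(np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2 + np.diff(z) ** 2))
        )
        best = min(best, length)
    return best
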