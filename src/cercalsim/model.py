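"""Morphogen fields and the hair-array cost function.

Two hypothetical morphogens pattern the filiform hair array:

* **Morphogen S** (spacing) is secreted at every hair socket and decays
  first-order as it diffuses, so its steady-state concentration falls off as
  ``exp(-r / lambda)`` with geodesic distance ``r`` from the socket.  Because
  S inhibits nearby hairs, each unordered hair pair contributes
  ``exp(-r_ij / lambda)`` to the cost.  The decay distance ``lambda`` rises
  linearly from 0.2 mm at the cercus base to 0.4 mm at the end of the modeled
  segment, matching the measured basal-to-distal hair density gradient.

* **Morphogen M** (movement direction) is secreted along the medial and
  lateral lineage-restriction lines.  Its normalized concentration m(x) is a
  two-source exponential in the fractional distance x from the medial line
  (x = 0 medial, x = 1 lateral), rescaled so that m = 1 on both lines and
  m = 0 midway between them.  High concentration prescribes longitudinal
  movement axes (0 / 180 deg), low concentration transverse axes (+-90 deg);
  the prescribed axis is ``theta* = 90 * (1 - m)`` interpreted modulo 180.

A hair whose movement direction ``theta`` deviates from the prescribed axis
pays ``c1 * |sin(theta - theta*)|`` (so a 180-deg flip is free: the morphogen
sets the movement *plane*, not which direction along it excites the neuron).
A small ventral correction ``a*`` discounts that penalty by 10% for hairs at
positive angles in the ventral half, reproducing the observed ventral excess
of hairs.

The per-hair cost is ``E_i = sum_{j != i} exp(-r_ij/lambda) + angle term``
and the total cost is ``E = sum_i E_i`` (each unordered pair therefore
appears twice in E, once in E_i and once in E_j; the optimizer is invariant
to this factor of two).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

from .geometry import (
    ConeDomain,
    DomainError,
    SurfacePoint,
    canonical_angle,
    canonical_circum,
    geodesic_analytic_arrays,
)

__all__ = [
    "Hair",
    "HairConfiguration",
    "ModelParams",
    "lambda_s",
    "m_concentration",
    "prescribed_angle",
    "pair_cost",
    "angle_cost",
    "hair_cost",
    "total_cost",
    "delta_cost_move",
]


@dataclass(frozen=True)
class Hair:
    """One filiform hair: surface position and excitatory movement direction.

    ``theta`` is measured in the flattened sheet, degrees in (-180, 180];
    0 points toward the cercus tip along the +axial direction.
    """

    pos: SurfacePoint
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "pos", SurfacePoint(*self.pos).canonical())
        object.__setattr__(self, "theta", float(canonical_angle(self.theta)))


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    ``c1`` weights directional alignment against inter-hair spacing; ``a_star``
    is the ventral discount; ``p_iterations`` counts Monte Carlo proposals;
    ``lambda_base``/``lambda_tip`` set the morphogen-S decay length (mm) at the
    two ends of the segment; ``lambda_m`` is the morphogen-M decay constant in
    fractional-distance units; ``ventral_sign`` selects which circumferential
    half (sign of circum) is ventral.
    """

    n_hairs: int = 300
    c1: float = 10.0
    a_star: float = 0.1
    p_iterations: int = 100_000
    lambda_base: float = 0.2
    lambda_tip: float = 0.4
    lambda_m: float = 0.25
    ventral_sign: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_hairs < 0:
            raise ValueError("n_hairs must be non-negative")
        if self.c1 < 0:
            raise ValueError("c1 must be non-negative")
        if not 0 <= self.a_star < 1:
            raise ValueError("a_star must be in [0, 1)")
        if self.p_iterations < 0:
            raise ValueError("p_iterations must be non-negative")
        if min(self.lambda_base, self.lambda_tip, self.lambda_m) <= 0:
            raise ValueError("decay lengths must be positive")
        if self.ventral_sign not in (-1, 1):
            raise ValueError("ventral_sign must be +1 or -1")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


class HairConfiguration:
    """An ordered collection of hairs on a cone domain.

    Stored internally as parallel numpy arrays (axial, circum, theta) for
    vectorized cost evaluation; iterating yields :class:`Hair` objects.
    """

    def __init__(self, domain: ConeDomain, axial, circum, theta):
        self.domain = domain
        self.axial = np.atleast_1d(np.asarray(axial, dtype=float)).copy()
        self.circum = canonical_circum(np.atleast_1d(circum))
        self.theta = canonical_angle(np.atleast_1d(theta))
        if not (self.axial.shape == self.circum.shape == self.theta.shape):
            raise ValueError("axial, circum, theta must have equal lengths")
        domain.check_axial(self.axial)

    @classmethod
    def from_hairs(cls, domain: ConeDomain, hairs: Sequence[Hair]) -> "HairConfiguration":
        ax = [h.pos.axial for h in hairs]
        ci = [h.pos.circum for h in hairs]
        th = [h.theta for h in hairs]
        return cls(domain, ax, ci, th)

    @classmethod
    def empty(cls, domain: ConeDomain) -> "HairConfiguration":
        return cls(domain, np.empty(0), np.empty(0), np.empty(0))

    def __len__(self) -> int:
        return self.axial.size

    def __iter__(self) -> Iterator[Hair]:
        for a, c, t in zip(self.axial, self.circum, self.theta):
            yield Hair(SurfacePoint(a, c), t)

    def __getitem__(self, i: int) -> Hair:
        return Hair(SurfacePoint(self.axial[i], self.circum[i]), self.theta[i])

    def copy(self) -> "HairConfiguration":
        return HairConfiguration(self.domain, self.axial, self.circum, self.theta)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HairConfiguration)
            and self.domain == other.domain
            and np.array_equal(self.axial, other.axial)
            and np.array_equal(self.circum, other.circum)
            and np.array_equal(self.theta, other.theta)
        )

    def pairwise_distances(self) -> np.ndarray:
        """Dense (N, N) matrix of geodesic distances (zeros on the diagonal)."""
        return geodesic_analytic_arrays(
            self.domain,
            self.axial[:, None],
            self.circum[:, None],
            self.axial[None, :],
            self.circum[None, :],
        )


# --- morphogen S -----------------------------------------------------------

def lambda_s(params: ModelParams, domain: ConeDomain, axial):
    """Morphogen-S decay length at an axial position: linear from
    ``lambda_base`` at the base to ``lambda_tip`` at the segment end, mm."""
    ax = domain.check_axial(axial)
    t = ax / domain.axial_length
    return params.lambda_base + (params.lambda_tip - params.lambda_base) * t


def pair_cost(params: ModelParams, domain: ConeDomain, h_i: Hair, h_j: Hair) -> float:
    """Spacing cost of one hair pair: exp(-r_ij / lambda), with lambda
    evaluated at the pair's mean axial coordinate.  Symmetric, in (0, 1]."""
    r = geodesic_analytic_arrays(
        domain, h_i.pos.axial, h_i.pos.circum, h_j.pos.axial, h_j.pos.circum
    )
    lam = lambda_s(params, domain, 0.5 * (h_i.pos.axial + h_j.pos.axial))
    return float(np.exp(-r / lam))


# --- morphogen M -----------------------------------------------------------

def m_concentration(params: ModelParams, x):
    """Normalized morphogen-M concentration at fractional distance ``x`` from
    the medial restriction line (x = 0 medial, x = 1 lateral).

    Two-source exponential, min-max rescaled: m(0) = m(1) = 1, m(0.5) = 0.
    """
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0.0) | (xa > 1.0)):
        raise DomainError("fractional distance x must be in [0, 1]")
    lm = params.lambda_m
    raw = np.exp(-xa / lm) + np.exp(-(1.0 - xa) / lm)
    raw0 = 1.0 + np.exp(-1.0 / lm)
    raw_half = 2.0 * np.exp(-0.5 / lm)
    out = (raw - raw_half) / (raw0 - raw_half)
    return out if out.ndim else float(out)


def x_medial(circum):
    """Fractional distance from the medial line: 1 - |circum|."""
    return 1.0 - np.abs(canonical_circum(circum))


def prescribed_angle(params: ModelParams, p: SurfacePoint):
    """Movement axis prescribed by morphogen M at ``p``, degrees modulo 180.

    0 (longitudinal) on both restriction lines, 90 (transverse) midway.
    """
    return float(prescribed_angle_arrays(params, p[1]))


def prescribed_angle_arrays(params: ModelParams, circum):
    return 90.0 * (1.0 - m_concentration(params, x_medial(circum)))


# --- cost function ---------------------------------------------------------

def _angle_cost_arrays(params: ModelParams, circum, theta):
    """Vectorized alignment cost c1 * (1 - a* V) * |sin(theta - theta*)|."""
    th_star = prescribed_angle_arrays(params, circum)
    dev = np.abs(np.sin(np.deg2rad(np.asarray(theta, dtype=float) - th_star)))
    ci = canonical_circum(circum)
    ventral = (np.asarray(theta) > 0) & (ci * params.ventral_sign > 0)
    return params.c1 * (1.0 - params.a_star * ventral) * dev


def angle_cost(params: ModelParams, h: Hair) -> float:
    """Alignment cost of one hair, in [0, c1].

    The sine of the angle difference means 180-deg flips are free, and the
    ventral discount ``a_star`` applies to positive-angle hairs in the ventral
    half (sign of circum equal to ``ventral_sign``).
    """
    return float(_angle_cost_arrays(params, h.pos.circum, h.theta))


def _pair_terms(params, config, D):
    """Matrix of pair costs exp(-r_ij / lambda_mid); diagonal zeroed."""
    mid = 0.5 * (config.axial[:, None] + config.axial[None, :])
    lam = lambda_s(params, config.domain, mid)
    T = np.exp(-D / lam)
    np.fill_diagonal(T, 0.0)
    return T


def hair_cost(params: ModelParams, config: HairConfiguration, i: int) -> float:
    """Cost of hair i: spacing terms against every other hair plus its own
    alignment term."""
    n = len(config)
    if not 0 <= i < n:
        raise IndexError(f"hair index {i} out of range for N={n}")
    r = geodesic_analytic_arrays(
        config.domain, config.axial[i], config.circum[i], config.axial, config.circum
    )
    lam = lambda_s(params, config.domain, 0.5 * (config.axial[i] + config.axial))
    terms = np.exp(-r / lam)
    terms[i] = 0.0
    return float(terms.sum() + _angle_cost_arrays(params, config.circum[i], config.theta[i]))


def total_cost(params: ModelParams, config: HairConfiguration) -> float:
    """Total cost E = sum_i E_i (each unordered pair counted twice)."""
    if len(config) == 0:
        return 0.0
    D = config.pairwise_distances()
    pair = _pair_terms(params, config, D).sum()
    ang = _angle_cost_arrays(params, config.circum, config.theta).sum()
    return float(pair + ang)


def delta_cost_move(
    params: ModelParams,
    config: HairConfiguration,
    i: int,
    new_pos: SurfacePoint,
    new_theta: float,
) -> float:
    """Change in E when hair i moves to ``new_pos`` with direction
    ``new_theta``, evaluated incrementally (O(N), not O(N^2))."""
    n = len(config)
    if not 0 <= i < n:
        raise IndexError(f"hair index {i} out of range for N={n}")
    new_pos = SurfacePoint(*new_pos).canonical()
    config.domain.check_axial(new_pos.axial)

    others = np.arange(n) != i
    ax_o, ci_o = config.axial[others], config.circum[others]

    def pair_sum(ax, ci):
        r = geodesic_analytic_arrays(config.domain, ax, ci, ax_o, ci_o)
        lam = lambda_s(params, config.domain, 0.5 * (ax + ax_o))
        return float(np.exp(-r / lam).sum())

    old_pairs = pair_sum(config.axial[i], config.circum[i])
    new_pairs = pair_sum(new_pos.axial, new_pos.circum)
    old_ang = float(_angle_cost_arrays(params, config.circum[i], config.theta[i]))
    new_ang = float(_angle_cost_arrays(params, new_pos.circum, new_theta))
    # each pair term appears in E_i and in E_j, hence the factor 2
    return 2.0 * (new_pairs - old_pairs) + (new_ang - old_ang)
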