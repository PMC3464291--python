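"""Assessment suite for hair arrays: Ripley's L, angle histograms, the
body-centric transform, peak counting, and the ventral/dorsal density ratio.

Ripley's L is the square-root-transformed Ripley's K,

    K(s) = A * sum_i sum_{j != i} 1[r_ij < s] / (N (N - 1)),   L = sqrt(K / pi)

with ``r_ij`` the geodesic distance on the cone and ``A`` the area of the
flattened trapezoid.  Under complete spatial randomness L(s) ~ s; values above
the diagonal indicate clustering, below it segregation (regular spacing).  No
edge correction is applied.  Note the circumferential direction wraps around
the cone: once the search radius exceeds roughly half the local circumference
(~0.6 mm) the geodesic "disc" self-overlaps and even a Poisson pattern falls
below the diagonal, so diagnostic window radii should stay below ~0.75 mm
(window diameters up to ~1.5 mm, the range shown in published comparisons).

Movement-direction histograms use 5-degree bins over (-180, 180], either in
the flattened frame (0 = toward the cercus tip) or transformed to the
body-centric frame (0 = directly anterior), which corrects for wrapping the
sheet onto the cone and for the cercus pointing 30 degrees out from the body
axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .geometry import canonical_angle
from .model import HairConfiguration

__all__ = [
    "RipleyCurve",
    "AngleHistogram",
    "StatisticError",
    "ripley_l",
    "ventral_dorsal_ratio",
    "flattened_histogram",
    "to_body_frame",
    "body_frame_angles",
    "count_peaks",
]

BIN_WIDTH_DEG = 5.0


class StatisticError(ValueError):
    """A statistic is undefined for the given configuration."""


@dataclass(frozen=True)
class RipleyCurve:
    """L(s) over a grid of search-window radii, with the Poisson reference
    (the diagonal L = s)."""

    radii: np.ndarray  # mm
    l_values: np.ndarray  # mm
    n_points: int
    area: float  # mm^2

    @property
    def diameters(self) -> np.ndarray:
        """Window diameters, the x axis used in published curves."""
        return 2.0 * self.radii

    @property
    def poisson_reference(self) -> np.ndarray:
        return np.asarray(self.radii)


@dataclass(frozen=True)
class AngleHistogram:
    """Binned movement-direction counts; 5-degree bins over (-180, 180]."""

    bin_edges: np.ndarray  # degrees, length n_bins + 1
    counts: np.ndarray
    frame: str  # "flattened" | "body_centric"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _bin_angles(theta_deg, frame: str) -> AngleHistogram:
    edges = np.arange(-180.0, 180.0 + BIN_WIDTH_DEG, BIN_WIDTH_DEG)
    counts, _ = np.histogram(np.asarray(theta_deg, dtype=float), bins=edges)
    return AngleHistogram(edges, counts, frame)


def ripley_l(config: HairConfiguration, radii) -> RipleyCurve:
    """Ripley's L over ``radii`` (positive, ascending), geodesic distances,
    unbiased N(N-1) normalization, no edge correction."""
    radii = np.asarray(radii, dtype=float)
    n = len(config)
    if n < 2:
        raise StatisticError("Ripley's L requires at least two hairs")
    if radii.size == 0 or np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly ascending")
    D = config.pairwise_distances()
    pair_d = np.sort(D[~np.eye(n, dtype=bool)])  # all ordered pairs
    counts = np.searchsorted(pair_d, radii, side="left")  # strict r < s
    area = config.domain.area
    k = area * counts / (n * (n - 1))
    return RipleyCurve(radii, np.sqrt(k / np.pi), n, area)


def ventral_dorsal_ratio(config: HairConfiguration, ventral_sign: int = 1) -> float:
    """Hair-count ratio ventral half / dorsal half (sign of circum); hairs
    exactly on the lateral line (circum = 0) are excluded from both."""
    s = np.sign(config.circum)
    ventral = int(np.sum(s == ventral_sign))
    dorsal = int(np.sum(s == -ventral_sign))
    if dorsal == 0:
        raise StatisticError("ventral/dorsal ratio undefined: empty dorsal half")
    return ventral / dorsal


def flattened_histogram(config: HairConfiguration) -> AngleHistogram:
    """5-degree histogram of movement directions in the flattened frame."""
    return _bin_angles(config.theta, "flattened")


def body_frame_angles(
    config: HairConfiguration, cercus_rotation: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Transform movement directions to the body-centric frame.

    Each hair's movement direction is a unit tangent to the cone (axial
    component ``cos(theta)`` along the slant, circumferential component
    ``sin(theta)``), embedded in 3-D, projected onto the horizontal plane
    (the plane holding the cercus axis and both restriction lines), converted
    to an azimuth with 0 = the unwrapped tip direction, and finally offset by
    ``cercus_rotation`` degrees for the cercus pointing out from the body axis
    (0 = directly anterior).  Hairs whose movement direction projects to a
    near-vertical (degenerate) vector are flagged and excluded.

    Returns ``(angles_deg, kept_mask)``; ``angles_deg`` has NaN at excluded
    hairs.
    """
    d = config.domain
    phi = np.pi * config.circum
    th = np.deg2rad(config.theta)
    m = d.radius_slope
    sq = d.slant_factor
    # tangent basis: u_ax along increasing axial (slant), u_circ along
    # increasing circum; frame: x = cone axis, y toward the lateral line,
    # z vertical
    tx = np.cos(th) / sq
    ty = np.cos(th) * m * np.cos(phi) / sq - np.sin(th) * np.sin(phi)
    horiz = np.hypot(tx, ty)
    kept = horiz >= 1e-6
    n_dropped = int(np.sum(~kept))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} hair(s) excluded from the body-frame transform: "
            "movement direction projects to a near-vertical vector",
            stacklevel=2,
        )
    angles = np.full(len(config), np.nan)
    beta = np.rad2deg(np.arctan2(ty[kept], tx[kept]))
    angles[kept] = canonical_angle(beta - cercus_rotation)
    return angles, kept


def to_body_frame(
    config: HairConfiguration, cercus_rotation: float = 30.0
) -> tuple[AngleHistogram, np.ndarray]:
    """Body-centric 5-degree histogram plus the per-hair transformed angles
    (NaN for degenerate, excluded hairs)."""
    angles, kept = body_frame_angles(config, cercus_rotation)
    return _bin_angles(angles[kept], "body_centric"), angles


def count_peaks(
    hist: AngleHistogram,
    smooth_window: int = 3,
    min_prominence_frac: float = 0.05,
) -> int:
    """Count distinct peaks of a circular angle histogram.

    Counts are circularly smoothed with a centered ``smooth_window``-bin
    moving average; a peak is a strict circular local maximum with prominence
    at least ``min_prominence_frac`` times the total count.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty histogram")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd bin count")
    n = counts.size
    kernel = np.ones(smooth_window) / smooth_window
    padded = np.concatenate([counts[-smooth_window:], counts, counts[:smooth_window]])
    smooth = np.convolve(padded, kernel, mode="same")[smooth_window : smooth_window + n]
    min_prom = min_prominence_frac * counts.sum()
    tiled = np.tile(smooth, 3)
    peaks, _ = find_peaks(tiled, prominence=max(min_prom, np.finfo(float).tiny))
    return int(np.sum((peaks >= n) & (peaks < 2 * n)))
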