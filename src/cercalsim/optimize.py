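"""Greedy Monte Carlo minimization of the hair-array cost function.

The search mirrors the published algorithm: seed N hairs uniformly at random
over the surface with uniform random movement directions, then repeat P times
(pick a random hair, offer it a new uniform-random location and a uniform
random rotation, accept iff the total cost strictly decreases).  P counts
proposals, accepted or not; the rule is strictly greedy (no temperature), so
the energy trace is non-increasing.  P regulates how much of the initial
randomness survives: P ~ 1e3 barely perturbs the random seed pattern, the
default P = 1e5 preserves some biological-looking noise, and P >~ 1e6
approaches the deterministic optimum.

Everything is driven by a single ``numpy.random.Generator`` seeded from
``ModelParams.seed``; identical seeds give bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import run_kernel
from .geometry import ConeDomain, SurfacePoint, canonical_angle
from .model import HairConfiguration, ModelParams, total_cost

__all__ = ["RunRecord", "initialize", "propose", "run", "sample_positions"]

LOG_STRIDE = 100  # proposals between energy-trace records


@dataclass(frozen=True)
class RunRecord:
    """Outcome of one Monte Carlo run.

    ``cost_trace`` has one row per record: (proposal index, total cost,
    cumulative accepted count), sampled every :data:`LOG_STRIDE` proposals;
    the cost column is non-increasing.
    """

    initial_config: HairConfiguration
    final_config: HairConfiguration
    cost_trace: np.ndarray  # (k, 3): proposal, cost, accepted_cum
    accepted_count: int
    params: ModelParams


def _axial_from_uniform(domain: ConeDomain, u):
    """Inverse-CDF sample of the axial coordinate with density proportional to
    the local flattened height (uniform per unit surface area)."""
    h0 = domain.base_height_flat
    h1 = domain.tip_height_flat
    L = domain.axial_length
    if h0 == h1:
        return np.asarray(u, dtype=float) * L
    a = (h1 - h0) / (2.0 * L)
    total = h0 * L + a * L * L
    return (np.sqrt(h0 * h0 + 4.0 * a * np.asarray(u) * total) - h0) / (2.0 * a)


def sample_positions(domain: ConeDomain, u_ax, u_ci):
    """Map uniforms in [0, 1) to positions uniform per unit area: axial by
    inverse CDF of the trapezoid height, circum uniform over (-1, 1]."""
    ax = _axial_from_uniform(domain, u_ax)
    ci = 1.0 - 2.0 * np.asarray(u_ci, dtype=float)
    return ax, ci


def initialize(
    params: ModelParams, domain: ConeDomain, rng: np.random.Generator
) -> HairConfiguration:
    """Seed ``n_hairs`` hairs uniformly over the surface area with uniform
    random movement directions in (-180, 180]."""
    u = rng.random((params.n_hairs, 3))
    ax, ci = sample_positions(domain, u[:, 0], u[:, 1])
    th = 180.0 - 360.0 * u[:, 2]
    return HairConfiguration(domain, ax, ci, th)


def propose(config: HairConfiguration, rng: np.random.Generator):
    """Draw one move: a uniform hair index, a fresh uniform-per-area position,
    and a rotated direction (uniform increment over a full circle).

    Consumes four uniforms, the same stream layout :func:`run` pre-draws, so a
    sequence of ``propose`` calls reproduces a run's proposals exactly.
    """
    if len(config) == 0:
        raise ValueError("cannot propose a move on an empty configuration")
    u = rng.random(4)
    i = min(int(u[0] * len(config)), len(config) - 1)
    ax, ci = sample_positions(config.domain, u[1], u[2])
    delta = 180.0 - 360.0 * u[3]
    theta = float(canonical_angle(config.theta[i] + delta))
    return i, SurfacePoint(float(ax), float(ci)), theta


def run(params: ModelParams, domain: ConeDomain | None = None) -> RunRecord:
    """Execute the full search: initialize, then ``p_iterations`` greedy
    proposals.  Deterministic given ``params.seed``."""
    if domain is None:
        domain = ConeDomain()
    rng = np.random.default_rng(params.seed)
    initial = initialize(params, domain, rng)
    config = initial.copy()
    e0 = total_cost(params, initial)

    P = params.p_iterations
    if P == 0 or len(config) == 0:
        trace = np.array([[0, e0, 0]], dtype=float)
        return RunRecord(initial, config, trace, 0, params)

    u = rng.random((P, 4))
    idx = np.minimum((u[:, 0] * len(config)).astype(np.int64), len(config) - 1)
    new_ax, new_ci = sample_positions(domain, u[:, 1], u[:, 2])
    dth = 180.0 - 360.0 * u[:, 3]

    tp, te, ta, e_final, accepted = run_kernel(
        config.axial,
        config.circum,
        config.theta,
        idx,
        new_ax,
        new_ci,
        dth,
        e0,
        domain.axial_length,
        domain.apex_axial,
        domain.slant_factor,
        domain.sector_factor,
        params.lambda_base,
        params.lambda_tip,
        params.lambda_m,
        params.c1,
        params.a_star,
        float(params.ventral_sign),
        LOG_STRIDE,
    )
    trace = np.column_stack([tp.astype(float), te, ta.astype(float)])
    final = HairConfiguration(domain, config.axial, config.circum, config.theta)
    return RunRecord(initial, final, trace, int(accepted), params)
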