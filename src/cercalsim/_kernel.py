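"""Numba inner loop for the Monte Carlo search.

The greedy acceptance loop evaluates ~2N geodesic pair costs per proposal;
at N = 300 and P = 1e5 proposals that is ~6e7 exponentials, so the loop is
compiled with numba.  The formulas duplicate the vectorized reference
implementations in :mod:`cercalsim.model` / :mod:`cercalsim.geometry` and are
cross-checked against them in the test suite (final energy vs full
recomputation; acceptance decisions replayed with ``delta_cost_move``).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _dist(ax1, ci1, ax2, ci2, apex, slant, sector):
    """Closed-form cone geodesic (unrolled-sector chord, short winding)."""
    rho1 = (apex - ax1) * slant
    rho2 = (apex - ax2) * slant
    d = ci1 - ci2
    d = d - 2.0 * round(d / 2.0)
    ang = math.pi * d * sector
    v = rho1 * rho1 + rho2 * rho2 - 2.0 * rho1 * rho2 * math.cos(ang)
    if v < 0.0:
        v = 0.0
    return math.sqrt(v)


@njit(cache=True)
def _theta_star(ci, lam_m):
    x = 1.0 - abs(ci)
    raw = math.exp(-x / lam_m) + math.exp(-(1.0 - x) / lam_m)
    raw0 = 1.0 + math.exp(-1.0 / lam_m)
    raw_half = 2.0 * math.exp(-0.5 / lam_m)
    m = (raw - raw_half) / (raw0 - raw_half)
    return 90.0 * (1.0 - m)


@njit(cache=True)
def _angle_cost(ci, th, c1, a_star, vsign, lam_m):
    dev = abs(math.sin(math.radians(th - _theta_star(ci, lam_m))))
    if th > 0.0 and ci * vsign > 0.0:
        return c1 * (1.0 - a_star) * dev
    return c1 * dev


@njit(cache=True)
def _pair_sum(ax, ci, axs, cis, skip, L, lam0, lam1, apex, slant, sector):
    s = 0.0
    for j in range(axs.size):
        if j == skip:
            continue
        r = _dist(ax, ci, axs[j], cis[j], apex, slant, sector)
        lam = lam0 + (lam1 - lam0) * (0.5 * (ax + axs[j]) / L)
        s += math.exp(-r / lam)
    return s


@njit(cache=True)
def run_kernel(
    ax,
    ci,
    th,
    idx,
    new_ax,
    new_ci,
    dth,
    e0,
    L,
    apex,
    slant,
    sector,
    lam0,
    lam1,
    lam_m,
    c1,
    a_star,
    vsign,
    stride,
):
    """Run the greedy loop in place on (ax, ci, th).

    Proposals are pre-drawn: hair ``idx[p]`` is offered position
    ``(new_ax[p], new_ci[p])`` and rotation increment ``dth[p]``; the move is
    accepted iff the total cost strictly decreases.  Returns the energy trace
    sampled every ``stride`` proposals (proposal index, energy, cumulative
    accepted count) plus the final energy and accepted count.
    """
    P = idx.size
    n_rec = P // stride + (1 if P % stride else 0) + 1
    trace_p = np.empty(n_rec, dtype=np.int64)
    trace_e = np.empty(n_rec, dtype=np.float64)
    trace_a = np.empty(n_rec, dtype=np.int64)
    e = e0
    acc = 0
    rec = 0
    trace_p[rec] = 0
    trace_e[rec] = e
    trace_a[rec] = 0
    rec += 1
    for p in range(P):
        i = idx[p]
        old_pairs = _pair_sum(ax[i], ci[i], ax, ci, i, L, lam0, lam1, apex, slant, sector)
        new_pairs = _pair_sum(new_ax[p], new_ci[p], ax, ci, i, L, lam0, lam1, apex, slant, sector)
        t = th[i] + dth[p]
        nt = 180.0 - ((180.0 - t) % 360.0)  # canonical (-180, 180]
        old_ang = _angle_cost(ci[i], th[i], c1, a_star, vsign, lam_m)
        new_ang = _angle_cost(new_ci[p], nt, c1, a_star, vsign, lam_m)
        de = 2.0 * (new_pairs - old_pairs) + (new_ang - old_ang)
        if de < 0.0:
            ax[i] = new_ax[p]
            ci[i] = new_ci[p]
            th[i] = nt
            e += de
            acc += 1
        if (p + 1) % stride == 0 or p + 1 == P:
            trace_p[rec] = p + 1
            trace_e[rec] = e
            trace_a[rec] = acc
            rec += 1
    return trace_p[:rec], trace_e[:rec], trace_a[:rec], e, acc
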