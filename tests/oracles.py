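"""Independent brute-force oracles for the constraint engine tests.

These re-derive the ordered-phase posterior by direct numerical integration
on a calendar-year lattice, sharing no code with the sampler: the boundary
nuisance parameters are integrated out in closed form (inner log factors)
or by midpoint quadrature, and event marginals come from summing the full
joint grid.
"""

from __future__ import annotations

import numpy as np

from kincal import C14Determination, CalCurve, CalendarPDF


def _likelihood(det: C14Determination, curve: CalCurve, grid: np.ndarray) -> np.ndarray:
    mu = np.interp(grid, curve.knots_cal, curve.mu)
    sg = np.interp(grid, curve.knots_cal, curve.sigma_curve)
    return np.exp(-((det.age - mu) ** 2) / (2.0 * (det.err**2 + sg**2)))


def two_phase_marginals(
    d1: C14Determination,
    d2: C14Determination,
    curve: CalCurve,
    support: tuple[float, float],
    resolution: float = 5.0,
    inner_points: int = 400,
    interval: tuple[float, float] | None = None,
) -> dict[str, CalendarPDF]:
    """Exact marginals for a contiguous 2-phase model with one date per phase.

    Model: L <= b0 <= t1 <= b1 <= t2 <= b2 <= U with prior
    (b1-b0)^-1 (b2-b1)^-1 (and optionally a normal interval prior on b1-b0).
    b0 and b2 integrate in closed form to log factors; b1 is integrated by
    midpoint quadrature (the endpoint log singularities are integrable).
    """
    lo, hi = support
    grid = np.arange(np.ceil(lo / resolution) * resolution, hi + 0.5 * resolution, resolution)
    lik1 = _likelihood(d1, curve, grid)
    lik2 = _likelihood(d2, curve, grid)
    n = grid.size
    post = np.zeros((n, n))
    u = (np.arange(inner_points) + 0.5) / inner_points
    idx1 = np.nonzero(lik1 > 1e-12)[0]
    idx2 = np.nonzero(lik2 > 1e-12)[0]
    for i in idx1:
        t1 = grid[i]
        for j in idx2:
            t2 = grid[j]
            if t2 <= t1:
                continue
            b1 = t1 + (t2 - t1) * u
            f2 = np.log((hi - b1) / (t2 - b1))
            if interval is None:
                f0 = np.log((b1 - lo) / (b1 - t1))
            else:
                # interval prior on the first gap b1-b0: integrate b0 numerically
                mean, sd = interval
                b0 = lo + (t1 - lo) * u
                gap = b1[:, None] - b0[None, :]
                f0 = (
                    np.exp(-0.5 * ((gap - mean) / sd) ** 2) / gap
                ).mean(axis=1) * (t1 - lo)
            post[i, j] = lik1[i] * lik2[j] * float((f0 * f2).mean()) * (t2 - t1)
    total = post.sum()
    assert total > 0, "oracle posterior vanished"
    post /= total
    return {
        d1.id: CalendarPDF(grid=grid, density=post.sum(axis=1)).normalised(),
        d2.id: CalendarPDF(grid=grid, density=post.sum(axis=0)).normalised(),
    }


def three_phase_middle_marginal(
    dets: list[C14Determination],
    curve: CalCurve,
    support: tuple[float, float],
    resolution: float = 5.0,
    inner_points: int = 200,
) -> dict[str, CalendarPDF]:
    """Marginals for a contiguous 3-phase model, one date per phase.

    L <= b0 <= t1 <= b1 <= t2 <= b2 <= t3 <= b3 <= U with span prior
    (b1-b0)^-1 (b2-b1)^-1 (b3-b2)^-1; b0 and b3 give closed-form log factors,
    b1 and b2 are integrated by midpoint quadrature.
    """
    d1, d2, d3 = dets
    lo, hi = support
    grid = np.arange(np.ceil(lo / resolution) * resolution, hi + 0.5 * resolution, resolution)
    liks = [_likelihood(d, curve, grid) for d in dets]
    n = grid.size
    u = (np.arange(inner_points) + 0.5) / inner_points
    post = np.zeros((n, n, n))
    idx = [np.nonzero(lk > 1e-12)[0] for lk in liks]
    for i in idx[0]:
        t1 = grid[i]
        for j in idx[1]:
            t2 = grid[j]
            if t2 <= t1:
                continue
            b1 = t1 + (t2 - t1) * u
            f0 = np.log((b1 - lo) / (b1 - t1))
            for k in idx[2]:
                t3 = grid[k]
                if t3 <= t2:
                    continue
                b2 = t2 + (t3 - t2) * u
                f3 = np.log((hi - b2) / (t3 - b2))
                # inner double integral over b1 < b2 factorises because the
                # middle span prior is 1/(b2-b1); evaluate on the product grid
                inv_gap = 1.0 / (b2[None, :] - b1[:, None])
                val = (f0[:, None] * inv_gap * f3[None, :]).mean() * (t2 - t1) * (t3 - t2)
                post[i, j, k] = liks[0][i] * liks[1][j] * liks[2][k] * val
    total = post.sum()
    assert total > 0
    post /= total
    return {
        d1.id: CalendarPDF(grid=grid, density=post.sum(axis=(1, 2))).normalised(),
        d2.id: CalendarPDF(grid=grid, density=post.sum(axis=(0, 2))).normalised(),
        d3.id: CalendarPDF(grid=grid, density=post.sum(axis=(0, 1))).normalised(),
    }
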