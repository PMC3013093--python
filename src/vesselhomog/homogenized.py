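"""Classical homogenization (case A): effective coefficient, corrector,
boundary layers, and an exact bulk-periodic resummation.

When the regime product ``p = delta*kappa*eps**2`` is small, the oscillating
coefficient may be replaced by its volumetric mean ``k_hat = delta*kappa``:

    -u0'' + k_hat u0 = f,   u0(0) = g0,  u0(1) = g1,

with relative error of order ``p``.  The microscale oscillation around
``u0`` is captured at leading order by the 1-periodic, zero-mean cell
function ``P`` with ``P'' = K(y) - k_hat`` (the first potential corrector):
``u ~ u0(x) * (1 + eps**2 P(x/eps))``.  Mismatches of the periodic bulk
profile at the two ends are healed by exponentially decaying boundary
layers.

Instead of summing the two-scale series to higher order, the module also
solves the cell problem *exactly* with periodic boundary conditions
(:func:`bulk_periodic_solution`); tiling that cell over the domain and adding
the two numerically computed boundary layers reconstructs the exact solution
in case A to high accuracy and is the reference against which truncations are
judged.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import DimensionlessParams
from .microscale import (
    GridSolution,
    PiecewiseAnalyticSolution,
    VesselProfile,
    solve_fd,
    solve_periodic,
)

__all__ = [
    "HomogenizedSolution",
    "CorrectorCell",
    "BoundaryLayer",
    "PeriodicCellSolution",
    "SemiAnalyticSolution",
    "volumetric_mean",
    "solve_homogenized",
    "build_corrector",
    "predict_oscillation",
    "solve_boundary_layer",
    "bulk_periodic_solution",
    "semianalytic_solution",
]

logger = logging.getLogger(__name__)


def volumetric_mean(profile: VesselProfile) -> float:
    """Volumetric mean of the coefficient over the domain (= delta*kappa)."""
    lo, hi = profile.domain
    return float(np.dot(profile.widths, profile.interval_kappa)) / (hi - lo)


@dataclass(frozen=True)
class HomogenizedSolution:
    """Closed-form solution of ``-u0'' + k_hat u0 = f`` with Dirichlet data.

    ``u0(x) = f/k_hat + A e^{-sqrt(k_hat) x} + B e^{-sqrt(k_hat) (1-x)}``;
    the anchored exponentials keep evaluation overflow-safe for large
    ``k_hat``.
    """

    k_hat: float
    f: float
    g0: float
    g1: float
    A: float
    B: float

    def evaluate(self, xs) -> np.ndarray:
        x = np.asarray(xs, dtype=float)
        r = math.sqrt(self.k_hat)
        return self.f / self.k_hat + self.A * np.exp(-r * x) + self.B * np.exp(-r * (1.0 - x))

    def derivative_at(self, xs) -> np.ndarray:
        x = np.asarray(xs, dtype=float)
        r = math.sqrt(self.k_hat)
        return -r * self.A * np.exp(-r * x) + r * self.B * np.exp(-r * (1.0 - x))

    def __call__(self, xs) -> np.ndarray:
        return self.evaluate(xs)


def solve_homogenized(k_hat: float, f: float, g0: float, g1: float) -> HomogenizedSolution:
    """Exact two-point solve of the homogenized equation."""
    if k_hat <= 0:
        raise ValueError(f"k_hat must be positive, got {k_hat}")
    E = math.exp(-math.sqrt(k_hat))
    c = f / k_hat
    det = 1.0 - E * E
    A = ((g0 - c) - E * (g1 - c)) / det
    B = ((g1 - c) - E * (g0 - c)) / det
    return HomogenizedSolution(k_hat=k_hat, f=f, g0=g0, g1=g1, A=A, B=B)


# ---------------------------------------------------------------------------
# first potential corrector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectorCell:
    """1-periodic zero-mean cell function ``P`` with ``P'' = K(y) - <K>``.

    ``P`` is piecewise quadratic with respect to the strip partition of the
    unit cell; ``pieces`` holds rows ``(y_left, c0, c1, c2)`` so that on the
    piece ``P(y) = c0 + c1 (y - y_left) + c2 (y - y_left)**2``.
    """

    y_breaks: np.ndarray
    pieces: np.ndarray  # (M, 3): c0, c1, c2 per piece
    k_hat: float
    kappa: float
    delta: float

    def evaluate(self, ys) -> np.ndarray:
        y = np.mod(np.asarray(ys, dtype=float), 1.0)
        idx = np.clip(np.searchsorted(self.y_breaks, y, side="right") - 1,
                      0, self.pieces.shape[0] - 1)
        t = y - self.y_breaks[idx]
        c = self.pieces[idx]
        return c[:, 0] + c[:, 1] * t + c[:, 2] * t * t

    def __call__(self, ys) -> np.ndarray:
        return self.evaluate(ys)

    def mean(self) -> float:
        w = np.diff(self.y_breaks)
        c = self.pieces
        return float(np.sum(c[:, 0] * w + c[:, 1] * w**2 / 2.0 + c[:, 2] * w**3 / 3.0))

    def _extrema(self) -> tuple[float, float]:
        w = np.diff(self.y_breaks)
        lo = math.inf
        hi = -math.inf
        for i in range(self.pieces.shape[0]):
            c0, c1, c2 = self.pieces[i]
            cand = [c0, c0 + c1 * w[i] + c2 * w[i] ** 2]
            if c2 != 0.0:
                t = -c1 / (2.0 * c2)
                if 0.0 < t < w[i]:
                    cand.append(c0 + c1 * t + c2 * t * t)
            lo = min(lo, *cand)
            hi = max(hi, *cand)
        return lo, hi

    @property
    def amplitude(self) -> float:
        """``max P - min P`` over one period.  For the centered strip this is
        exactly ``kappa * delta * (1 - delta) / 8``."""
        lo, hi = self._extrema()
        return hi - lo

    def to_csv(self, path, n: int = 401) -> None:
        ys = np.linspace(0.0, 1.0, n)
        arr = np.column_stack([ys, self.evaluate(ys)])
        np.savetxt(path, arr, delimiter=",", header="y,P", comments="")


def _cell_partition(profile: VesselProfile) -> tuple[np.ndarray, np.ndarray]:
    """Unit-cell breakpoints and per-piece coefficient values."""
    d, k = profile.delta, profile.kappa
    if d == 1.0:
        return np.array([0.0, 1.0]), np.array([k])
    if profile.placement == "centered":
        return (np.array([0.0, (1.0 - d) / 2.0, (1.0 + d) / 2.0, 1.0]),
                np.array([0.0, k, 0.0]))
    return np.array([0.0, d, 1.0]), np.array([k, 0.0])


def build_corrector(profile: VesselProfile) -> CorrectorCell:
    """Construct ``P`` by double integration of ``K(y) - <K>`` over one
    period, with periodicity of ``P`` and ``P'`` and zero mean.

    The right-hand side is piecewise constant with zero mean, so its first
    primitive is automatically periodic; the free constants are fixed by
    ``P(1) = P(0)`` and ``<P> = 0``.  All coefficients are closed-form.
    """
    ys, kvals = _cell_partition(profile)
    k_hat = float(np.dot(np.diff(ys), kvals))  # cell measure is 1
    q = kvals - k_hat  # P'' on each piece
    w = np.diff(ys)
    M = q.size

    # P'(y) = t0 + S_j + q_j (y - y_j) on piece j, S_j = sum_{i<j} q_i w_i.
    S = np.concatenate([[0.0], np.cumsum(q * w)])[:-1]
    # P(1) - P(0) = t0 + sum_j (S_j w_j + q_j w_j^2 / 2) = 0
    t0 = -float(np.sum(S * w + q * w**2 / 2.0))
    # accumulate piece values with c = P(0) = 0 provisionally
    c0 = np.empty(M)
    acc = 0.0
    for j in range(M):
        c0[j] = acc
        acc += (t0 + S[j]) * w[j] + q[j] * w[j] ** 2 / 2.0
    c1 = t0 + S
    c2 = q / 2.0
    pieces = np.column_stack([c0, c1, c2])
    cell = CorrectorCell(ys, pieces, k_hat, profile.kappa, profile.delta)
    # shift to zero mean
    pieces = pieces.copy()
    pieces[:, 0] -= cell.mean()
    return CorrectorCell(ys, pieces, k_hat, profile.kappa, profile.delta)


def predict_oscillation(params: DimensionlessParams, corrector: CorrectorCell) -> float:
    """Predicted relative bulk oscillation ``(max u - min u)/mean u``.

    The leading corrector enters as ``u ~ u0 (1 + eps**2 P(x/eps))``, so the
    relative oscillation is ``eps**2 * amplitude(P)``; for the centered strip
    this equals ``p (1 - delta) / 8`` with ``p = delta*kappa*eps**2``.
    """
    p = params.delta * params.kappa * params.eps**2
    if p > 1.0:
        warnings.warn(
            f"regime product p = {p:.3g} > 1: corrector prediction is outside "
            "its regime of validity", stacklevel=2,
        )
    return params.eps**2 * corrector.amplitude


# ---------------------------------------------------------------------------
# boundary layers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryLayer:
    """Numerical boundary-layer correction on a truncated half-domain.

    Solves ``-z'' + K_eps z = 0`` with ``z = mismatch`` at the boundary and
    ``z = 0`` at the cut, in a local coordinate measured from the boundary
    into the domain.  ``evaluate`` maps global positions and returns 0 beyond
    the cut.
    """

    side: str  # "left" | "right"
    mismatch: float
    cut: float
    nodes: np.ndarray  # local coordinate, 0 at the boundary
    values: np.ndarray
    decay_rate_fit: float
    eps: float

    def evaluate(self, xs) -> np.ndarray:
        x = np.asarray(xs, dtype=float)
        local = x if self.side == "left" else 1.0 - x
        out = np.zeros_like(local)
        inside = (local >= 0.0) & (local <= self.cut)
        out[inside] = np.interp(local[inside], self.nodes, self.values)
        return out

    def __call__(self, xs) -> np.ndarray:
        return self.evaluate(xs)


def _clip_reflect(profile: VesselProfile, side: str, cut: float):
    """Breakpoints/coefficients of K_eps on the half-domain near one end,
    in a local coordinate starting at that end."""
    b = profile.breakpoints
    k = profile.interval_kappa
    if side == "left":
        keep = b < cut - 1e-14
        breaks = np.concatenate([b[keep], [cut]])
        kappas = k[: breaks.size - 1]
    else:
        lo = 1.0 - cut
        keep = b > lo + 1e-14
        breaks_g = np.concatenate([[lo], b[keep]])
        kappas_g = k[b.size - 1 - keep.sum():]
        # reflect to local coordinate t = 1 - x
        breaks = (1.0 - breaks_g)[::-1].copy()
        kappas = kappas_g[::-1].copy()
        breaks -= breaks[0]
    breaks[0] = 0.0
    return breaks, kappas


def solve_boundary_layer(
    profile: VesselProfile,
    side: str,
    mismatch: float,
    cut_length: float | None = None,
    N: int | None = None,
) -> BoundaryLayer:
    """Finite-difference boundary layer with a fitted decay rate.

    The cut defaults to 8 homogenized decay lengths ``8/sqrt(delta*kappa)``,
    rounded up to a whole number of periods and clipped to the domain (with a
    warning).  The decay rate is fitted by least squares on ``log|z|`` at
    period midpoints, skipping the first period.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    d, k, eps = profile.delta, profile.kappa, profile.eps
    rate0 = math.sqrt(d * k)
    if cut_length is None:
        cut_length = 8.0 / rate0
    n_periods = max(1, math.ceil(cut_length / eps - 1e-12))
    max_periods = round(1.0 / eps)
    if n_periods > max_periods:
        warnings.warn(
            f"boundary-layer cut {n_periods * eps:.3g} exceeds the domain; "
            "clipped to the full domain", stacklevel=2,
        )
        n_periods = max_periods
    cut = n_periods * eps

    breaks, kappas = _clip_reflect(profile, side, cut)
    sub = VesselProfile(eps, d, k, breaks, kappas, profile.placement)
    if N is None:
        N = max(4000, 40 * sub.n_intervals)
    grid = solve_fd(sub, 0.0, mismatch, 0.0, N)

    # decay-rate fit at period midpoints, first period skipped
    mids = (np.arange(1, n_periods) + 0.5) * eps
    mids = mids[mids < cut]
    rate = math.nan
    if mismatch != 0.0 and mids.size >= 2:
        z = np.abs(grid.evaluate(mids))
        ok = z > 1e-280
        if ok.sum() >= 2:
            slope = np.polyfit(mids[ok], np.log(z[ok]), 1)[0]
            rate = -float(slope)
    return BoundaryLayer(side=side, mismatch=float(mismatch), cut=float(cut),
                         nodes=grid.nodes, values=grid.values,
                         decay_rate_fit=rate, eps=eps)


# ---------------------------------------------------------------------------
# exact bulk-periodic resummation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodicCellSolution:
    """Exact solution of ``-w'' + K w = f`` on one period with periodic
    ``w, w'``; evaluation tiles the cell over the whole line."""

    cell: PiecewiseAnalyticSolution
    eps: float

    def evaluate(self, xs) -> np.ndarray:
        x = np.mod(np.asarray(xs, dtype=float), self.eps)
        x = np.clip(x, 0.0, self.eps)
        return self.cell.evaluate(x)

    def derivative_at(self, xs) -> np.ndarray:
        x = np.mod(np.asarray(xs, dtype=float), self.eps)
        x = np.clip(x, 0.0, self.eps)
        return self.cell.derivative_at(x)

    def __call__(self, xs) -> np.ndarray:
        return self.evaluate(xs)

    @property
    def mean(self) -> float:
        return self.cell.integral_u() / self.eps

    def oscillation(self, n: int = 2001) -> float:
        """max w - min w over one period (dense sampling + breakpoints)."""
        xs = np.union1d(np.linspace(0.0, self.eps, n), self.cell.profile.breakpoints)
        v = self.cell.evaluate(xs)
        return float(v.max() - v.min())


def bulk_periodic_solution(profile: VesselProfile, f: float) -> PeriodicCellSolution:
    """Solve the cell problem exactly on one period of the given profile.

    The cell inherits the profile's strip placement, so tiling it reproduces
    ``K_eps`` on the whole domain.
    """
    eps, d, k = profile.eps, profile.delta, profile.kappa
    ys, kvals = _cell_partition(profile)
    cell_profile = VesselProfile(eps, d, k, ys * eps, kvals, profile.placement)
    cell = solve_periodic(cell_profile, f)
    return PeriodicCellSolution(cell=cell, eps=eps)


@dataclass(frozen=True)
class SemiAnalyticSolution:
    """Tiled periodic bulk solution plus the two boundary layers.

    In case A (layers well separated) this reconstructs the exact solution to
    within exponentially small truncation terms plus the FD error of the
    layers.
    """

    bulk: PeriodicCellSolution
    layer_left: BoundaryLayer
    layer_right: BoundaryLayer
    f: float
    g0: float
    g1: float

    def evaluate(self, xs) -> np.ndarray:
        return (self.bulk.evaluate(xs) + self.layer_left.evaluate(xs)
                + self.layer_right.evaluate(xs))

    def __call__(self, xs) -> np.ndarray:
        return self.evaluate(xs)


def semianalytic_solution(
    profile: VesselProfile,
    f: float,
    g0: float,
    g1: float,
    cut_length: float | None = None,
) -> SemiAnalyticSolution:
    """Reconstruct the solution as periodic bulk + boundary layers."""
    bulk = bulk_periodic_solution(profile, f)
    w0 = float(bulk.evaluate([0.0])[0])
    w1 = float(bulk.evaluate([1.0])[0])
    left = solve_boundary_layer(profile, "left", g0 - w0, cut_length)
    right = solve_boundary_layer(profile, "right", g1 - w1, cut_length)
    return SemiAnalyticSolution(bulk=bulk, layer_left=left, layer_right=right,
                                f=f, g0=g0, g1=g1)
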