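"""Opaque-vessel (case B) approximation: parabola arches with a smooth cutoff.

When the vessels are optically opaque (``sqrt(kappa)*delta*eps`` large, regime
product ``p = delta*kappa*eps**2`` not small), light barely penetrates the
strips and the solution becomes, to leading order, an independent parabolic
arch in every inter-vessel gap:

    u ~ (f/2) s (l - s),   s in (0, l),   l = eps (1 - delta),

vanishing at the vessel walls and of height ``f eps**2 (1-delta)**2 / 8`` at
the gap midpoints — a periodic piecewise-quadratic profile that no constant
effective absorption coefficient can reproduce.  The arches are multiplied by
a C^2 quintic-smoothstep cutoff so the approximation is smooth across the
vessels and (essentially) zero inside them; the two gaps touching the domain
ends use parabolas fitted to the boundary data so the boundary conditions
hold exactly.

The next-order wall value of the exact solution, ``f l / (2 sqrt(kappa))``
(the flux the gap pushes into each wall divided by the vessel's absorption
rate), is *not* part of the leading-order arch profile; pass
``wall_offset=True`` to add it when a sharper approximation is wanted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import DimensionlessParams
from .microscale import VesselProfile, build_profile

__all__ = ["CutoffFunction", "CaseBApproximation", "build_caseb", "residual_caseb"]

logger = logging.getLogger(__name__)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 at t<=0, 1 at t>=1, two vanishing derivatives at
    both ends."""
    t = np.clip(t, 0.0, 1.0)
    return t**3 * (10.0 - 15.0 * t + 6.0 * t**2)


def _smoothstep_d1(t: np.ndarray) -> np.ndarray:
    inside = (t > 0.0) & (t < 1.0)
    out = np.zeros_like(t)
    ti = t[inside]
    out[inside] = 30.0 * ti**2 * (1.0 - ti) ** 2
    return out


def _smoothstep_d2(t: np.ndarray) -> np.ndarray:
    inside = (t > 0.0) & (t < 1.0)
    out = np.zeros_like(t)
    ti = t[inside]
    out[inside] = 60.0 * ti * (1.0 - 2.0 * ti) * (1.0 - ti)
    return out


@dataclass(frozen=True)
class CutoffFunction:
    """C^2 cutoff equal to 1 in gap interiors and 0 deep inside vessels.

    The transition is centered on each vessel wall with total width
    ``transition_width`` times the vessel half-width ``delta*eps/2`` (default
    0.5, i.e. the transition extends ``delta*eps/8`` to each side of the
    wall).  Built on the signed distance to the vessel set, positive in gaps.
    """

    profile: VesselProfile
    transition_width: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.transition_width <= 1):
            raise ValueError("transition_width must lie in (0, 1]")

    @property
    def half_width(self) -> float:
        """Half of the transition's total width."""
        return self.transition_width * self.profile.delta * self.profile.eps / 4.0

    def _signed_distance(self, xs) -> np.ndarray:
        """Distance to the vessel set: positive in gaps, negative inside."""
        p = self.profile
        x = np.asarray(xs, dtype=float)
        idx = np.clip(np.searchsorted(p.breakpoints, x, side="right") - 1,
                      0, p.n_intervals - 1)
        k = p.interval_kappa[idx]
        left = p.breakpoints[idx]
        right = p.breakpoints[idx + 1]
        d = np.empty_like(x)
        ves = k > 0
        d[ves] = -np.minimum(x[ves] - left[ves], right[ves] - x[ves])
        gap = ~ves
        # distance to the adjacent vessel walls; domain ends are not walls
        dl = np.where(idx[gap] > 0, x[gap] - left[gap], np.inf)
        dr = np.where(idx[gap] < p.n_intervals - 1, right[gap] - x[gap], np.inf)
        d[gap] = np.minimum(dl, dr)
        return d

    def _t(self, xs) -> np.ndarray:
        return (self._signed_distance(xs) + self.half_width) / (2.0 * self.half_width)

    def evaluate(self, xs) -> np.ndarray:
        return _smoothstep(self._t(xs))

    def derivative_at(self, xs) -> np.ndarray:
        # d(dist)/dx = +-1 depending on which wall is nearest; recompute signs
        t = self._t(xs)
        sgn = self._distance_sign(xs)
        return _smoothstep_d1(t) * sgn / (2.0 * self.half_width)

    def second_derivative_at(self, xs) -> np.ndarray:
        t = self._t(xs)
        return _smoothstep_d2(t) / (2.0 * self.half_width) ** 2

    def _distance_sign(self, xs) -> np.ndarray:
        """Sign of d(dist)/dx (the distance is piecewise linear in x)."""
        p = self.profile
        x = np.asarray(xs, dtype=float)
        idx = np.clip(np.searchsorted(p.breakpoints, x, side="right") - 1,
                      0, p.n_intervals - 1)
        k = p.interval_kappa[idx]
        left = p.breakpoints[idx]
        right = p.breakpoints[idx + 1]
        out = np.empty_like(x)
        ves = k > 0
        # inside a vessel distance decreases toward the middle then increases
        out[ves] = np.where(x[ves] - left[ves] < right[ves] - x[ves], -1.0, 1.0)
        gap = ~ves
        dl = np.where(idx[gap] > 0, x[gap] - left[gap], np.inf)
        dr = np.where(idx[gap] < p.n_intervals - 1, right[gap] - x[gap], np.inf)
        out[gap] = np.where(dl < dr, 1.0, -1.0)
        return out

    def __call__(self, xs) -> np.ndarray:
        return self.evaluate(xs)


@dataclass(frozen=True)
class CaseBApproximation:
    """Arch-per-gap case-B approximation ``u_B = q(x) * phi(x)``.

    ``q`` is the piecewise parabola solving ``-q'' = f`` with zero values at
    the vessel walls in every interior gap (continued smoothly a short way
    into the vessels, where the cutoff ``phi`` extinguishes it); the two
    boundary gaps interpolate the Dirichlet data exactly.  ``gap_coeffs[i]``
    stores ``(alpha, beta)`` of ``q = -f s**2/2 + alpha s + beta`` in the
    local coordinate of gap interval ``i``.
    """

    profile: VesselProfile
    f: float
    g0: float
    g1: float
    cutoff: CutoffFunction
    gap_coeffs: np.ndarray  # (n_intervals, 2); rows for vessels unused
    wall_offset: float = 0.0

    # -- parabola bookkeeping ---------------------------------------------

    def _q_pieces(self, xs):
        """Which gap parabola governs each x, and the local coordinate."""
        p = self.profile
        x = np.asarray(xs, dtype=float)
        idx = np.clip(np.searchsorted(p.breakpoints, x, side="right") - 1,
                      0, p.n_intervals - 1)
        k = p.interval_kappa[idx]
        gov = idx.copy()
        ves = k > 0
        mid = (p.breakpoints[idx] + p.breakpoints[idx + 1]) / 2.0
        # inside a vessel, continue the nearer gap's parabola
        gov[ves] = np.where(x[ves] < mid[ves],
                            np.maximum(idx[ves] - 1, 0),
                            np.minimum(idx[ves] + 1, p.n_intervals - 1))
        s = x - p.breakpoints[gov]
        return gov, s

    def _q(self, xs) -> np.ndarray:
        gov, s = self._q_pieces(xs)
        a = self.gap_coeffs[gov, 0]
        b = self.gap_coeffs[gov, 1]
        return -self.f * s**2 / 2.0 + a * s + b

    def _q_d1(self, xs) -> np.ndarray:
        gov, s = self._q_pieces(xs)
        a = self.gap_coeffs[gov, 0]
        return -self.f * s + a

    # -- public surface ----------------------------------------------------

    def evaluate(self, xs) -> np.ndarray:
        return self._eval(xs)

    def _eval(self, xs) -> np.ndarray:
        out = self._q(xs) * self.cutoff.evaluate(xs)
        if self.wall_offset:
            out = out + self.wall_offset * self._offset_shape(xs)
        return out

    def _offset_shape(self, xs) -> np.ndarray:
        """1 in gaps, decaying as e^{-sqrt(kappa) dist} inside vessels."""
        d = self.cutoff._signed_distance(xs)
        r = math.sqrt(self.profile.kappa)
        return np.where(d >= 0.0, 1.0, np.exp(r * d))

    def derivative_at(self, xs) -> np.ndarray:
        out = (self._q_d1(xs) * self.cutoff.evaluate(xs)
               + self._q(xs) * self.cutoff.derivative_at(xs))
        if self.wall_offset:
            d = self.cutoff._signed_distance(xs)
            r = math.sqrt(self.profile.kappa)
            sgn = self.cutoff._distance_sign(xs)
            out = out + self.wall_offset * np.where(
                d >= 0.0, 0.0, r * sgn * np.exp(r * d))
        return out

    def second_derivative_at(self, xs) -> np.ndarray:
        return (-self.f * self.cutoff.evaluate(xs)
                + 2.0 * self._q_d1(xs) * self.cutoff.derivative_at(xs)
                + self._q(xs) * self.cutoff.second_derivative_at(xs))

    def __call__(self, xs) -> np.ndarray:
        return self._eval(xs)

    @property
    def arch_midpoint_value(self) -> float:
        """Closed-form interior-arch maximum ``f eps**2 (1-delta)**2 / 8``."""
        p = self.profile
        return self.f * p.eps**2 * (1.0 - p.delta) ** 2 / 8.0

    @property
    def opacity(self) -> float:
        """Vessel thickness in units of the in-vessel penetration depth."""
        p = self.profile
        return math.sqrt(p.kappa) * p.delta * p.eps


def build_caseb(
    params: DimensionlessParams,
    transition_width: float = 0.5,
    wall_offset: bool = False,
) -> CaseBApproximation:
    """Construct the case-B arch approximation for centered strips.

    Warns when the regime product ``p < 1`` (the approximation then has no
    asymptotic justification).  With ``wall_offset=True`` the next-order wall
    value ``f l/(2 sqrt(kappa))`` is added (a refinement beyond the
    leading-order arch profile; see the module docstring).
    """
    profile = build_profile(params, placement="centered")
    p = params.delta * params.kappa * params.eps**2
    if p < 1.0:
        warnings.warn(
            f"regime product p = {p:.3g} < 1: case-B approximation is outside "
            "its regime of validity", stacklevel=2,
        )
    f, g0, g1 = params.f, params.g0, params.g1
    cutoff = CutoffFunction(profile, transition_width)

    n_int = profile.n_intervals
    coeffs = np.zeros((n_int, 2))
    kappas = profile.interval_kappa
    widths = profile.widths
    offset = f * params.eps * (1.0 - params.delta) / (2.0 * math.sqrt(params.kappa)) \
        if wall_offset else 0.0
    for i in range(n_int):
        if kappas[i] > 0:
            continue
        w = widths[i]
        if i == 0:  # left boundary gap: q(0) = g0 - offset, q(w) = 0
            b = g0 - offset
            a = f * w / 2.0 - b / w
        elif i == n_int - 1:  # right boundary gap: q(0) = 0, q(w) = g1 - offset
            b = 0.0
            a = (g1 - offset) / w + f * w / 2.0
        else:  # interior gap arch: zeros at both walls
            b = 0.0
            a = f * w / 2.0
        coeffs[i] = (a, b)
    approx = CaseBApproximation(profile=profile, f=f, g0=float(g0), g1=float(g1),
                                cutoff=cutoff, gap_coeffs=coeffs,
                                wall_offset=offset)
    logger.info("case-B approximation built: p = %.4g, opacity = %.3g",
                p, approx.opacity)
    return approx


def residual_caseb(
    approx: CaseBApproximation,
    n_per_interval: int = 400,
) -> dict:
    """Equation residual ``-u_B'' + K_eps u_B - f`` on a fine grid.

    Returns sup and L1 norms, split into gap-interior, cutoff-transition and
    vessel-interior contributions (the gap-interior residual vanishes by
    construction; the vessel interior carries ``kappa`` times the cutoff
    leakage plus the constant ``-f``).
    """
    p = approx.profile
    zones = {z: {"sup": 0.0, "l1": 0.0} for z in ("gap", "transition", "vessel")}
    total_sup = 0.0
    total_l1 = 0.0
    h_t = approx.cutoff.half_width
    for i in range(p.n_intervals):
        left, right = p.breakpoints[i], p.breakpoints[i + 1]
        # cell-centered samples avoid evaluating exactly on breakpoints
        xs = left + (np.arange(n_per_interval) + 0.5) * (right - left) / n_per_interval
        dx = (right - left) / n_per_interval
        res = (-approx.second_derivative_at(xs) + p.kappa_at(xs) * approx._eval(xs)
               - approx.f)
        dist = approx.cutoff._signed_distance(xs)
        zone = np.where(np.abs(dist) <= h_t, "transition",
                        np.where(dist < 0, "vessel", "gap"))
        for z in zones:
            m = zone == z
            if m.any():
                zones[z]["sup"] = max(zones[z]["sup"], float(np.abs(res[m]).max()))
                zones[z]["l1"] += float(np.abs(res[m]).sum() * dx)
        total_sup = max(total_sup, float(np.abs(res).max()))
        total_l1 += float(np.abs(res).sum() * dx)
    return {"sup": total_sup, "l1": total_l1, "zones": zones}
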