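"""Physical tissue-optics quantities and their dimensionless counterparts.

The microscale model lives on the unit interval after non-dimensionalization
and is fully described by three numbers:

* ``eps``   — ratio of the inter-vessel period to the macroscopic size ``L``
  (the classical homogenization parameter; ``1/eps`` is required to be an
  integer so a whole number of periods fits in the domain),
* ``delta`` — ratio of vessel thickness to the period (the volume fraction of
  blood),
* ``kappa`` — dimensionless in-vessel absorption: the ratio of the absorption
  coefficient to the diffusion coefficient, multiplied by ``L**2``.

The product ``p = delta * kappa * eps**2`` controls whether classical
homogenization (volumetric averaging of the absorption coefficient) is valid:
``p`` small is "case A" (averaging justified, relative error of order ``p``),
``p`` large is "case B" (vessels optically opaque, averaging fails).

This module converts between a dimensional tissue description
(:class:`PhysicalScenario`) and the dimensionless triple
(:class:`DimensionlessParams`), and classifies the regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PhysicalScenario",
    "DimensionlessParams",
    "RegimeIndicator",
    "HB_MOLAR_MASS",
    "extinction_conversion_factor",
    "extinction_to_mua",
    "mua_to_kappa",
    "geometry_to_eps_delta",
    "snap_epsilon",
    "regime_product",
]

logger = logging.getLogger(__name__)

#: Molar mass of haemoglobin (tetramer), g/mol.  Standard value used by the
#: compiled extinction spectra of whole blood.
HB_MOLAR_MASS = 64_500.0

#: Default thresholds on the regime product separating case A / transition /
#: case B.  The theory only asserts "small" vs "not small"; these bracket the
#: worked tissue scenarios and are configurable everywhere they are used.
DEFAULT_REGIME_THRESHOLDS = (0.1, 10.0)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class PhysicalScenario:
    """Dimensional description of a vessel-laden tissue slab.

    Lengths in mm, ``reduced_scattering`` in 1/mm, ``hb_concentration`` in
    g/L, ``molar_extinction`` in (mol/L)^-1 cm^-1.
    """

    macro_size_L: float
    vessel_spacing: float
    vessel_diameter: float
    reduced_scattering: float
    hb_concentration: float
    molar_extinction: float
    hb_molar_mass: float = HB_MOLAR_MASS
    label: str = ""

    def __post_init__(self) -> None:
        _require_positive(
            macro_size_L=self.macro_size_L,
            vessel_spacing=self.vessel_spacing,
            vessel_diameter=self.vessel_diameter,
            reduced_scattering=self.reduced_scattering,
            hb_concentration=self.hb_concentration,
            molar_extinction=self.molar_extinction,
            hb_molar_mass=self.hb_molar_mass,
        )
        if not (self.vessel_diameter < self.vessel_spacing < self.macro_size_L):
            raise ValueError(
                "expected vessel_diameter < vessel_spacing < macro_size_L, got "
                f"{self.vessel_diameter} / {self.vessel_spacing} / {self.macro_size_L}"
            )

    @property
    def mua(self) -> float:
        """Blood absorption coefficient, 1/mm."""
        return extinction_to_mua(
            self.molar_extinction, self.hb_concentration, self.hb_molar_mass
        )

    @property
    def kappa(self) -> float:
        return mua_to_kappa(self.mua, self.reduced_scattering, self.macro_size_L)


@dataclass(frozen=True)
class DimensionlessParams:
    """The dimensionless model state: (eps, delta, kappa) plus source and
    boundary data.

    Boundary values default to ``f / (delta * kappa)``, the choice that makes
    the solution exactly constant when the absorption coefficient is replaced
    by its volumetric mean.  ``1/eps`` must be an integer (use
    :func:`snap_epsilon` on raw ratios).
    """

    eps: float
    delta: float
    kappa: float
    f: float = 1.0
    g0: float | None = None
    g1: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.eps < 1):
            raise ValueError(f"eps must lie in (0, 1), got {self.eps}")
        n = 1.0 / self.eps
        if abs(n - round(n)) > 1e-8 * n:
            raise ValueError(
                f"1/eps must be an integer (got 1/eps = {n!r}); "
                "use snap_epsilon() on the raw ratio first"
            )
        if not (0 < self.delta <= 1):
            raise ValueError(f"delta must lie in (0, 1], got {self.delta}")
        _require_positive(kappa=self.kappa)
        if self.f < 0:
            raise ValueError(f"f must be non-negative, got {self.f}")
        default_g = self.f / (self.delta * self.kappa)
        if self.g0 is None:
            object.__setattr__(self, "g0", default_g)
        if self.g1 is None:
            object.__setattr__(self, "g1", default_g)
        if self.g0 < 0 or self.g1 < 0:
            raise ValueError("boundary values g0, g1 must be non-negative")

    @property
    def n_periods(self) -> int:
        return round(1.0 / self.eps)

    @property
    def gamma(self) -> float:
        """Inverse square root of the in-vessel absorption, ``kappa**-0.5``."""
        return self.kappa ** -0.5

    @property
    def k_hat(self) -> float:
        """Volumetric-mean (effective) absorption ``delta * kappa``."""
        return self.delta * self.kappa

    def with_boundary(self, g0: float, g1: float) -> "DimensionlessParams":
        return replace(self, g0=g0, g1=g1)

    @classmethod
    def from_scenario(
        cls,
        scenario: PhysicalScenario,
        f: float = 1.0,
        g0: float | None = None,
        g1: float | None = None,
    ) -> "DimensionlessParams":
        """Non-dimensionalize a physical scenario (snapping eps)."""
        eps_raw, delta = geometry_to_eps_delta(scenario)
        return cls(
            eps=snap_epsilon(eps_raw),
            delta=delta,
            kappa=scenario.kappa,
            f=f,
            g0=g0,
            g1=g1,
        )


@dataclass(frozen=True)
class RegimeIndicator:
    """Regime product ``p = delta*kappa*eps**2`` and its classification."""

    product_p: float
    regime_label: str
    thresholds: tuple[float, float] = DEFAULT_REGIME_THRESHOLDS

    def __post_init__(self) -> None:
        _require_positive(product_p=self.product_p)
        lo, hi = self.thresholds
        if not (0 < lo < hi):
            raise ValueError(f"thresholds must satisfy 0 < lo < hi, got {self.thresholds}")


def extinction_conversion_factor(
    hb_concentration: float, hb_molar_mass: float = HB_MOLAR_MASS
) -> float:
    """Factor converting a molar extinction coefficient in (mol/L)^-1 cm^-1
    to an absorption coefficient in 1/mm at the given haemoglobin
    concentration (g/L).

    ``factor = ln(10) * c / M / 10``; the ``ln 10`` converts decadic
    extinction to a Napierian absorption coefficient and the ``/10`` converts
    1/cm to 1/mm.  At 150 g/L and 64,500 g/mol this is ~0.00054.
    """
    _require_positive(hb_concentration=hb_concentration, hb_molar_mass=hb_molar_mass)
    return math.log(10.0) * hb_concentration / hb_molar_mass / 10.0


def extinction_to_mua(
    molar_extinction: float,
    hb_concentration: float,
    hb_molar_mass: float = HB_MOLAR_MASS,
) -> float:
    """Absorption coefficient (1/mm) from a molar extinction coefficient.

    Linear in both the extinction and the concentration.  Zero extinction is
    allowed (returns 0); everything else must be positive.
    """
    if molar_extinction < 0:
        raise ValueError(f"molar_extinction must be non-negative, got {molar_extinction}")
    return molar_extinction * extinction_conversion_factor(hb_concentration, hb_molar_mass)


def mua_to_kappa(mua: float, reduced_scattering: float, macro_size_L: float) -> float:
    """Dimensionless in-vessel absorption ``kappa = 3 * mua * mus' * L**2``.

    The diffusion coefficient of the diffusion approximation is taken as
    ``D = 1/(3 mus')``, so kappa is the absorption-to-diffusion ratio scaled
    by the square of the macroscopic size.
    """
    _require_positive(mua=mua, reduced_scattering=reduced_scattering, macro_size_L=macro_size_L)
    return 3.0 * mua * reduced_scattering * macro_size_L**2


def geometry_to_eps_delta(scenario: PhysicalScenario) -> tuple[float, float]:
    """(eps_raw, delta) from the vessel geometry.  ``eps_raw`` is the raw
    spacing/size ratio, not yet snapped to a reciprocal integer."""
    eps_raw = scenario.vessel_spacing / scenario.macro_size_L
    delta = scenario.vessel_diameter / scenario.vessel_spacing
    return eps_raw, delta


def snap_epsilon(eps_raw: float) -> float:
    """Snap a raw period-to-size ratio to the nearest reciprocal integer.

    The model requires a whole number of periods in the unit interval.  The
    relative adjustment is logged at INFO level.
    """
    if not (0 < eps_raw < 1):
        raise ValueError(f"eps_raw must lie in (0, 1), got {eps_raw}")
    n = max(2, round(1.0 / eps_raw))
    eps = 1.0 / n
    rel = (eps - eps_raw) / eps_raw
    if abs(rel) > 1e-12:
        logger.info("snapped eps from %.6g to 1/%d = %.6g (relative change %.2e)",
                    eps_raw, n, eps, rel)
    return eps


def regime_product(
    params: DimensionlessParams,
    thresholds: tuple[float, float] = DEFAULT_REGIME_THRESHOLDS,
) -> RegimeIndicator:
    """Compute ``p = delta * kappa * eps**2`` and classify the regime.

    ``p <= thresholds[0]`` is labelled ``"caseA"`` (homogenization valid),
    ``p >= thresholds[1]`` is ``"caseB"`` (opaque vessels, averaging fails),
    anything in between ``"transition"``.
    """
    p = params.delta * params.kappa * params.eps**2
    lo, hi = thresholds
    if p <= lo:
        label = "caseA"
    elif p >= hi:
        label = "caseB"
    else:
        label = "transition"
    logger.info("regime product p = %.4g -> %s", p, label)
    return RegimeIndicator(product_p=p, regime_label=label, thresholds=(lo, hi))
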