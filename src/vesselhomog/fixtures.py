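"""Worked tissue scenarios shipped with the package.

Two cerebral-cortex presets at the 575 nm oxyhaemoglobin absorption peak,
built from standard micro-angioarchitecture and blood-optics values: large
cortical microvessels of ~15 um diameter spaced ~180 um apart, penetrating
vessels of ~65 um diameter at the same spacing, a macroscopic probing depth
of 10 mm (typical of diffuse optical tomography), whole-blood haemoglobin
150 g/L, molar extinction 55,500 (mol/L)^-1 cm^-1 and reduced scattering
2.5 /mm.
"""

from __future__ import annotations

from .params import PhysicalScenario

__all__ = ["PRESETS", "get_preset", "list_presets"]

PRESETS: dict[str, PhysicalScenario] = {
    "cortex_575nm_microvessels": PhysicalScenario(
        macro_size_L=10.0,
        vessel_spacing=0.18,
        vessel_diameter=0.015,
        reduced_scattering=2.5,
        hb_concentration=150.0,
        molar_extinction=55_500.0,
        label=(
            "primate cortex microvessels at 575 nm: 15 um diameter, 180 um "
            "spacing, L = 10 mm, mus' = 2.5 /mm, Hb 150 g/L, "
            "extinction 55,500 (mol/L)^-1 cm^-1"
        ),
    ),
    "cortex_575nm_penetrating": PhysicalScenario(
        macro_size_L=10.0,
        vessel_spacing=0.18,
        vessel_diameter=0.065,
        reduced_scattering=2.5,
        hb_concentration=150.0,
        molar_extinction=55_500.0,
        label=(
            "cortex penetrating vessels at 575 nm: 65 um diameter, otherwise "
            "as the microvessel preset"
        ),
    ),
}


def get_preset(name: str) -> PhysicalScenario:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list[str]:
    return sorted(PRESETS)
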