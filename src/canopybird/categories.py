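"""Forest management-type and age-class categories.

Compartments carry a *detailed* management type and age class from the
forest management database; the statistical analysis uses *simplified*
categories: management types conifer, broadleaved, mixture, open/other,
and age classes restock/pre-thicket, thicket/pole, mature, mixed, and
"not applicable" (forced for open/other management, which has no stand
age).
"""

from __future__ import annotations

__all__ = [
    "DETAILED_MANAGEMENT",
    "DETAILED_AGE_CLASSES",
    "AGE_BANDS",
    "SIMPLIFIED_MANAGEMENT",
    "SIMPLIFIED_AGE",
    "NOT_APPLICABLE",
    "simplify_management",
    "simplify_age",
    "age_band_from_years",
    "simplify_categories",
]

NOT_APPLICABLE = "Not applicable"

#: detailed management type -> simplified category
DETAILED_MANAGEMENT: dict[str, str] = {
    "Corsican pine monoculture": "Conifer",
    "Scots pine monoculture": "Conifer",
    "Douglas fir monoculture": "Conifer",
    "Other conifer monoculture": "Conifer",
    "Birch monoculture": "Broadleaved",
    "Other broadleaved monoculture": "Broadleaved",
    "Conifer/broadleaved mixture (conifer)": "Mixture",
    "Conifer/broadleaved mixture (broadleaved)": "Mixture",
    "Open": "Open/other",
    "Open with trees": "Open/other",
    "Other": "Open/other",
    "Felled": "Open/other",
}

#: detailed age class -> simplified category
DETAILED_AGE_CLASSES: dict[str, str] = {
    "Restock": "Restock/pre-thicket",
    "Pre-thicket": "Restock/pre-thicket",
    "Thicket": "Thicket/pole",
    "Pole": "Thicket/pole",
    "Mature": "Mature",
    "Mixed ages": "Mixed",
    NOT_APPLICABLE: NOT_APPLICABLE,
}

#: stand age in years -> detailed age band (inclusive bounds; mature is
#: open-ended, 80 is only the sampling cap used by the generator)
AGE_BANDS: dict[str, tuple[int, int]] = {
    "Restock": (0, 6),
    "Pre-thicket": (7, 11),
    "Thicket": (12, 21),
    "Pole": (22, 45),
    "Mature": (46, 80),
}

SIMPLIFIED_MANAGEMENT = ("Conifer", "Broadleaved", "Mixture", "Open/other")
SIMPLIFIED_AGE = (
    "Restock/pre-thicket",
    "Thicket/pole",
    "Mature",
    "Mixed",
    NOT_APPLICABLE,
)


def simplify_management(detailed: str) -> str:
    """Map a detailed management type to its simplified category."""
    try:
        return DETAILED_MANAGEMENT[detailed]
    except KeyError:
        raise ValueError(
            f"unknown management type {detailed!r}; valid values: "
            f"{sorted(DETAILED_MANAGEMENT)}"
        ) from None


def age_band_from_years(years: float) -> str:
    """Detailed age band for a stand age in years."""
    if years < 0:
        raise ValueError("stand age must be >= 0")
    for band, (lo, hi) in AGE_BANDS.items():
        if lo <= years <= hi:
            return band
    return "Mature"  # 46 years and older


def simplify_age(detailed) -> str:
    """Map a detailed age class (band name or years) to its simplified category."""
    if isinstance(detailed, (int, float)):
        detailed = age_band_from_years(detailed)
    try:
        return DETAILED_AGE_CLASSES[detailed]
    except KeyError:
        raise ValueError(
            f"unknown age class {detailed!r}; valid values: "
            f"{sorted(DETAILED_AGE_CLASSES)}"
        ) from None


def simplify_categories(management: str, age_class=None) -> tuple[str, str]:
    """Simplified (management, age class) pair for one compartment.

    ``age_class`` may be a detailed band name, a stand age in years, or
    None/"Not applicable".  Open/other management always takes the
    "not applicable" age class, whatever age was recorded.
    """
    mgmt = simplify_management(management)
    if mgmt == "Open/other":
        return mgmt, NOT_APPLICABLE
    if age_class is None:
        raise ValueError(f"age class required for management type {management!r}")
    return mgmt, simplify_age(age_class)
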