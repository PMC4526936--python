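"""Impact x certainty color encoding and the 9-level potential-effect scale.

Every variant falls into one of nine (impact, evidence) categories.  These are
totally ordered into an ordinal "potential effect" rank: the pathogenic block
first, then benign, then protective, and within each block well-established,
then likely, then uncertain.  Rank 1 is therefore a well-established pathogenic
variant and rank 9 an uncertain protective one.

Two palettes are provided:

* ``study3`` — red (pathogenic) / near-white neutral (benign) / blue
  (protective), with color saturation falling as evidence certainty falls.
  Red-blue is safe for red-green color-vision deficiency.
* ``legacy_redgreen`` — the older red/green prototype scheme (green =
  protective), kept only for reproducing the original two-level treemap.

The hex values are frozen constants computed once from HLS coordinates
(hue 0 deg for red, 220 deg for blue, 120 deg for green; saturation
0.90 / 0.55 / 0.25 for well-established / likely / uncertain; the neutral
benign family steps lightness 0.92 / 0.95 / 0.98 instead of saturation), so
rendering is bit-exact across platforms.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass

from .model import (
    EVIDENCE_VALUES,
    IMPACT_VALUES,
    VariantAnnotation,
    effect_rank,
)

SCHEMES = ("study3", "legacy_redgreen")

_SATURATION = {"well-established": 0.90, "likely": 0.55, "uncertain": 0.25}
_NEUTRAL_LIGHTNESS = {"well-established": 0.92, "likely": 0.95, "uncertain": 0.98}
_COLORED_LIGHTNESS = 0.55
_HUE = {
    ("study3", "pathogenic"): 0.0,
    ("study3", "protective"): 220.0,
    ("legacy_redgreen", "pathogenic"): 0.0,
    ("legacy_redgreen", "protective"): 120.0,
}

_HUE_FAMILY = {
    ("study3", "pathogenic"): "red",
    ("study3", "benign"): "neutral",
    ("study3", "protective"): "blue",
    ("legacy_redgreen", "pathogenic"): "red",
    ("legacy_redgreen", "benign"): "neutral",
    ("legacy_redgreen", "protective"): "green",
}

_SATURATION_LEVEL = {"well-established": "high", "likely": "mid", "uncertain": "low"}


@dataclass(frozen=True)
class EffectCategory:
    """One of the nine (impact, evidence) cells with its ordinal rank."""

    impact: str
    evidence: str
    rank: int


@dataclass(frozen=True)
class ColorAssignment:
    hue_family: str
    saturation_level: str
    hex: str


def _hls_hex(hue_deg: float, lightness: float, saturation: float) -> str:
    r, g, b = colorsys.hls_to_rgb(hue_deg / 360.0, lightness, saturation)
    return "#{:02x}{:02x}{:02x}".format(
        round(r * 255), round(g * 255), round(b * 255)
    )


def _build_palette(scheme: str) -> dict[tuple[str, str], str]:
    table = {}
    for impact in IMPACT_VALUES:
        for evidence in EVIDENCE_VALUES:
            if impact == "benign":
                hexval = _hls_hex(0.0, _NEUTRAL_LIGHTNESS[evidence], 0.0)
            else:
                hexval = _hls_hex(
                    _HUE[(scheme, impact)], _COLORED_LIGHTNESS, _SATURATION[evidence]
                )
            table[(impact, evidence)] = hexval
    return table


PALETTES: dict[str, dict[tuple[str, str], str]] = {s: _build_palette(s) for s in SCHEMES}

ALL_CATEGORIES: tuple[EffectCategory, ...] = tuple(
    sorted(
        (
            EffectCategory(
                impact=i,
                evidence=e,
                rank=3 * IMPACT_VALUES.index(i) + EVIDENCE_VALUES.index(e) + 1,
            )
            for i in IMPACT_VALUES
            for e in EVIDENCE_VALUES
        ),
        key=lambda c: c.rank,
    )
)

_BY_PAIR = {(c.impact, c.evidence): c for c in ALL_CATEGORIES}


def category_for(impact: str, evidence: str) -> EffectCategory:
    return _BY_PAIR[(impact, evidence)]


def effect_category(variant: VariantAnnotation) -> EffectCategory:
    """The unique potential-effect category (and rank 1..9) for a variant."""
    cat = _BY_PAIR[(variant.impact, variant.evidence)]
    assert cat.rank == effect_rank(variant)
    return cat


def encode_color(category: EffectCategory, scheme: str = "study3") -> ColorAssignment:
    """Deterministic color for a category under the given scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ColorAssignment(
        hue_family=_HUE_FAMILY[(scheme, category.impact)],
        saturation_level=_SATURATION_LEVEL[category.evidence],
        hex=PALETTES[scheme][(category.impact, category.evidence)],
    )


def decode_color(hexval: str, scheme: str = "study3") -> EffectCategory:
    """Inverse of :func:`encode_color` for hex values in the scheme's palette."""
    for pair, h in PALETTES[scheme].items():
        if h == hexval.lower():
            return _BY_PAIR[pair]
    raise ValueError(f"hex {hexval!r} is not in the {scheme!r} palette")


_PLAIN = {
    "pathogenic": "may be harmful",
    "benign": "no known effect",
    "protective": "may be protective",
}
_CERTAINTY = {
    "well-established": "strong evidence",
    "likely": "moderate evidence",
    "uncertain": "weak evidence",
}


def category_label(category: EffectCategory) -> str:
    """Display label combining the canonical term with a plain-language gloss."""
    return (
        f"{category.evidence} {category.impact} "
        f"({_PLAIN[category.impact]}, {_CERTAINTY[category.evidence]})"
    )


def legend(scheme: str = "study3") -> list[tuple[EffectCategory, ColorAssignment, str]]:
    """The 9-entry color key in rank order."""
    return [
        (cat, encode_color(cat, scheme), category_label(cat)) for cat in ALL_CATEGORIES
    ]


def legend_json(scheme: str = "study3") -> str:
    rows = [
        {
            "rank": cat.rank,
            "impact": cat.impact,
            "evidence": cat.evidence,
            "hex": color.hex,
            "label": label,
        }
        for cat, color, label in legend(scheme)
    ]
    return json.dumps(rows, sort_keys=True, indent=1)
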