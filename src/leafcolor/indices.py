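"""The 22 derived vegetation indices computed from per-leaf mean color
features, including the redness-based contrast indices SREx and TREx.

Indices are evaluated from the *mean* feature record of a leaf (not per
pixel then averaged).  Raw-channel indices (GMR, ExG, TREx, ...) use the
0-255 channel scale; normalized-channel indices (NDI, WI, ExR, ExB) use the
chromatic fractions r, g, b; DGCI uses H in degrees with S, V as fractions.

A ratio or contrast index whose denominator vanishes is returned as a
flagged *undefined* value with a reason string, never raised, so batch runs
survive degenerate leaves.

Note on ExR/ExB: the excess-red and excess-blue indices are implemented
with their standard literature semantics, ExR = 1.4 r - g and
ExB = 1.4 b - g.  Some published tabulations swap the two labels; passing
``table1_literal=True`` reproduces that swapped assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .imaging import ColorFeatures

#: Canonical output order of the derived indices.
INDEX_NAMES: tuple[str, ...] = (
    "NGBDI", "WI", "NDPI", "NDI", "G/R", "G/B", "Intensity", "R/B",
    "GLI", "VARI", "NGRDI", "DGCI", "GMR", "R+G-B", "ExG", "ExR", "ExB",
    "AGRI", "R-G", "R-B", "SREx", "TREx",
)


@dataclass(frozen=True)
class IndexValue:
    """One evaluated index: a finite value, or an undefined flag + reason."""

    value: float
    defined: bool = True
    reason: str | None = None

    @staticmethod
    def undefined(reason: str) -> "IndexValue":
        return IndexValue(math.nan, defined=False, reason=reason)


def srex(R: float, G: float, B: float) -> float:
    """Simple Red Excess, SREx = R - G - B (0-255 channel scale)."""
    return R - G - B


def trex(R: float, G: float, B: float) -> float:
    """Two-fold Red Excess, TREx = 2R - G - B (0-255 channel scale).

    Equivalently the sum of the two red-contrast differences,
    (R - G) + (R - B); range [-510, 510].
    """
    return 2.0 * R - G - B


def dgci(H: float, S: float, V: float) -> float:
    """Dark Green Color Index, DGCI = [1 + H/60 - S - V] / 3.

    H must be in degrees (the /60 term maps a 360° hue circle onto [0, 6]).
    """
    return (1.0 + H / 60.0 - S - V) / 3.0


def agri(R: float, G: float) -> IndexValue:
    """Augmented Green-Red Index, AGRI = GMR * G/R; undefined when R = 0."""
    if R == 0:
        return IndexValue.undefined("R = 0 in G/R factor")
    return IndexValue((G - R) * (G / R))


def _ratio(num: float, den: float, reason: str) -> IndexValue:
    if den == 0:
        return IndexValue.undefined(reason)
    return IndexValue(num / den)


def compute_all_indices(
    features: "ColorFeatures", *, table1_literal: bool = False
) -> dict[str, IndexValue]:
    """Evaluate all 22 derived indices from one mean-feature record.

    Returns a dict keyed by :data:`INDEX_NAMES` in canonical order.
    """
    f = features
    R, G, B = f.R, f.G, f.B
    out: dict[str, IndexValue] = {}

    out["NGBDI"] = _ratio(G - B, G + B, "G + B = 0")
    out["NDPI"] = _ratio(R - B, R + B, "R + B = 0")
    out["G/R"] = _ratio(G, R, "R = 0")
    out["G/B"] = _ratio(G, B, "B = 0")
    out["Intensity"] = IndexValue((R + G + B) / 3.0)
    out["R/B"] = _ratio(R, B, "B = 0")
    out["GLI"] = _ratio(2.0 * G - R - B, 2.0 * G + R + B, "2G + R + B = 0")
    out["VARI"] = _ratio(G - R, G + R - B, "G + R - B = 0")
    out["NGRDI"] = _ratio(G - R, G + R, "G + R = 0")
    out["DGCI"] = IndexValue(dgci(f.H, f.S, f.V))
    out["GMR"] = IndexValue(G - R)
    out["R+G-B"] = IndexValue(R + G - B)
    out["ExG"] = IndexValue(2.0 * G - R - B)
    out["AGRI"] = agri(R, G)
    out["R-G"] = IndexValue(R - G)
    out["R-B"] = IndexValue(R - B)
    out["SREx"] = IndexValue(srex(R, G, B))
    out["TREx"] = IndexValue(trex(R, G, B))

    # indices built on chromatic fractions need a defined chromaticity
    r, g, b = f.r, f.g, f.b
    chroma_ok = all(math.isfinite(v) for v in (r, g, b))
    if not chroma_ok:
        for name in ("WI", "NDI", "ExR", "ExB"):
            out[name] = IndexValue.undefined("chromatic rgb undefined (black mean)")
    else:
        if r == g:
            out["WI"] = IndexValue.undefined("|r - g| = 0")
        else:
            out["WI"] = IndexValue((g - b) / abs(r - g))
        out["NDI"] = IndexValue((r - g) / (r + g + 0.01))
        exr = 1.4 * r - g
        exb = 1.4 * b - g
        if table1_literal:
            exr, exb = exb, exr
        out["ExR"] = IndexValue(exr)
        out["ExB"] = IndexValue(exb)

    return {name: out[name] for name in INDEX_NAMES}
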