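"""CIELAB color differences: ΔE76, CIEDE2000, and perceptibility banding.

ΔE76 is the plain Euclidean distance in (L*, a*, b*). CIEDE2000 refines it
with the G chroma correction (rescaling a* for near-neutral colors), hue
rotation R_T, the weighting functions S_L/S_C/S_H and parametric factors
k_L/k_C/k_H:

    ΔE00 = sqrt( (ΔL'/(kL SL))² + (ΔC'/(kC SC))² + (ΔH'/(kH SH))²
                 + R_T · ΔC'/(kC SC) · ΔH'/(kH SH) )

All hue arithmetic is in degrees with atan2-based hue angles in [0°, 360°).
Every intermediate (a', C', h', the means, T, the weights) is exposed on
the returned :class:`ColorDifference` so pairwise difference panels can be
reproduced cell by cell.

ΔE76 magnitudes map onto five perceptibility bands (unnoticeable below 1,
visible only to an experienced observer to 2, to an unexperienced observer
to 3.5, clearly noticeable to 5, two different colors beyond); boundary
values fall to the lower band, i.e. intervals are (lo, hi].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "LabColor",
    "ColorDifference",
    "PerceptibilityBand",
    "PERCEPTIBILITY_BANDS",
    "delta_e76",
    "delta_e00",
    "classify_de76",
    "difference_panel",
]


@dataclass(frozen=True)
class LabColor:
    """A CIELAB triplet (D65/10° assumed)."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class ColorDifference:
    """Full CIEDE2000 difference panel between two Lab colors.

    ``dHp`` is the CIEDE2000 hue-difference term
    2·sqrt(C'1·C'2)·sin(Δh'/2) and ``dhp`` the hue-angle difference in
    degrees; both are reported as magnitudes along with signed use inside
    dE00. Intermediates follow the standard formula notation.
    """

    dE76: float
    dE00: float
    dLp: float
    dCp: float
    dHp: float
    dhp: float
    # intermediates
    G: float
    ap1: float
    ap2: float
    Cp1: float
    Cp2: float
    hp1: float
    hp2: float
    Lp_mean: float
    Cp_mean: float
    hp_mean: float
    T: float
    S_L: float
    S_C: float
    S_H: float
    R_T: float
    k_L: float = 1.0
    k_C: float = 1.0
    k_H: float = 1.0


def delta_e76(c1: LabColor, c2: LabColor) -> float:
    """Euclidean CIELAB distance ΔE*ab (1976)."""
    return math.sqrt((c1.L_star - c2.L_star) ** 2
                     + (c1.a_star - c2.a_star) ** 2
                     + (c1.b_star - c2.b_star) ** 2)


def _hue_angle_deg(ap: float, b: float) -> float:
    """atan2 hue angle in degrees, [0, 360); 0 for a neutral (ap=b=0) color."""
    if ap == 0.0 and b == 0.0:
        return 0.0
    return math.degrees(math.atan2(b, ap)) % 360.0


def delta_e00(c1: LabColor, c2: LabColor,
              k_L: float = 1.0, k_C: float = 1.0, k_H: float = 1.0) -> ColorDifference:
    """CIEDE2000 color difference with all intermediates.

    Symmetric in its two arguments; identical colors give an all-zero
    difference.
    """
    L1, a1, b1 = c1.L_star, c1.a_star, c1.b_star
    L2, a2, b2 = c2.L_star, c2.a_star, c2.b_star

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    C_mean = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - math.sqrt(C_mean**7 / (C_mean**7 + 25.0**7)))

    ap1, ap2 = (1.0 + G) * a1, (1.0 + G) * a2
    Cp1, Cp2 = math.hypot(ap1, b1), math.hypot(ap2, b2)
    hp1, hp2 = _hue_angle_deg(ap1, b1), _hue_angle_deg(ap2, b2)

    dLp = L2 - L1
    dCp = Cp2 - Cp1

    if Cp1 * Cp2 == 0.0:
        dhp = 0.0
    else:
        diff = hp2 - hp1
        if abs(diff) <= 180.0:
            dhp = diff
        elif diff > 180.0:
            dhp = diff - 360.0
        else:
            dhp = diff + 360.0
    dHp = 2.0 * math.sqrt(Cp1 * Cp2) * math.sin(math.radians(dhp) / 2.0)

    Lp_mean = 0.5 * (L1 + L2)
    Cp_mean = 0.5 * (Cp1 + Cp2)
    if Cp1 * Cp2 == 0.0:
        hp_mean = hp1 + hp2
    else:
        s, d = hp1 + hp2, abs(hp1 - hp2)
        if d <= 180.0:
            hp_mean = 0.5 * s
        elif s < 360.0:
            hp_mean = 0.5 * (s + 360.0)
        else:
            hp_mean = 0.5 * (s - 360.0)

    T = (1.0
         - 0.17 * math.cos(math.radians(hp_mean - 30.0))
         + 0.24 * math.cos(math.radians(2.0 * hp_mean))
         + 0.32 * math.cos(math.radians(3.0 * hp_mean + 6.0))
         - 0.20 * math.cos(math.radians(4.0 * hp_mean - 63.0)))

    d_theta = 30.0 * math.exp(-(((hp_mean - 275.0) / 25.0) ** 2))
    R_C = 2.0 * math.sqrt(Cp_mean**7 / (Cp_mean**7 + 25.0**7))
    R_T = -math.sin(math.radians(2.0 * d_theta)) * R_C

    S_L = 1.0 + 0.015 * (Lp_mean - 50.0) ** 2 / math.sqrt(20.0 + (Lp_mean - 50.0) ** 2)
    S_C = 1.0 + 0.045 * Cp_mean
    S_H = 1.0 + 0.015 * Cp_mean * T

    tL = dLp / (k_L * S_L)
    tC = dCp / (k_C * S_C)
    tH = dHp / (k_H * S_H)
    dE00 = math.sqrt(tL**2 + tC**2 + tH**2 + R_T * tC * tH)

    return ColorDifference(
        dE76=delta_e76(c1, c2), dE00=dE00,
        dLp=abs(dLp), dCp=abs(dCp), dHp=abs(dHp), dhp=abs(dhp),
        G=G, ap1=ap1, ap2=ap2, Cp1=Cp1, Cp2=Cp2, hp1=hp1, hp2=hp2,
        Lp_mean=Lp_mean, Cp_mean=Cp_mean, hp_mean=hp_mean,
        T=T, S_L=S_L, S_C=S_C, S_H=S_H, R_T=R_T,
        k_L=k_L, k_C=k_C, k_H=k_H,
    )


@dataclass(frozen=True)
class PerceptibilityBand:
    band: str
    lo: float
    hi: float  # inclusive upper bound; math.inf for the last band


#: (lo, hi] bands for ΔE76 perceptibility
PERCEPTIBILITY_BANDS: tuple[PerceptibilityBand, ...] = (
    PerceptibilityBand("unnoticeable", 0.0, 1.0),
    PerceptibilityBand("experienced-observer", 1.0, 2.0),
    PerceptibilityBand("unexperienced-observer", 2.0, 3.5),
    PerceptibilityBand("clearly-noticeable", 3.5, 5.0),
    PerceptibilityBand("different-colors", 5.0, math.inf),
)

#: footnote markers for panel rendering, matching common reporting practice
BAND_MARKERS: Mapping[str, str] = {
    "unnoticeable": "",
    "experienced-observer": "*",
    "unexperienced-observer": "**",
    "clearly-noticeable": "***",
    "different-colors": "****",
}


def classify_de76(value: float) -> PerceptibilityBand:
    """Map a ΔE76 magnitude onto its perceptibility band ((lo, hi] intervals)."""
    if value < 0:
        raise ValueError("dE76 must be non-negative")
    for band in PERCEPTIBILITY_BANDS:
        if value <= band.hi:
            return band
    raise AssertionError("unreachable: bands partition [0, inf)")


def difference_panel(colors: Mapping[str, LabColor],
                     k_L: float = 1.0, k_C: float = 1.0, k_H: float = 1.0) -> pd.DataFrame:
    """Pairwise difference panel over a named color collection.

    One row per unordered pair (n(n-1)/2 rows) with dE00, dE76 and its
    perceptibility marker, and the |ΔL'|, |ΔC'|, |Δh'|, |ΔH'| terms.
    """
    names = list(colors)
    if len(names) < 2:
        raise ValueError("need at least two named colors")
    if len(set(names)) != len(names):
        raise ValueError("duplicate color names")
    rows = []
    for n1, n2 in itertools.combinations(names, 2):
        d = delta_e00(colors[n1], colors[n2], k_L=k_L, k_C=k_C, k_H=k_H)
        rows.append({
            "pair": f"{n1}-{n2}",
            "dE00": d.dE00,
            "dE76": d.dE76,
            "band": classify_de76(d.dE76).band,
            "marker": BAND_MARKERS[classify_de76(d.dE76).band],
            "dL": d.dLp,
            "dC": d.dCp,
            "dh": d.dhp,
            "dH": d.dHp,
        })
    return pd.DataFrame(rows).set_index("pair")
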