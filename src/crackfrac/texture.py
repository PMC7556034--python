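"""Puncture-test feature extraction from force-deformation curves.

A cylindrical probe is driven through the cookie (20 mm travel at 1 mm/s
in the reference protocol); the recorded force-distance trace shows a
rise to a crust peak, a drop, and a plateau through the soft interior.
Three features are derived:

* hardness (N): the maximum force reached during puncturing;
* crust thickness (mm): distance from the start of the test to the onset
  of the maximum force;
* work of deformation, WOD (N mm): area under the curve from the maximum
  force to complete probe penetration (the last recorded point),
  integrated by the trapezoid rule over the recorded samples.

The start of the test is the first sample whose force reaches a contact
threshold (default 0.05 N; set 0 to use the first sample). If the peak
force occurs at several points the first occurrence defines both the
thickness and the WOD integration start. No smoothing is applied before
peak detection; an optional moving-average window is available for noisy
instruments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ForceCurve", "TextureFeatures", "extract_features", "batch_features"]


@dataclass(frozen=True)
class ForceCurve:
    """Ordered (distance mm, force N) samples of one puncture test."""

    distance_mm: np.ndarray
    force_N: np.ndarray
    curve_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_mm, dtype=float).ravel()
        f = np.asarray(self.force_N, dtype=float).ravel()
        if d.size != f.size:
            raise ValueError("distance and force arrays differ in length")
        if d.size < 3:
            raise ValueError("a force curve needs at least 3 points")
        if not np.all(np.diff(d) > 0):
            raise ValueError("distances must be strictly increasing")
        if not np.all(f >= 0):
            raise ValueError("forces must be non-negative")
        object.__setattr__(self, "distance_mm", d)
        object.__setattr__(self, "force_N", f)


@dataclass(frozen=True)
class TextureFeatures:
    hardness_N: float
    crust_thickness_mm: float
    wod_Nmm: float


def extract_features(curve: ForceCurve, contact_threshold_N: float = 0.05,
                     smooth_window: int = 0) -> TextureFeatures:
    """Compute hardness, crust thickness and WOD from one curve.

    Raises a no-contact error on an all-zero curve. With
    ``smooth_window > 1`` a centered moving average defines the working
    trace used for peak detection and hardness (the WOD integration
    still uses the raw forces); by default the raw trace is used and
    hardness equals the maximum recorded force exactly.
    """
    if contact_threshold_N < 0:
        raise ValueError("contact_threshold_N must be >= 0")
    d, f = curve.distance_mm, curve.force_N
    if np.all(f == 0):
        raise ValueError(f"no contact detected: curve {curve.curve_id!r} is all-zero")

    f_peak = f
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        f_peak = np.convolve(f, kernel, mode="same")

    above = np.nonzero(f_peak >= contact_threshold_N)[0]
    start = int(above[0]) if above.size else 0

    rel = f_peak[start:]
    peak = start + int(np.argmax(rel))  # first occurrence of the maximum
    hardness = float(np.max(rel))
    thickness = float(d[peak] - d[start])
    wod = float(np.trapezoid(f[peak:], d[peak:]))
    return TextureFeatures(hardness_N=hardness, crust_thickness_mm=thickness,
                           wod_Nmm=wod)


def batch_features(curves: Iterable[ForceCurve],
                   groups: Sequence[str] | None = None,
                   contact_threshold_N: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features for a batch of curves plus per-group mean and SD.

    Returns ``(per_curve, per_group)`` frames; SD is the sample (ddof=1)
    standard deviation, NaN for singleton groups.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    if groups is None:
        groups = [""] * len(curves)
    if len(groups) != len(curves):
        raise ValueError("groups must match curves in length")
    rows = []
    for curve, group in zip(curves, groups):
        feats = extract_features(curve, contact_threshold_N=contact_threshold_N)
        rows.append({
            "curve_id": curve.curve_id,
            "group": group,
            "hardness_N": feats.hardness_N,
            "thickness_mm": feats.crust_thickness_mm,
            "wod_Nmm": feats.wod_Nmm,
        })
    per_curve = pd.DataFrame(rows)
    per_group = per_curve.groupby("group")[["hardness_N", "thickness_mm", "wod_Nmm"]].agg(
        ["mean", "std"])
    return per_curve, per_group
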