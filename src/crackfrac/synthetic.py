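"""Seeded generators for every input the toolkit consumes.

All fitting and segmentation code is testable without the original study
data: each generator is a pure function of its parameters and a seed, and
returns ground truth alongside the data.

* :func:`gen_lognormal` / :func:`gen_powerlaw` — area samples from the two
  component distributions (parameters in back-transformed form:
  geometric mean ``mu_star``, geometric SD ``sigma_star``; Pareto
  exponent ``alpha`` and cutoff ``xmin``).
* :func:`gen_spliced` — the body-plus-tail composite that emulates real
  crack-area samples: log-normal body below ``xmin``, power-law tail
  above. The default tail weight is moment-matched so the composite's
  geometric mean equals the nominal ``mu_star`` (see ``tail_fraction``).
* :func:`gen_crack_image` — dark blobs of exactly requested pixel areas
  on a light textured background, with the exact ground-truth mask.
* :func:`gen_force_curve` — puncture-test trace: linear rise to the crust
  peak, exponential drop, plateau to full travel.

Defaults for the spliced sampler sit in the range observed for real
amaretti crack areas (mu* ~ 0.21-0.31 mm^2, sigma* ~ 3.2-3.4,
alpha ~ 1.67, xmin ~ 0.22-0.29 mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .imaging import BinaryMask
from .texture import ForceCurve

__all__ = [
    "gen_lognormal",
    "gen_powerlaw",
    "gen_spliced",
    "SplicedTruth",
    "gen_crack_image",
    "gen_force_curve",
]

_MAX_REJECTIONS = 10**6


def gen_lognormal(mu_star: float, sigma_star: float, n: int,
                  seed: int | np.random.Generator) -> np.ndarray:
    """n log-normal draws with ln(x) ~ Normal(ln mu_star, ln sigma_star)."""
    if not (mu_star > 0 and sigma_star >= 1):
        raise ValueError("need mu_star > 0 and sigma_star >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(np.log(mu_star), np.log(sigma_star), size=n))


def gen_powerlaw(xmin: float, alpha: float, n: int,
                 seed: int | np.random.Generator) -> np.ndarray:
    """n Pareto draws by inversion: x = xmin * (1 - u)^(-1/(alpha-1))."""
    if not (xmin > 0 and alpha > 1):
        raise ValueError("need xmin > 0 and alpha > 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


@dataclass(frozen=True)
class SplicedTruth:
    """Generator truth for a spliced body+tail sample."""

    mu_star: float
    sigma_star: float
    xmin: float
    alpha: float
    tail_fraction: float
    n: int
    seed: int | None = None

    @property
    def log_geo_mean(self) -> float:
        """Analytic mean of ln X under the spliced distribution."""
        return _spliced_log_mean(self.mu_star, self.sigma_star, self.xmin,
                                 self.alpha, self.tail_fraction)


def _body_tail_log_means(mu_star: float, sigma_star: float, xmin: float,
                         alpha: float) -> tuple[float, float]:
    mu, sigma = np.log(mu_star), np.log(sigma_star)
    z = (np.log(xmin) - mu) / sigma
    # truncated normal below z: E[ln X | X < xmin]
    e_body = mu - sigma * stats.norm.pdf(z) / stats.norm.cdf(z)
    # Pareto tail: E[ln X | X >= xmin]
    e_tail = np.log(xmin) + 1.0 / (alpha - 1.0)
    return float(e_body), float(e_tail)


def _spliced_log_mean(mu_star, sigma_star, xmin, alpha, tail_fraction) -> float:
    e_body, e_tail = _body_tail_log_means(mu_star, sigma_star, xmin, alpha)
    return (1.0 - tail_fraction) * e_body + tail_fraction * e_tail


def matched_tail_fraction(mu_star: float, sigma_star: float, xmin: float,
                          alpha: float) -> float:
    """Tail weight that makes the spliced geometric mean equal mu_star.

    Solves ``(1-tf) E[ln X | body] + tf E[ln X | tail] = ln(mu_star)``.
    """
    e_body, e_tail = _body_tail_log_means(mu_star, sigma_star, xmin, alpha)
    tf = (np.log(mu_star) - e_body) / (e_tail - e_body)
    if not 0.0 < tf < 1.0:
        raise ValueError(
            f"no admissible moment-matched tail fraction for these parameters ({tf:.3f})")
    return float(tf)


def gen_spliced(mu_star: float = 0.26, sigma_star: float = 3.3,
                xmin: float = 0.25, alpha: float = 1.67,
                tail_fraction: float | str = "auto", n: int = 5000,
                seed: int | np.random.Generator = 0) -> tuple[np.ndarray, SplicedTruth]:
    """Spliced sample: log-normal body below xmin, power-law tail above.

    With probability ``tail_fraction`` a value is an exact Pareto draw at
    ``xmin``; otherwise it comes from the log-normal truncated below
    ``xmin`` (rejection sampling). ``tail_fraction="auto"`` moment-matches
    the tail weight so the composite's geometric mean equals ``mu_star``,
    which is what makes the truth record round-trip through the
    log-normal fit. Returns ``(values, truth)``.
    """
    if not (mu_star > 0 and sigma_star > 1 and xmin > 0 and alpha > 1):
        raise ValueError("invalid spliced parameters")
    if n < 1:
        raise ValueError("n must be >= 1")
    if tail_fraction == "auto":
        tf = matched_tail_fraction(mu_star, sigma_star, xmin, alpha)
    else:
        tf = float(tail_fraction)
        if not 0.0 <= tf <= 1.0:
            raise ValueError("tail_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    in_tail = rng.random(n) < tf
    n_tail = int(in_tail.sum())
    values = np.empty(n)
    values[in_tail] = gen_powerlaw(xmin, alpha, n_tail, rng) if n_tail else 0.0

    n_body = n - n_tail
    body = np.empty(0)
    rejections = 0
    while body.size < n_body:
        draw = gen_lognormal(mu_star, sigma_star, max(n_body, 64), rng)
        keep = draw[draw < xmin]
        rejections += draw.size - keep.size
        if rejections > _MAX_REJECTIONS:
            raise RuntimeError("truncated log-normal rejection budget exhausted")
        body = np.concatenate([body, keep])
    values[~in_tail] = body[:n_body]
    truth = SplicedTruth(mu_star=mu_star, sigma_star=sigma_star, xmin=xmin,
                         alpha=alpha, tail_fraction=tf, n=n,
                         seed=seed if isinstance(seed, int) else None)
    return values, truth


def _grow_blob(rng: np.random.Generator, start: tuple[int, int], area: int,
               shape: tuple[int, int], forbidden: np.ndarray) -> np.ndarray | None:
    """Grow a 4-connected region of exactly ``area`` pixels by random accretion.

    Returns the boolean region, or None if growth stalls against the
    canvas edge / forbidden zone.
    """
    region = np.zeros(shape, dtype=bool)
    r0, c0 = start
    if forbidden[r0, c0]:
        return None
    region[r0, c0] = True
    frontier = [(r0, c0)]
    count = 1
    while count < area:
        candidates = []
        for r, c in frontier:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1] \
                        and not region[rr, cc] and not forbidden[rr, cc]:
                    candidates.append((rr, cc))
        if not candidates:
            return None
        rr, cc = candidates[rng.integers(len(candidates))]
        region[rr, cc] = True
        count += 1
        frontier.append((rr, cc))
        # keep the frontier lean: drop interior pixels occasionally
        if len(frontier) > 4 * int(np.sqrt(area)) + 16:
            frontier = [
                (r, c) for r, c in frontier
                if any(0 <= r + dr < shape[0] and 0 <= c + dc < shape[1]
                       and not region[r + dr, c + dc] and not forbidden[r + dr, c + dc]
                       for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)))
            ]
    return region


def gen_crack_image(area_list_px: list[int], canvas_shape: tuple[int, int] = (256, 256),
                    seed: int | np.random.Generator = 0,
                    background_mean: float = 200.0, background_sd: float = 10.0,
                    blob_mean: float = 40.0, blob_sd: float = 10.0,
                    pixel_pitch_um: float = 63.5,
                    max_attempts: int = 200) -> tuple[np.ndarray, BinaryMask]:
    """Dark blobs of exactly the requested pixel areas on a light background.

    Blobs are random-walk-grown connected regions; any two blobs are
    separated by at least 2 background pixels (Chebyshev gap >= 2), so
    8-connected labeling recovers them individually. Background and blob
    intensities are Gaussian (clipped to [0, 255]) with a contrast that
    keeps the two histogram modes Otsu-separable. Returns the 8-bit image
    and the exact ground-truth mask.
    """
    from skimage.morphology import dilation, footprint_rectangle

    rng = np.random.default_rng(seed)
    shape = tuple(canvas_shape)
    if any(a < 1 for a in area_list_px):
        raise ValueError("every blob area must be >= 1 px")
    if sum(area_list_px) > 0.3 * shape[0] * shape[1]:
        raise ValueError("requested blob area exceeds 30% of the canvas")

    mask = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)  # occupied + 2-px guard band
    gap = footprint_rectangle((5, 5))       # dilation radius 2 (Chebyshev)
    # place large blobs first: they are the hardest to pack
    for area in sorted(area_list_px, reverse=True):
        placed = False
        for _ in range(max_attempts):
            start = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
            region = _grow_blob(rng, start, int(area), shape, forbidden)
            if region is not None:
                mask |= region
                forbidden |= dilation(region, gap)
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place a blob of {area} px "
                               f"(infeasible packing on {shape} canvas)")

    img = rng.normal(background_mean, background_sd, size=shape)
    img[mask] = rng.normal(blob_mean, blob_sd, size=int(mask.sum()))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, BinaryMask(mask)


def gen_force_curve(hardness: float = 12.0, thickness: float = 2.0,
                    plateau_force: float = 3.0, travel: float = 20.0,
                    step: float = 0.01, noise_sd: float = 0.0,
                    seed: int | np.random.Generator = 0,
                    drop_width: float = 1.0, curve_id: str = "") -> ForceCurve:
    """Puncture trace: linear rise to (thickness, hardness), exponential
    drop to the plateau, plateau to full travel, plus Gaussian noise.

    The distance grid always contains the peak point exactly, so with
    ``noise_sd=0`` the features round-trip through feature extraction.
    """
    if not (0 < thickness < travel):
        raise ValueError("need 0 < thickness < travel")
    if not (hardness > 0 and 0 < plateau_force <= hardness):
        raise ValueError("need 0 < plateau_force <= hardness")
    if step <= 0 or drop_width <= 0:
        raise ValueError("step and drop_width must be positive")
    rng = np.random.default_rng(seed)
    d = np.arange(0.0, travel + step / 2, step)
    if not np.any(np.isclose(d, thickness)):
        d = np.sort(np.append(d, thickness))
    f = np.empty_like(d)
    rise = d <= thickness
    f[rise] = hardness * d[rise] / thickness
    after = ~rise
    f[after] = plateau_force + (hardness - plateau_force) * np.exp(
        -5.0 * (d[after] - thickness) / drop_width)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    f = np.clip(f, 0.0, None)
    return ForceCurve(d, f, curve_id=curve_id)
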