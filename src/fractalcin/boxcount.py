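"""Box-counting (monofractal) dimension of a binary mask.

The box-counting dimension d_BOX of a set is the scaling exponent of the
number N(r) of grid boxes of side r that intersect the set:

    N(r) ~ r^(-d_BOX)   as r -> 0,

estimated here as the negative slope of an ordinary least-squares fit of
log N(r) against log r over a geometric ladder of box sizes.  The grid is
anchored at the top-left corner; images whose side is not a power of the
scale base are padded with background so that every box size tiles the
image exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging import NucleiMask

__all__ = ["BoxCountResult", "BoxCountConfig", "count_boxes", "fit_loglog", "box_dimension"]


class DegenerateMaskError(ValueError):
    """Raised when a mask has no foreground; d_BOX is undefined."""


@dataclass
class BoxCountConfig:
    """Scale-selection policy for :func:`box_dimension`.

    base:
        Geometric base of the box-size ladder (2 for dyadic, 3 for triadic
        patterns such as the Sierpinski carpet).
    drop_largest:
        Number of the largest scales to exclude from the regression
        (the r = L box always has N = 1 and carries no information; it is
        kept by default).
    min_side:
        Smallest box side included in the ladder.
    n_offsets:
        When > 1, each scale is counted at this many grid origins along the
        diagonal and the minimum count retained (a cheap approximation to
        multi-grid sampling); default is the single top-left origin.
    """

    base: int = 2
    drop_largest: int = 0
    min_side: int = 2
    n_offsets: int = 1


def _pad_to_multiple(pixels: np.ndarray, side: int) -> np.ndarray:
    """Pad with background so the image side becomes exactly ``side``."""
    h, w = pixels.shape
    if (h, w) == (side, side):
        return pixels
    out = np.zeros((side, side), dtype=bool)
    out[:h, :w] = pixels
    return out


def _padded_side(n: int, base: int) -> int:
    side = base
    while side < n:
        side *= base
    return side


def default_scales(image_side: int, base: int = 2, min_side: int = 2) -> list[int]:
    """Geometric ladder of box sides {L, L/base, ..., >= min_side}."""
    scales = []
    r = image_side
    while r >= max(min_side, 1):
        scales.append(r)
        if r == 1:
            break
        r //= base
    return scales


def count_boxes(
    mask: NucleiMask | np.ndarray,
    scales: list[int],
    offset: tuple[int, int] = (0, 0),
) -> list[tuple[int, int]]:
    """Count occupied grid boxes at each box side in ``scales``.

    Returns ``[(r, N(r)), ...]`` where N(r) is the number of axis-aligned
    boxes of side r (top-left-anchored grid, optionally shifted by
    ``offset``) containing at least one foreground pixel.
    """
    pixels = mask.pixels if isinstance(mask, NucleiMask) else np.asarray(mask, dtype=bool)
    if not pixels.any():
        raise DegenerateMaskError("empty mask: box-counting dimension undefined")
    if not scales:
        raise ValueError("no scales given")
    out = []
    for r in scales:
        if r < 1:
            raise ValueError(f"box side must be >= 1, got {r}")
        dy, dx = offset[0] % r, offset[1] % r
        shifted = np.zeros(
            (pixels.shape[0] + dy, pixels.shape[1] + dx), dtype=bool
        )
        shifted[dy:, dx:] = pixels
        # pad to an exact multiple of r (cheapest sufficient padding)
        side = int(np.ceil(max(shifted.shape) / r)) * r
        padded = _pad_to_multiple(shifted, side)
        n = side // r
        occupied = padded.reshape(n, r, n, r).any(axis=(1, 3))
        out.append((int(r), int(occupied.sum())))
    return out


def fit_loglog(points: list[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS fit of log N against log r; returns (slope, intercept, r_squared).

    Natural logs are used; the base cancels in the slope.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 points for a log-log fit, got {len(points)}")
    r = np.array([p[0] for p in points], dtype=float)
    n = np.array([p[1] for p in points], dtype=float)
    if np.any(n <= 0) or np.any(r <= 0):
        raise ValueError("all scales and counts must be positive")
    res = stats.linregress(np.log(r), np.log(n))
    r2 = 1.0 if np.allclose(np.log(n), np.log(n)[0]) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


@dataclass
class BoxCountResult:
    """Scales, counts and fitted dimension for one mask."""

    scales: list[int]
    counts: list[int]
    slope: float
    intercept: float
    r_squared: float
    d_box: float = field(init=False)

    def __post_init__(self) -> None:
        self.d_box = -self.slope

    @property
    def n_scales_used(self) -> int:
        return len(self.scales)

    def to_dict(self) -> dict:
        return {
            "scales": self.scales,
            "counts": self.counts,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "d_box": self.d_box,
            "n_scales_used": self.n_scales_used,
        }


def box_dimension(
    mask: NucleiMask | np.ndarray,
    config: BoxCountConfig | None = None,
    scales: list[int] | None = None,
) -> BoxCountResult:
    """Estimate d_BOX of a binary mask.

    ``scales`` overrides the config's geometric ladder when given.  With
    ``config.n_offsets > 1`` the minimum count over shifted grid origins is
    used at each scale.
    """
    config = config or BoxCountConfig()
    pixels = mask.pixels if isinstance(mask, NucleiMask) else np.asarray(mask, dtype=bool)
    if scales is None:
        side = _padded_side(max(pixels.shape), config.base)
        scales = default_scales(side, base=config.base, min_side=config.min_side)
        scales = scales[config.drop_largest:]
    if len(scales) < 3:
        raise ValueError("scale ladder too short for regression (need >= 3 scales)")
    if config.n_offsets <= 1:
        points = count_boxes(pixels, scales)
    else:
        points = []
        for r in scales:
            offsets = [(int(k * r / config.n_offsets),) * 2 for k in range(config.n_offsets)]
            n_min = min(count_boxes(pixels, [r], offset=o)[0][1] for o in offsets)
            points.append((r, n_min))
    slope, intercept, r2 = fit_loglog(points)
    return BoxCountResult(
        scales=[p[0] for p in points],
        counts=[p[1] for p in points],
        slope=slope,
        intercept=intercept,
        r_squared=r2,
    )
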