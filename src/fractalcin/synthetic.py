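"""Synthetic inputs: benchmark fractals, multiplicative cascades, and
grade-parameterized pseudo-histology tiles.

Three families of generators make every pipeline stage testable without
any external data:

* deterministic benchmark sets (filled square, point, line, Sierpinski
  triangle and carpet) whose box-counting dimensions are known in closed
  form;
* 2-D multiplicative cascades — recursive subdivision of the unit square
  into four cells with fixed mass weights w1..w4 — whose generalized
  dimension spectrum has the closed form
  ``D_q = -log2(sum_i w_i^q) / (q - 1)`` (entropy form at q = 1), serving
  as an exact oracle for the D_q estimator;
* pseudo-H&E tiles: blue-purple elliptical nuclei on a pink eosin-like
  background, where a basal strip of the epithelium (its height the
  "atypia fraction" of the tile) carries densely clustered, enlarged,
  pleomorphic nuclei.  The atypia fraction follows the histological
  thirds rule — 0 for normal epithelium, 1/3 for CIN 1, 2/3 for CIN 2 and
  the full height for CIN 3 — so nuclear coverage, and with it the
  box-counting dimension of the segmented mask, rises with grade.

The histology generator targets the statistical structure the analysis
assumes (denser, more space-filling nuclear masks at higher grade), not
visual realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.draw import ellipse

from .imaging import NucleiMask, RgbTile

__all__ = [
    "GRADES",
    "GRADE_ATYPIA_FRACTION",
    "CascadeSpec",
    "HistologySpec",
    "StudyTile",
    "render_benchmark",
    "generate_cascade",
    "cascade_analytic_dq",
    "generate_histology",
    "generate_study",
    "DEFAULT_GROUP_SIZES",
]

GRADES = ("normal", "CIN1", "CIN2", "CIN3")

#: fraction of the epithelium height occupied by atypical cells, per grade
GRADE_ATYPIA_FRACTION = {"normal": 0.0, "CIN1": 1 / 3, "CIN2": 2 / 3, "CIN3": 1.0}

#: default cohort shape: 46 cases over the four groups
DEFAULT_GROUP_SIZES = {"normal": 15, "CIN1": 8, "CIN2": 6, "CIN3": 17}

BENCHMARK_DIMENSIONS = {
    "filled_square": 2.0,
    "point": 0.0,
    "hline": 1.0,
    "sierpinski_triangle": np.log(3) / np.log(2),
    "sierpinski_carpet": np.log(8) / np.log(3),
}


def _is_power(n: int, base: int) -> bool:
    if n < 1:
        return False
    while n % base == 0:
        n //= base
    return n == 1


def render_benchmark(name: str, size: int) -> NucleiMask:
    """Render a deterministic benchmark set with known dimension.

    ``sierpinski_triangle`` requires a power-of-2 size (3^k cells at depth
    k), ``sierpinski_carpet`` a power-of-3 size (8^k cells).  The known
    dimension is attached as provenance metadata.
    """
    if name not in BENCHMARK_DIMENSIONS:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARK_DIMENSIONS)}")
    if name == "sierpinski_carpet":
        if not _is_power(size, 3):
            raise ValueError(f"sierpinski_carpet needs a power-of-3 size, got {size}")
    elif size < 1 or (name == "sierpinski_triangle" and not _is_power(size, 2)):
        raise ValueError(f"{name} needs a power-of-2 size, got {size}")

    if name == "filled_square":
        px = np.ones((size, size), dtype=bool)
    elif name == "point":
        px = np.zeros((size, size), dtype=bool)
        px[size // 2, size // 2] = True
    elif name == "hline":
        px = np.zeros((size, size), dtype=bool)
        px[size // 2, :] = True
    elif name == "sierpinski_triangle":
        # cell (i, j) occupied iff i AND j share no binary digit
        i = np.arange(size)
        px = np.bitwise_and.outer(i, i) == 0
    else:  # sierpinski_carpet: no base-3 digit position where both are 1
        i = np.arange(size)
        px = np.ones((size, size), dtype=bool)
        p = 1
        while p < size:
            d = (i // p) % 3
            px &= ~np.outer(d == 1, d == 1)
            p *= 3
    return NucleiMask(
        pixels=px,
        id=f"{name}_{size}",
        provenance={"benchmark": name, "known_dimension": float(BENCHMARK_DIMENSIONS[name])},
    )


@dataclass
class CascadeSpec:
    """Parameters of a 2-D four-cell multiplicative cascade."""

    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    depth: int = 6
    mode: Literal["exact_measure", "point_sample"] = "exact_measure"
    n_points: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != 4:
            raise ValueError("cascade needs exactly 4 weights")
        if (w < 0).any():
            raise ValueError("cascade weights must be non-negative")
        if not np.isclose(w.sum(), 1.0, atol=1e-12):
            raise ValueError(f"cascade weights must sum to 1, got {w.sum()!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def side(self) -> int:
        return 2**self.depth


def cascade_analytic_dq(weights, q) -> np.ndarray:
    """Closed-form D_q of a four-cell cascade; zero weights are excluded.

    ``D_q = -log2(sum w_i^q)/(q-1)`` for q != 1 and
    ``D_1 = -sum w_i log2 w_i``.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty_like(q)
    for i, qi in enumerate(q):
        if np.isclose(qi, 1.0):
            out[i] = -float(np.sum(w * np.log2(w)))
        else:
            out[i] = -np.log2(np.sum(w**qi)) / (qi - 1.0)
    return out if out.size > 1 else out


def generate_cascade(spec: CascadeSpec):
    """Generate a cascade measure and its analytic-spectrum closure.

    ``exact_measure`` returns the 2^depth x 2^depth cell-mass array (sums
    to 1); ``point_sample`` draws ``n_points`` i.i.d. cells from that
    measure and returns the integer point-count grid (summing to
    ``n_points``).  Point counts, not binary occupancy, are returned
    because the moment estimator needs N_υ = points per box: binarizing
    saturates dense cells and biases D_q for q > 0.  The occupancy mask is
    ``counts > 0`` if needed.  The second return value is a vectorized
    ``analytic_dq(q)`` closure.
    """
    w = np.asarray(spec.weights, dtype=float).reshape(2, 2)

    def analytic(q):
        return cascade_analytic_dq(spec.weights, q)

    if spec.mode == "exact_measure":
        grid = np.ones((1, 1))
        for _ in range(spec.depth):
            grid = np.kron(grid, w)
        return grid, analytic

    rng = np.random.default_rng(spec.seed)
    flat_w = np.asarray(spec.weights, dtype=float)
    rows = np.zeros(spec.n_points, dtype=np.int64)
    cols = np.zeros(spec.n_points, dtype=np.int64)
    for _ in range(spec.depth):
        quadrant = rng.choice(4, size=spec.n_points, p=flat_w)
        rows = rows * 2 + quadrant // 2
        cols = cols * 2 + quadrant % 2
    counts = np.zeros((spec.side, spec.side), dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    return counts, analytic


@dataclass
class HistologySpec:
    """Parameters of one pseudo-H&E tile.

    ``atypia_fraction`` defaults to the thirds rule for the grade.
    Densities are nuclei per pixel^2; radii in pixels.  The palette is
    chosen so the nuclear blue share (~56 %) and background blue share
    (~33 %) straddle the 41 % segmentation threshold with margin.
    """

    size: int = 1024
    grade: str = "normal"
    atypia_fraction: float | None = None
    nucleus_density: float = 4.5e-4
    radius_mean: float = 7.0
    radius_sd: float = 1.5
    atypical_density_factor: float = 3.5
    atypical_radius_factor: float = 1.35
    cluster_size: int = 6
    cluster_spread: float = 18.0
    nucleus_rgb: tuple[int, int, int] = (70, 50, 150)
    background_rgb: tuple[int, int, int] = (235, 185, 205)
    colour_jitter: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}; choose from {GRADES}")
        if self.atypia_fraction is None:
            self.atypia_fraction = GRADE_ATYPIA_FRACTION[self.grade]
        if not 0.0 <= self.atypia_fraction <= 1.0:
            raise ValueError("atypia_fraction must lie in [0, 1]")


def _draw_nuclei(mask, centers, rng, r_mean, r_sd, min_ratio):
    """Stamp rotated ellipses at the given centers; returns per-nucleus params."""
    params = []
    for cy, cx in centers:
        r_major = max(2.0, rng.normal(r_mean, r_sd))
        r_minor = r_major * rng.uniform(min_ratio, 1.0)
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, r_major, r_minor, shape=mask.shape, rotation=theta)
        mask[rr, cc] = True
        params.append((rr, cc))
    return params


def generate_histology(spec: HistologySpec) -> tuple[RgbTile, NucleiMask]:
    """Render one pseudo-H&E tile plus its exact ground-truth nucleus mask.

    The basal ``atypia_fraction`` of the tile height carries clustered
    atypical nuclei (denser, larger, more pleomorphic, placed by a
    parent-offspring cluster process); the remainder carries sparse,
    regular nuclei.  Deterministic for a given spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    H = W = spec.size
    strip_h = int(round(spec.atypia_fraction * H))
    regular_h = H - strip_h

    # packing feasibility check for the atypical strip
    atypical_cov = (
        spec.nucleus_density * spec.atypical_density_factor
        * np.pi * (spec.radius_mean * spec.atypical_radius_factor) ** 2
    )
    if atypical_cov > 0.9:
        warnings.warn(
            f"requested atypical nuclear coverage {atypical_cov:.2f} exceeds packing"
            " feasibility; nuclei will overlap heavily",
            stacklevel=2,
        )

    mask = np.zeros((H, W), dtype=bool)
    nuclei = []

    if regular_h > 0:
        n_reg = rng.poisson(spec.nucleus_density * W * regular_h)
        centers = np.column_stack(
            [rng.uniform(0, regular_h, n_reg), rng.uniform(0, W, n_reg)]
        )
        nuclei += _draw_nuclei(mask, centers, rng, spec.radius_mean, spec.radius_sd, 0.7)

    if strip_h > 0:
        n_aty = rng.poisson(
            spec.nucleus_density * spec.atypical_density_factor * W * strip_h
        )
        n_parents = max(1, int(np.ceil(n_aty / spec.cluster_size)))
        parents = np.column_stack(
            [rng.uniform(regular_h, H, n_parents), rng.uniform(0, W, n_parents)]
        )
        idx = rng.integers(0, n_parents, n_aty)
        offsets = rng.normal(0, spec.cluster_spread, size=(n_aty, 2))
        centers = parents[idx] + offsets
        centers[:, 0] = np.clip(centers[:, 0], regular_h, H - 1)
        centers[:, 1] = np.clip(centers[:, 1], 0, W - 1)
        nuclei += _draw_nuclei(
            mask, centers, rng,
            spec.radius_mean * spec.atypical_radius_factor,
            spec.radius_sd * 1.5, 0.5,
        )

    jit = spec.colour_jitter
    pixels = np.empty((H, W, 3), dtype=np.int16)
    bg = np.asarray(spec.background_rgb, dtype=np.int16)
    pixels[:] = bg
    pixels += rng.integers(-jit, jit + 1, size=(H, W, 3), dtype=np.int16)
    nuc = np.asarray(spec.nucleus_rgb, dtype=np.int16)
    for rr, cc in nuclei:
        colour = nuc + rng.integers(-jit, jit + 1, size=3)
        pixels[rr, cc] = colour
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)

    tile_id = f"{spec.grade}_s{spec.seed}"
    tile = RgbTile(pixels=pixels, id=tile_id)
    truth = NucleiMask(
        pixels=mask,
        id=tile_id,
        provenance={"generator": "pseudo_histology", "grade": spec.grade,
                    "atypia_fraction": float(spec.atypia_fraction), "seed": spec.seed},
    )
    return tile, truth


@dataclass
class StudyTile:
    """One labelled cohort member: tile, ground truth and identifiers."""

    case_id: str
    grade: str
    tile: RgbTile
    truth: NucleiMask


def generate_study(
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    size: int = 1024,
    spec_overrides: dict | None = None,
) -> list[StudyTile]:
    """Generate a labelled synthetic cohort (default 15/8/6/17 = 46 tiles).

    Per-tile seeds are spawned deterministically from ``seed``, so the same
    seed yields a bit-identical cohort and different seeds yield different
    tiles with the same labels.
    """
    n_per_group = n_per_group or dict(DEFAULT_GROUP_SIZES)
    for g, n in n_per_group.items():
        if g not in GRADES:
            raise ValueError(f"unknown grade {g!r}")
        if n < 1:
            raise ValueError(f"need >= 1 tile per requested group, got {n} for {g}")
    overrides = spec_overrides or {}
    ss = np.random.SeedSequence(seed)
    total = sum(n_per_group.values())
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(total)]
    out = []
    k = 0
    for grade in GRADES:
        for i in range(n_per_group.get(grade, 0)):
            spec = HistologySpec(size=size, grade=grade, seed=child_seeds[k], **overrides)
            tile, truth = generate_histology(spec)
            out.append(StudyTile(case_id=f"{grade}_{i:02d}", grade=grade, tile=tile, truth=truth))
            k += 1
    return out
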