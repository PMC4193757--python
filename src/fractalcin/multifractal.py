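"""Generalized-dimension (D_q) spectra from box masses.

For a measure coarse-grained onto grid boxes of relative side ε, with box
probabilities p_υ(ε) = N_υ(ε) / Σ_υ N_υ(ε) taken over *non-empty* boxes,
the generalized dimensions are defined through the scaling of the moment
("partition") sums:

    q != 1:  D_q = 1/(q-1) * lim  ln Σ_υ p_υ(ε)^q / ln ε
    q == 1:  D_1 =           lim  Σ_υ p_υ(ε) ln p_υ(ε) / ln ε

On a finite image the limits are replaced by least-squares slopes across a
ladder of box sizes.  D_0 is the box-counting dimension (Σ p^0 counts the
non-empty boxes) and D_1 the information dimension; D_q is non-increasing
in q, with q < 0 weighting sparse boxes and q > 0 dense ones.

Empty boxes are always excluded: for q < 0 the moment of a vanishing mass
diverges, so the sums are over boxes where p_υ is defined and positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxcount import DegenerateMaskError, fit_loglog
from .imaging import NucleiMask

__all__ = [
    "MultifractalSpectrum",
    "default_q_grid",
    "default_mf_scales",
    "box_masses",
    "partition_function",
    "dq_spectrum",
    "spectrum_table",
]


def default_q_grid() -> np.ndarray:
    """Moment orders q from -10 to +10.75 in steps of 0.25 (84 values)."""
    return -10.0 + 0.25 * np.arange(84)


def default_mf_scales(image_side: int, min_side: int = 4) -> list[int]:
    """Dyadic box sides from L/2 down to ``min_side``.

    The r = L box is dropped (its partition sum is identically 1) and very
    small boxes are dropped because negative-q moments of near-empty boxes
    destabilize the regression.
    """
    scales = []
    r = image_side // 2
    while r >= min_side:
        scales.append(r)
        r //= 2
    return scales


def _as_grid(mask: NucleiMask | np.ndarray) -> np.ndarray:
    """Accept a binary mask or a non-negative mass grid as a float array."""
    if isinstance(mask, NucleiMask):
        return mask.pixels.astype(np.float64)
    arr = np.asarray(mask, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D grid, got {arr.ndim}-D")
    if (arr < 0).any():
        raise ValueError("mass grid must be non-negative")
    return arr


def box_masses(mask: NucleiMask | np.ndarray, eps: int) -> np.ndarray:
    """Masses N_υ(ε) of all non-empty grid boxes of side ``eps``.

    For a binary mask the mass of a box is its foreground-pixel count, so
    the masses sum to the total foreground count exactly.  The grid is
    top-left-anchored; ragged edges are padded with zero mass.
    """
    grid = _as_grid(mask)
    if grid.sum() == 0:
        raise DegenerateMaskError("empty mask: box masses undefined")
    if eps < 1:
        raise ValueError(f"box side must be >= 1, got {eps}")
    h, w = grid.shape
    ph = int(np.ceil(h / eps)) * eps
    pw = int(np.ceil(w / eps)) * eps
    if (ph, pw) != (h, w):
        padded = np.zeros((ph, pw))
        padded[:h, :w] = grid
        grid = padded
    sums = grid.reshape(ph // eps, eps, pw // eps, eps).sum(axis=(1, 3))
    flat = sums.ravel()
    return flat[flat > 0]


def partition_function(masses: np.ndarray, q: float) -> float:
    """Moment sum Σ p^q over non-empty boxes (entropy Σ p ln p at q = 1)."""
    masses = np.asarray(masses, dtype=np.float64)
    if masses.size == 0:
        raise ValueError("no box masses given")
    if (masses <= 0).any():
        raise ValueError("box masses must be strictly positive (exclude empty boxes)")
    p = masses / masses.sum()
    if np.isclose(q, 1.0):
        return float(np.sum(p * np.log(p)))
    return float(np.sum(p**q))


@dataclass
class MultifractalSpectrum:
    """D_q estimates with per-q regression diagnostics."""

    q_values: np.ndarray
    d_q: np.ndarray
    per_q_slope: np.ndarray
    per_q_r2: np.ndarray
    scales: list[int]
    mass_counts: list[int]  # number of non-empty boxes per scale
    id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.d_q = np.asarray(self.d_q, dtype=float)
        if self.q_values.shape != self.d_q.shape:
            raise ValueError("q grid and D_q arrays differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.q_values, "Dq": self.d_q, "slope": self.per_q_slope, "r2": self.per_q_r2}
        )

    def d_at(self, q: float) -> float:
        idx = int(np.argmin(np.abs(self.q_values - q)))
        if not np.isclose(self.q_values[idx], q):
            raise KeyError(f"q={q} not on the spectrum grid")
        return float(self.d_q[idx])


def dq_spectrum(
    mask: NucleiMask | np.ndarray,
    q_values: np.ndarray | None = None,
    scales: list[int] | None = None,
    id: str = "",
) -> MultifractalSpectrum:
    """Estimate the D_q spectrum of a binary mask or mass grid.

    For each q != 1, D_q is 1/(q-1) times the slope of ln Σ p^q regressed
    on ln ε, with ε the box side relative to the (padded) image side, so
    the estimates do not depend on the pixel-size convention.  q = 1 takes
    the entropy branch.  At least 3 scales are required.
    """
    grid = _as_grid(mask)
    if q_values is None:
        q_values = default_q_grid()
    q_values = np.asarray(q_values, dtype=float)
    if scales is None:
        scales = default_mf_scales(max(grid.shape))
    if len(scales) < 3:
        raise ValueError("need >= 3 scales for the D_q regression")

    side = float(max(grid.shape))
    masses_per_scale = [box_masses(grid, eps) for eps in scales]
    log_eps = np.log(np.array(scales, dtype=float) / side)

    d_q = np.empty_like(q_values)
    slopes = np.empty_like(q_values)
    r2s = np.empty_like(q_values)
    for i, q in enumerate(q_values):
        if np.isclose(q, 1.0):
            y = np.array([partition_function(m, 1.0) for m in masses_per_scale])
        else:
            y = np.log([partition_function(m, q) for m in masses_per_scale])
        slope, _, r2 = _ols(log_eps, y)
        slopes[i] = slope
        r2s[i] = r2
        d_q[i] = slope if np.isclose(q, 1.0) else slope / (q - 1.0)

    return MultifractalSpectrum(
        q_values=q_values,
        d_q=d_q,
        per_q_slope=slopes,
        per_q_r2=r2s,
        scales=list(scales),
        mass_counts=[int(m.size) for m in masses_per_scale],
        id=id,
        provenance={"scales": list(map(int, scales)), "grid_origin": "top-left"},
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), r2


def spectrum_table(
    spectra: list[MultifractalSpectrum],
    labels: list[str],
    case_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Stack spectra into a tidy long-form table (case_id, label, q, Dq).

    All spectra must share one q grid; the row count is
    ``len(spectra) * len(q grid)``.
    """
    if len(spectra) != len(labels):
        raise ValueError("spectra and labels differ in length")
    if case_ids is None:
        case_ids = [s.id or f"case{i}" for i, s in enumerate(spectra)]
    if not spectra:
        return pd.DataFrame(columns=["case_id", "label", "q", "Dq"])
    q0 = spectra[0].q_values
    frames = []
    for s, lab, cid in zip(spectra, labels, case_ids):
        if s.q_values.shape != q0.shape or not np.allclose(s.q_values, q0):
            raise ValueError(f"spectrum {cid!r}: q grid differs from the first spectrum")
        frames.append(
            pd.DataFrame({"case_id": cid, "label": lab, "q": s.q_values, "Dq": s.d_q})
        )
    return pd.concat(frames, ignore_index=True)
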