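"""Spatial information gain (SIG) surfaces and region-of-interest extraction.

For every grid cell the dose distribution of the cell's respondents is the
prior; conditioning on a factor (binarized at the cell-local median) gives
posteriors, and the expected Kullback-Leibler divergence of posterior from
prior — the plug-in mutual information I(dose; binarized factor), in nats —
is the cell's SIG for that factor. Per-factor cell maps are aggregated by a
weighted sum, interpolated with an isotropic Gaussian kernel over cell
centers, and thresholded at a fraction of the surface maximum; connected
supra-threshold components become ROI subgroups whose members share similar
perceptions but differ in vaccine doses.

Conventions: natural logarithm; 0 * log(0/q) = 0; cells with fewer members
than the occupancy floor contribute 0 (the plug-in estimator is upward
biased in tiny samples); ties at the median go to the low group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .embedding import Embedding2D, GridSpec

__all__ = [
    "ROISubgroup",
    "SIGSurface",
    "assign_cells",
    "cell_sig_factor",
    "sig_surfaces",
    "aggregate_sig",
    "smooth_surface",
    "extract_rois",
]

DEFAULT_OCCUPANCY_FLOOR = 5
DEFAULT_CUTOFF_FRACTION = 0.34
DEFAULT_CONTOUR_FRACTIONS = (0.0, 0.17, 0.34, 0.51)


@dataclass
class ROISubgroup:
    """A connected supra-threshold region and its member respondents."""

    roi_id: str
    cell_mask: np.ndarray  # boolean (nx, ny)
    member_indices: np.ndarray  # positional indices into the embedding
    member_ids: list
    dose_mean: float
    dose_sd: float
    peak_signal: float

    @property
    def n(self) -> int:
        return len(self.member_indices)

    def bounding_box(self) -> tuple[int, int, int, int]:
        ix, iy = np.nonzero(self.cell_mask)
        return int(ix.min()), int(ix.max()), int(iy.min()), int(iy.max())


@dataclass
class SIGSurface:
    """Raw per-factor, aggregated and smoothed SIG cell matrices."""

    grid: GridSpec
    raw: dict[str, np.ndarray]
    aggregated: np.ndarray
    smoothed: np.ndarray
    sigma: float = 1.0
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION
    contour_fractions: tuple[float, ...] = DEFAULT_CONTOUR_FRACTIONS

    @property
    def cutoff(self) -> float:
        return self.cutoff_fraction * float(self.smoothed.max())

    def contour_levels(self) -> dict[float, float]:
        peak = float(self.smoothed.max())
        return {f: f * peak for f in self.contour_fractions}


def assign_cells(
    embedding: Embedding2D, grid: GridSpec
) -> dict[tuple[int, int], np.ndarray]:
    """Exhaustive, disjoint map of grid cell -> positional member indices."""
    idx = grid.cells_of(embedding.coords)
    cells: dict[tuple[int, int], list[int]] = {}
    for pos, (ix, iy) in enumerate(idx):
        cells.setdefault((int(ix), int(iy)), []).append(pos)
    return {c: np.array(v, dtype=int) for c, v in cells.items()}


def _expected_kl(
    split: np.ndarray,
    doses: np.ndarray,
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Expected KL of the dose posterior from the prior over a binary split.

    With the default cell-local prior this equals the plug-in mutual
    information (nats). ``prior`` may supply (values, probabilities) of a
    global dose distribution instead.
    """
    n = len(doses)
    kl = 0.0
    p_a = np.array([(~split).mean(), split.mean()])
    if prior is None:
        dose_vals, dose_counts = np.unique(doses, return_counts=True)
        p_d = dose_counts / n
    else:
        dose_vals, p_d = np.asarray(prior[0]), np.asarray(prior[1], dtype=float)
    for a_val, pa in zip((False, True), p_a):
        if pa == 0:
            continue
        sub = doses[split == a_val]
        sub_vals, sub_counts = np.unique(sub, return_counts=True)
        post = sub_counts / len(sub)
        pri = p_d[np.searchsorted(dose_vals, sub_vals)]
        kl += pa * float(np.sum(post * np.log(post / pri)))
    return max(kl, 0.0)


def cell_sig_factor(
    factor_values: np.ndarray,
    doses: np.ndarray,
    floor: int = DEFAULT_OCCUPANCY_FLOOR,
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """SIG of one factor in one cell.

    The factor is binarized at the cell-local median (<= median is the low
    group); the SIG is sum_a P(a) * KL(P(dose | a) || P(dose)) over the
    cell's members, i.e. the plug-in mutual information. Degenerate splits
    and constant doses yield exactly 0.
    """
    factor_values = np.asarray(factor_values, dtype=float)
    doses = np.asarray(doses)
    if len(doses) < max(floor, 1):
        return 0.0
    split = factor_values > np.median(factor_values)
    if split.all() or not split.any():
        return 0.0
    return _expected_kl(split, doses, prior=prior)


def sig_surfaces(
    scores: pd.DataFrame,
    dose: pd.Series,
    cells: dict[tuple[int, int], np.ndarray],
    grid: GridSpec,
    floor: int = DEFAULT_OCCUPANCY_FLOOR,
    prior: str = "cell",
) -> dict[str, np.ndarray]:
    """Per-factor raw SIG cell matrices of shape (nx, ny).

    ``prior="cell"`` (default) uses each cell's own dose distribution as
    the prior, so the cell SIG is the plug-in mutual information and always
    finite. ``prior="global"`` measures divergence from the whole cohort's
    dose distribution instead.
    """
    if prior not in ("cell", "global"):
        raise ValueError("prior must be 'cell' or 'global'")
    score_arr = scores.to_numpy(dtype=float)
    dose_arr = dose.to_numpy()
    global_prior = None
    if prior == "global":
        vals, counts = np.unique(dose_arr, return_counts=True)
        global_prior = (vals, counts / counts.sum())
    out = {
        f: np.zeros((grid.nx, grid.ny)) for f in scores.columns
    }
    for (ix, iy), members in cells.items():
        if len(members) < floor:
            continue
        d = dose_arr[members]
        for j, f in enumerate(scores.columns):
            out[f][ix, iy] = cell_sig_factor(
                score_arr[members, j], d, floor=floor, prior=global_prior
            )
    return out


def aggregate_sig(
    per_factor: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Element-wise weighted sum of per-factor SIG maps (default weight 1)."""
    if not per_factor:
        raise ValueError("no SIG maps to aggregate")
    shapes = {m.shape for m in per_factor.values()}
    if len(shapes) != 1:
        raise ValueError(f"SIG maps have mismatched shapes: {shapes}")
    total = np.zeros(next(iter(shapes)))
    for f, mat in per_factor.items():
        w = 1.0 if weights is None else float(weights.get(f, 0.0))
        total += w * mat
    return total


def smooth_surface(
    raw: np.ndarray, grid: GridSpec, sigma: float = 1.0
) -> np.ndarray:
    """Gaussian-kernel interpolation of a cell matrix over cell centers.

    h(p) = sum_v h_v * (1 / (sqrt(2 pi) sigma)) * exp(-||p - v||^2 / (2 sigma^2))

    with ||p - v|| the Euclidean distance between cell centers in embedding
    units. Linear in ``raw``; a unit impulse contributes 1/sqrt(2 pi) at its
    own cell for sigma = 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (grid.nx, grid.ny):
        raise ValueError(f"raw shape {raw.shape} != grid ({grid.nx}, {grid.ny})")
    cx, cy = grid.centers()
    # separable kernel: K2d[(p, v)] = kx[px, vx] * ky[py, vy] up to the
    # single 1/(sqrt(2 pi) sigma) normalization of the printed formula
    dx2 = (cx[:, None] - cx[None, :]) ** 2
    dy2 = (cy[:, None] - cy[None, :]) ** 2
    kx = np.exp(-dx2 / (2.0 * sigma**2))
    ky = np.exp(-dy2 / (2.0 * sigma**2))
    coef = 1.0 / (np.sqrt(2.0 * np.pi) * sigma)
    return coef * (kx @ raw @ ky.T)


def extract_rois(
    smoothed: np.ndarray,
    grid: GridSpec,
    cells: dict[tuple[int, int], np.ndarray],
    dose: pd.Series,
    *,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    min_members: int = 10,
) -> list[ROISubgroup]:
    """Threshold the smoothed surface and label connected ROI subgroups.

    The cutoff is ``cutoff_fraction`` times the surface maximum; connected
    components use 8-connectivity; components with fewer than
    ``min_members`` respondents are dropped. ROIs are ordered by member
    count (descending, ties by peak signal) and labelled ROI-1, ROI-2, ...
    An all-zero surface yields an empty list.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.min() < -1e-12:
        raise ValueError("smoothed SIG surface must be nonnegative")
    peak = float(smoothed.max())
    if peak <= 0:
        return []
    cutoff = cutoff_fraction * peak
    mask = smoothed >= cutoff
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    dose_arr = dose.to_numpy()
    ids = np.asarray(dose.index)
    candidates = []
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        members = [
            m
            for (ix, iy), m in cells.items()
            if comp_mask[ix, iy]
        ]
        members = np.concatenate(members) if members else np.array([], dtype=int)
        if len(members) < min_members:
            continue
        d = dose_arr[members]
        candidates.append(
            (
                comp_mask,
                members,
                float(d.mean()),
                float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                float(smoothed[comp_mask].max()),
            )
        )
    candidates.sort(key=lambda c: (-len(c[1]), -c[4]))
    rois = []
    for rank, (comp_mask, members, mean, sd, pk) in enumerate(candidates, start=1):
        members = np.sort(members)
        rois.append(
            ROISubgroup(
                roi_id=f"ROI-{rank}",
                cell_mask=comp_mask,
                member_indices=members,
                member_ids=list(ids[members]),
                dose_mean=mean,
                dose_sd=sd,
                peak_signal=pk,
            )
        )
    return rois


def compute_sig_surface(
    scores: pd.DataFrame,
    dose: pd.Series,
    embedding: Embedding2D,
    grid: GridSpec,
    *,
    sigma: float = 1.0,
    floor: int = DEFAULT_OCCUPANCY_FLOOR,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    weights: dict[str, float] | None = None,
) -> tuple[SIGSurface, dict[tuple[int, int], np.ndarray]]:
    """Convenience wrapper: cells -> per-factor SIG -> aggregate -> smooth."""
    cells = assign_cells(embedding, grid)
    raw = sig_surfaces(scores, dose, cells, grid, floor=floor)
    agg = aggregate_sig(raw, weights=weights)
    smoothed = smooth_surface(agg, grid, sigma=sigma)
    surface = SIGSurface(
        grid=grid,
        raw=raw,
        aggregated=agg,
        smoothed=smoothed,
        sigma=sigma,
        cutoff_fraction=cutoff_fraction,
    )
    return surface, cells
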