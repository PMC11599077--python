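"""2D latent projection of respondents and the regular grid over it.

Respondents are embedded by their factor-score profiles so that proximity
reflects similarity of perceptions. The default projector is UMAP with a
fixed seed (deterministic); PCA is available as a fast, closed-form
alternative with the same contract, and any callable returning an n x 2
array can be plugged in. Factor columns are z-scored before projection by
default so 4-point and 5-point scales contribute comparably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Embedding2D", "GridSpec", "embed_umap", "embed_pca", "build_grid"]


@dataclass
class Embedding2D:
    """Respondent coordinates in the 2D latent space."""

    respondent_ids: pd.Index
    coords: np.ndarray
    params: dict = field(default_factory=dict)
    standardized: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.respondent_ids) != len(self.coords):
            raise ValueError("one coordinate row per respondent required")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")

    @property
    def n(self) -> int:
        return len(self.coords)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords, index=self.respondent_ids, columns=["x", "y"]
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over the embedding extent with a fixed step.

    Cells are half-open ``[edge, edge + step)`` in both axes except the last
    cell per axis, which is closed at the top so the extreme point is
    covered; every respondent therefore falls in exactly one cell.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    step: float = 0.5
    nx: int = 0
    ny: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        object.__setattr__(self, "nx", max(1, math.ceil((self.x_max - self.x_min) / self.step - 1e-12)))
        object.__setattr__(self, "ny", max(1, math.ceil((self.y_max - self.y_min) / self.step - 1e-12)))

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        if not (self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max):
            raise ValueError(f"point ({x}, {y}) outside grid bounds")
        ix = min(int((x - self.x_min) // self.step), self.nx - 1)
        iy = min(int((y - self.y_min) // self.step), self.ny - 1)
        return ix, iy

    def cells_of(self, coords: np.ndarray) -> np.ndarray:
        """(n, 2) integer cell indices for an (n, 2) coordinate array."""
        rel = (np.asarray(coords, dtype=float) - [self.x_min, self.y_min]) / self.step
        idx = np.floor(rel).astype(int)
        idx[:, 0] = np.clip(idx[:, 0], 0, self.nx - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, self.ny - 1)
        return idx

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates: (nx,) x-centers and (ny,) y-centers."""
        cx = self.x_min + (np.arange(self.nx) + 0.5) * self.step
        cy = self.y_min + (np.arange(self.ny) + 0.5) * self.step
        return cx, cy

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
            "step": self.step,
            "nx": self.nx,
            "ny": self.ny,
        }


def _standardize(scores: pd.DataFrame) -> np.ndarray:
    x = scores.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def embed_umap(
    scores: pd.DataFrame,
    *,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 42,
    standardize: bool = True,
) -> Embedding2D:
    """Deterministic UMAP projection of factor scores to 2D.

    With a fixed ``seed`` (passed as ``random_state``) UMAP runs
    single-threaded and reproduces coordinates bit-for-bit, which the
    downstream grid and SIG surfaces inherit.
    """
    if len(scores) < 10:
        raise ValueError("embedding needs at least 10 respondents")
    if n_neighbors >= len(scores):
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than n={len(scores)}"
        )
    import umap  # deferred: numba compilation is expensive at import time

    x = _standardize(scores) if standardize else scores.to_numpy(dtype=float)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(x), dtype=float)
    return Embedding2D(
        respondent_ids=scores.index,
        coords=coords,
        params={
            "method": "umap",
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "metric": metric,
            "seed": seed,
        },
        standardized=standardize,
    )


def embed_pca(
    scores: pd.DataFrame, *, seed: int = 42, standardize: bool = True
) -> Embedding2D:
    """First two principal components of the factor scores.

    Linear, closed-form and fast; shares the determinism contract of
    :func:`embed_umap` and is the projector of choice for tests and for
    quick looks at large cohorts. Component signs are fixed by making each
    loading vector's largest-magnitude entry positive.
    """
    from sklearn.decomposition import PCA

    if len(scores) < 3:
        raise ValueError("embedding needs at least 3 respondents")
    x = _standardize(scores) if standardize else scores.to_numpy(dtype=float)
    pca = PCA(n_components=2, random_state=seed)
    coords = pca.fit_transform(x)
    for j in range(2):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    return Embedding2D(
        respondent_ids=scores.index,
        coords=coords,
        params={"method": "pca", "seed": seed},
        standardized=standardize,
    )


def build_grid(embedding: Embedding2D, step: float = 0.5) -> GridSpec:
    """Grid over the exact coordinate extrema of an embedding."""
    if embedding.n < 1:
        raise ValueError("cannot grid an empty embedding")
    x = embedding.coords[:, 0]
    y = embedding.coords[:, 1]
    return GridSpec(
        x_min=float(x.min()),
        x_max=float(x.max()),
        y_min=float(y.min()),
        y_max=float(y.max()),
        step=float(step),
    )
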