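"""Nestbox landscape generation.

Boxes are laid out by jittered-grid (blue-noise-like) sampling inside a
circular woodland whose diameter equals the configured extent, so that the
maximum pairwise box distance approximates the woodland span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .config import SimulationConfig

__all__ = ["NestboxMap", "build_landscape"]


@dataclass(frozen=True)
class NestboxMap:
    box_ids: np.ndarray  # (n,) int
    xy: np.ndarray       # (n, 2) metres

    def __post_init__(self) -> None:
        if len(self.box_ids) < 2:
            raise ValueError("a nestbox map needs at least 2 boxes")
        if len(np.unique(self.box_ids)) != len(self.box_ids):
            raise ValueError("box ids must be unique")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("box coordinates must be finite")

    @property
    def n_boxes(self) -> int:
        return len(self.box_ids)

    @property
    def woodland_extent(self) -> float:
        """Maximum pairwise box distance (hull diameter)."""
        pts = self.xy
        if len(pts) > 10:
            pts = pts[ConvexHull(pts).vertices]
        return float(pdist(pts).max())

    def coords_of(self, box_ids) -> np.ndarray:
        idx = np.searchsorted(self.box_ids, box_ids)
        return self.xy[idx]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"box_id": self.box_ids,
                             "x": self.xy[:, 0], "y": self.xy[:, 1]})


def build_landscape(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> NestboxMap:
    """Place ``n_boxes`` boxes inside a circle of diameter ``extent_m``.

    A square grid fine enough to hold the requested count inside the circle is
    jittered uniformly by up to 40% of the grid spacing; a uniform random
    subset of size ``n_boxes`` is kept.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, radius = config.n_boxes, config.extent_m / 2.0

    # choose spacing so the circle comfortably holds n grid nodes
    spacing = np.sqrt(np.pi * radius**2 / (1.35 * n))
    ax = np.arange(-radius, radius + spacing, spacing)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.uniform(-0.4 * spacing, 0.4 * spacing, size=pts.shape)
    r = np.hypot(pts[:, 0], pts[:, 1])
    inside = pts[r <= radius]
    if len(inside) < n:  # pragma: no cover - spacing margin prevents this
        raise RuntimeError("grid too coarse for requested box count")
    keep = np.sort(rng.choice(len(inside), size=n, replace=False))
    xy = inside[keep]
    return NestboxMap(box_ids=np.arange(n, dtype=np.int64), xy=xy)
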