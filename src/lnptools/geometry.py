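"""Periodic-boundary geometry for orthorhombic boxes.

All distance-based metrics in the toolkit go through the minimum-image
convention implemented here.  Boxes are orthorhombic 3-vectors in Angstrom;
the periodic dimensions can be restricted (membrane analyses typically wrap
only x and y).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

_DIM_INDEX = {"x": 0, "y": 1, "z": 2}


def _dim_mask(dims: Iterable[str]) -> np.ndarray:
    mask = np.zeros(3, dtype=bool)
    for d in dims:
        mask[_DIM_INDEX[d]] = True
    return mask


def minimum_image_displacement(
    a: np.ndarray,
    b: np.ndarray,
    box: np.ndarray,
    dims: Iterable[str] = ("x", "y", "z"),
) -> np.ndarray:
    """Displacement ``a - b`` wrapped into [-L/2, L/2) along the requested dims.

    Components not listed in *dims* are returned raw.  Broadcasts over leading
    axes, so ``a`` and ``b`` may be (N, 3) stacks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box components must be positive")
    d = a - b
    mask = _dim_mask(dims)
    wrapped = d - box * np.floor(d / box + 0.5)
    return np.where(mask, wrapped, d)


def wrap_displacements(d: np.ndarray, box: np.ndarray, dims=("x", "y", "z")) -> np.ndarray:
    """Minimum-image wrap of an array of displacement vectors (..., 3)."""
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    mask = _dim_mask(dims)
    wrapped = d - box * np.floor(d / box + 0.5)
    return np.where(mask, wrapped, d)


def lateral_distance_matrix(xy_a: np.ndarray, xy_b: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """In-plane (x-y) minimum-image distance matrix between two point sets."""
    d = xy_a[:, None, :] - xy_b[None, :, :]
    d -= box_xy * np.round(d / box_xy)
    return np.sqrt((d ** 2).sum(axis=-1))


def minimum_image_distance_matrix(pts: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Full 3-D minimum-image distance matrix of one point set."""
    d = pts[:, None, :] - pts[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d ** 2).sum(axis=-1))


def pairwise_min_distance(pts: np.ndarray, box: np.ndarray | None = None) -> float:
    """Smallest interatomic distance in a point set (periodic if box given)."""
    from scipy.spatial import cKDTree

    pts = np.asarray(pts, dtype=float)
    if len(pts) < 2:
        return np.inf
    if box is not None:
        box = np.asarray(box, dtype=float)
        wrapped = np.mod(pts, box)
        # guard against coordinates landing exactly on the upper box face
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(pts)
    dist, _ = tree.query(wrapped if box is not None else pts, k=2)
    return float(dist[:, 1].min())
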