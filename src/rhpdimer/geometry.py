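"""Distance primitives under orthorhombic periodic boundary conditions.

The minimum-image convention for an orthorhombic box reduces to wrapping
each Cartesian component into [-L/2, L/2).  The fast pair search delegates
to MDAnalysis' grid-based ``capped_distance``; its contract here is the
exhaustive definition (every pair at minimum-image distance within the
cutoff, boundary inclusive by default).
"""

from __future__ import annotations

import numpy as np
from MDAnalysis.lib.distances import capped_distance

from .model import Frame

__all__ = ["min_image_displacement", "min_image_distance", "neighbor_pairs"]


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or not np.all(box > 0):
        raise ValueError("box must be three positive edge lengths")
    return box


def min_image_displacement(p: np.ndarray, q: np.ndarray, box) -> np.ndarray:
    """Minimum-image displacement vector(s) q -> p for an orthorhombic box."""
    box = _check_box(box)
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p, q, box) -> float | np.ndarray:
    """Minimum-image Euclidean distance between points (broadcastable)."""
    d = min_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def _mda_box(box: np.ndarray) -> np.ndarray:
    return np.asarray([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)


def neighbor_pairs(
    frame: Frame,
    set_a: np.ndarray,
    set_b: np.ndarray,
    cutoff: float,
    *,
    use_pbc: bool = True,
    boundary: str = "closed",
) -> np.ndarray:
    """All (a, b) atom-id pairs with pairwise distance within ``cutoff``.

    Returns an ``(n_pairs, 2)`` int array of atom ids drawn from ``set_a``
    and ``set_b`` (which must be disjoint).  With ``use_pbc`` distances are
    minimum-image; the cutoff must then not exceed half the smallest box
    edge, otherwise the minimum image is ambiguous.  ``boundary='closed'``
    includes pairs at exactly the cutoff.
    """
    set_a = np.asarray(set_a, dtype=np.int64)
    set_b = np.asarray(set_b, dtype=np.int64)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("set_a and set_b must be disjoint")
    if len(set_a) == 0 or len(set_b) == 0:
        return np.empty((0, 2), dtype=np.int64)
    box = _check_box(frame.box)
    if use_pbc and cutoff > box.min() / 2.0:
        raise ValueError(
            f"cutoff {cutoff} exceeds half the smallest box edge ({box.min() / 2.0}); "
            "minimum image is ambiguous"
        )
    coords_a = np.asarray(frame.coordinates[set_a], dtype=np.float64)
    coords_b = np.asarray(frame.coordinates[set_b], dtype=np.float64)
    mda_box = _mda_box(box) if use_pbc else None
    # The grid search runs in float32 internally; gather candidates with a
    # safety margin, then apply the boundary rule with exact float64
    # minimum-image distances.
    margin = cutoff * (1.0 + 1e-4) + 1e-4
    if use_pbc and margin > box.min() / 2.0:
        margin = box.min() / 2.0
    pairs = capped_distance(
        coords_a, coords_b, max_cutoff=margin, box=mda_box, return_distances=False
    )
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    delta = coords_a[pairs[:, 0]] - coords_b[pairs[:, 1]]
    if use_pbc:
        delta -= box * np.round(delta / box)
    dists = np.sqrt(np.sum(delta * delta, axis=1))
    keep = dists <= cutoff if boundary == "closed" else dists < cutoff
    pairs = pairs[keep]
    out = np.column_stack([set_a[pairs[:, 0]], set_b[pairs[:, 1]]])
    # canonical ordering for set-like comparisons
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order]
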