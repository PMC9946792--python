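"""Surface-style map values: sphere-averaged smoothing and significance overlays.

Display values mirror the figures of intracranial mapping studies: each
target point (a supplied vertex list or a regular lattice over the
electrode bounding box) receives the unweighted mean of all electrode
values — significant or not — within a 10 mm sphere; points with no
electrode in range are masked.  The smoothing is linear in the electrode
values and its output stays inside their range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data_model import ElectrodeTable, ValidationError

__all__ = ["smooth_to_points", "lattice_points", "significance_overlay"]


def lattice_points(
    electrode_coords: np.ndarray, spacing_mm: float = 2.0, margin_mm: float = 15.0
) -> np.ndarray:
    """Regular lattice over the electrode bounding box plus a margin;
    a mesh-free stand-in for a cortical vertex list."""
    coords = np.atleast_2d(np.asarray(electrode_coords, dtype=float))
    lo = coords.min(axis=0) - margin_mm
    hi = coords.max(axis=0) + margin_mm
    axes = [np.arange(a, b + spacing_mm / 2, spacing_mm) for a, b in zip(lo, hi)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def smooth_to_points(
    electrode_values: np.ndarray,
    electrode_coords: np.ndarray,
    target_points: np.ndarray,
    radius_mm: float = 10.0,
) -> pd.DataFrame:
    """Sphere-average electrode values onto target points.

    Each target point gets the unweighted mean of every electrode value
    within ``radius_mm`` (inclusive); points with no electrode in range
    are masked (value NaN, ``mask`` False).  Returns a frame with
    columns x, y, z, value, mask.
    """
    if radius_mm <= 0:
        raise ValidationError("radius_mm must be positive")
    values = np.asarray(electrode_values, dtype=float)
    coords = np.atleast_2d(np.asarray(electrode_coords, dtype=float))
    points = np.atleast_2d(np.asarray(target_points, dtype=float))
    if values.size != len(coords):
        raise ValidationError("one value per electrode required")
    tree = cKDTree(coords)
    neighbours = tree.query_ball_point(points, r=radius_mm)
    out = np.full(len(points), np.nan)
    mask = np.zeros(len(points), dtype=bool)
    for i, idx in enumerate(neighbours):
        if idx:
            out[i] = values[idx].mean()
            mask[i] = True
    return pd.DataFrame({
        "x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
        "value": out, "mask": mask,
    })


def significance_overlay(results: pd.DataFrame, electrodes: ElectrodeTable) -> pd.DataFrame:
    """Per-electrode plotting category from permutation outcomes.

    ``results`` needs columns electrode, significant, direction.  The
    category is the test's direction for significant electrodes and
    ``"none"`` otherwise; coordinates come from the electrode table.
    """
    elec = electrodes.contacts[["name", "x", "y", "z"]].rename(columns={"name": "electrode"})
    merged = results.merge(elec, on="electrode", how="left", validate="many_to_one")
    merged["category"] = np.where(merged["significant"], merged["direction"], "none")
    return merged[["electrode", "x", "y", "z", "category"]
                  + [c for c in ("band", "contrast") if c in merged.columns]]
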