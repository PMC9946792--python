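"""Assign electrodes to resting-state fMRI networks from a volumetric parcellation.

Each electrode receives the modal network label of all labelled voxels
whose centre lies within a configurable radius (default 5 mm) of the
electrode in millimetre space.  Background voxels (label 0) never vote;
electrodes with no labelled voxel in range are ``unassigned``.  Ties on
the mode are broken deterministically by the smallest label id.

An optional nearest-surface-point snap is provided as a simple stand-in
for brain-shift compensation: it moves each electrode to the closest
point of a supplied surface point cloud and records the displacement.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .data_model import ElectrodeTable, LabelVolume, UNASSIGNED, ValidationError

__all__ = ["snap_to_surface", "assign_network", "project_hemisphere"]


def snap_to_surface(
    electrodes: ElectrodeTable, surface_points: np.ndarray
) -> ElectrodeTable:
    """Move each electrode to its nearest surface point.

    Returns a new table with updated coordinates and a
    ``snap_displacement_mm`` column recording how far each contact moved.
    """
    surface_points = np.atleast_2d(np.asarray(surface_points, dtype=float))
    if surface_points.size == 0:
        raise ValidationError("surface_points must be non-empty")
    tree = cKDTree(surface_points)
    dist, idx = tree.query(electrodes.coords)
    df = electrodes.contacts.copy()
    df[["x", "y", "z"]] = surface_points[idx]
    df["snap_displacement_mm"] = dist
    return electrodes.with_contacts(df)


def assign_network(
    electrodes: ElectrodeTable,
    labels: LabelVolume,
    radius_mm: float = 5.0,
) -> ElectrodeTable:
    """Label electrodes with the modal network within ``radius_mm``.

    The candidate set for an electrode is every nonzero voxel whose
    centre is within ``radius_mm`` (inclusive) of the electrode's mm
    coordinates.  The most frequent label wins; ties go to the smallest
    label id; an empty candidate set yields ``"unassigned"``.
    """
    if radius_mm <= 0:
        raise ValidationError("radius_mm must be positive")
    voxel_mm, voxel_labels = labels.labelled_voxel_mm()
    df = electrodes.contacts.copy()
    if len(voxel_mm) == 0:
        warnings.warn("label volume has no labelled voxels; all electrodes unassigned")
        df["network"] = UNASSIGNED
        return electrodes.with_contacts(df)
    tree = cKDTree(voxel_mm)
    assigned = []
    for xyz in electrodes.coords:
        idx = tree.query_ball_point(xyz, r=radius_mm)
        if not idx:
            assigned.append(UNASSIGNED)
            continue
        cand = voxel_labels[idx]
        uniq, counts = np.unique(cand, return_counts=True)
        # np.unique sorts ascending, so argmax already favours the
        # smallest label id on count ties
        winner = int(uniq[np.argmax(counts)])
        assigned.append(labels.name_of(winner))
    df["network"] = assigned
    return electrodes.with_contacts(df)


def project_hemisphere(electrodes: ElectrodeTable, target: str = "L") -> ElectrodeTable:
    """Mirror contacts of the non-target hemisphere across the midline.

    Display-only convenience (both hemispheres shown on one side); never
    used for assignment or statistics.  The flip is keyed on the
    ``hemisphere`` field, which is left untouched, so applying the
    projection twice returns the original coordinates (involution).
    """
    if target not in ("L", "R"):
        raise ValidationError("target hemisphere must be 'L' or 'R'")
    df = electrodes.contacts.copy()
    x = df["x"].to_numpy(dtype=float)
    wrong_side = (df["hemisphere"] != target).to_numpy()
    df["x"] = np.where(wrong_side, -x, x)
    return electrodes.with_contacts(df)
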