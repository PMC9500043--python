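"""Deformation-field disagreement metrics.

Two normalization pipelines applied to the same subject map every
template-space point x' to (possibly different) subject-space points
x_a = x' + d_a(x') and x_b = x' + d_b(x').  The per-voxel displacement
between the pipelines is the Euclidean distance ||x_a - x_b|| = ||d_a - d_b||
in mm; over a cohort it is summarized as a root-mean-square (RMS) map and
pooled per atlas region.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import LabelAtlas, region_key
from .errors import ValidationError
from .grids import Grid
from .registration import DeformationField

GLOBAL_ROW = "GLOBAL"


@dataclass
class DisplacementMap:
    """Per-voxel scalar displacement (mm) on a template grid."""

    grid: Grid
    values: np.ndarray
    n_subjects: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError("displacement map shape != grid shape")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("displacements must be non-negative")


def pointwise_displacement(field_a: DeformationField,
                           field_b: DeformationField) -> DisplacementMap:
    """Per-voxel ||d_a - d_b|| in mm; fields must share the template grid."""
    if not field_a.grid.same_geometry(field_b.grid):
        raise ValidationError("fields live on incompatible grids; resample first")
    diff = field_a.displacement - field_b.displacement
    return DisplacementMap(grid=field_a.grid,
                           values=np.sqrt((diff ** 2).sum(axis=0)),
                           n_subjects=1)


def rms_over_subjects(maps) -> DisplacementMap:
    """Voxel-wise RMS over subjects: sqrt(mean_i ||.||_i^2).

    The printed-formula variant (sum of roots, no 1/N) is available via
    :func:`aggregate_over_subjects`.
    """
    maps = list(maps)
    if not maps:
        raise ValidationError("need at least one displacement map")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.same_geometry(grid):
            raise ValidationError("displacement maps on different grids")
    sq = np.mean([m.values ** 2 for m in maps], axis=0)
    return DisplacementMap(grid=grid, values=np.sqrt(sq), n_subjects=len(maps))


def aggregate_over_subjects(maps, aggregate: str = "rms") -> DisplacementMap:
    """Aggregate per-subject maps; ``aggregate`` is "rms" (default) or
    "sum_root" (the literal printed formula, kept for forensic comparison)."""
    if aggregate == "rms":
        return rms_over_subjects(maps)
    if aggregate == "sum_root":
        maps = list(maps)
        if not maps:
            raise ValidationError("need at least one displacement map")
        total = np.sum([m.values for m in maps], axis=0)
        return DisplacementMap(grid=maps[0].grid, values=total, n_subjects=len(maps))
    raise ValidationError(f"unknown aggregate {aggregate!r}")


def regional_displacement(maps, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-region RMS displacement pooled over voxels and subjects.

    For region masks V and subjects i: sqrt( sum_{i,v in V} D_{i,v}^2 / (N |V|) ).
    A GLOBAL row pools every labelled (brain) voxel.  Empty regions are
    reported as NaN.
    """
    maps = list(maps)
    if not maps:
        raise ValidationError("need at least one displacement map")
    grid = maps[0].grid
    if not atlas.grid.same_geometry(grid):
        raise ValidationError("atlas grid differs from displacement grid")
    sq = np.stack([m.values ** 2 for m in maps])   # (N_subj,) + shape
    labels = atlas.volume.values
    rows = []
    for _, r in atlas.regions.iterrows():
        m = labels == r["label"]
        if not m.any():
            rows.append({"region": region_key(r), "rms_displacement_mm": np.nan,
                         "n_voxels": 0})
            continue
        rows.append({"region": region_key(r),
                     "rms_displacement_mm": float(np.sqrt(sq[:, m].mean())),
                     "n_voxels": int(m.sum())})
    brain = labels > 0
    rows.append({"region": GLOBAL_ROW,
                 "rms_displacement_mm": float(np.sqrt(sq[:, brain].mean()))
                 if brain.any() else np.nan,
                 "n_voxels": int(brain.sum())})
    return pd.DataFrame(rows, columns=["region", "rms_displacement_mm", "n_voxels"])
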