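"""VOI atlas construction from a hierarchical brain ontology.

Builds a labelled volume-of-interest (VOI) atlas from an annotation volume
(voxel values are ontology structure ids) plus a hierarchical structure
ontology in the Allen JSON schema.  Each VOI is the union of one or more
ontology subtrees ("every substructure"), optionally split into left/right
hemispheres at the mediolateral midline, then regularized by a one-voxel
morphological erosion.  Regions whose post-erosion volume falls below a
minimum size (relative to PET resolution) are rejected.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import ValidationError
from .grids import AnnotatedVolume, Grid

log = logging.getLogger(__name__)

#: minimum post-erosion VOI volume (mm^3), large compared to PET resolution
MIN_VOI_VOLUME_MM3 = 1.5
#: index axis along which hemispheres are split (mediolateral, R-positive)
ML_AXIS = 2


@dataclass
class OntologyNode:
    """Node of the hierarchical structure ontology."""

    id: int
    acronym: str
    name: str
    parent_id: int | None = None
    children: list["OntologyNode"] = field(default_factory=list)

    def iter_subtree(self):
        yield self
        for child in self.children:
            yield from child.iter_subtree()

    def index(self) -> dict[int, "OntologyNode"]:
        return {n.id: n for n in self.iter_subtree()}

    def find_by_acronym(self, acronym: str) -> "OntologyNode":
        for n in self.iter_subtree():
            if n.acronym == acronym:
                return n
        raise KeyError(f"acronym {acronym!r} not in ontology")


@dataclass(frozen=True)
class VOISpec:
    """One template region: ontology roots plus laterality handling."""

    name: str
    abbreviation: str
    laterality: str  # "bilateral" or "central"
    root_acronyms: tuple[str, ...] = ()
    root_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if self.laterality not in ("bilateral", "central"):
            raise ValidationError(f"laterality must be bilateral/central, got {self.laterality!r}")
        if not self.root_acronyms and not self.root_ids:
            raise ValidationError(f"VOI {self.abbreviation}: no ontology roots given")


@dataclass
class LabelAtlas:
    """Integer-labelled VOI volume plus its region table.

    ``regions`` columns: label, name, abbreviation, side (L/R/C), volume_mm3.
    Label 0 is background; labels are consecutive positive integers.
    """

    volume: AnnotatedVolume
    regions: pd.DataFrame

    @property
    def grid(self) -> Grid:
        return self.volume.grid

    def brain_mask(self) -> AnnotatedVolume:
        """Union of all labelled regions (the toolbox's brain definition)."""
        return AnnotatedVolume(grid=self.grid,
                               values=(self.volume.values > 0).astype(np.uint8),
                               modality="mask")

    def region_mask(self, label: int) -> np.ndarray:
        return self.volume.values == label


# ---------------------------------------------------------------------------
# Ontology handling

def _parse_node(d: dict, parent_id=None) -> OntologyNode:
    node = OntologyNode(id=int(d["id"]), acronym=str(d.get("acronym", "")),
                        name=str(d.get("name", "")), parent_id=parent_id)
    for child in d.get("children", []):
        node.children.append(_parse_node(child, parent_id=node.id))
    return node


def load_ontology(path) -> OntologyNode:
    """Load and validate an ontology tree from Allen-schema JSON.

    Accepts either the raw API response (``{"msg": [root]}``) or a bare
    nested node object.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict) and "msg" in doc:
        roots = doc["msg"]
    elif isinstance(doc, list):
        roots = doc
    else:
        roots = [doc]
    if len(roots) != 1:
        raise ValidationError(f"ontology must have exactly one root, got {len(roots)}")
    tree = _parse_node(roots[0])
    ids = [n.id for n in tree.iter_subtree()]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate ontology ids: {dupes[:5]}")
    return tree


def collect_substructures(tree: OntologyNode, root_ids) -> set[int]:
    """Union of each requested structure id and all of its descendants."""
    index = tree.index()
    out: set[int] = set()
    for rid in root_ids:
        if rid not in index:
            raise KeyError(f"ontology id {rid} not found")
        out.update(n.id for n in index[rid].iter_subtree())
    return out


# ---------------------------------------------------------------------------
# Mask machinery

def _hemisphere_slices(shape, side: str):
    """Index ranges of the L / R hemisphere along the ML axis.

    Even ML dimension: the midplane falls between the two central columns.
    Odd dimension: the central column belongs to neither hemisphere.
    """
    n = shape[ML_AXIS]
    if side == "L":
        return slice(0, n // 2)
    if side == "R":
        return slice(n - n // 2, n)
    raise ValidationError(f"side must be L or R, got {side!r}")


def build_voi_mask(annotation: AnnotatedVolume, ids, side: str = "whole") -> AnnotatedVolume:
    """Binary mask of voxels whose annotation id is in ``ids``.

    ``side``: "L", "R" (hemisphere-restricted by the ML midline) or "whole".
    """
    if annotation.modality != "annotation":
        raise ValidationError("build_voi_mask expects an annotation volume")
    ids = set(int(i) for i in ids)
    if not ids:
        raise ValidationError("empty structure id set")
    mask = np.isin(annotation.values, sorted(ids))
    if side != "whole":
        keep = np.zeros_like(mask)
        sl = [slice(None)] * 3
        sl[ML_AXIS] = _hemisphere_slices(annotation.grid.shape, side)
        keep[tuple(sl)] = True
        mask &= keep
    if not mask.any():
        log.warning("VOI mask empty: none of %d ids present (side=%s)", len(ids), side)
    return AnnotatedVolume(grid=annotation.grid, values=mask.astype(np.uint8),
                           modality="mask")


def erode_mask(mask: AnnotatedVolume, iterations: int = 1,
               connectivity: int = 6) -> AnnotatedVolume:
    """Morphological erosion of a binary mask.

    ``connectivity``: 6 (face neighbours, default) or 26 (full cube).
    Voxels outside the volume count as background, so erosion bites at the
    volume border too.
    """
    if connectivity not in (6, 26):
        raise ValidationError("connectivity must be 6 or 26")
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    values = mask.values.astype(bool)
    if iterations and values.any():
        structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
        values = ndimage.binary_erosion(values, structure=structure,
                                        iterations=iterations, border_value=0)
    return AnnotatedVolume(grid=mask.grid, values=values.astype(np.uint8),
                           modality="mask")


# ---------------------------------------------------------------------------
# Atlas assembly

def _resolve_root_ids(spec: VOISpec, tree: OntologyNode | None) -> tuple[int, ...]:
    if spec.root_ids:
        return spec.root_ids
    if tree is None:
        raise ValidationError(f"VOI {spec.abbreviation}: acronym roots need an ontology tree")
    return tuple(tree.find_by_acronym(a).id for a in spec.root_acronyms)


def build_label_atlas(annotation: AnnotatedVolume, specs, tree: OntologyNode | None = None,
                      erosion_iters: int = 1, connectivity: int = 6,
                      min_volume_mm3: float = MIN_VOI_VOLUME_MM3) -> LabelAtlas:
    """Assemble the labelled VOI atlas.

    For each spec (in order) and each side (L/R for bilateral, C for
    central), the substructure union is masked, hemisphere-restricted,
    eroded, and assigned the next consecutive label.  Regions smaller than
    ``min_volume_mm3`` after erosion are rejected and logged.  A voxel
    already labelled is never relabelled (overlaps indicate spec errors and
    are logged).
    """
    labels = np.zeros(annotation.grid.shape, dtype=np.int32)
    voxvol = annotation.grid.voxel_volume
    rows = []
    next_label = 1
    for spec in specs:
        ids = collect_substructures(tree, _resolve_root_ids(spec, tree)) if tree \
            else set(_resolve_root_ids(spec, None))
        sides = ("L", "R") if spec.laterality == "bilateral" else ("C",)
        for side in sides:
            mask = build_voi_mask(annotation, ids, side="whole" if side == "C" else side)
            mask = erode_mask(mask, iterations=erosion_iters, connectivity=connectivity)
            m = mask.values.astype(bool)
            vol_mm3 = float(m.sum()) * voxvol
            if vol_mm3 < min_volume_mm3:
                log.warning("VOI %s/%s rejected: %.3f mm^3 < %.3f mm^3 after erosion",
                            spec.abbreviation, side, vol_mm3, min_volume_mm3)
                continue
            overlap = m & (labels > 0)
            if overlap.any():
                log.warning("VOI %s/%s overlaps %d already-labelled voxels; "
                            "keeping earlier labels", spec.abbreviation, side,
                            int(overlap.sum()))
                m &= labels == 0
                vol_mm3 = float(m.sum()) * voxvol
                if vol_mm3 < min_volume_mm3:
                    log.warning("VOI %s/%s rejected after overlap removal", spec.abbreviation, side)
                    continue
            labels[m] = next_label
            rows.append({"label": next_label, "name": spec.name,
                         "abbreviation": spec.abbreviation, "side": side,
                         "volume_mm3": vol_mm3})
            next_label += 1
    volume = AnnotatedVolume(grid=annotation.grid, values=labels, modality="label")
    return LabelAtlas(volume=volume, regions=pd.DataFrame(
        rows, columns=["label", "name", "abbreviation", "side", "volume_mm3"]))


def region_volumes(atlas: LabelAtlas) -> pd.DataFrame:
    """Per-region volume in mm^3 (voxel count x voxel volume); background excluded."""
    voxvol = atlas.grid.voxel_volume
    counts = np.bincount(atlas.volume.values.ravel(),
                         minlength=int(atlas.volume.values.max()) + 1)
    df = atlas.regions[["label", "name", "abbreviation", "side"]].copy()
    df["volume_mm3"] = [counts[l] * voxvol for l in df["label"]]
    return df


def region_key(row) -> str:
    """Human-readable region identifier, e.g. 'STRd L' or 'CB'."""
    return row["abbreviation"] if row["side"] == "C" else f"{row['abbreviation']} {row['side']}"


# ---------------------------------------------------------------------------
# Default VOI specification (ships as an editable data file)

def load_voi_specs(path=None) -> list[VOISpec]:
    """Load VOI specs from YAML; default is the packaged 27-region set.

    The YAML is a list of mappings with keys name, abbreviation, laterality,
    and acronyms (ontology root acronyms) or ids.
    """
    if path is None:
        with resources.files("mousepet.data").joinpath("allen_vois.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    specs = []
    for entry in doc:
        specs.append(VOISpec(name=entry["name"], abbreviation=entry["abbreviation"],
                             laterality=entry["laterality"],
                             root_acronyms=tuple(entry.get("acronyms", ())),
                             root_ids=tuple(entry.get("ids", ()))))
    abbrs = [s.abbreviation for s in specs]
    if len(abbrs) != len(set(abbrs)):
        raise ValidationError("duplicate abbreviations in VOI spec set")
    return specs
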