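"""Regional uptake quantification and paired test-retest statistics.

PET volumes are converted to standardized uptake values (SUV), scaled to
the cerebral global mean (the union of all atlas labels is the toolbox's
brain definition), reduced to per-region means, and compared between the
two conditions of a paired design with Student's t for paired samples plus
Benjamini-Hochberg FDR adjustment across regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import LabelAtlas, region_key
from .errors import ValidationError
from .grids import AnnotatedVolume, read_volume, resample

log = logging.getLogger(__name__)

REQUIRED_MANIFEST_COLUMNS = ("subject", "condition", "pet",
                             "injected_activity_mbq", "body_weight_g")


def to_suv(pet: AnnotatedVolume, injected_activity_mbq: float,
           body_weight_g: float) -> AnnotatedVolume:
    """SUV = concentration / (injected activity / body weight).

    PET values are kBq/mL; the dose is converted to kBq and tissue density
    is taken as 1 g/mL, so the output is dimensionless.
    """
    if injected_activity_mbq <= 0 or body_weight_g <= 0:
        raise ValidationError("injected activity and body weight must be positive")
    factor = injected_activity_mbq * 1000.0 / body_weight_g  # kBq / g
    out = pet.copy_with(values=pet.values / factor)
    out.units = "SUV"
    return out


def scale_to_global_mean(vol: AnnotatedVolume,
                         brain_mask: AnnotatedVolume) -> AnnotatedVolume:
    """Divide by the mean over the brain mask; masked mean becomes exactly 1."""
    if not brain_mask.grid.same_geometry(vol.grid):
        raise ValidationError("brain mask grid differs from volume grid")
    m = brain_mask.values.astype(bool)
    if not m.any():
        raise ValidationError("brain mask is empty")
    mean = float(vol.values[m].mean())
    if mean <= 0:
        raise ValidationError(f"global mean must be positive, got {mean}")
    out = vol.copy_with(values=vol.values / mean)
    out.units = "global-mean-scaled"
    return out


def extract_regional_means(vol: AnnotatedVolume, atlas: LabelAtlas) -> pd.DataFrame:
    """Arithmetic mean of voxel values per atlas region.

    The volume is resampled (trilinear) onto the atlas grid if needed.
    Regions empty on this grid get NaN with a warning.
    """
    if not vol.grid.same_geometry(atlas.grid):
        vol = resample(vol, atlas.grid, interpolation="trilinear")
    rows = []
    for _, r in atlas.regions.iterrows():
        m = atlas.region_mask(r["label"])
        if not m.any():
            log.warning("region %s empty on this grid", region_key(r))
            rows.append({"region": region_key(r), "mean": np.nan})
            continue
        rows.append({"region": region_key(r), "mean": float(vol.values[m].mean())})
    return pd.DataFrame(rows, columns=["region", "mean"])


def paired_t_test(x_a, x_b) -> tuple[float, float]:
    """Two-tailed Student's t for paired samples, subjects in matched order.

    Degenerate case (all differences identical): p = 1 if the common
    difference is 0, else p = 0 (logged as degenerate).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape or x_a.ndim != 1 or x_a.size < 2:
        raise ValidationError("paired t-test needs two equal-length vectors, n >= 2")
    diff = x_b - x_a
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        log.warning("paired t-test: zero variance with nonzero mean difference")
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(x_b, x_a)
    return float(t), float(p)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags at q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values given")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# Cohort analysis

def _validate_paired(manifest: pd.DataFrame) -> tuple[list, list]:
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    conditions = sorted(manifest["condition"].unique())
    if len(conditions) != 2:
        raise ValidationError(
            f"paired design requires exactly 2 conditions, got {conditions}")
    subjects = []
    for s, g in manifest.groupby("subject", sort=True):
        have = sorted(g["condition"].unique())
        if have != conditions or len(g) != 2:
            log.warning("subject %s excluded: conditions %s (need one row per "
                        "condition)", s, have)
            continue
        subjects.append(s)
    if len(subjects) < 2:
        raise ValidationError("fewer than 2 complete subject pairs")
    return subjects, conditions


def analyze_paired_volumes(pets: dict, doses: dict, atlas: LabelAtlas,
                           conditions: tuple[str, str], q: float = 0.05,
                           one_tailed: bool = False) -> pd.DataFrame:
    """Core paired analysis on in-memory template-space PET volumes.

    ``pets``: (subject, condition) -> AnnotatedVolume (template space);
    ``doses``: (subject, condition) -> (injected_activity_mbq, body_weight_g).
    Returns one row per region with means, t, p, BH-adjusted p and flags.
    """
    brain = atlas.brain_mask()
    subjects = sorted({s for s, _ in pets})
    means: dict[tuple, pd.Series] = {}
    for (s, cond), pet in pets.items():
        suv = to_suv(pet, *doses[(s, cond)])
        if not suv.grid.same_geometry(atlas.grid):
            suv = resample(suv, atlas.grid, interpolation="trilinear")
        scaled = scale_to_global_mean(suv, brain)
        df = extract_regional_means(scaled, atlas)
        means[(s, cond)] = df.set_index("region")["mean"]
    regions = [region_key(r) for _, r in atlas.regions.iterrows()]
    cond_a, cond_b = conditions
    rows = []
    for region in regions:
        xa = np.array([means[(s, cond_a)][region] for s in subjects])
        xb = np.array([means[(s, cond_b)][region] for s in subjects])
        t, p = paired_t_test(xa, xb)
        if one_tailed:
            p = p / 2 if t > 0 else 1 - p / 2
        rows.append({"region": region, f"mean_{cond_a}": xa.mean(),
                     f"mean_{cond_b}": xb.mean(), "t_statistic": t, "p_value": p})
    out = pd.DataFrame(rows)
    p_adj, reject = fdr_bh(out["p_value"].to_numpy(), q=q)
    out["p_adjusted"] = p_adj
    out["significant_unadjusted"] = out["p_value"] < 0.05
    out["significant_fdr"] = reject
    return out


def analyze_cohort(manifest: pd.DataFrame, atlas: LabelAtlas,
                   normalization=None, settings=None, q: float = 0.05,
                   one_tailed: bool = False) -> pd.DataFrame:
    """Full cohort analysis from a study manifest.

    ``normalization``: a CT template volume to drive the CT-based
    normalization of each session (requires a ``ct`` column with paths); or
    None when the images are already in template/atlas space.
    ``manifest`` columns: subject, condition, pet [, ct],
    injected_activity_mbq, body_weight_g.
    """
    subjects, conditions = _validate_paired(manifest)
    pets, doses = {}, {}
    rows = manifest[manifest["subject"].isin(subjects)]
    for _, row in rows.iterrows():
        key = (row["subject"], row["condition"])
        pet = read_volume(row["pet"], modality="PET")
        if normalization is not None:
            from .templates import SubjectSession, normalize_subject_ct
            ct = read_volume(row["ct"], modality="CT")
            session = SubjectSession(subject_id=str(key), ct=ct, pet=pet)
            total = normalize_subject_ct(session, normalization, settings)
            from .registration import apply_transform
            pet = apply_transform(pet, field=total)
        pets[key] = pet
        doses[key] = (float(row["injected_activity_mbq"]), float(row["body_weight_g"]))
    return analyze_paired_volumes(pets, doses, atlas, tuple(conditions), q=q,
                                  one_tailed=one_tailed)
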