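"""Two-stage template construction and subject normalization pipelines.

Stage 1: each subject MR is registered (rigid + elastic) to an atlas-space
reference and the warped images are averaged.  Stage 2: each MR is
re-registered intra-modality to the stage-1 mean; the warped MRs form the
final MR template, and the per-subject total deformations are propagated to
the co-registered CT and PET volumes to build CT and PET templates on the
same grid.  The CT template then anchors the MR-free, CT-only normalization
path used for quantification.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import RegistrationFailure, ValidationError
from .grids import AnnotatedVolume, Grid
from .registration import (DeformationField, RegistrationSettings, RigidTransform,
                           apply_transform, compose_fields, register_elastic,
                           register_rigid)

log = logging.getLogger(__name__)


@dataclass
class SubjectSession:
    """One animal's imaging session.

    CT and PET share the scanner frame (bed-locked acquisition); the MR, if
    present, needs ``rigid_mr_to_petct`` unless it already shares the frame.
    """

    subject_id: str
    ct: AnnotatedVolume | None = None
    pet: AnnotatedVolume | None = None
    mr: AnnotatedVolume | None = None
    rigid_mr_to_petct: RigidTransform | None = None


@dataclass
class TemplateSet:
    """Co-aligned MR/CT/PET templates plus the per-subject deformations."""

    mr_template: AnnotatedVolume | None
    ct_template: AnnotatedVolume | None
    pet_template: AnnotatedVolume | None
    per_subject_deformations: dict[str, DeformationField] = field(default_factory=dict)
    stage: str = "final"
    qc: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        grids = [t.grid for t in (self.mr_template, self.ct_template, self.pet_template)
                 if t is not None]
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise ValidationError("templates must share one grid")


def _register_to_reference(moving: AnnotatedVolume, reference: AnnotatedVolume,
                           settings: RegistrationSettings):
    """Rigid then elastic registration; returns (rigid, field, total_field)."""
    rigid = register_rigid(moving, reference, settings)
    # the elastic stage works on the rigidly aligned volume
    aligned = apply_transform(moving, rigid=rigid, out_grid=reference.grid)
    field = register_elastic(aligned, reference, settings=settings)
    total = compose_fields(field, rigid)
    return rigid, field, total


def build_stage1_mean(mrs, ara_reference: AnnotatedVolume,
                      settings: RegistrationSettings | None = None) -> AnnotatedVolume:
    """Register every MR to the atlas-space reference and average.

    Subjects whose elastic stage fails to converge are excluded (logged).
    """
    mrs = list(mrs)
    if len(mrs) < 2:
        raise ValidationError("stage-1 averaging needs at least 2 subjects")
    settings = settings or RegistrationSettings(metric="MI")
    warped = []
    for i, mr in enumerate(mrs):
        rigid, field, _ = _register_to_reference(mr, ara_reference, settings)
        if not field.converged:
            log.warning("subject %d excluded from stage-1 mean: elastic stage "
                        "did not converge", i)
            continue
        aligned = apply_transform(mr, rigid=rigid, out_grid=ara_reference.grid)
        warped.append(apply_transform(aligned, field=field).values)
    if not warped:
        raise RegistrationFailure("no subject registered successfully")
    mean = np.mean(warped, axis=0)
    return AnnotatedVolume(grid=ara_reference.grid, values=mean, modality="MR")


def build_final_templates(sessions, stage1_mean: AnnotatedVolume,
                          settings: RegistrationSettings | None = None,
                          template_grid: Grid | None = None) -> TemplateSet:
    """Intra-modality normalization of each MR to the stage-1 mean; average
    MR/CT/PET through the per-subject total deformations.

    ``template_grid`` defaults to the stage-1 grid (use a 0.2 mm grid for
    the final product).  PET contributions are scaled to their own global
    mean before averaging so injected-dose differences cancel.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValidationError("no sessions given")
    settings = settings or RegistrationSettings(metric="SSD")
    grid = template_grid or stage1_mean.grid
    reference = stage1_mean
    if not grid.same_geometry(stage1_mean.grid):
        from .grids import resample
        reference = resample(stage1_mean, grid, interpolation="trilinear")
        reference.modality = "MR"
    warped = {"MR": [], "CT": [], "PET": []}
    deformations: dict[str, DeformationField] = {}
    qc: dict[str, dict] = {}
    for s in sessions:
        if s.mr is None:
            raise ValidationError(f"session {s.subject_id}: MR required for MR-based "
                                  "template building")
        rigid, field, total_mr = _register_to_reference(s.mr, reference, settings)
        warped["MR"].append(apply_transform(s.mr, rigid=rigid, field=field,
                                            out_grid=grid).values)
        # template -> MR frame -> PET-CT frame
        to_petct = s.rigid_mr_to_petct or RigidTransform.identity()
        total = compose_fields(total_mr, to_petct) if not to_petct.is_identity() else total_mr
        deformations[s.subject_id] = total
        qc[s.subject_id] = {"final_ssd": field.final_ssd,
                            "converged": field.converged,
                            "mean_disp_mm": float(field.magnitude().mean())}
        if s.ct is not None:
            warped["CT"].append(apply_transform(s.ct, field=total, out_grid=grid).values)
        if s.pet is not None:
            pet = apply_transform(s.pet, field=total, out_grid=grid).values
            m = pet[pet > 0].mean() if (pet > 0).any() else 1.0
            warped["PET"].append(pet / m)
    def _mean(mod):
        if not warped[mod]:
            return None
        return AnnotatedVolume(grid=grid, values=np.mean(warped[mod], axis=0),
                               modality=mod if mod != "PET" else "PET")
    return TemplateSet(mr_template=_mean("MR"), ct_template=_mean("CT"),
                       pet_template=_mean("PET"),
                       per_subject_deformations=deformations, stage="final", qc=qc)


def normalize_subject_ct(session: SubjectSession, ct_template: AnnotatedVolume,
                         settings: RegistrationSettings | None = None) -> DeformationField:
    """CT-only normalization: rigid + elastic CT-to-CT-template registration.

    Returns the total pull-back deformation (template space -> subject
    scanner frame); applying it to the subject's co-registered PET warps the
    PET into template space.
    """
    if session.ct is None:
        raise ValidationError(f"session {session.subject_id}: no CT")
    if session.ct.values.max() == session.ct.values.min():
        raise RegistrationFailure(f"session {session.subject_id}: CT has no signal")
    settings = settings or RegistrationSettings(metric="SSD")
    rigid = register_rigid(session.ct, ct_template, settings)
    aligned = apply_transform(session.ct, rigid=rigid, out_grid=ct_template.grid)
    field = register_elastic(aligned, ct_template, settings=settings)
    if not field.converged:
        log.warning("session %s: elastic CT normalization flagged non-converged",
                    session.subject_id)
    return compose_fields(field, rigid)


def normalize_subject_mr(session: SubjectSession, mr_template: AnnotatedVolume,
                         settings: RegistrationSettings | None = None) -> DeformationField:
    """MR-based normalization path (the validation gold standard).

    Total deformation maps template space into the subject's PET-CT frame,
    chaining the MR elastic warp with the MR-to-scanner rigid link if one
    is present.
    """
    if session.mr is None:
        raise ValidationError(f"session {session.subject_id}: no MR")
    settings = settings or RegistrationSettings(metric="SSD")
    rigid = register_rigid(session.mr, mr_template, settings)
    aligned = apply_transform(session.mr, rigid=rigid, out_grid=mr_template.grid)
    field = register_elastic(aligned, mr_template, settings=settings)
    total = compose_fields(field, rigid)
    if session.rigid_mr_to_petct is not None and not session.rigid_mr_to_petct.is_identity():
        total = compose_fields(total, session.rigid_mr_to_petct)
    return total
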