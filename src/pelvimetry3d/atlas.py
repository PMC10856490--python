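"""Reference ("atlas") pelvic model construction and automatic labeling.

The reference model is the population average: starting from the first
model as template, every model is brought into dense correspondence with
the template by similarity alignment plus per-bone non-rigid registration,
corresponded vertices are averaged (after mapping back to the template
pose with a rigid Procrustes fit, so the reference keeps the mean size of
the population), and the consensus landmarks of each model are carried to
the template parametrization barycentrically and averaged.  The cycle is
repeated a few times so the template converges toward the mean shape.

Labeling a new pelvis reverses the machinery: the reference is matched to
the target (similarity then per-bone non-rigid), and every embedded
reference landmark is projected through the deformed reference surface.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .landmarks import LANDMARK_HOST_BONE, Landmark, LandmarkSet
from .meshes import BONES, PelvicModel, SurfaceMesh
from .registration import (
    BarycentricLandmark,
    embed_landmark,
    nonrigid_register,
    project_landmark,
    similarity_align,
    _umeyama,
)

__all__ = [
    "ConsensusLandmarks",
    "ReferenceModel",
    "consensus_landmarks",
    "build_reference",
    "auto_label",
]


@dataclasses.dataclass
class ConsensusLandmarks:
    """Mean landmark positions over raters for one pelvic model."""

    landmarks: LandmarkSet
    n_raters: int

    def __post_init__(self):
        if self.n_raters < 2:
            raise ValueError("consensus needs at least 2 raters")


@dataclasses.dataclass
class ReferenceModel:
    """Mean pelvic shape with landmarks embedded barycentrically."""

    model: PelvicModel
    landmarks: list[BarycentricLandmark]
    provenance: dict = dataclasses.field(default_factory=dict)
    version: str = "1"

    def __post_init__(self):
        seen = set()
        for lm in self.landmarks:
            key = (lm.name, lm.side)
            if key in seen:
                raise ValueError(f"duplicate reference landmark {key}")
            seen.add(key)
            if lm.bone not in BONES:
                raise ValueError(f"landmark {key} hosted on unknown bone {lm.bone!r}")

    def landmark_positions(self) -> LandmarkSet:
        """Evaluate the embedded landmarks on the reference meshes."""
        out = LandmarkSet(subject_id="reference", rater_id="reference")
        for lm in self.landmarks:
            pos = project_landmark(lm, self.model.bones()[lm.bone])
            out.add(Landmark(lm.name, lm.side, pos, "reference"))
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.model.save(directory)
        doc = {
            "version": self.version,
            "provenance": self.provenance,
            "landmarks": [
                {
                    "name": lm.name,
                    "side": lm.side,
                    "bone": lm.bone,
                    "face_index": int(lm.face_index),
                    "weights": [float(w) for w in lm.weights],
                    "offset_normal": float(lm.offset_normal),
                    "host_n_vertices": int(lm.host_n_vertices),
                    "host_n_faces": int(lm.host_n_faces),
                }
                for lm in self.landmarks
            ],
        }
        (directory / "reference_landmarks.json").write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModel":
        directory = Path(directory)
        model = PelvicModel.load(directory, subject_id="reference")
        doc = json.loads((directory / "reference_landmarks.json").read_text())
        landmarks = [
            BarycentricLandmark(
                name=rec["name"],
                face_index=rec["face_index"],
                weights=np.array(rec["weights"]),
                offset_normal=rec["offset_normal"],
                side=rec["side"],
                bone=rec["bone"],
                host_n_vertices=rec["host_n_vertices"],
                host_n_faces=rec["host_n_faces"],
            )
            for rec in doc["landmarks"]
        ]
        return cls(model, landmarks, doc.get("provenance", {}), doc.get("version", "1"))


def consensus_landmarks(
    labelings: list[LandmarkSet], on_missing: str = "fail"
) -> ConsensusLandmarks:
    """Arithmetic mean landmark positions over raters.

    ``on_missing`` chooses the policy for a landmark absent from some
    rater: ``fail`` raises, ``skip`` drops the landmark from the consensus.
    """
    if len(labelings) < 2:
        raise ValueError("consensus needs at least 2 raters")
    keys = set(labelings[0].keys())
    all_keys = set().union(*(ls.keys() for ls in labelings))
    common = set.intersection(*(set(ls.keys()) for ls in labelings))
    if common != all_keys:
        if on_missing == "fail":
            missing = sorted(all_keys - common)
            raise ValueError(f"incomplete labeling: {missing} not present for every rater")
        keys = common
    first = labelings[0]
    out = LandmarkSet(first.subject_id, first.segmentation_id, "consensus")
    for name, side in sorted(keys):
        mean = np.mean([ls.position(name, side) for ls in labelings], axis=0)
        out.add(Landmark(name, side, mean, "consensus"))
    return ConsensusLandmarks(out, n_raters=len(labelings))


def _register_model(
    template: PelvicModel, target: PelvicModel, **reg_kwargs
) -> tuple[dict[str, SurfaceMesh], "np.ndarray"]:
    """Similarity-align the whole template pelvis to the target, then
    register each bone non-rigidly.  Returns deformed bones (template
    topology, target frame) and the similarity matrix used."""
    sim = similarity_align(template, target)
    moved = template.transformed(sim.matrix)
    deformed = {}
    for bone in BONES:
        field = nonrigid_register(moved.bones()[bone], target.bones()[bone], **reg_kwargs)
        deformed[bone] = field.deformed()
    return deformed, sim.matrix


def build_reference(
    models: list[PelvicModel],
    consensus: list[ConsensusLandmarks],
    n_mean_iters: int = 3,
    on_failure: str = "abort",
    **reg_kwargs,
) -> ReferenceModel:
    """Iterative mean-shape construction with landmark averaging.

    Deterministic given model order and parameters.  Registration failure
    on a model aborts unless ``on_failure='skip'``, in which case the model
    is excluded and listed in the provenance report.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to build a reference")
    if len(consensus) != len(models):
        raise ValueError("one consensus landmark set per model required")

    template = models[0].copy()
    # similarity-normalize the initial template: centroid at the origin
    center = template.all_vertices().mean(axis=0)
    shift = np.eye(4)
    shift[:3, 3] = -center
    template = template.transformed(shift)

    mean_landmarks: dict[tuple[str, str], np.ndarray] = {}
    excluded: list[str] = []
    for _ in range(n_mean_iters):
        sums = {bone: np.zeros_like(template.bones()[bone].vertices) for bone in BONES}
        lm_sums: dict[tuple[str, str], np.ndarray] = {}
        n_used = 0
        for model, cons in zip(models, consensus):
            try:
                deformed, _ = _register_model(template, model, **reg_kwargs)
            except (ValueError, RuntimeError) as exc:
                if on_failure == "skip":
                    mid = f"{model.subject_id}/{model.segmentation_id}"
                    if mid not in excluded:
                        excluded.append(mid)
                    warnings.warn(f"excluding {mid}: {exc}", stacklevel=2)
                    continue
                raise
            # rigid map back to the template pose (no scaling: the mean
            # keeps the average size of the population)
            src = np.vstack([deformed[b].vertices for b in BONES])
            dst = template.all_vertices()
            back = _umeyama(src, dst, with_scale=False)
            for bone in BONES:
                sums[bone] += back.apply(deformed[bone].vertices)
            # carry this model's consensus landmarks to the template
            # parametrization: embed on the deformed template bone, then
            # evaluate the embedding on the mapped-back vertices
            for lm in cons.landmarks:
                bone = LANDMARK_HOST_BONE(lm.name, lm.side)
                emb = embed_landmark(deformed[bone], lm.position, lm.name, lm.side)
                mapped = SurfaceMesh(
                    back.apply(deformed[bone].vertices), deformed[bone].faces, bone
                )
                pos = project_landmark(emb, mapped)
                key = (lm.name, lm.side)
                lm_sums[key] = lm_sums.get(key, 0.0) + pos
            n_used += 1
        if n_used == 0:
            raise RuntimeError("registration failed for every model")
        new_bones = {
            bone: SurfaceMesh(sums[bone] / n_used, template.bones()[bone].faces.copy(), bone)
            for bone in BONES
        }
        template = PelvicModel(
            new_bones["sacrum"], new_bones["left_hip"], new_bones["right_hip"],
            subject_id="reference",
        )
        mean_landmarks = {k: v / n_used for k, v in lm_sums.items()}

    embedded = [
        embed_landmark(
            template.bones()[LANDMARK_HOST_BONE(name, side)], pos, name, side
        )
        for (name, side), pos in sorted(mean_landmarks.items())
    ]
    provenance = {
        "n_models": len(models),
        "model_ids": [f"{m.subject_id}/{m.segmentation_id}" for m in models],
        "excluded": excluded,
        "n_mean_iters": n_mean_iters,
    }
    return ReferenceModel(template, embedded, provenance)


def auto_label(
    reference: ReferenceModel,
    target: PelvicModel,
    residual_threshold: float = 2.0,
    **reg_kwargs,
) -> LandmarkSet:
    """Label a pelvic model automatically from the reference.

    The reference is similarity-aligned and then non-rigidly registered to
    the target per bone; every embedded reference landmark is projected
    through the deformation.  If the mean registration residual of any
    bone exceeds ``residual_threshold`` (mm), a warning is attached via
    the ``registration_warning`` attribute (and emitted).
    """
    sim = similarity_align(reference.model, target)
    moved = reference.model.transformed(sim.matrix)
    out = LandmarkSet(
        subject_id=target.subject_id, segmentation_id=target.segmentation_id,
        rater_id="automatic",
    )
    residuals = {}
    deformed = {}
    for bone in BONES:
        field = nonrigid_register(moved.bones()[bone], target.bones()[bone], **reg_kwargs)
        deformed[bone] = field.deformed()
        residuals[bone] = field.residual
    for lm in reference.landmarks:
        pos = project_landmark(lm, deformed[lm.bone])
        out.add(Landmark(lm.name, lm.side, pos, "automatic"))
    worst = max(residuals.values())
    out.registration_residuals = residuals
    out.registration_warning = worst > residual_threshold
    if out.registration_warning:
        warnings.warn(
            f"registration residual {worst:.2f} mm exceeds {residual_threshold} mm",
            stacklevel=2,
        )
    return out
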