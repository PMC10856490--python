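"""Anatomical landmark containers and file formats.

The canonical roster holds the 12 pelvimetry landmarks: 10 bilateral
(labeled separately for the left and right side, hosted on the hip bones)
and 2 midline (promontory and lower sacrum border, hosted on the sacrum),
for 22 point instances per labeled pelvis.  Landmarks are exchanged either
as Slicer-style fiducial CSV (``.fcsv``, Markups version-4 column layout,
RAS+ mm) or as a JSON document; JSON is the canonical format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_LANDMARKS",
    "BILATERAL_LANDMARKS",
    "MIDLINE_LANDMARKS",
    "LANDMARK_HOST_BONE",
    "canonical_instances",
    "Landmark",
    "LandmarkSet",
]

#: name -> True if labeled on both sides
CANONICAL_LANDMARKS: dict[str, bool] = {
    "promontory": False,
    "lower_sacrum_border": False,
    "pubic_symphysis_superior": True,
    "pubic_symphysis_inferior": True,
    "pubic_tubercle": True,
    "iliopectineal_eminence": True,
    "ischial_spine": True,
    "ischial_tuberosity": True,
    "ischium_inferior_ramus": True,
    "antero_superior_iliac_spine": True,
    "postero_superior_iliac_spine": True,
    "iliac_crest": True,
}

BILATERAL_LANDMARKS = tuple(n for n, b in CANONICAL_LANDMARKS.items() if b)
MIDLINE_LANDMARKS = tuple(n for n, b in CANONICAL_LANDMARKS.items() if not b)


def _host_bone(name: str, side: str) -> str:
    if not CANONICAL_LANDMARKS.get(name, True):
        return "sacrum"
    return {"left": "left_hip", "right": "right_hip"}[side]


LANDMARK_HOST_BONE = _host_bone


def canonical_instances() -> list[tuple[str, str]]:
    """All 22 (name, side) instances of the canonical roster."""
    out: list[tuple[str, str]] = []
    for name, bilateral in CANONICAL_LANDMARKS.items():
        if bilateral:
            out.append((name, "left"))
            out.append((name, "right"))
        else:
            out.append((name, "midline"))
    return out


@dataclasses.dataclass
class Landmark:
    name: str
    side: str  # left | right | midline
    position: np.ndarray
    provenance: str = ""  # rater id | "automatic" | "consensus" | "truth"

    def __post_init__(self):
        if self.side not in ("left", "right", "midline"):
            raise ValueError(f"invalid side {self.side!r}")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("landmark position must be finite")


class LandmarkSet:
    """Named 3D landmarks of one labeling of one pelvic model."""

    def __init__(
        self,
        subject_id: str = "",
        segmentation_id: str = "",
        rater_id: str = "",
    ):
        self.subject_id = subject_id
        self.segmentation_id = segmentation_id
        self.rater_id = rater_id
        self._landmarks: dict[tuple[str, str], Landmark] = {}

    def add(self, lm: Landmark) -> None:
        key = (lm.name, lm.side)
        if key in self._landmarks:
            raise ValueError(f"duplicate landmark {key}")
        self._landmarks[key] = lm

    def get(self, name: str, side: str = "midline") -> Landmark:
        return self._landmarks[(name, side)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._landmarks

    def __len__(self) -> int:
        return len(self._landmarks)

    def __iter__(self):
        return iter(self._landmarks.values())

    def keys(self) -> list[tuple[str, str]]:
        return list(self._landmarks.keys())

    def position(self, name: str, side: str = "midline") -> np.ndarray:
        return self.get(name, side).position

    def positions(self, keys: list[tuple[str, str]] | None = None) -> np.ndarray:
        keys = keys if keys is not None else self.keys()
        return np.array([self._landmarks[k].position for k in keys])

    def missing(self) -> list[tuple[str, str]]:
        """Canonical instances absent from this set."""
        return [k for k in canonical_instances() if k not in self._landmarks]

    @property
    def is_complete(self) -> bool:
        return not self.missing()

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        out = LandmarkSet(self.subject_id, self.segmentation_id, self.rater_id)
        rot, t = matrix[:3, :3], matrix[:3, 3]
        for lm in self:
            out.add(Landmark(lm.name, lm.side, rot @ lm.position + t, lm.provenance))
        return out

    def copy(self) -> "LandmarkSet":
        out = LandmarkSet(self.subject_id, self.segmentation_id, self.rater_id)
        for lm in self:
            out.add(Landmark(lm.name, lm.side, lm.position.copy(), lm.provenance))
        return out

    # ------------------------------------------------------------------ I/O

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "subject": self.subject_id,
            "segmentation": self.segmentation_id,
            "rater": self.rater_id,
            "landmarks": [
                {
                    "name": lm.name,
                    "side": lm.side,
                    "xyz": [float(v) for v in lm.position],
                    "provenance": lm.provenance,
                }
                for lm in self
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "LandmarkSet":
        if isinstance(source, dict):
            doc = source
        else:
            doc = json.loads(Path(source).read_text())
        ls = cls(doc.get("subject", ""), doc.get("segmentation", ""), doc.get("rater", ""))
        for rec in doc["landmarks"]:
            ls.add(
                Landmark(
                    rec["name"], rec["side"], np.array(rec["xyz"]), rec.get("provenance", "")
                )
            )
        return ls

    def to_fcsv(self, path: str | Path) -> None:
        """Slicer Markups fiducial CSV (version-4 layout, RAS mm)."""
        lines = [
            "# Markups fiducial file version = 4.11",
            "# CoordinateSystem = RAS",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
        ]
        for i, lm in enumerate(self):
            label = lm.name if lm.side == "midline" else f"{lm.name}_{lm.side}"
            x, y, z = lm.position
            lines.append(
                f"vtkMRMLMarkupsFiducialNode_{i},{x:.6f},{y:.6f},{z:.6f},"
                f"0,0,0,1,1,1,0,{label},,"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_fcsv(
        cls, path: str | Path, subject_id: str = "", segmentation_id: str = "", rater_id: str = ""
    ) -> "LandmarkSet":
        ls = cls(subject_id, segmentation_id, rater_id)
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            cols = line.split(",")
            x, y, z = (float(v) for v in cols[1:4])
            label = cols[11]
            side = "midline"
            name = label
            for s in ("left", "right"):
                if label.endswith(f"_{s}"):
                    name, side = label[: -len(s) - 1], s
            ls.add(Landmark(name, side, np.array([x, y, z]), rater_id))
        return ls
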