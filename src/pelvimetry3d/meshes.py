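"""Core data containers: voxel segmentations, surface meshes, pelvic models.

Coordinates follow the scanner world frame defined by the NIfTI affine
(RAS+ convention), in millimeters, for voxel grids, meshes and landmarks
alike.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

BONES = ("sacrum", "left_hip", "right_hip")


@dataclasses.dataclass
class VoxelSegmentation:
    """Labeled 3D voxel grid with a voxel-to-world affine.

    Parameters
    ----------
    array : (i, j, k) integer label grid
    affine : (4, 4) voxel-to-world transform, mm
    label_map : mapping from segment name (``sacrum``, ``left_hip``,
        ``right_hip``) to the integer label used in ``array``.
    """

    array: np.ndarray
    affine: np.ndarray
    label_map: dict[str, int]

    def __post_init__(self):
        self.array = np.asarray(self.array)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three grid axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def mask(self, segment: str) -> np.ndarray:
        """Binary mask of one named segment."""
        if segment not in self.label_map:
            raise KeyError(f"unknown label: {segment!r}")
        return self.array == self.label_map[segment]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @classmethod
    def from_nifti(cls, path: str | Path, label_map: dict[str, int]) -> "VoxelSegmentation":
        img = nib.load(str(path))
        return cls(
            np.asarray(img.dataobj).astype(np.int32),
            np.asarray(img.affine),
            dict(label_map),
        )

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.array.astype(np.int16), self.affine)
        nib.save(img, str(path))


@dataclasses.dataclass
class SurfaceMesh:
    """Triangle mesh in world coordinates (mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    @property
    def euler_characteristic(self) -> int:
        return self.as_trimesh().euler_number

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        """Apply a 4x4 homogeneous transform to the vertices."""
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return SurfaceMesh(v, self.faces.copy(), self.name)

    def save(self, path: str | Path) -> None:
        """Write PLY/STL/OBJ by extension (PLY binary little-endian preferred)."""
        self.as_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path, name: str = "") -> "SurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(tm, name or Path(path).stem)


@dataclasses.dataclass
class PelvicModel:
    """Three bone meshes (sacrum, left hip, right hip) sharing one world frame."""

    sacrum: SurfaceMesh
    left_hip: SurfaceMesh
    right_hip: SurfaceMesh
    subject_id: str = ""
    segmentation_id: str = ""

    def bones(self) -> dict[str, SurfaceMesh]:
        return {b: getattr(self, b) for b in BONES}

    def copy(self) -> "PelvicModel":
        return PelvicModel(
            self.sacrum.copy(),
            self.left_hip.copy(),
            self.right_hip.copy(),
            self.subject_id,
            self.segmentation_id,
        )

    def transformed(self, matrix: np.ndarray) -> "PelvicModel":
        return PelvicModel(
            self.sacrum.transformed(matrix),
            self.left_hip.transformed(matrix),
            self.right_hip.transformed(matrix),
            self.subject_id,
            self.segmentation_id,
        )

    def all_vertices(self) -> np.ndarray:
        return np.vstack([m.vertices for m in (self.sacrum, self.left_hip, self.right_hip)])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for bone, mesh in self.bones().items():
            mesh.save(directory / f"{bone}.ply")

    @classmethod
    def load(cls, directory: str | Path, subject_id: str = "", segmentation_id: str = "") -> "PelvicModel":
        directory = Path(directory)
        meshes = {}
        for bone in BONES:
            for ext in (".ply", ".stl", ".obj"):
                p = directory / f"{bone}{ext}"
                if p.exists():
                    meshes[bone] = SurfaceMesh.load(p, bone)
                    break
            else:
                raise FileNotFoundError(f"no mesh file for bone {bone!r} in {directory}")
        return cls(subject_id=subject_id, segmentation_id=segmentation_id, **meshes)
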