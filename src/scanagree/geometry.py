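"""Spatial primitives: 3D scalar images, integer label maps, affine transforms.

Images live on a regular grid in physical (mm) space.  The voxel at integer
index ``(i, j, k)`` sits at physical position

    x = origin + direction @ (spacing * (i, j, k))

with ``direction`` an orthonormal cosine matrix (identity by default).  Arrays
are indexed ``voxels[i, j, k]`` in the same axis order as the physical axes,
which matches the SimpleITK index convention (numpy arrays obtained from
``sitk.GetArrayFromImage`` are transposed relative to this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelMap",
    "AffineTransform",
    "same_grid",
]

_ORTHO_TOL = 1e-6


def _as_float3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class AffineTransform:
    """A 12-DOF affine map between physical coordinate frames.

    Convention: maps *moving*-image physical coordinates to *fixed*-image
    physical coordinates, ``x_fixed = linear @ x_moving + translation_mm``.
    The linear part must be orientation preserving (positive determinant).
    """

    linear: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation_mm = _as_float3(self.translation_mm)
        if np.linalg.det(self.linear) <= 0:
            raise ValueError("affine linear part must have positive determinant")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(..., 3)`` array of physical points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation_mm

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation_mm)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return AffineTransform(
            self.linear @ other.linear,
            self.linear @ other.translation_mm + self.translation_mm,
        )

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 representation."""
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation_mm
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "AffineTransform":
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_sitk(self) -> sitk.AffineTransform:
        """SimpleITK transform applying the same point map."""
        t = sitk.AffineTransform(3)
        t.SetMatrix(self.linear.ravel().tolist())
        t.SetTranslation(self.translation_mm.tolist())
        return t

    def save_txt(self, path) -> None:
        np.savetxt(path, self.as_matrix(), fmt="%.12g")

    @classmethod
    def load_txt(cls, path) -> "AffineTransform":
        return cls.from_matrix(np.loadtxt(path))


@dataclass
class _Grid:
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def _check_grid(self, shape) -> None:
        self.spacing_mm = _as_float3(self.spacing_mm)
        self.origin_mm = _as_float3(self.origin_mm)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix must be orthonormal")
        if len(shape) != 3:
            raise ValueError("expected a 3D array")

    @property
    def shape(self):  # pragma: no cover - trivial
        raise NotImplementedError

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return self.origin_mm + (idx * self.spacing_mm) @ self.direction.T

    def physical_grid(self) -> np.ndarray:
        """Physical coordinates of every voxel, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(
            *[np.arange(n) for n in self.shape], indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1)
        return self.index_to_physical(idx)


@dataclass
class ImageVolume(_Grid):
    """A 3D scalar image on a regular physical grid."""

    voxels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1)))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self._check_grid(self.voxels.shape)

    @property
    def shape(self):
        return self.voxels.shape

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))
        img.SetSpacing(self.spacing_mm.tolist())
        img.SetOrigin(self.origin_mm.tolist())
        img.SetDirection(self.direction.ravel().tolist())
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            voxels=sitk.GetArrayFromImage(img).T.astype(float),
            spacing_mm=np.array(img.GetSpacing()),
            origin_mm=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
        )

    def nifti_affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def save_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), self.nifti_affine()), str(path))

    @classmethod
    def load_nifti(cls, path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        direction = aff[:3, :3] / spacing
        return cls(
            voxels=np.asarray(img.get_fdata(), dtype=float),
            spacing_mm=spacing,
            origin_mm=aff[:3, 3],
            direction=direction,
        )


@dataclass
class LabelMap(_Grid):
    """Integer segmentation on a regular physical grid (0 = background)."""

    labels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int32))
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must be integer typed")
        if self.labels.min() < 0:
            raise ValueError("label ids must be >= 0")
        self._check_grid(self.labels.shape)

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def volume_ml(self, label_id: int) -> float:
        """Volume of one structure in mL (voxel count x voxel volume)."""
        voxel_mm3 = float(np.prod(self.spacing_mm))
        return float(np.count_nonzero(self.labels == label_id)) * voxel_mm3 / 1000.0

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.labels.T.astype(np.int32)))
        img.SetSpacing(self.spacing_mm.tolist())
        img.SetOrigin(self.origin_mm.tolist())
        img.SetDirection(self.direction.ravel().tolist())
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, names: dict | None = None) -> "LabelMap":
        return cls(
            labels=sitk.GetArrayFromImage(img).T.astype(np.int32),
            spacing_mm=np.array(img.GetSpacing()),
            origin_mm=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
            names=dict(names or {}),
        )

    def save_nifti(self, path) -> None:
        import nibabel as nib

        grid = ImageVolume(
            voxels=np.zeros(self.shape),
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            direction=self.direction,
        )
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), grid.nifti_affine()), str(path)
        )

    @classmethod
    def load_nifti(cls, path, names: dict | None = None) -> "LabelMap":
        vol = ImageVolume.load_nifti(path)
        return cls(
            labels=np.rint(vol.voxels).astype(np.int32),
            spacing_mm=vol.spacing_mm,
            origin_mm=vol.origin_mm,
            direction=vol.direction,
            names=dict(names or {}),
        )


def same_grid(a: _Grid, b: _Grid, tol: float = 1e-6) -> bool:
    """Whether two objects share shape, spacing, origin and orientation."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing_mm, b.spacing_mm, atol=tol)
        and np.allclose(a.origin_mm, b.origin_mm, atol=tol)
        and np.allclose(a.direction, b.direction, atol=tol)
    )
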