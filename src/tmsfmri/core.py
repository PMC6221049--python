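"""Core containers shared by every pipeline stage.

Three small value types circulate through the package:

* :class:`VolumeSeries` — a 4-D EPI raster with its voxel-to-world affine
  and repetition time (TR).  All spatial quantities in the package are
  world millimetres in the RAS+ frame defined by the affine; voxel indices
  are 0-based.
* :class:`RigidTransform` — a proper rigid body motion (rotation with
  determinant +1 plus translation) acting on world-mm points.
* :class:`PulseTrain` — the ordered TMS events (onset in seconds,
  intensity level) that drive both simulation and design construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "VolumeSeries",
    "RigidTransform",
    "PulseTrain",
    "HIGH",
    "LOW",
]

#: Intensity-level labels for the two pulse conditions (115% and 60% of
#: the resting motor threshold in the acquisition protocol modelled here).
HIGH = "high"
LOW = "low"


@dataclass
class VolumeSeries:
    """A 4-D signal raster (x, y, z, t) with geometry and timing.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, nt)``.  The third voxel axis is the
        slice axis throughout the package.
    affine
        4x4 voxel-to-world matrix (NIfTI convention, RAS+ mm).
    tr
        Repetition time in seconds (one dynamic = one 3-D volume).
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's direction columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def world_center(self) -> np.ndarray:
        """World coordinates of the grid centre (rotation centre convention)."""
        center_vox = (np.array(self.grid_shape, dtype=float) - 1.0) / 2.0
        return self.affine[:3, :3] @ center_vox + self.affine[:3, 3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition onset time of each dynamic, in seconds."""
        return np.arange(self.n_volumes) * self.tr

    def volume(self, t: int) -> np.ndarray:
        return self.data[..., t]

    def copy(self) -> "VolumeSeries":
        return VolumeSeries(self.data.copy(), self.affine.copy(), self.tr)

    # -- IO ---------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        zooms = tuple(self.voxel_size) + (self.tr,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, tr: float | None = None) -> "VolumeSeries":
        data = np.asanyarray(img.dataobj, dtype=np.float32)
        if tr is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ValueError("TR not stored in header; pass tr explicitly")
            tr = float(zooms[3])
        return cls(data, np.asarray(img.affine), tr)

    @classmethod
    def load(cls, path: str | Path, tr: float | None = None) -> "VolumeSeries":
        return cls.from_nifti(nib.load(str(path)), tr=tr)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a boolean 3-D mask as uint8 NIfTI."""
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.asarray(affine, float)), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0, np.asarray(img.affine)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` on world-mm points.

    ``rotation`` is orthonormal with determinant +1; composition and
    inversion are closed.  Euler angles follow the extrinsic x-y-z
    convention (``R = Rz @ Ry @ Rx``), reported in degrees.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(
        cls,
        params: np.ndarray,
        center: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Build from 6 parameters (tx, ty, tz mm, rx, ry, rz degrees).

        When ``center`` is given the rotation is applied about that world
        point: ``x -> R (x - c) + c + t``.
        """
        p = np.asarray(params, dtype=float).reshape(6)
        R = Rotation.from_euler("xyz", p[3:], degrees=True).as_matrix()
        t = p[:3].copy()
        if center is not None:
            c = np.asarray(center, dtype=float).reshape(3)
            t = t + c - R @ c
        return cls(R, t)

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float)
        return cls(mat[:3, :3], mat[:3, 3])

    # -- conversions ------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def params(self, center: np.ndarray | None = None) -> np.ndarray:
        """Inverse of :meth:`from_params` (same ``center`` convention)."""
        angles = Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)
        t = self.translation.copy()
        if center is not None:
            c = np.asarray(center, dtype=float).reshape(3)
            t = t - c + self.rotation @ c
        return np.concatenate([t, angles])

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )


def load_affine(path: str | Path) -> np.ndarray:
    """Read a 4x4 transform stored as whitespace-separated text, row major."""
    mat = np.loadtxt(str(path), dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got {mat.shape}")
    return mat


def save_affine(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(mat, dtype=float), fmt="%.10g")


@dataclass
class PulseTrain:
    """Ordered TMS pulse events: onset (s) and intensity level per pulse."""

    onsets: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float).reshape(-1)
        self.levels = np.asarray(self.levels, dtype=object).reshape(-1)
        if self.onsets.shape != self.levels.shape:
            raise ValueError("onsets and levels must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.levels) - {HIGH, LOW}
        if bad:
            raise ValueError(f"unknown intensity levels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.onsets.size

    def onsets_for(self, level: str) -> np.ndarray:
        return self.onsets[self.levels == level]

    def relabeled(self, levels: np.ndarray) -> "PulseTrain":
        """Same onsets with a new level assignment (used by permutation FWE)."""
        return PulseTrain(self.onsets.copy(), np.asarray(levels, dtype=object))

    # -- IO ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets, "level": self.levels})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PulseTrain":
        df = pd.read_csv(path, sep="\t")
        return cls(df["onset_s"].to_numpy(), df["level"].to_numpy())


# ---------------------------------------------------------------------------
# resampling helpers shared by synth (motion), preproc (realign/reslice)
# ---------------------------------------------------------------------------

def world_map_to_voxel(affine: np.ndarray, world: RigidTransform | np.ndarray) -> np.ndarray:
    """Express a world-space map as a voxel-to-voxel homogeneous matrix.

    Returns M such that sampling ``input[M @ v]`` evaluates the input image
    at world position ``W(A v)`` for output voxel ``v``.
    """
    A = np.asarray(affine, dtype=float)
    W = world.as_matrix() if isinstance(world, RigidTransform) else np.asarray(world, float)
    return np.linalg.inv(A) @ W @ A


def resample_volume(
    vol: np.ndarray,
    affine: np.ndarray,
    world: RigidTransform | np.ndarray,
    order: int = 1,
    cval: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly sample ``vol`` at world-mapped positions.

    ``out(v) = vol(A^-1 W A v)``.  Returns the resampled volume and a
    boolean validity mask marking output voxels whose sample position fell
    inside the input grid (outside samples are filled with ``cval``).
    """
    from scipy.ndimage import affine_transform

    M = world_map_to_voxel(affine, world)
    out = affine_transform(
        np.asarray(vol, dtype=float), M[:3, :3], offset=M[:3, 3], order=order,
        mode="constant", cval=cval, prefilter=(order > 1),
    )
    # validity: warped voxel coordinates inside [0, n-1]
    shape = vol.shape
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    warped = M[:3, :3] @ idx + M[:3, 3:4]
    ok = np.ones(warped.shape[1], dtype=bool)
    for ax in range(3):
        ok &= (warped[ax] >= 0) & (warped[ax] <= shape[ax] - 1)
    return out, ok.reshape(shape)
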