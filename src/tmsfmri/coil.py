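"""TMS coil pose reconstruction and motion-corrected isocenter tracking.

The coil carries six water-filled fiducial capsules on its back plate,
visible in a T2-weighted scan.  Fitting the known template geometry to
the observed marker positions (labelled correspondences, closed-form
orthogonal Procrustes with SVD sign correction) yields the coil pose;
applying the pose to the template's isocenter offset yields the point of
maximal induced field.  During the EPI run the head moves under the
fixed coil, so the per-volume realignment transforms are used to
reconstruct where, in reference anatomy, the isocenter sat at each
dynamic; the track is summarised by its centre of gravity (COG) and the
maximum displacement from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RigidTransform

__all__ = [
    "CoilModel",
    "CoilTrack",
    "default_coil_model",
    "fit_coil_pose",
    "project_isocenter",
    "track_isocenter",
    "summarize_track",
]


@dataclass
class CoilModel:
    """Template fiducial geometry in the coil frame (mm).

    ``isocenter_offset`` is the point of maximal induced field relative
    to the marker plate.  The shipped default places six markers in two
    rows on the back plate and the isocenter 20 mm below the plate
    centre along the inward normal — an assumed, configurable geometry,
    since the physical plate is not standardised.
    """

    template_markers: dict[str, np.ndarray]
    isocenter_offset: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -20.0]))
    normal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.template_markers = {
            str(k): np.asarray(v, dtype=float).reshape(3)
            for k, v in self.template_markers.items()
        }
        self.isocenter_offset = np.asarray(self.isocenter_offset, dtype=float).reshape(3)
        self.normal_axis = np.asarray(self.normal_axis, dtype=float).reshape(3)
        self.validate()

    def validate(self) -> None:
        if len(self.template_markers) < 3:
            raise ValueError("coil model needs at least 3 markers")
        pts = np.stack(list(self.template_markers.values()))
        if _collinear(pts):
            raise ValueError("coil template markers are collinear")
        n = np.linalg.norm(self.normal_axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("normal_axis must be unit length")

    def marker_array(self, labels: list[str] | None = None) -> np.ndarray:
        labels = list(self.template_markers) if labels is None else labels
        return np.stack([self.template_markers[l] for l in labels])

    # -- IO ---------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "template_markers": {k: v.tolist() for k, v in self.template_markers.items()},
            "isocenter_offset": self.isocenter_offset.tolist(),
            "normal_axis": self.normal_axis.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoilModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            template_markers=payload["template_markers"],
            isocenter_offset=np.asarray(payload["isocenter_offset"]),
            normal_axis=np.asarray(payload["normal_axis"]),
        )


def default_coil_model() -> CoilModel:
    """Six back-plate markers in two rows, isocenter 20 mm inward."""
    markers = {
        "m1": (-30.0, -20.0, 0.0),
        "m2": (0.0, -25.0, 0.0),
        "m3": (30.0, -20.0, 0.0),
        "m4": (-30.0, 20.0, 5.0),
        "m5": (0.0, 25.0, 5.0),
        "m6": (30.0, 20.0, 5.0),
    }
    return CoilModel({k: np.array(v) for k, v in markers.items()})


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(1.0, s[0])


def fit_coil_pose(
    observed_markers: pd.DataFrame | dict[str, np.ndarray],
    coil_model: CoilModel,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of the template to observed markers.

    Correspondence is by marker label.  The solution is the closed-form
    orthogonal Procrustes rotation (Kabsch) with the SVD sign corrected
    to a proper rotation (no scaling, no reflection), plus the matching
    translation.  Returns the transform mapping template to observed
    coordinates and the root-mean-square marker residual in mm.
    """
    if isinstance(observed_markers, pd.DataFrame):
        obs = {
            str(r["marker_id"]): np.array([r["x_mm"], r["y_mm"], r["z_mm"]], dtype=float)
            for _, r in observed_markers.iterrows()
        }
    else:
        obs = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in observed_markers.items()}
    labels = [l for l in coil_model.template_markers if l in obs]
    if len(labels) < 3:
        raise ValueError("need at least 3 corresponding markers")
    P = coil_model.marker_array(labels)          # template
    Q = np.stack([obs[l] for l in labels])       # observed
    if _collinear(P) or _collinear(Q):
        raise ValueError("degenerate (collinear) marker configuration")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cP).T @ (Q - cQ)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    pose = RigidTransform(R, t)
    resid = pose.apply(P) - Q
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return pose, rms


def project_isocenter(pose: RigidTransform, coil_model: CoilModel) -> np.ndarray:
    """Isocenter position in the observed frame: pose applied to the offset."""
    return pose.apply(coil_model.isocenter_offset)


@dataclass
class CoilTrack:
    """Per-volume isocenter positions with COG and displacement summary."""

    per_volume_isocenter: np.ndarray   # (n_volumes, 3) world mm
    cog: np.ndarray
    max_displacement: float

    @classmethod
    def from_points(cls, points: np.ndarray) -> "CoilTrack":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            raise ValueError("empty isocenter track")
        cog = pts.mean(axis=0)
        disp = np.linalg.norm(pts - cog, axis=1)
        return cls(pts, cog, float(disp.max()))

    @property
    def displacements(self) -> np.ndarray:
        return np.linalg.norm(self.per_volume_isocenter - self.cog, axis=1)

    def to_frame(self) -> pd.DataFrame:
        pts = self.per_volume_isocenter
        return pd.DataFrame({
            "volume": np.arange(len(pts)),
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "displacement_from_cog_mm": self.displacements,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def track_isocenter(
    iso_anat: np.ndarray,
    epi_to_anat: RigidTransform | np.ndarray | None,
    realign_transforms: list[RigidTransform],
) -> CoilTrack:
    """Head-motion-corrected isocenter reconstruction per EPI volume.

    The coil is fixed in scanner space while the head moves, so the
    anatomical point under the isocenter at dynamic t is obtained by
    carrying the (T1-space) isocenter into the EPI reference frame with
    the inverse of the EPI-to-anatomical affine, applying the volume's
    realignment map (volume → reference, itself the inverse of the
    resampling transform estimated during realignment), and re-expressing
    the result in anatomical world mm.  ``epi_to_anat=None`` means the
    frames coincide (identity).
    """
    iso = np.asarray(iso_anat, dtype=float).reshape(3)
    if epi_to_anat is None:
        A = np.eye(4)
    elif isinstance(epi_to_anat, RigidTransform):
        A = epi_to_anat.as_matrix()
    else:
        A = np.asarray(epi_to_anat, dtype=float)
        if A.shape != (4, 4):
            raise ValueError("epi_to_anat must be a RigidTransform or 4x4 matrix")
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValueError("epi_to_anat affine is not invertible") from e
    iso_epi = Ainv[:3, :3] @ iso + Ainv[:3, 3]
    points = np.empty((len(realign_transforms), 3))
    for t, M in enumerate(realign_transforms):
        p = M.apply(iso_epi)
        points[t] = A[:3, :3] @ p + A[:3, 3]
    return CoilTrack.from_points(points)


def summarize_track(track: CoilTrack, precision_mm: float = 0.1) -> dict[str, float]:
    """COG coordinates and max displacement, rounded to 0.1 mm."""
    if track.per_volume_isocenter.size == 0:
        raise ValueError("empty track")
    ndig = max(0, int(round(-np.log10(precision_mm))))
    return {
        "cog_x_mm": round(float(track.cog[0]), ndig),
        "cog_y_mm": round(float(track.cog[1]), ndig),
        "cog_z_mm": round(float(track.cog[2]), ndig),
        "max_displacement_mm": round(float(track.max_displacement), ndig),
    }
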