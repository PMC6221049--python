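"""Rigid-body realignment, reslicing and Gaussian smoothing of EPI series.

Realignment estimates, for every volume, the six rigid parameters (three
translations in mm, three rotations in degrees, about the grid centre)
that minimise the mean squared intensity difference to a reference under
trilinear resampling.  The optimiser is Gauss-Newton with an analytic
image-gradient Jacobian, run coarse-to-fine over a Gaussian image
pyramid, in two passes: first to the initial volume, then to the mean of
the aligned series (the common reference policy).  Transforms are
finally re-expressed relative to volume 0 so the first volume's
transform is exactly the identity.

Boundary handling is zero padding with a validity mask excluded from the
cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .core import RigidTransform, VolumeSeries, resample_volume

__all__ = [
    "RealignResult",
    "realign",
    "smooth",
    "reslice",
    "FWHM_TO_SIGMA",
]

#: fwhm = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RealignResult:
    """Realignment output.

    ``motion`` holds the estimated head-motion parameters per volume
    (tx, ty, tz mm, rx, ry, rz degrees, rotations about the grid
    centre): the transform that carries reference-position anatomy to
    its position in that volume.  ``transforms`` holds the inverse maps
    (volume → reference), which is what coil tracking consumes.
    ``resampled`` is the series aligned to the reference frame.
    """

    motion: np.ndarray                 # (n_volumes, 6)
    transforms: list[RigidTransform]   # volume -> reference
    resampled: VolumeSeries

    def motion_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
        ).assign(volume=np.arange(len(self.motion)))[
            ["volume", "tx", "ty", "tz", "rx", "ry", "rz"]
        ]


def _euler_rotation_derivatives(angles_rad: np.ndarray) -> list[np.ndarray]:
    """d(Rz Ry Rx)/d(angle) for the extrinsic x-y-z convention."""
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    dRx = np.array([[0, 0, 0], [0, -sx, -cx], [0, cx, -sx]])
    dRy = np.array([[-sy, 0, cy], [0, 0, 0], [-cy, 0, -sy]])
    dRz = np.array([[-sz, -cz, 0], [cz, -sz, 0], [0, 0, 0]])
    return [Rz @ Ry @ dRx, Rz @ dRy @ Rx, dRz @ Ry @ Rx]


def _rotation(angles_rad: np.ndarray) -> np.ndarray:
    return Rotation.from_euler("xyz", angles_rad).as_matrix()


def _downsample(vol: np.ndarray) -> np.ndarray:
    return gaussian_filter(vol, sigma=1.0, mode="nearest")[::2, ::2, ::2]


def _register_volume(
    moving: np.ndarray,
    reference: np.ndarray,
    affine: np.ndarray,
    center: np.ndarray,
    p0: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> np.ndarray:
    """Gauss-Newton fit of 6 rigid parameters at one pyramid level.

    Minimises sum over reference voxels v of
    ``(moving(A^-1 G_p(A v)) - reference(v))^2`` where
    ``G_p(x) = R (x - c) + c + t``; the Jacobian uses sampled image
    gradients of the moving volume and analytic rotation derivatives.
    Parameters are (tx, ty, tz mm, rx, ry, rz rad) here.
    """
    shape = reference.shape
    A = affine
    A3 = A[:3, :3]
    A3inv = np.linalg.inv(A3)
    vox = np.indices(shape, dtype=float).reshape(3, -1)
    world = A3 @ vox + A[:3, 3:4]          # (3, N) world coords of ref voxels
    world_c = world - center[:, None]
    ref_flat = reference.reshape(-1)
    grads = np.stack(np.gradient(moving))  # voxel-unit gradients, (3, ...)

    p = p0.astype(float).copy()
    lam = 1e-6
    prev_cost = np.inf
    for _ in range(max_iter):
        R = _rotation(p[3:])
        warped_world = R @ world_c + center[:, None] + p[:3, None]
        warped_vox = A3inv @ (warped_world - A[:3, 3:4])
        valid = np.ones(warped_vox.shape[1], dtype=bool)
        for ax in range(3):
            valid &= (warped_vox[ax] >= 0) & (warped_vox[ax] <= shape[ax] - 1)
        if valid.sum() < 32:
            break
        coords = warped_vox[:, valid]
        sampled = map_coordinates(moving, coords, order=1, mode="constant")
        r = sampled - ref_flat[valid]
        cost = float(np.mean(r ** 2))

        g = np.stack([map_coordinates(grads[ax], coords, order=1, mode="constant")
                      for ax in range(3)])          # (3, n) voxel-space gradient
        dR = _euler_rotation_derivatives(p[3:])
        J = np.empty((coords.shape[1], 6))
        wc = world_c[:, valid]
        for j in range(3):                           # translations
            dwdp = A3inv[:, j]
            J[:, j] = g.T @ dwdp
        for j in range(3):                           # rotations
            dworld = dR[j] @ wc
            dwdp = A3inv @ dworld                    # (3, n)
            J[:, 3 + j] = np.einsum("an,an->n", g, dwdp)

        JtJ = J.T @ J
        Jtr = J.T @ r
        try:
            delta = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ)) + 1e-12 * np.eye(6), -Jtr)
        except np.linalg.LinAlgError:
            break
        if cost > prev_cost + 1e-12:
            lam *= 10.0
        else:
            lam = max(lam / 10.0, 1e-9)
        prev_cost = cost
        p = p + delta
        if np.max(np.abs(delta[:3])) < tol and np.max(np.abs(np.degrees(delta[3:]))) < tol:
            break
    return p


def _estimate(
    moving: np.ndarray,
    reference: np.ndarray,
    affine: np.ndarray,
    center: np.ndarray,
    p0: np.ndarray,
    pyramid_levels: int,
    tol: float,
) -> np.ndarray:
    # build matched pyramids; level 0 = full resolution
    movs, refs, affs = [moving], [reference], [affine]
    for _ in range(pyramid_levels - 1):
        if min(movs[-1].shape) < 8:
            break
        movs.append(_downsample(movs[-1]))
        refs.append(_downsample(refs[-1]))
        S = np.diag([2.0, 2.0, 2.0, 1.0])
        affs.append(affs[-1] @ S)
    p = p0.copy()
    for lvl in reversed(range(len(movs))):
        p = _register_volume(movs[lvl], refs[lvl], affs[lvl], center, p, tol=tol)
    return p


def realign(
    series: VolumeSeries,
    reference: str = "two_pass_mean",
    pyramid_levels: int = 3,
    tol: float = 1e-4,
) -> RealignResult:
    """Rigid-body motion correction of a 4-D series.

    ``reference='two_pass_mean'`` (default) registers to the first
    volume, rebuilds the mean of the aligned series, and re-registers to
    that mean; ``reference='first'`` stops after the first pass.  The
    returned transforms are normalised so volume 0 is exactly identity.
    """
    if series.n_volumes < 2:
        raise ValueError("realignment needs at least 2 volumes")
    if reference not in ("two_pass_mean", "first"):
        raise ValueError(f"unknown reference policy: {reference}")
    data = np.asarray(series.data, dtype=float)
    affine = series.affine
    center = series.world_center
    nt = series.n_volumes

    params = np.zeros((nt, 6))       # internal: mm + radians
    ref_img = data[..., 0]
    for t in range(1, nt):
        p0 = params[t - 1].copy()    # warm start from the previous volume
        params[t] = _estimate(data[..., t], ref_img, affine, center, p0,
                              pyramid_levels, tol)

    if reference == "two_pass_mean":
        aligned = np.empty_like(data)
        for t in range(nt):
            G = _params_to_transform(params[t], center)
            vol, _ = resample_volume(data[..., t], affine, G)
            aligned[..., t] = vol
        mean_img = aligned.mean(axis=3)
        for t in range(nt):
            params[t] = _estimate(data[..., t], mean_img, affine, center,
                                  params[t], pyramid_levels, tol)

    # normalise: express motion relative to volume 0 (exact identity there)
    G0 = _params_to_transform(params[0], center)
    G0inv = G0.inverse()
    motions: list[RigidTransform] = []
    for t in range(nt):
        Gt = _params_to_transform(params[t], center)
        motions.append(Gt.compose(G0inv))

    motion_params = np.stack([m.params(center=center) for m in motions])
    transforms = [m.inverse() for m in motions]

    resampled = series.copy()
    out = np.empty_like(data)
    for t in range(nt):
        vol, _ = resample_volume(data[..., t], affine, motions[t])
        out[..., t] = vol
    resampled.data = out.astype(series.data.dtype)
    return RealignResult(motion_params, transforms, resampled)


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> RigidTransform:
    """Internal (mm, radians) parameters to a world transform about center."""
    q = np.concatenate([p[:3], np.degrees(p[3:])])
    return RigidTransform.from_params(q, center=center)


def smooth(series: VolumeSeries, fwhm: float | tuple[float, float, float]) -> VolumeSeries:
    """Per-volume 3-D Gaussian smoothing with FWHM given in mm.

    The kernel width is converted to voxels via the voxel size
    (``sigma = fwhm / (2 sqrt(2 ln 2)) / voxel_size``); ``fwhm=0`` is
    the identity.  Zero padding at the volume boundary.
    """
    fwhm_arr = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,)).copy()
    if np.any(fwhm_arr < 0):
        raise ValueError("fwhm must be non-negative")
    if np.all(fwhm_arr == 0):
        return series.copy()
    sigma_vox = fwhm_arr * FWHM_TO_SIGMA / series.voxel_size
    out = series.copy()
    smoothed = np.empty_like(np.asarray(out.data, dtype=float))
    for t in range(series.n_volumes):
        smoothed[..., t] = gaussian_filter(
            np.asarray(series.data[..., t], dtype=float),
            sigma=sigma_vox, mode="constant", cval=0.0,
        )
    out.data = smoothed.astype(series.data.dtype)
    return out


def reslice(
    series: VolumeSeries,
    target_voxel_size: float | tuple[float, float, float],
) -> VolumeSeries:
    """Trilinearly resample onto a grid of the requested voxel size.

    The new grid spans the same world field of view (the half-voxel
    bounding box is preserved), so world coordinates of image content
    are unchanged.
    """
    new_vs = np.broadcast_to(np.asarray(target_voxel_size, dtype=float), (3,)).copy()
    if np.any(new_vs <= 0):
        raise ValueError("target voxel size must be positive")
    old_vs = series.voxel_size
    old_shape = np.array(series.grid_shape)
    new_shape = np.maximum(1, np.round(old_shape * old_vs / new_vs).astype(int))

    A = series.affine
    dirs = A[:3, :3] / old_vs                    # unit direction columns
    new_A = np.eye(4)
    new_A[:3, :3] = dirs * new_vs
    # keep the FOV corner (voxel -0.5 along each axis) fixed in world space
    corner = A[:3, 3] - A[:3, :3] @ np.full(3, 0.5)
    new_A[:3, 3] = corner + new_A[:3, :3] @ np.full(3, 0.5)

    M = np.linalg.inv(A) @ new_A                 # new voxel -> old voxel
    out_data = np.empty(tuple(new_shape) + (series.n_volumes,), dtype=float)
    for t in range(series.n_volumes):
        out_data[..., t] = affine_transform(
            np.asarray(series.data[..., t], dtype=float),
            M[:3, :3], offset=M[:3, 3], output_shape=tuple(new_shape),
            order=1, mode="constant", cval=0.0,
        )
    return VolumeSeries(out_data.astype(series.data.dtype), new_A, series.tr)
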