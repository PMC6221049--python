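"""Synthetic concurrent TMS-fMRI acquisitions with known ground truth.

The generator emulates the acquisition protocol the pipeline targets —
a 30-slice, 4x4x4 mm³ EPI run of 500 dynamics at TR 2.0 s, with single
TMS pulses delivered at random intervals of 5-8 dynamics (10-16 s) and
strictly interleaved 115%/60% RMT intensities — so that every downstream
stage (realignment, spike repair, coil tracking, GLM) can be validated
against injected truth without any external data.

Anatomy is deliberately schematic: three concentric ellipsoidal shells
(CSF outside, grey matter in the middle, white matter at the core) on a
rectangular grid.  The signal model per voxel is

``baseline * (1 + effect) + drift + AR(1) noise``

where the effect is the percent-signal-change response to high-intensity
pulses (HRF-convolved, unit peak per isolated event), the drift is a
low-order Legendre polynomial with per-voxel random coefficients, and the
noise is stationary AR(1) Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coil import CoilModel
from .core import HIGH, LOW, PulseTrain, RigidTransform, VolumeSeries, resample_volume
from .glm import HRFParams, event_regressors

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_pulse_train",
    "generate_phantom",
    "inject_spikes",
    "apply_motion",
    "generate_motion_params",
    "generate_coil_markers",
]

#: baseline signal level per tissue class (arbitrary EPI units)
TISSUE_BASELINE = {"wm": 900.0, "gm": 1000.0, "csf": 500.0}

#: normalised-radius bands of the concentric-shell anatomy
SHELL_BANDS = {"wm": (0.0, 0.35), "gm": (0.35, 0.65), "csf": (0.65, 0.85)}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic acquisition.

    Defaults reproduce the modelled protocol: 30 slices of 4 mm isotropic
    voxels, 500 dynamics at TR 2.0 s (17 min), ~1% peak signal change in
    the target region for high-intensity pulses, temporal SNR ≈ 67
    (noise_sd 15 on a grey-matter baseline of 1000), AR(1) coefficient
    0.3 and ~1% slow drift — all realistic single-subject 3T EPI values.
    The in-plane matrix is kept small (16x16); only slice count, voxel
    size and timing carry protocol meaning for the recovery tests.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 30)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_dynamics: int = 500
    tr: float = 2.0
    noise_sd: float = 15.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 10.0
    effect_pct: float = 1.0
    texture_pct: float = 5.0
    interval_range: tuple[int, int] = (5, 8)
    target_regions: dict[str, np.ndarray] | None = None
    hrf_params: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 8")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.n_dynamics <= 0 or self.tr <= 0:
            raise ValueError("n_dynamics and tr must be positive")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with the grid centre at the world origin."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxel_size)
        half = (np.array(self.grid_shape, dtype=float) - 1.0) / 2.0
        A[:3, 3] = -np.array(self.voxel_size) * half
        return A


@dataclass
class GroundTruth:
    """Everything injected into a phantom, for recovery tests."""

    beta_map: np.ndarray                      # true effect, signal units
    motion_params: np.ndarray                 # (n_volumes, 6): tx ty tz mm, rx ry rz deg
    spike_events: list[tuple[int, int, float]]
    coil_pose: RigidTransform
    pulse_train: PulseTrain

    def __post_init__(self) -> None:
        R = self.coil_pose.rotation
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("coil_pose rotation must be proper orthonormal")

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "motion_params": self.motion_params.tolist(),
            "spike_events": [[int(v), int(z), float(a)] for v, z, a in self.spike_events],
            "coil_pose": self.coil_pose.as_matrix().tolist(),
            "pulses": {"onset_s": self.pulse_train.onsets.tolist(),
                       "level": list(self.pulse_train.levels)},
            "beta_nonzero_voxels": int(np.count_nonzero(self.beta_map)),
            "beta_max": float(np.max(self.beta_map)),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def generate_pulse_train(
    n_dynamics: int,
    tr: float,
    interval_range: tuple[int, int] = (5, 8),
    seed: int = 0,
    alternate: bool = True,
) -> PulseTrain:
    """Random-interval pulse schedule with interleaved intensities.

    Inter-pulse gaps are whole numbers of dynamics drawn uniformly from
    ``interval_range`` inclusive (default 5-8 dynamics = 10-16 s at
    TR 2 s); the first pulse sits one such gap after acquisition start.
    Intensity levels strictly alternate high, low, high, … by default;
    ``alternate=False`` randomises the level of each pulse instead (the
    alternative reading of an interleaved schedule).
    """
    if n_dynamics <= 0 or tr <= 0:
        raise ValueError("n_dynamics and tr must be positive")
    lo, hi = int(interval_range[0]), int(interval_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("interval_range must satisfy 1 <= low <= high")
    if n_dynamics < hi:
        raise ValueError("n_dynamics must be >= the largest interval")
    rng = np.random.default_rng(seed)
    onsets_dyn: list[int] = []
    t = 0
    while True:
        t += int(rng.integers(lo, hi + 1))
        if t >= n_dynamics:
            break
        onsets_dyn.append(t)
    onsets = np.asarray(onsets_dyn, dtype=float) * tr
    n = onsets.size
    if alternate:
        levels = np.where(np.arange(n) % 2 == 0, HIGH, LOW).astype(object)
    else:
        levels = rng.choice([HIGH, LOW], size=n).astype(object)
    return PulseTrain(onsets, levels)


def _shell_masks(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    idx = np.indices(grid_shape, dtype=float)
    half = (np.array(grid_shape, dtype=float).reshape(3, 1, 1, 1) - 1.0) / 2.0
    rho = np.sqrt(np.sum(((idx - half) / half) ** 2, axis=0))
    masks = {}
    for name, (lo, hi) in SHELL_BANDS.items():
        masks[name] = (rho >= lo) & (rho < hi)
    masks["brain"] = masks["wm"] | masks["gm"] | masks["csf"]
    return masks


def _default_target(masks: dict[str, np.ndarray], spec: PhantomSpec) -> np.ndarray:
    """A compact grey-matter blob on the +x side at mid-height.

    The seed voxel is the GM voxel nearest the point halfway out along
    +x at the grid centre plane; the region is its 3x3x3 neighbourhood
    intersected with GM.
    """
    gm = masks["gm"]
    gx, gy, gz = spec.grid_shape
    target_world = np.array([0.5 * (gx - 1) / 2.0 * spec.voxel_size[0], 0.0, 0.0])
    A = spec.affine
    vox = np.argwhere(gm)
    world = vox @ A[:3, :3].T + A[:3, 3]
    seed_vox = vox[np.argmin(np.linalg.norm(world - target_world, axis=1))]
    region = np.zeros_like(gm)
    sl = tuple(slice(max(0, c - 1), min(n, c + 2)) for c, n in zip(seed_vox, gm.shape))
    region[sl] = True
    return region & gm


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeSeries, dict[str, np.ndarray], GroundTruth]:
    """Build a motion-free, spike-free phantom with known activation.

    Returns the series, the tissue masks (``gm``, ``wm``, ``csf``,
    ``brain``; disjoint nested shells) and the :class:`GroundTruth`.
    Identical spec (including seed) yields a bit-identical phantom.
    """
    rng = np.random.default_rng(spec.seed)
    masks = _shell_masks(spec.grid_shape)

    targets = spec.target_regions
    if targets is None:
        targets = {"target": _default_target(masks, spec)}
    for name, region in targets.items():
        region = np.asarray(region, dtype=bool)
        if region.shape != tuple(spec.grid_shape):
            raise ValueError(f"target region '{name}' grid mismatch")
        if np.any(region & ~masks["gm"]):
            raise ValueError(f"target region '{name}' extends outside the GM mask")

    baseline = np.zeros(spec.grid_shape)
    for tissue, level in TISSUE_BASELINE.items():
        baseline[masks[tissue]] = level

    # smooth multiplicative intensity texture (tissue inhomogeneity / coil
    # sensitivity); without it the shell anatomy would be rotationally
    # symmetric and motion unidentifiable
    if spec.texture_pct > 0:
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=2.0)
        field /= max(field.std(), 1e-12)
        baseline = baseline * (1.0 + spec.texture_pct / 100.0 * field)

    if spec.n_dynamics >= spec.interval_range[1]:
        pulses = generate_pulse_train(spec.n_dynamics, spec.tr,
                                      spec.interval_range, spec.seed)
    else:
        # run too short for even one inter-pulse interval: no events
        pulses = PulseTrain(np.array([]), np.array([], dtype=object))
    x_high, _ = event_regressors(pulses.onsets_for(HIGH), spec.n_dynamics, spec.tr,
                                 spec.hrf_params)

    beta_map = np.zeros(spec.grid_shape)
    for region in targets.values():
        beta_map[np.asarray(region, dtype=bool)] = True
    beta_map = beta_map * baseline * (spec.effect_pct / 100.0)

    brain = masks["brain"]
    n_vox = int(brain.sum())
    T = spec.n_dynamics
    data = np.zeros(spec.grid_shape + (T,), dtype=np.float32)

    # task signal + baseline
    series_flat = (baseline[brain, None]
                   + beta_map[brain, None] * x_high[None, :])

    # Legendre drift (orders 1 and 2) with per-voxel random coefficients
    if spec.drift_amplitude > 0:
        tt = np.linspace(-1.0, 1.0, T)
        basis = np.stack([tt, 0.5 * (3 * tt ** 2 - 1)])           # P1, P2
        coefs = rng.uniform(-1.0, 1.0, size=(n_vox, 2)) * spec.drift_amplitude
        series_flat = series_flat + coefs @ basis
    else:
        rng.uniform(-1.0, 1.0, size=(n_vox, 2))  # keep stream position stable

    # stationary AR(1) noise
    if spec.noise_sd > 0:
        a = spec.ar1_coef
        w = rng.standard_normal((n_vox, T))
        e = np.empty((n_vox, T))
        e[:, 0] = spec.noise_sd * w[:, 0]
        scale = spec.noise_sd * np.sqrt(1.0 - a * a)
        for t in range(1, T):
            e[:, t] = a * e[:, t - 1] + scale * w[:, t]
        series_flat = series_flat + e

    data[brain] = series_flat.astype(np.float32)
    series = VolumeSeries(data, spec.affine, spec.tr)
    truth = GroundTruth(
        beta_map=beta_map,
        motion_params=np.zeros((T, 6)),
        spike_events=[],
        coil_pose=RigidTransform.identity(),
        pulse_train=pulses,
    )
    return series, masks, truth


def inject_spikes(
    series: VolumeSeries,
    events: list[tuple[int, int, float]],
    mask: np.ndarray | None = None,
) -> VolumeSeries:
    """Add single-sample, single-slice deflections.

    For each ``(volume, slice, amplitude)`` event every in-mask voxel of
    that slice in that volume only is offset by the amplitude — the
    signature of the leak-current artifact the detector targets.  All
    other samples are bit-identical to the input.
    """
    out = series.copy()
    seen = set()
    nz, nt = series.n_slices, series.n_volumes
    if mask is None:
        mask = np.ones(series.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    for vol, sl, amp in events:
        if not (0 <= vol < nt and 0 <= sl < nz):
            raise ValueError(f"spike event ({vol}, {sl}) out of bounds")
        if (vol, sl) in seen:
            raise ValueError(f"duplicate spike event at volume {vol}, slice {sl}")
        seen.add((vol, sl))
        plane = mask[:, :, sl]
        out.data[:, :, sl, vol][plane] += amp
    return out


def generate_motion_params(
    n_dynamics: int,
    trans_sd_mm: float = 0.3,
    rot_sd_deg: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Smooth small head motion: a scaled Gaussian random walk per axis.

    Volume 0 is zero by convention; the walk is rescaled so the per-axis
    standard deviation over the run equals the requested magnitude
    (defaults ~0.3 mm / 0.15°, typical of a compliant subject).
    """
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_dynamics, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    walk = walk / sd * np.array([trans_sd_mm] * 3 + [rot_sd_deg] * 3)
    return walk


def apply_motion(series: VolumeSeries, motion_params: np.ndarray) -> VolumeSeries:
    """Resample each volume under its rigid head-motion transform.

    ``motion_params`` has one row (tx, ty, tz mm, rx, ry, rz deg) per
    volume, interpreted as the motion of the head: volume t's content is
    the reference anatomy moved by that transform (rotations about the
    grid centre, trilinear resampling).  Volume 0 is conventionally
    identity.
    """
    params = np.asarray(motion_params, dtype=float)
    if params.shape != (series.n_volumes, 6):
        raise ValueError("motion_params must be (n_volumes, 6)")
    out = series.copy()
    center = series.world_center
    for t in range(series.n_volumes):
        T = RigidTransform.from_params(params[t], center=center)
        if T.is_identity(tol=1e-12):
            continue
        # content moved by T: new(x) = old(T^-1 x)
        vol, _ = resample_volume(series.data[..., t], series.affine, T.inverse())
        out.data[..., t] = vol.astype(series.data.dtype)
    return out


def generate_coil_markers(
    coil_model: CoilModel,
    pose: RigidTransform,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pose-transformed template markers with iid Gaussian jitter.

    Emulates locating the coil's six water-capsule fiducials in a
    T2-weighted scan; ``noise_sd`` (mm, per coordinate) models the
    localisation error.  Returns a table with columns
    ``marker_id, x_mm, y_mm, z_mm``.
    """
    coil_model.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for label, point in coil_model.template_markers.items():
        obs = pose.apply(point)
        if noise_sd > 0:
            obs = obs + rng.normal(0.0, noise_sd, size=3)
        rows.append({"marker_id": label, "x_mm": obs[0], "y_mm": obs[1], "z_mm": obs[2]})
    return pd.DataFrame(rows)
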