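"""Event-related GLM for the intensity-contrast TMS-fMRI design.

The model follows the standard single-subject event-related analysis: each
pulse condition (high = 115% RMT, low = 60% RMT) is modelled as a train of
zero-duration impulses convolved with the canonical double-gamma
haemodynamic response function (HRF) and its first-order temporal
derivative; white-matter and CSF mean signals enter as nuisance
regressors; slow drifts are absorbed by a discrete-cosine (DCT) basis
implementing a high-pass filter; the fit is voxel-wise ordinary least
squares; and the high-vs-low contrast is tested with an F statistic over
both basis functions, thresholded with family-wise error control
(Bonferroni by default, a max-statistic permutation test as the exact
alternative).

Notes on conventions
--------------------
* The high-pass cut-off is a *period* in seconds (default 80 s, i.e. a
  1/80 Hz corner); DCT regressors with periods >= the cut-off are kept.
* OLS without prewhitening is the default estimator; an AR(1)
  Cochrane-Orcutt mode is available via ``fit_glm(..., ar1_prewhiten=True)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import HIGH, LOW, PulseTrain, VolumeSeries

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "GLMResult",
    "StatMap",
    "canonical_hrf",
    "hrf_basis",
    "event_regressors",
    "dct_drift_basis",
    "build_design",
    "fit_glm",
    "f_contrast",
    "default_contrast",
    "fwe_threshold",
    "permutation_max_f",
]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma canonical HRF parameters (seconds unless noted).

    Defaults are the de-facto canonical values: response peak at 6 s,
    undershoot at 16 s, unit dispersions, peak:undershoot ratio 6,
    kernel length 32 s, 16 microtime subdivisions per TR.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration: float = 32.0
    microtime_resolution: int = 16

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all HRF parameters must be positive")
        if self.duration < self.undershoot_delay:
            raise ValueError("duration must cover the undershoot delay")


def canonical_hrf(params: HRFParams = HRFParams(), tr: float = 2.0) -> tuple[np.ndarray, float]:
    """Sample the canonical double-gamma HRF at microtime resolution.

    Returns ``(kernel, dt)`` where ``dt = tr / microtime_resolution`` and
    the kernel is peak-normalised to 1, so a convolved isolated event has
    unit peak amplitude.
    """
    dt = tr / params.microtime_resolution
    t = np.arange(0.0, params.duration, dt)
    peak = stats.gamma.pdf(t, a=params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, a=params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - under / params.peak_undershoot_ratio
    return h / h.max(), dt


def hrf_basis(params: HRFParams = HRFParams(), tr: float = 2.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Canonical kernel and its first-order temporal derivative.

    The derivative is the time derivative of the peak-normalised kernel
    (units 1/s), the usual first-order Taylor term for onset-latency
    flexibility.
    """
    h, dt = canonical_hrf(params, tr)
    dh = np.gradient(h, dt)
    return h, dh, dt


def event_regressors(
    onsets_s: np.ndarray,
    n_dynamics: int,
    tr: float,
    params: HRFParams = HRFParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Impulse train convolved with the HRF basis, sampled at frame times.

    Events are placed as unit impulses on the microtime grid (nearest
    bin), convolved with the canonical kernel and its derivative, and
    downsampled at each dynamic's acquisition onset ``n * tr``.
    Returns ``(canonical_column, derivative_column)`` of length
    ``n_dynamics``.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    total = n_dynamics * tr
    if onsets.size and (onsets.min() < 0 or onsets.max() >= total):
        raise ValueError("pulse onsets must lie within the acquisition")
    h, dh, dt = hrf_basis(params, tr)
    n_fine = n_dynamics * params.microtime_resolution
    impulses = np.zeros(n_fine)
    idx = np.clip(np.round(onsets / dt).astype(int), 0, n_fine - 1)
    np.add.at(impulses, idx, 1.0)
    canon = np.convolve(impulses, h)[:n_fine]
    deriv = np.convolve(impulses, dh)[:n_fine]
    pick = np.arange(n_dynamics) * params.microtime_resolution
    return canon[pick], deriv[pick]


def dct_drift_basis(n_frames: int, tr: float, cutoff_s: float | None) -> np.ndarray:
    """Orthonormal discrete-cosine drift regressors with period >= cutoff.

    Column k (k = 1..K) is ``sqrt(2/n) cos(pi (2t+1) k / (2n))`` with
    period ``2 n tr / k``; K = floor(2 n tr / cutoff).  ``cutoff_s=None``
    disables drift modelling (returns zero columns).
    """
    if cutoff_s is None:
        return np.zeros((n_frames, 0))
    if cutoff_s <= 0:
        raise ValueError("high-pass cutoff period must be positive")
    K = int(np.floor(2.0 * n_frames * tr / cutoff_s))
    K = min(K, n_frames - 1)
    t = np.arange(n_frames)
    cols = [np.sqrt(2.0 / n_frames) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_frames))
            for k in range(1, K + 1)]
    return np.column_stack(cols) if cols else np.zeros((n_frames, 0))


@dataclass
class DesignMatrix:
    """Labelled regression design: one row per dynamic."""

    frame: pd.DataFrame
    frame_times: np.ndarray
    hrf_params: HRFParams = field(default_factory=HRFParams)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


#: canonical task-column labels
TASK_COLUMNS = ("high_canon", "high_deriv", "low_canon", "low_deriv")


def build_design(
    pulses: PulseTrain,
    n_dynamics: int,
    tr: float,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
    highpass_cutoff: float | None = 80.0,
    hrf_params: HRFParams = HRFParams(),
) -> DesignMatrix:
    """Assemble the event-related design matrix.

    Columns, in order: ``high_canon, high_deriv, low_canon, low_deriv``
    (HRF-convolved impulse trains per intensity level), mean-centred
    ``wm_nuisance`` / ``csf_nuisance`` when supplied, the DCT drift basis
    (``drift_1..K``, periods >= ``highpass_cutoff`` seconds), and a
    trailing ``intercept``.
    """
    cols: dict[str, np.ndarray] = {}
    for level, canon_name, deriv_name in ((HIGH, "high_canon", "high_deriv"),
                                          (LOW, "low_canon", "low_deriv")):
        onsets = pulses.onsets_for(level) if len(pulses) else np.array([])
        canon, deriv = event_regressors(onsets, n_dynamics, tr, hrf_params)
        if onsets.size:
            cols[canon_name] = canon
            cols[deriv_name] = deriv
    for name, sig in (("wm_nuisance", wm_signal), ("csf_nuisance", csf_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float).reshape(-1)
            if sig.size != n_dynamics:
                raise ValueError(f"{name} length {sig.size} != n_dynamics {n_dynamics}")
            cols[name] = sig - sig.mean()
    drift = dct_drift_basis(n_dynamics, tr, highpass_cutoff)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    cols["intercept"] = np.ones(n_dynamics)

    frame = pd.DataFrame(cols)
    X = frame.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose residual after projecting
        # on the others is (numerically) zero
        bad = []
        for j, name in enumerate(frame.columns):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(name)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame, np.arange(n_dynamics) * tr, hrf_params)


@dataclass
class GLMResult:
    """Voxel-wise OLS fit: coefficients, residual variance, df."""

    betas: np.ndarray           # (n_regressors, n_voxels)
    sigma2: np.ndarray          # (n_voxels,)
    df: int
    mask: np.ndarray            # boolean 3-D
    design: DesignMatrix
    xtx_inv: np.ndarray         # (n_regressors, n_regressors)

    def beta_map(self, label: str) -> np.ndarray:
        j = self.design.columns.index(label)
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.betas[j]
        return out

    def sigma2_map(self) -> np.ndarray:
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.sigma2
        return out


def fit_glm(
    series: VolumeSeries,
    design: DesignMatrix,
    mask: np.ndarray,
    ar1_prewhiten: bool = False,
) -> GLMResult:
    """Per-voxel ordinary least squares fit of the design.

    With ``ar1_prewhiten=True`` a single Cochrane-Orcutt pass is applied:
    a global AR(1) coefficient is estimated from the pooled OLS residuals
    and both sides of the model are quasi-differenced before refitting.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask grid does not match series grid")
    X = design.matrix
    if X.shape[0] != series.n_volumes:
        raise ValueError("design rows != number of volumes")
    df = X.shape[0] - np.linalg.matrix_rank(X)
    if df <= 0:
        raise ValueError("non-positive error degrees of freedom")
    Y = series.data[mask].T.astype(float)  # (T, nvox)

    def _ols(Xm, Ym):
        xtx_inv = np.linalg.inv(Xm.T @ Xm)
        betas = xtx_inv @ Xm.T @ Ym
        resid = Ym - Xm @ betas
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        return betas, sigma2, resid, xtx_inv

    betas, sigma2, resid, xtx_inv = _ols(X, Y)
    if ar1_prewhiten:
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid[:-1] ** 2)
        rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
        Xw = X[1:] - rho * X[:-1]
        Yw = Y[1:] - rho * Y[:-1]
        df = Xw.shape[0] - np.linalg.matrix_rank(Xw)
        betas, sigma2, _, xtx_inv = _ols(Xw, Yw)
    return GLMResult(betas, sigma2, int(df), mask, design, xtx_inv)


@dataclass
class StatMap:
    """Voxel-wise F map with inference metadata."""

    f: np.ndarray               # 3-D, NaN outside mask
    p: np.ndarray               # 3-D uncorrected p, NaN outside mask
    q: int                      # numerator df (contrast rows)
    df_denom: int
    mask: np.ndarray
    method: str | None = None   # FWE method once thresholded
    alpha: float | None = None
    n_tests: int | None = None
    f_threshold: float | None = None
    suprathreshold: np.ndarray | None = None

    @property
    def n_in_mask(self) -> int:
        return int(self.mask.sum())

    def neglog10p(self) -> np.ndarray:
        out = np.full(self.p.shape, np.nan)
        m = self.mask
        out[m] = -np.log10(np.clip(self.p[m], 1e-300, 1.0))
        return out


def default_contrast(design: DesignMatrix) -> np.ndarray:
    """High-vs-low rows over both basis functions: {high−low canonical,
    high−low derivative}."""
    cols = design.columns
    rows = []
    for a, b in (("high_canon", "low_canon"), ("high_deriv", "low_deriv")):
        row = np.zeros(len(cols))
        row[cols.index(a)] = 1.0
        row[cols.index(b)] = -1.0
        rows.append(row)
    return np.vstack(rows)


def f_contrast(result: GLMResult, contrast_rows: np.ndarray | None = None) -> StatMap:
    """F statistic of a multi-row contrast, per in-mask voxel.

    ``F = (c b)' [c (X'X)^-1 c']^-1 (c b) / (q s²)`` with p-values from
    the F(q, df) distribution.
    """
    C = default_contrast(result.design) if contrast_rows is None else np.atleast_2d(
        np.asarray(contrast_rows, dtype=float))
    if C.shape[1] != len(result.design.columns):
        raise ValueError("contrast width does not match design")
    q = C.shape[0]
    M = C @ result.xtx_inv @ C.T
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular contrast covariance (rows not estimable)") from e
    B = C @ result.betas                       # (q, nvox)
    quad = np.einsum("qv,qr,rv->v", B, Minv, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        fvals = quad / (q * result.sigma2)
    fvals = np.where(result.sigma2 > 0, fvals, 0.0)
    fvals = np.maximum(fvals, 0.0)
    pvals = stats.f.sf(fvals, q, result.df)
    f3 = np.full(result.mask.shape, np.nan)
    p3 = np.full(result.mask.shape, np.nan)
    f3[result.mask] = fvals
    p3[result.mask] = pvals
    return StatMap(f3, p3, q, result.df, result.mask)


def permutation_max_f(
    series: VolumeSeries,
    pulses: PulseTrain,
    mask: np.ndarray,
    n_dynamics: int,
    tr: float,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
    highpass_cutoff: float | None = 80.0,
    hrf_params: HRFParams = HRFParams(),
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Max-F null distribution under pulse-intensity relabelling.

    Each permutation shuffles the high/low labels across pulses (keeping
    the level counts), rebuilds the design, refits, and records the
    maximum in-mask F of the default high-vs-low contrast.
    """
    levels = np.asarray(pulses.levels)
    n_high = int(np.sum(levels == HIGH))
    n_low = int(np.sum(levels == LOW))
    if min(n_high, n_low) < 20:
        raise ValueError("permutation FWE needs >= 20 pulses per level")
    rng = np.random.default_rng(seed)
    max_f = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(levels)
        design = build_design(pulses.relabeled(perm), n_dynamics, tr,
                              wm_signal, csf_signal, highpass_cutoff, hrf_params)
        res = fit_glm(series, design, mask)
        stat = f_contrast(res)
        max_f[i] = np.nanmax(stat.f[mask])
    return max_f


def fwe_threshold(
    stat: StatMap,
    alpha: float = 0.05,
    method: str = "bonferroni",
    perm_null: np.ndarray | None = None,
) -> StatMap:
    """Family-wise-error threshold the F map.

    ``bonferroni``: a voxel survives iff its uncorrected p is below
    ``alpha / n_in_mask``.  ``permutation``: a voxel survives iff its F
    exceeds the ``1 - alpha`` quantile of the supplied max-F null (from
    :func:`permutation_max_f`).
    """
    if stat.n_in_mask == 0:
        raise ValueError("empty analysis mask")
    out = dataclasses.replace(stat)
    out.alpha = alpha
    out.n_tests = stat.n_in_mask
    if method == "bonferroni":
        p_thr = alpha / stat.n_in_mask
        out.method = "bonferroni"
        out.f_threshold = float(stats.f.isf(p_thr, stat.q, stat.df_denom))
        supra = np.zeros(stat.mask.shape, dtype=bool)
        supra[stat.mask] = stat.p[stat.mask] < p_thr
    elif method == "permutation":
        if perm_null is None:
            raise ValueError("permutation method requires perm_null from permutation_max_f")
        out.method = "permutation"
        out.f_threshold = float(np.quantile(perm_null, 1.0 - alpha))
        supra = np.zeros(stat.mask.shape, dtype=bool)
        supra[stat.mask] = stat.f[stat.mask] > out.f_threshold
    else:
        raise ValueError(f"unknown FWE method: {method}")
    out.suprathreshold = supra
    return out
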