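"""Interpretability maps: discriminating volumes and GLM contrast T-maps.

A trained linear SVM's weight vector is re-projected onto the brain grid
(the *discriminating volume*): positive voxels push the decision toward
the positive class.  Per fold the volume is standardized to unit
in-mask variance (divide by SD, no mean subtraction, so zeros stay
zero), fold volumes are averaged into a subject map, subject maps are
smoothed with an 8-mm-FWHM Gaussian and averaged into the group map.

The mass-univariate GLM models each task's acknowledged blocks as a
32-s boxcar convolved with the canonical HRF, with motion parameters,
session constants and a sub-0.0078-Hz DCT basis as confounds, optionally
prewhitened with a pooled-coefficient AR(1) model.  Contrast T-maps and
the group one-sample t complete the comparison surface; similarity
between a group T-map and a mean discriminating volume is the in-mask
voxelwise Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .datatypes import REST, BoldRun
from .hrf import block_regressor
from .preprocess import dct_basis

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class DiscriminatingVolume:
    volume: np.ndarray
    level: str  # "fold" | "subject" | "group"
    smoothing_fwhm_mm: float = 0.0


@dataclass
class GLMResult:
    betas: np.ndarray  # (n_regressors, X, Y, Z)
    regressor_names: list[str]
    residual_variance: np.ndarray  # (X, Y, Z)
    dof: int
    xtx_inv: np.ndarray
    mask: np.ndarray
    ar1_rho: float | None = None

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.regressor_names))
        for name, w in weights.items():
            c[self.regressor_names.index(name)] = w
        return c


def weights_to_volume(
    weights: np.ndarray, feature_index: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Place each weight at its voxel coordinate; off-mask voxels are 0."""
    weights = np.asarray(weights).ravel()
    coords = np.asarray(feature_index)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) != len(weights):
        raise ValueError(
            f"feature_index {coords.shape} does not match {len(weights)} weights"
        )
    vol = np.zeros(shape)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = weights
    return vol


def standardize_volume(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide by the in-mask SD (unit variance; zero structure preserved)."""
    sd = volume[mask].std()
    if sd == 0:
        raise ValueError("zero-variance volume cannot be standardized")
    return volume / sd


def smooth_volume(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm=(3.0, 3.0, 4.0)
) -> np.ndarray:
    """Gaussian smoothing with per-axis sigma in voxel units.

    Anisotropic voxels are handled per axis; the kernel is truncated at
    4 sigma and the volume is zero-padded outside the grid.
    """
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    return gaussian_filter(volume, sigma=sigma_vox, mode="constant", truncate=4.0)


def mean_disc_volume(
    per_subject_fold_volumes: list[list[np.ndarray]],
    mask: np.ndarray,
    fwhm_mm: float = 8.0,
    voxel_size_mm=(3.0, 3.0, 4.0),
) -> DiscriminatingVolume:
    """Fold volumes -> unit-variance -> subject mean -> smooth -> group mean."""
    subject_maps = []
    for fold_volumes in per_subject_fold_volumes:
        std = [standardize_volume(v, mask) for v in fold_volumes]
        subj = np.mean(std, axis=0)
        subject_maps.append(smooth_volume(subj, fwhm_mm, voxel_size_mm))
    group = np.mean(subject_maps, axis=0)
    return DiscriminatingVolume(volume=group, level="group", smoothing_fwhm_mm=fwhm_mm)


# ---------------------------------------------------------------------------
# mass-univariate GLM


def _glm_design(
    runs: list[BoldRun],
    events: pd.DataFrame,
    motion: list[np.ndarray],
    cutoff_hz: float,
) -> tuple[np.ndarray, list[str]]:
    """Task regressors (acknowledged blocks only), motion, constants, DCT."""
    lengths = [r.n_scans for r in runs]
    t_total = sum(lengths)
    tasks = sorted(t for t in events["task"].unique() if t != REST)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for task in tasks:
        col = np.zeros(t_total)
        offset = 0
        for r in runs:
            sel = events[
                (events["session_id"] == r.session_id)
                & (events["task"] == task)
                & events["response_time_ms"].notna()
            ]
            if len(sel):
                col[offset : offset + r.n_scans] = block_regressor(
                    sel["onset_scan"].to_numpy(), sel["n_scans"].to_numpy(), r.n_scans, r.tr
                )
            offset += r.n_scans
        cols.append(col)
        names.append(task)
    mot = np.concatenate(motion, axis=0)
    for j in range(6):
        cols.append(mot[:, j])
        names.append(f"motion{j + 1}")
    offset = 0
    for r in runs:
        ind = np.zeros(t_total)
        ind[offset : offset + r.n_scans] = 1.0
        cols.append(ind)
        names.append(f"session_{r.session_id}")
        offset += r.n_scans
    offset = 0
    for r in runs:
        K = dct_basis(r.n_scans, r.tr, cutoff_hz)[:, 1:]  # constants already present
        for j in range(K.shape[1]):
            col = np.zeros(t_total)
            col[offset : offset + r.n_scans] = K[:, j]
            cols.append(col)
            names.append(f"dct_{r.session_id}_{j + 1}")
        offset += r.n_scans
    return np.column_stack(cols), names


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    xtx_inv = np.linalg.pinv(X.T @ X)
    return beta, resid, xtx_inv, dof


def glm_fit(
    runs: list[BoldRun],
    events: pd.DataFrame,
    motion: list[np.ndarray],
    mask: np.ndarray,
    cutoff_hz: float = 0.0078,
    ar1: bool = False,
) -> GLMResult:
    """Fit the voxelwise GLM over all sessions of one subject.

    With ``ar1`` a single pooled lag-1 autocorrelation coefficient is
    estimated from the OLS residuals (in-mask average), both data and
    design are prewhitened per session, and the model is refit.
    """
    X, names = _glm_design(runs, events, motion, cutoff_hz)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design")
    mask = np.asarray(mask, dtype=bool)
    Y = np.concatenate([r.data[mask] for r in runs], axis=1).T  # t_total x n_vox
    beta, resid, xtx_inv, dof = _ols(X, Y)
    rho = None
    if ar1:
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid[:-1] ** 2)
        rho = float(num / den) if den > 0 else 0.0
        lengths = [r.n_scans for r in runs]
        Xw = _prewhiten(X, rho, lengths)
        Yw = _prewhiten(Y, rho, lengths)
        beta, resid, xtx_inv, dof = _ols(Xw, Yw)
    rss = np.sum(resid**2, axis=0)
    sigma2 = np.where(dof > 0, rss / max(dof, 1), np.nan)
    shape = runs[0].shape3d
    betas = np.zeros((len(names),) + shape)
    betas[:, mask] = beta
    resvar = np.zeros(shape)
    resvar[mask] = sigma2
    return GLMResult(
        betas=betas,
        regressor_names=names,
        residual_variance=resvar,
        dof=dof,
        xtx_inv=xtx_inv,
        mask=mask,
        ar1_rho=rho,
    )


def _prewhiten(A: np.ndarray, rho: float, session_lengths: list[int]) -> np.ndarray:
    """First-order autoregressive whitening applied per session."""
    out = np.empty_like(A, dtype=float)
    offset = 0
    for T in session_lengths:
        block = A[offset : offset + T]
        out[offset] = block[0] * np.sqrt(1.0 - rho**2)
        out[offset + 1 : offset + T] = block[1:] - rho * block[:-1]
        offset += T
    return out


def contrast_tmap(glm: GLMResult, contrast: np.ndarray) -> np.ndarray:
    """T = c'beta / sqrt(sigma^2 * c'(X'X)^-1 c) per voxel (0 off-mask)."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(glm.regressor_names),):
        raise ValueError(
            f"contrast length {c.shape} does not match {len(glm.regressor_names)} regressors"
        )
    if not np.any(c):
        raise ValueError("contrast vector is all zero")
    effect = np.tensordot(c, glm.betas, axes=1)
    var_scale = float(c @ glm.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(glm.residual_variance * var_scale)
    t[~glm.mask] = 0.0
    t[~np.isfinite(t)] = 0.0
    return t


def group_tmap(subject_maps: list[np.ndarray], mask: np.ndarray | None = None) -> np.ndarray:
    """One-sample t across subjects per voxel (dof = n_subjects - 1).

    Voxels with zero between-subject variance and nonzero mean get
    +-inf; zero mean and zero variance give 0.
    """
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subjects for a group map")
    stack = np.stack(subject_maps, axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    if mask is not None:
        t = np.where(np.asarray(mask, dtype=bool), t, 0.0)
    return t


def map_correlation(
    tmap: np.ndarray, disc_volume: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """In-mask voxelwise Pearson r between two maps, with two-sided p."""
    mask = np.asarray(mask, dtype=bool)
    a = tmap[mask]
    b = disc_volume[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def peak_table(tmap: np.ndarray, affine: np.ndarray, threshold: float) -> pd.DataFrame:
    """Descriptive cluster/peak table at a T threshold (26-connectivity)."""
    from scipy.ndimage import label as cc_label

    rows = []
    for sign in (1.0, -1.0):
        above = sign * tmap > threshold
        labeled, n = cc_label(above, structure=np.ones((3, 3, 3)))
        for k in range(1, n + 1):
            sel = labeled == k
            vals = np.where(sel, sign * tmap, -np.inf)
            peak = np.unravel_index(np.argmax(vals), tmap.shape)
            mm = affine[:3, :3] @ np.array(peak) + affine[:3, 3]
            rows.append(
                dict(
                    x_mm=mm[0],
                    y_mm=mm[1],
                    z_mm=mm[2],
                    t=float(tmap[peak]),
                    cluster_voxels=int(sel.sum()),
                )
            )
    return pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "t", "cluster_voxels"]).sort_values(
        "t", ascending=False, key=abs
    ).reset_index(drop=True)
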