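"""Machine-learning-branch preprocessing of BOLD runs.

The stages run in a fixed order on all sessions of one subject:

1. ``regress_nuisance`` -- per voxel, OLS residual against the six head
   motion parameters, white-matter and CSF sphere means, the global
   (grey-mask) mean, and one constant per session.
2. ``highpass`` -- per session, residualization against a discrete-cosine
   basis spanning frequencies below 0.008 Hz (constant included).
3. ``grand_mean_scale`` -- per session, multiply by ``100 / raw_mean``
   where ``raw_mean`` is the in-mask mean of the *raw* session (computed
   before regression; session constants zero the residual means, so the
   raw mean is the only well-defined scale reference).
4. ``standardize_experiment`` -- per voxel, z-score against the mean and
   population SD of the series concatenated over all sessions.

``preprocess_subject`` applies the four stages and returns an audit log
of the order actually executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import BoldRun, NuisanceSet


@dataclass
class PreprocessConfig:
    cutoff_hz: float = 0.008
    target_grand_mean: float = 100.0
    sphere_radius_mm: float = 3.0
    grey_threshold: float = 0.22  # threshold for probabilistic grey-matter images
    include_global: bool = True


@dataclass
class PreprocessReport:
    """Audit trail: stage order and per-stage diagnostics."""

    stages: list[str] = field(default_factory=list)
    raw_session_means: list[float] = field(default_factory=list)
    zero_variance_voxels: np.ndarray | None = None


def sphere_mean(run: BoldRun, center_mm, radius_mm: float) -> np.ndarray:
    """Mean time series over voxels whose centers lie within a world-mm sphere.

    Membership uses Euclidean distance between voxel centers and
    ``center_mm``; ties at exactly ``radius_mm`` are included.
    """
    shape = run.shape3d
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    centers = idx @ run.affine[:3, :3].T + run.affine[:3, 3]
    dist = np.linalg.norm(centers - np.asarray(center_mm, dtype=float), axis=-1)
    sel = dist <= radius_mm
    if not sel.any():
        raise ValueError(f"no voxel centers within {radius_mm} mm of {tuple(center_mm)}")
    return run.data[sel].mean(axis=0)


def _nuisance_design(
    runs: list[BoldRun],
    nuisances: list[NuisanceSet],
    config: PreprocessConfig,
) -> tuple[np.ndarray, list[str]]:
    """Concatenated nuisance design: motion, WM, CSF, global, session constants."""
    n_sessions = len(runs)
    lengths = [r.n_scans for r in runs]
    t_total = sum(lengths)
    cols: list[np.ndarray] = []
    names: list[str] = []
    motion = np.concatenate([n.motion for n in nuisances], axis=0)
    if motion.shape[0] != t_total:
        raise ValueError("motion parameters do not cover all scans")
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion{j + 1}")
    wm = np.concatenate(
        [sphere_mean(r, n.wm_center, config.sphere_radius_mm) for r, n in zip(runs, nuisances)]
    )
    csf = np.concatenate(
        [sphere_mean(r, n.csf_center, config.sphere_radius_mm) for r, n in zip(runs, nuisances)]
    )
    cols += [wm, csf]
    names += ["wm", "csf"]
    if config.include_global:
        glob = np.concatenate(
            [
                r.data[np.asarray(n.grey_mask, dtype=bool)].mean(axis=0)
                for r, n in zip(runs, nuisances)
            ]
        )
        cols.append(glob)
        names.append("global")
    offset = 0
    for s, T in enumerate(lengths):
        ind = np.zeros(t_total)
        ind[offset : offset + T] = 1.0
        cols.append(ind)
        names.append(f"session_{runs[s].session_id}")
        offset += T
    X = np.column_stack(cols)
    return X, names


def regress_nuisance(
    runs: list[BoldRun],
    nuisances: list[NuisanceSet],
    config: PreprocessConfig | None = None,
    mask: np.ndarray | None = None,
) -> list[BoldRun]:
    """OLS-residualize every voxel against the nuisance design.

    All sessions are fit jointly so the session-indicator constants
    absorb per-session means.  Residuals are orthogonal to every design
    column.  Raises if the design is rank-deficient, naming the
    collinear columns.
    """
    config = config or PreprocessConfig()
    X, names = _nuisance_design(runs, nuisances, config)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose QR pivot is (numerically) zero
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad or names}")
    shape = runs[0].shape3d
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    Y = np.concatenate([r.data[mask] for r in runs], axis=1).T  # t_total x n_vox
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = []
    offset = 0
    for r in runs:
        data = np.zeros_like(r.data)
        data[mask] = resid[offset : offset + r.n_scans].T
        out.append(r.copy_with(data))
        offset += r.n_scans
    return out


def dct_basis(n_scans: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Constant plus DCT-II columns with frequency below ``cutoff_hz``.

    Column ``j`` is ``cos(pi * j * (2t + 1) / (2T))`` with frequency
    ``j / (2 * T * tr)`` Hz.
    """
    t = np.arange(n_scans)
    n_basis = int(np.floor(2.0 * n_scans * tr * cutoff_hz))
    cols = [np.ones(n_scans)]
    for j in range(1, n_basis + 1):
        cols.append(np.cos(np.pi * j * (2 * t + 1) / (2.0 * n_scans)))
    return np.column_stack(cols)


def highpass(run: BoldRun, cutoff_hz: float = 0.008) -> BoldRun:
    """Remove slow components: residualize on the sub-cutoff DCT basis."""
    if run.n_scans < 2:
        raise ValueError("need at least 2 scans")
    nyquist = 1.0 / (2.0 * run.tr)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    K = dct_basis(run.n_scans, run.tr, cutoff_hz)
    Y = run.data.reshape(-1, run.n_scans).T
    beta, *_ = np.linalg.lstsq(K, Y, rcond=None)
    resid = (Y - K @ beta).T.reshape(run.data.shape)
    return run.copy_with(resid)


def grand_mean_scale(
    run: BoldRun, raw_session_mean: float, target: float = 100.0
) -> BoldRun:
    """Multiply the session by ``target / raw_session_mean``."""
    if raw_session_mean <= 0:
        raise ValueError(f"raw session mean must be positive, got {raw_session_mean}")
    return run.copy_with(run.data * (target / raw_session_mean))


def standardize_experiment(
    runs: list[BoldRun], mask: np.ndarray | None = None
) -> tuple[list[BoldRun], np.ndarray]:
    """Per-voxel z-scoring over the concatenated experiment.

    Uses the population SD so the concatenated series has exactly mean 0
    and SD 1.  Voxels with zero variance are set to all-zero and returned
    as a flag volume.
    """
    shape = runs[0].shape3d
    concat = np.concatenate([r.data.reshape(-1, r.n_scans) for r in runs], axis=1)
    mean = concat.mean(axis=1)
    sd = concat.std(axis=1)  # population SD
    zero_var = (sd == 0).reshape(shape)
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = []
    for r in runs:
        flat = (r.data.reshape(-1, r.n_scans) - mean[:, None]) / safe_sd[:, None]
        flat[sd == 0] = 0.0
        out.append(r.copy_with(flat.reshape(r.data.shape)))
    return out, zero_var


def preprocess_subject(
    runs: list[BoldRun],
    nuisances: list[NuisanceSet],
    mask: np.ndarray,
    config: PreprocessConfig | None = None,
) -> tuple[list[BoldRun], PreprocessReport]:
    """Run the four stages in the fixed order and log what was done."""
    config = config or PreprocessConfig()
    report = PreprocessReport()
    raw_means = [float(r.data[np.asarray(mask, dtype=bool)].mean()) for r in runs]
    report.raw_session_means = raw_means

    runs = regress_nuisance(runs, nuisances, config, mask=mask)
    report.stages.append("regress_nuisance")
    runs = [highpass(r, config.cutoff_hz) for r in runs]
    report.stages.append("highpass")
    runs = [
        grand_mean_scale(r, m, config.target_grand_mean) for r, m in zip(runs, raw_means)
    ]
    report.stages.append("grand_mean_scale")
    runs, zero_var = standardize_experiment(runs, mask)
    report.stages.append("standardize_experiment")
    report.zero_variance_voxels = zero_var
    return runs, report
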