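"""Shared in-memory containers for BOLD runs and nuisance data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every event table carries (one row per block, rest included).
EVENT_COLUMNS = [
    "session_id",
    "block_index",
    "task",
    "onset_scan",
    "n_scans",
    "response_time_ms",
]

TASKS = ("Countdown", "NAM", "PAM")
REST = "Rest"


@dataclass
class BoldRun:
    """One session's 4D BOLD time series on a fixed grid.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Signal in arbitrary scanner units (or residual/standardized units
        after preprocessing).
    tr : float
        Repetition time in seconds.
    session_id : str
        Unique session identifier within a subject, ordered by acquisition.
    session_type : {"A", "B"}
        Which task pairing the session used.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm map; must be invertible.
    """

    data: np.ndarray
    tr: float
    session_id: str
    session_type: str
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy_with(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(
            data=data,
            tr=self.tr,
            session_id=self.session_id,
            session_type=self.session_type,
            affine=self.affine.copy(),
        )


@dataclass
class NuisanceSet:
    """Per-session nuisance information for the regression stage.

    ``motion`` holds the six rigid-body parameters per scan (3 translations
    in mm, 3 rotations in rad).  White-matter and CSF signals are summarized
    as the mean over a small sphere (world-mm coordinates); the global
    signal is the mean over ``grey_mask``.
    """

    motion: np.ndarray
    wm_center: tuple[float, float, float]
    csf_center: tuple[float, float, float]
    sphere_radius: float = 3.0
    grey_mask: np.ndarray | None = None
    include_global: bool = True

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError(
                f"motion must have exactly 6 columns, got shape {self.motion.shape}"
            )


@dataclass
class SubjectData:
    """Everything the generator produces for one subject."""

    subject_id: str
    runs: list[BoldRun]
    events: pd.DataFrame
    nuisance: list[NuisanceSet]
    truth: "object" = None
    extras: dict = field(default_factory=dict)

    @property
    def n_sessions(self) -> int:
        return len(self.runs)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check block-table invariants: required columns, non-overlap, order."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    for sid, grp in events.groupby("session_id", sort=False):
        grp = grp.sort_values("onset_scan")
        ends = grp["onset_scan"].to_numpy() + grp["n_scans"].to_numpy()
        if np.any(grp["onset_scan"].to_numpy()[1:] < ends[:-1]):
            raise ValueError(f"overlapping blocks in session {sid}")
    return events
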