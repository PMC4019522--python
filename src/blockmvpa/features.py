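"""From preprocessed runs to balanced, labeled scan datasets.

Task blocks are first screened on the behavioral acknowledgment rule
(response to the start cue within 2000 ms, strict ``<``).  Datasets are
then strictly balanced at the block level: a block enters the dataset
only if both it and its counterpart block -- the same ordinal block of
the other task in the same session (within-session pairs) or in the
paired adjacent session (NAM vs PAM) -- were acknowledged.  Scans are
extracted with the block onsets shifted by 2 TRs (4 s) to account for
hemodynamic delay, then encoded either voxel-wise (one feature per
in-mask voxel with data) or region-wise (mean over each of the 116
atlas parcels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import REST, BoldRun
from .grids import N_REGIONS

#: Block key: (session_id, block_index)
BlockKey = tuple[str, int]

TASK_PAIRS = {
    "cd-nam": ("Countdown", "NAM"),
    "cd-pam": ("Countdown", "PAM"),
    "nam-pam": ("NAM", "PAM"),
}


@dataclass
class FeatureDataset:
    """Scans-by-features matrix with per-scan annotations."""

    matrix: np.ndarray
    labels: np.ndarray  # task label per scan
    block_id: np.ndarray  # "<subject>:<session>:<block_index>" per scan
    session_id: np.ndarray
    subject_id: np.ndarray
    encoding: str  # "voxel" | "region"
    feature_index: np.ndarray  # (D, 3) voxel coords or (D,) region labels
    group_id: np.ndarray | None = None  # balancing/permutation unit per scan
    empty_regions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def check_balance(self) -> None:
        """Assert equal class counts within every grouping unit."""
        groups = self.group_id if self.group_id is not None else self.session_id
        df = pd.DataFrame({"g": groups, "y": self.labels})
        counts = df.groupby(["g", "y"]).size().unstack(fill_value=0)
        if counts.shape[1] != 2 or not (counts.iloc[:, 0] == counts.iloc[:, 1]).all():
            raise ValueError(f"dataset is not strictly balanced:\n{counts}")


@dataclass
class FoldPlan:
    """Cross-validation folds over scan indices."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    scheme: str
    fold_units: list[object] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.folds)


def screen_blocks(events: pd.DataFrame, rt_limit_ms: float = 2000.0) -> set[BlockKey]:
    """Task blocks whose start cue was acknowledged within the limit (strict <)."""
    task = events[events["task"] != REST]
    ok = task["response_time_ms"].notna() & (task["response_time_ms"] < rt_limit_ms)
    return set(zip(task.loc[ok, "session_id"], task.loc[ok, "block_index"]))


def _ordinal_blocks(events: pd.DataFrame) -> pd.DataFrame:
    """Task-block rows with, per (session, task), a 0-based ordinal by onset."""
    task = events[events["task"] != REST].copy()
    task = task.sort_values(["session_id", "onset_scan"])
    task["ordinal"] = task.groupby(["session_id", "task"]).cumcount()
    return task


def balance_blocks(
    events: pd.DataFrame,
    acknowledged: set[BlockKey],
    pairing_rule: str,
    tasks: tuple[str, str],
    session_pairs: list[tuple[str, str]] | None = None,
) -> set[BlockKey]:
    """Keep a block only if its counterpart block is acknowledged too.

    ``pairing_rule='within_session'``: the counterpart of the i-th block
    of one task is the i-th block of the other task in the same session.
    ``pairing_rule='paired_sessions'``: tasks live in different sessions
    (NAM vs PAM); the counterpart is the i-th block of the other task in
    the paired adjacent session, given by ``session_pairs``.
    """
    task_rows = _ordinal_blocks(events)
    task_rows = task_rows[task_rows["task"].isin(tasks)]
    by_key = {
        (r.session_id, r.task, r.ordinal): (r.session_id, r.block_index)
        for r in task_rows.itertuples()
    }
    if pairing_rule == "within_session":
        session_of = {s: s for s in task_rows["session_id"].unique()}
    elif pairing_rule == "paired_sessions":
        if not session_pairs:
            raise ValueError("paired_sessions pairing needs session_pairs")
        session_of = {}
        for a, b in session_pairs:
            session_of[a] = b
            session_of[b] = a
    else:
        raise ValueError(f"unknown pairing rule {pairing_rule!r}")

    other = {tasks[0]: tasks[1], tasks[1]: tasks[0]}
    keep: set[BlockKey] = set()
    for r in task_rows.itertuples():
        key = (r.session_id, r.block_index)
        partner_session = session_of.get(r.session_id)
        counterpart = by_key.get((partner_session, other[r.task], r.ordinal))
        if counterpart is None:
            raise ValueError(
                f"block {key} of task {r.task} has no counterpart "
                f"({other[r.task]} ordinal {r.ordinal} in session {partner_session})"
            )
        if key in acknowledged and counterpart in acknowledged:
            keep.add(key)
    return keep


def extract_task_scans(
    events: pd.DataFrame,
    valid_blocks: set[BlockKey],
    shift_trs: int = 2,
    block_scans: int = 16,
    session_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per valid block, the ``block_scans`` scans starting at onset + shift.

    Returns one row per scan: (session_id, block_index, task, scan_index).
    """
    rows = []
    for r in events[events["task"] != REST].itertuples():
        key = (r.session_id, r.block_index)
        if key not in valid_blocks:
            continue
        start = int(r.onset_scan) + shift_trs
        stop = start + block_scans
        if session_lengths is not None and stop > session_lengths[r.session_id]:
            raise ValueError(
                f"shifted window [{start}, {stop}) for block {key} exceeds "
                f"session length {session_lengths[r.session_id]}"
            )
        for t in range(start, stop):
            rows.append(
                dict(session_id=r.session_id, block_index=r.block_index, task=r.task, scan_index=t)
            )
    return pd.DataFrame(rows, columns=["session_id", "block_index", "task", "scan_index"])


def voxel_feature_index(runs: list[BoldRun], mask: np.ndarray) -> np.ndarray:
    """In-mask voxels with data (not all-zero across sessions), (x,y,z)-sorted.

    Returns an (D, 3) integer coordinate array in lexicographic order;
    this fixed order is the documented voxel-feature layout.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    has_data = np.zeros(mask.shape, dtype=bool)
    for r in runs:
        has_data |= np.any(r.data != 0, axis=3)
    return np.argwhere(mask & has_data)  # argwhere is lexicographic


def _gather(runs: list[BoldRun], scan_rows: pd.DataFrame) -> dict[str, np.ndarray]:
    return {r.session_id: r.data for r in runs}


def encode_voxels(
    runs: list[BoldRun],
    scan_rows: pd.DataFrame,
    mask: np.ndarray,
    subject_id: str = "sub01",
) -> FeatureDataset:
    """Voxel-based encoding: one feature per in-mask voxel with data."""
    coords = voxel_feature_index(runs, mask)
    data = _gather(runs, scan_rows)
    mat = np.empty((len(scan_rows), len(coords)))
    for i, r in enumerate(scan_rows.itertuples()):
        mat[i] = data[r.session_id][coords[:, 0], coords[:, 1], coords[:, 2], r.scan_index]
    return _annotate(mat, scan_rows, "voxel", coords, subject_id)


def encode_regions(
    runs: list[BoldRun],
    scan_rows: pd.DataFrame,
    atlas: np.ndarray,
    subject_id: str = "sub01",
    n_regions: int = N_REGIONS,
) -> FeatureDataset:
    """Region-based encoding: mean over voxels of each atlas label (1..116).

    Regions without any voxel (possible on scaled-down grids) contribute a
    constant 0 feature and are flagged in ``empty_regions``.
    """
    atlas = np.asarray(atlas)
    labels = np.arange(1, n_regions + 1)
    flat_atlas = atlas.ravel()
    counts = np.bincount(flat_atlas[flat_atlas > 0], minlength=n_regions + 1)[1:]
    empty = labels[counts == 0]
    data = _gather(runs, scan_rows)
    mat = np.zeros((len(scan_rows), n_regions))
    safe = np.where(counts == 0, 1, counts)
    for i, r in enumerate(scan_rows.itertuples()):
        vol = data[r.session_id][..., r.scan_index].ravel()
        sums = np.bincount(flat_atlas, weights=vol, minlength=n_regions + 1)[1:]
        mat[i] = sums / safe
    mat[:, counts == 0] = 0.0
    ds = _annotate(mat, scan_rows, "region", labels, subject_id)
    ds.empty_regions = empty
    return ds


def _annotate(
    mat: np.ndarray, scan_rows: pd.DataFrame, encoding: str, feature_index, subject_id: str
) -> FeatureDataset:
    return FeatureDataset(
        matrix=mat,
        labels=scan_rows["task"].to_numpy(),
        block_id=np.array(
            [f"{subject_id}:{s}:{b}" for s, b in zip(scan_rows["session_id"], scan_rows["block_index"])]
        ),
        session_id=scan_rows["session_id"].to_numpy(),
        subject_id=np.full(len(scan_rows), subject_id),
        encoding=encoding,
        feature_index=np.asarray(feature_index),
    )


def adjacent_session_pairs(session_ids: list[str]) -> list[tuple[str, str]]:
    """Pair sessions (1,2), (3,4), ... by acquisition order."""
    if len(session_ids) % 2:
        raise ValueError("need an even number of sessions to pair")
    ordered = list(session_ids)
    return [(ordered[i], ordered[i + 1]) for i in range(0, len(ordered), 2)]


def build_dataset(
    subject,
    pair: str = "cd-nam",
    encoding: str = "voxel",
    mask: np.ndarray | None = None,
    atlas: np.ndarray | None = None,
    shift_trs: int = 2,
    rt_limit_ms: float = 2000.0,
) -> FeatureDataset:
    """High-level builder: screen, balance, extract and encode one subject.

    ``pair`` is one of ``cd-nam``, ``cd-pam``, ``nam-pam``.  For the
    within-session pairs only sessions of the relevant type are used; for
    NAM vs PAM all sessions are used and balancing crosses adjacent
    session pairs.  The per-scan ``group_id`` is set to the balancing
    unit (session, or session pair) for later permutation shuffling.
    """
    tasks = TASK_PAIRS[pair]
    events = subject.events
    block_scans = int(
        events.loc[events["task"] != REST, "n_scans"].iloc[0]
    )
    if pair == "nam-pam":
        pairing = "paired_sessions"
        session_ids = [r.session_id for r in subject.runs]
        pairs = adjacent_session_pairs(session_ids)
        runs = subject.runs
    else:
        pairing = "within_session"
        pairs = None
        wanted_type = "A" if pair == "cd-nam" else "B"
        runs = [r for r in subject.runs if r.session_type == wanted_type]
        keep_sessions = {r.session_id for r in runs}
        events = events[events["session_id"].isin(keep_sessions)]

    acknowledged = screen_blocks(events, rt_limit_ms)
    valid = balance_blocks(events, acknowledged, pairing, tasks, session_pairs=pairs)
    lengths = {r.session_id: r.n_scans for r in runs}
    scan_rows = extract_task_scans(
        events, valid, shift_trs=shift_trs, block_scans=block_scans, session_lengths=lengths
    )
    if encoding == "voxel":
        if mask is None:
            mask = subject.truth.mask
        ds = encode_voxels(runs, scan_rows, mask, subject_id=subject.subject_id)
    elif encoding == "region":
        if atlas is None:
            raise ValueError("region encoding needs an atlas")
        ds = encode_regions(runs, scan_rows, atlas, subject_id=subject.subject_id)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    if pair == "nam-pam":
        pair_of = {}
        for a, b in pairs:
            pair_of[a] = f"{subject.subject_id}:{a}+{b}"
            pair_of[b] = f"{subject.subject_id}:{a}+{b}"
        ds.group_id = np.array([pair_of[s] for s in ds.session_id])
    else:
        ds.group_id = np.array([f"{subject.subject_id}:{s}" for s in ds.session_id])
    ds.check_balance()
    return ds


def concat_datasets(datasets: list[FeatureDataset]) -> FeatureDataset:
    """Stack per-subject datasets that share a feature index."""
    first = datasets[0]
    for d in datasets[1:]:
        if d.encoding != first.encoding or d.matrix.shape[1] != first.matrix.shape[1]:
            raise ValueError("datasets have incompatible encodings")
    return FeatureDataset(
        matrix=np.vstack([d.matrix for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        block_id=np.concatenate([d.block_id for d in datasets]),
        session_id=np.concatenate([d.session_id for d in datasets]),
        subject_id=np.concatenate([d.subject_id for d in datasets]),
        encoding=first.encoding,
        feature_index=first.feature_index,
        group_id=np.concatenate(
            [
                d.group_id if d.group_id is not None else d.session_id
                for d in datasets
            ]
        ),
    )


def make_folds(dataset: FeatureDataset, scheme: str) -> FoldPlan:
    """Build cross-validation folds.

    - ``loso-session``: one fold per session (or per session pair when
      the dataset's grouping unit is a session pair).
    - ``adjacent-pairs``: alias for the session-pair variant.
    - ``loso-subject``: one fold per subject.
    """
    if scheme in ("loso-session", "adjacent-pairs"):
        units = dataset.group_id if dataset.group_id is not None else dataset.session_id
    elif scheme == "loso-subject":
        units = dataset.subject_id
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    unique_units = list(pd.unique(units))
    if len(unique_units) < 2:
        raise ValueError(f"need at least 2 units for {scheme}, got {len(unique_units)}")
    folds = []
    for u in unique_units:
        test = np.where(units == u)[0]
        train = np.where(units != u)[0]
        folds.append((train, test))
    return FoldPlan(folds=folds, scheme=scheme, fold_units=unique_units)


def intersect_subject_masks(per_subject_coords: list[np.ndarray]) -> np.ndarray:
    """Voxels common to all subjects, in fixed lexicographic order."""
    if len(per_subject_coords) < 2:
        raise ValueError("need at least 2 subjects to intersect")
    sets = [set(map(tuple, np.asarray(c))) for c in per_subject_coords]
    common = set.intersection(*sets)
    if not common:
        raise ValueError("empty intersection of subject masks")
    return np.array(sorted(common))


def restrict_to_voxels(dataset: FeatureDataset, coords: np.ndarray) -> FeatureDataset:
    """Subset a voxel-encoded dataset to the given voxel coordinates."""
    if dataset.encoding != "voxel":
        raise ValueError("only voxel-encoded datasets can be restricted")
    index = {tuple(c): i for i, c in enumerate(dataset.feature_index)}
    cols = np.array([index[tuple(c)] for c in np.asarray(coords)])
    out = FeatureDataset(
        matrix=dataset.matrix[:, cols],
        labels=dataset.labels,
        block_id=dataset.block_id,
        session_id=dataset.session_id,
        subject_id=dataset.subject_id,
        encoding="voxel",
        feature_index=np.asarray(coords),
        group_id=dataset.group_id,
    )
    return out
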