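"""Synthetic multi-session block-design BOLD datasets with known ground truth.

The generator emulates the paradigm the analysis modules expect: 12
sessions per subject, each alternating 32-s task blocks with 16-s rest
at TR = 2 s, repeated in 3 cycles.  Sessions alternate between two types:
Type A pairs a Countdown task with a Negative Autobiographical Memory
(NAM) task, Type B pairs Countdown with Positive Autobiographical Memory
(PAM).  Each voxel's time series is

    offset + sum_k pattern_k * (boxcar_k (*) HRF) + drift + physio
           + global_loading * g(t) + motion_coupling . M(t) + white noise

so downstream stages can be validated against the planted patterns.
Task blocks are independently flagged as unacknowledged (no button-press
response recorded) with a small probability, mimicking missed start cues.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import EVENT_COLUMNS, REST, BoldRun, NuisanceSet, SubjectData
from .grids import Grid, brain_mask, make_grid
from .hrf import block_regressor

def default_sphere_centers(grid: Grid) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Deep white-matter-like and CSF-like sphere centers for a grid.

    Placed at 30% of the half-extent along opposite diagonals, well
    inside the ellipsoidal mask on any grid size.
    """
    semi = (np.array(grid.shape) - 1) * grid.voxel_size_mm / 2.0
    wm = 0.3 * semi * np.array([1.0, -1.0, 1.0])
    csf = 0.3 * semi * np.array([-1.0, 1.0, -1.0])
    return tuple(wm), tuple(csf)

#: Response-time window (ms) for acknowledged task-start cues.
RT_RANGE_MS = (300.0, 1500.0)


@dataclass(frozen=True)
class DesignSpec:
    """Block-design layout of one subject's experiment.

    Defaults reproduce the study paradigm: 12 sessions, 3 cycles per
    session of task(32 s) / rest(16 s) / task(32 s) / rest(16 s), TR 2 s,
    session types strictly alternating.
    """

    n_sessions: int = 12
    cycles_per_session: int = 3
    task_block_s: float = 32.0
    rest_block_s: float = 16.0
    tr: float = 2.0
    session_type_order: tuple[str, ...] | None = None
    p_missed_block: float = 0.01

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for name in ("task_block_s", "rest_block_s"):
            value = getattr(self, name)
            if abs(value / self.tr - round(value / self.tr)) > 1e-9:
                raise ValueError(f"{name}={value} is not an integer multiple of tr={self.tr}")
        if not 0 <= self.p_missed_block < 1:
            raise ValueError("p_missed_block must lie in [0, 1)")
        order = self.session_type_order
        if order is None:
            order = tuple("A" if i % 2 == 0 else "B" for i in range(self.n_sessions))
            object.__setattr__(self, "session_type_order", order)
        if len(order) != self.n_sessions:
            raise ValueError("session_type_order length must equal n_sessions")
        if any(t not in ("A", "B") for t in order):
            raise ValueError("session types must be 'A' or 'B'")
        if any(order[i] == order[i + 1] for i in range(len(order) - 1)):
            raise ValueError("session types must strictly alternate")

    @property
    def task_block_scans(self) -> int:
        return int(round(self.task_block_s / self.tr))

    @property
    def rest_block_scans(self) -> int:
        return int(round(self.rest_block_s / self.tr))

    @property
    def scans_per_session(self) -> int:
        return self.cycles_per_session * 2 * (self.task_block_scans + self.rest_block_scans)

    def session_tasks(self, session_type: str) -> tuple[str, str]:
        """The (first, second) task of each cycle for a session type."""
        return ("Countdown", "NAM") if session_type == "A" else ("Countdown", "PAM")


@dataclass
class GroundTruth:
    """Planted spatial patterns and noise parameters of a synthetic subject.

    ``pattern_maps`` give, per task, the sustained BOLD amplitude each
    voxel shows during that task (signal units per unit HRF plateau).
    The remaining fields parameterize the nuisance sources: white-noise
    SD, slow drift, physiological-band sinusoids, a global AR(1)
    fluctuation entering through ``global_loading``, per-session mean
    offsets, and a motion-coupled artifact ``motion_coupling . M(t)``.
    """

    grid: Grid
    mask: np.ndarray
    pattern_maps: dict[str, np.ndarray]
    noise_sd: float = 1.0
    baseline: float = 800.0
    drift_amp: float = 2.0
    physio_amp: float = 0.5
    physio_freqs: tuple[float, ...] = (0.3, 1.1)
    global_amp: float = 1.0
    global_loading: np.ndarray | None = None
    session_offset_sd: float = 5.0
    motion_walk_sd: tuple[float, ...] = (0.02, 0.02, 0.02, 5e-4, 5e-4, 5e-4)
    motion_coupling: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid")
        for task, pattern in self.pattern_maps.items():
            if np.asarray(pattern).shape != tuple(self.grid.shape):
                raise ValueError(f"pattern map for {task!r} does not match the grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.global_loading is None:
            self.global_loading = self.mask.astype(float)
        if self.motion_coupling is None:
            self.motion_coupling = np.zeros(tuple(self.grid.shape) + (6,))
        if self.global_loading.shape != tuple(self.grid.shape):
            raise ValueError("global_loading shape does not match grid")
        if self.motion_coupling.shape != tuple(self.grid.shape) + (6,):
            raise ValueError("motion_coupling must have shape grid + (6,)")


def default_ground_truth(
    grid: Grid | None = None,
    mask: np.ndarray | None = None,
    amplitude: float = 0.08,
    pattern_style: str = "smooth",
    atlas: np.ndarray | None = None,
    seed: int = 0,
    tasks: tuple[str, ...] = ("Countdown", "NAM", "PAM"),
    **overrides,
) -> GroundTruth:
    """Build a GroundTruth with random per-task activation patterns.

    ``pattern_style='smooth'`` plants spatially smoothed random fields
    (in-mask RMS = ``amplitude``), a coarse-scale pattern that survives
    region averaging.  ``pattern_style='fine'`` plants sign-alternating
    voxel-level patterns (value +-amplitude, random sign per voxel) whose
    region means are near zero -- the regime in which voxel-based
    encodings should beat region-based ones.
    """
    grid = grid or make_grid()
    mask = brain_mask(grid) if mask is None else np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    # The WM/CSF nuisance spheres stand for non-grey tissue: no task
    # activation there, otherwise regressing their means out would remove
    # the task subspace itself.
    centers = default_sphere_centers(grid)
    voxel_mm = grid.voxel_centers_mm()
    quiet = np.zeros(grid.shape, dtype=bool)
    for ctr in centers:
        quiet |= np.linalg.norm(voxel_mm - np.asarray(ctr), axis=-1) <= 8.0
    patterns: dict[str, np.ndarray] = {}
    for task in tasks:
        if pattern_style == "smooth":
            raw = gaussian_filter(rng.standard_normal(grid.shape), sigma=1.5)
            raw *= mask & ~quiet
            rms = np.sqrt(np.mean(raw[mask] ** 2))
            patterns[task] = raw * (amplitude / rms)
        elif pattern_style == "fine":
            signs = rng.choice([-1.0, 1.0], size=grid.shape)
            patterns[task] = signs * (mask & ~quiet) * amplitude
        else:
            raise ValueError(f"unknown pattern_style {pattern_style!r}")
    # mild spatial variation in how strongly the global fluctuation loads
    loading = mask * (1.0 + 0.2 * gaussian_filter(rng.standard_normal(grid.shape), 2.0))
    coupling = np.zeros(tuple(grid.shape) + (6,))
    coupling[mask] = rng.normal(0.0, 1.0, size=(int(mask.sum()), 6))
    params = dict(
        grid=grid,
        mask=mask,
        pattern_maps=patterns,
        global_loading=loading,
        motion_coupling=coupling,
    )
    params.update(overrides)
    return GroundTruth(**params)


def make_design(spec: DesignSpec) -> list[pd.DataFrame]:
    """Lay out each session's block table (task and rest blocks, no RTs yet).

    Each cycle is task1(32 s), rest(16 s), task2(32 s), rest(16 s); with
    the default spec every session holds 3 Countdown and 3 Memory blocks
    of 16 scans each, 144 scans total.
    """
    tables = []
    for s in range(spec.n_sessions):
        session_id = f"ses{s + 1:02d}"
        task1, task2 = spec.session_tasks(spec.session_type_order[s])
        rows = []
        onset = 0
        block_index = 0
        for _ in range(spec.cycles_per_session):
            for task in (task1, REST, task2, REST):
                n = spec.task_block_scans if task != REST else spec.rest_block_scans
                rows.append(
                    dict(
                        session_id=session_id,
                        block_index=block_index,
                        task=task,
                        onset_scan=onset,
                        n_scans=n,
                        response_time_ms=np.nan,
                    )
                )
                onset += n
                block_index += 1
        tables.append(pd.DataFrame(rows, columns=EVENT_COLUMNS))
    return tables


def _ar1(rng: np.random.Generator, n: int, rho: float = 0.5, sd: float = 1.0) -> np.ndarray:
    innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov[t]
    return out


def simulate_subject(
    design: DesignSpec,
    truth: GroundTruth,
    seed: int,
    subject_id: str = "sub01",
    wm_center_mm: tuple[float, float, float] | None = None,
    csf_center_mm: tuple[float, float, float] | None = None,
) -> SubjectData:
    """Generate all sessions of one synthetic subject.

    Identical ``(design, truth, seed)`` give bit-identical outputs.  The
    task-locked signal is planted in every task block whether or not the
    block is acknowledged; acknowledgment only determines whether a
    response time is recorded.
    """
    rng = np.random.default_rng(seed)
    if wm_center_mm is None or csf_center_mm is None:
        wm_default, csf_default = default_sphere_centers(truth.grid)
        wm_center_mm = wm_center_mm or wm_default
        csf_center_mm = csf_center_mm or csf_default
    tables = make_design(design)
    shape = tuple(truth.grid.shape)
    flat_idx = np.argwhere(truth.mask)
    n_vox = len(flat_idx)
    patt_flat = {k: v[truth.mask] for k, v in truth.pattern_maps.items()}
    load_flat = truth.global_loading[truth.mask]
    coup_flat = truth.motion_coupling[truth.mask]

    runs: list[BoldRun] = []
    nuisances: list[NuisanceSet] = []
    events = []
    T = design.scans_per_session
    t_sec = np.arange(T) * design.tr
    for s, table in enumerate(tables):
        table = table.copy()
        # acknowledged / missed task blocks
        is_task = table["task"] != REST
        missed = rng.random(is_task.sum()) < design.p_missed_block
        rts = rng.uniform(*RT_RANGE_MS, size=is_task.sum())
        rts[missed] = np.nan
        table.loc[is_task, "response_time_ms"] = rts
        events.append(table)

        Y = np.zeros((n_vox, T))
        for task in design.session_tasks(design.session_type_order[s]):
            blocks = table[table["task"] == task]
            reg = block_regressor(
                blocks["onset_scan"].to_numpy(), blocks["n_scans"].to_numpy(), T, design.tr
            )
            Y += patt_flat[task][:, None] * reg[None, :]

        lin = (t_sec - t_sec.mean()) / max(t_sec[-1] - t_sec[0], design.tr) * 2.0
        a, b = rng.normal(size=2)
        drift = truth.drift_amp * (a * lin + b * np.cos(np.pi * t_sec / t_sec[-1]))
        physio = np.zeros(T)
        for f in truth.physio_freqs:
            physio += truth.physio_amp * np.cos(2 * np.pi * f * t_sec + rng.uniform(0, 2 * np.pi))
        g = _ar1(rng, T, rho=0.5, sd=truth.global_amp)
        motion = np.cumsum(
            rng.normal(0.0, 1.0, size=(T, 6)) * np.asarray(truth.motion_walk_sd), axis=0
        )
        offset = truth.baseline + rng.normal(0.0, truth.session_offset_sd)

        Y += (drift + physio + offset)[None, :]
        Y += load_flat[:, None] * g[None, :]
        Y += coup_flat @ motion.T
        if truth.noise_sd > 0:
            Y += rng.normal(0.0, truth.noise_sd, size=(n_vox, T))

        vol = np.zeros(shape + (T,))
        vol[flat_idx[:, 0], flat_idx[:, 1], flat_idx[:, 2], :] = Y
        runs.append(
            BoldRun(
                data=vol,
                tr=design.tr,
                session_id=table["session_id"].iloc[0],
                session_type=design.session_type_order[s],
                affine=truth.grid.affine,
            )
        )
        nuisances.append(
            NuisanceSet(
                motion=motion,
                wm_center=wm_center_mm,
                csf_center=csf_center_mm,
                grey_mask=truth.mask,
            )
        )
    return SubjectData(
        subject_id=subject_id,
        runs=runs,
        events=pd.concat(events, ignore_index=True),
        nuisance=nuisances,
        truth=truth,
    )


def simulate_study(
    n_subjects: int,
    design: DesignSpec,
    seed: int,
    amplitude: float = 0.08,
    pattern_style: str = "smooth",
    grid: Grid | None = None,
    shared_patterns: bool = True,
    **truth_overrides,
) -> list[SubjectData]:
    """Simulate a cohort.

    With ``shared_patterns`` the activation patterns are common to all
    subjects (the assumption under which across-subject decoding can
    work); noise realizations always differ per subject.
    """
    grid = grid or make_grid()
    mask = brain_mask(grid)
    subjects = []
    for i in range(n_subjects):
        pattern_seed = seed if shared_patterns else seed + 104729 * (i + 1)
        truth = default_ground_truth(
            grid=grid,
            mask=mask,
            amplitude=amplitude,
            pattern_style=pattern_style,
            seed=pattern_seed,
            **truth_overrides,
        )
        subjects.append(
            simulate_subject(design, truth, seed=seed + 7919 * (i + 1), subject_id=f"sub{i + 1:02d}")
        )
    return subjects


# ---------------------------------------------------------------------------
# on-disk round trip


def write_dataset(subject: SubjectData, atlas: np.ndarray, out_dir) -> dict:
    """Write one subject to NIfTI/TSV/JSON files; returns a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: GroundTruth = subject.truth
    affine = subject.runs[0].affine
    manifest: dict = {"subject_id": subject.subject_id, "bold": [], "nuisance": []}
    for run, nuis in zip(subject.runs, subject.nuisance):
        bold_path = out / f"{subject.subject_id}_{run.session_id}_bold.nii"
        nib.save(nib.Nifti1Image(run.data.astype(np.float32), run.affine), bold_path)
        manifest["bold"].append(str(bold_path))
        nuis_path = out / f"{subject.subject_id}_{run.session_id}_motion.tsv"
        pd.DataFrame(nuis.motion, columns=[f"mp{i + 1}" for i in range(6)]).to_csv(
            nuis_path, sep="\t", index=False
        )
        manifest["nuisance"].append(str(nuis_path))
    events_path = out / f"{subject.subject_id}_events.tsv"
    subject.events.to_csv(events_path, sep="\t", index=False)
    manifest["events"] = str(events_path)
    atlas_path = out / "atlas.nii"
    nib.save(nib.Nifti1Image(np.asarray(atlas, dtype=np.int16), affine), atlas_path)
    manifest["atlas"] = str(atlas_path)
    labels = np.unique(np.asarray(atlas))
    labels = labels[labels > 0]
    regions_path = out / "atlas_regions.tsv"
    pd.DataFrame(
        {"label": labels, "region_name": [f"region_{int(lab):03d}" for lab in labels]}
    ).to_csv(regions_path, sep="\t", index=False)
    manifest["atlas_regions"] = str(regions_path)
    mask_path = out / "mask.nii"
    nib.save(nib.Nifti1Image(truth.mask.astype(np.uint8), affine), mask_path)
    manifest["mask"] = str(mask_path)
    truth_path = out / f"{subject.subject_id}_truth.json"
    truth_path.write_text(json.dumps(_truth_to_json(truth)))
    manifest["truth"] = str(truth_path)
    manifest["session_types"] = [r.session_type for r in subject.runs]
    manifest["tr"] = subject.runs[0].tr
    manifest["wm_center"] = list(subject.nuisance[0].wm_center)
    manifest["csf_center"] = list(subject.nuisance[0].csf_center)
    (out / f"{subject.subject_id}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _truth_to_json(truth: GroundTruth) -> dict:
    d = {
        f.name: getattr(truth, f.name)
        for f in dataclasses.fields(truth)
        if f.name not in ("grid", "mask", "pattern_maps", "global_loading", "motion_coupling")
    }
    d["motion_walk_sd"] = list(truth.motion_walk_sd)
    d["physio_freqs"] = list(truth.physio_freqs)
    d["grid_shape"] = list(truth.grid.shape)
    d["affine"] = truth.grid.affine.tolist()
    d["pattern_maps"] = {k: v.tolist() for k, v in truth.pattern_maps.items()}
    d["global_loading"] = truth.global_loading.tolist()
    d["motion_coupling"] = truth.motion_coupling.tolist()
    return d


def read_dataset(manifest: dict) -> SubjectData:
    """Load a subject written by :func:`write_dataset`."""
    runs = []
    nuisances = []
    mask = np.asarray(nib.load(manifest["mask"]).dataobj).astype(bool)
    raw = json.loads(Path(manifest["truth"]).read_text())
    grid = Grid(shape=tuple(raw["grid_shape"]), affine=np.array(raw["affine"]))
    truth = GroundTruth(
        grid=grid,
        mask=mask,
        pattern_maps={k: np.array(v) for k, v in raw["pattern_maps"].items()},
        noise_sd=raw["noise_sd"],
        baseline=raw["baseline"],
        drift_amp=raw["drift_amp"],
        physio_amp=raw["physio_amp"],
        physio_freqs=tuple(raw["physio_freqs"]),
        global_amp=raw["global_amp"],
        global_loading=np.array(raw["global_loading"]),
        session_offset_sd=raw["session_offset_sd"],
        motion_walk_sd=tuple(raw["motion_walk_sd"]),
        motion_coupling=np.array(raw["motion_coupling"]),
    )
    events = pd.read_csv(manifest["events"], sep="\t")
    wm_center = tuple(manifest["wm_center"])
    csf_center = tuple(manifest["csf_center"])
    for bold_path, nuis_path, stype in zip(
        manifest["bold"], manifest["nuisance"], manifest["session_types"]
    ):
        img = nib.load(bold_path)
        session_id = Path(bold_path).name.split("_")[1]
        runs.append(
            BoldRun(
                data=np.asarray(img.dataobj, dtype=np.float32),
                tr=manifest["tr"],
                session_id=session_id,
                session_type=stype,
                affine=img.affine,
            )
        )
        motion = pd.read_csv(nuis_path, sep="\t").to_numpy()
        nuisances.append(
            NuisanceSet(
                motion=motion,
                wm_center=wm_center,
                csf_center=csf_center,
                grey_mask=mask,
            )
        )
    return SubjectData(
        subject_id=manifest["subject_id"],
        runs=runs,
        events=events,
        nuisance=nuisances,
        truth=truth,
    )
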