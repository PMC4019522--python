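"""Shared fixtures: small grids, simulated subjects, direct feature datasets."""

from __future__ import annotations

import numpy as np

import pytest
from hypothesis import settings

from blockmvpa.features import FeatureDataset
from blockmvpa.grids import brain_mask, make_grid, partition_atlas
from blockmvpa.preprocess import preprocess_subject
from blockmvpa.simdata import DesignSpec, default_ground_truth, simulate_subject

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

TINY_SHAPE = (10, 12, 8)


@pytest.fixture(scope="session")
def tiny_grid():
    return make_grid(TINY_SHAPE)


@pytest.fixture(scope="session")
def tiny_mask(tiny_grid):
    return brain_mask(tiny_grid)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_mask):
    return partition_atlas(tiny_mask)


@pytest.fixture(scope="session")
def small_design():
    """6 alternating sessions, full-length blocks, no missed cues."""
    return DesignSpec(n_sessions=6, p_missed_block=0.0)


@pytest.fixture(scope="session")
def default_design():
    return DesignSpec(p_missed_block=0.0)


@pytest.fixture(scope="session")
def sim_subject(small_design, tiny_grid, tiny_mask):
    """One simulated subject on the tiny grid (session-scoped, reused)."""
    truth = default_ground_truth(grid=tiny_grid, mask=tiny_mask, amplitude=0.1, seed=11)
    return simulate_subject(small_design, truth, seed=5, subject_id="sub01")


@pytest.fixture(scope="session")
def preprocessed_subject(sim_subject, tiny_mask):
    subj = sim_subject
    runs, report = preprocess_subject(subj.runs, subj.nuisance, tiny_mask)
    out = type(subj)(
        subject_id=subj.subject_id,
        runs=runs,
        events=subj.events,
        nuisance=subj.nuisance,
        truth=subj.truth,
    )
    return out, report


def make_feature_dataset(
    n_sessions: int = 4,
    blocks_per_class: int = 3,
    scans_per_block: int = 8,
    n_features: int = 20,
    effect: float = 0.0,
    seed: int = 0,
    subject_id: str = "sub01",
    classes: tuple[str, str] = ("Countdown", "NAM"),
) -> FeatureDataset:
    """Balanced block-structured dataset built directly in feature space.

    Class means differ by ``effect`` along a fixed random direction;
    ``effect=0`` gives pure-noise (null) data.
    """
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    rows_X, labels, blocks, sessions = [], [], [], []
    for s in range(n_sessions):
        sid = f"ses{s + 1:02d}"
        order = [classes[0]] * blocks_per_class + [classes[1]] * blocks_per_class
        for b, lab in enumerate(order):
            mean = (effect / 2 if lab == classes[0] else -effect / 2) * direction
            X = rng.standard_normal((scans_per_block, n_features)) + mean
            rows_X.append(X)
            labels += [lab] * scans_per_block
            blocks += [f"{subject_id}:{sid}:{b}"] * scans_per_block
            sessions += [sid] * scans_per_block
    ds = FeatureDataset(
        matrix=np.vstack(rows_X),
        labels=np.array(labels),
        block_id=np.array(blocks),
        session_id=np.array(sessions),
        subject_id=np.full(len(labels), subject_id),
        encoding="voxel",
        feature_index=np.stack([np.arange(n_features)] * 3, axis=1),
        group_id=np.array([f"{subject_id}:{s}" for s in sessions]),
    )
    ds.check_balance()
    return ds
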