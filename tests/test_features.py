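"""Screening, block balancing, scan extraction, encodings and folds."""

import numpy as np
import pandas as pd
import pytest

from blockmvpa.datatypes import REST
from blockmvpa.features import (
    adjacent_session_pairs,
    balance_blocks,
    build_dataset,
    concat_datasets,
    encode_regions,
    extract_task_scans,
    intersect_subject_masks,
    make_folds,
    restrict_to_voxels,
    screen_blocks,
    voxel_feature_index,
)
from blockmvpa.simdata import DesignSpec, default_ground_truth, make_design, simulate_subject


def _events_with_rts(design, rt=500.0):
    tables = make_design(design)
    ev = pd.concat(tables, ignore_index=True)
    ev.loc[ev["task"] != REST, "response_time_ms"] = rt
    return ev


class TestScreenBlocks:
    def test_all_acknowledged_retained(self):
        ev = _events_with_rts(DesignSpec())
        acked = screen_blocks(ev)
        assert len(acked) == 12 * 6  # 6 task blocks per session

    def test_missing_response_excluded(self):
        ev = _events_with_rts(DesignSpec())
        task_idx = ev.index[ev["task"] != REST]
        ev.loc[task_idx[0], "response_time_ms"] = np.nan
        acked = screen_blocks(ev)
        key = (ev.loc[task_idx[0], "session_id"], ev.loc[task_idx[0], "block_index"])
        assert key not in acked
        assert len(acked) == 12 * 6 - 1

    def test_boundary_exactly_2000_ms_excluded(self):
        ev = _events_with_rts(DesignSpec(), rt=2000.0)
        assert screen_blocks(ev) == set()
        ev2 = _events_with_rts(DesignSpec(), rt=1999.999)
        assert len(screen_blocks(ev2)) == 72


class TestBalanceBlocks:
    def test_counterpart_dropped_with_missed_block(self):
        ev = _events_with_rts(DesignSpec())
        # miss the 2nd NAM block of session 1 (ordinal 1)
        nam = ev[(ev["session_id"] == "ses01") & (ev["task"] == "NAM")]
        ev.loc[nam.index[1], "response_time_ms"] = np.nan
        acked = screen_blocks(ev)
        ses1 = ev[ev["session_id"] == "ses01"]
        keep = balance_blocks(
            ses1, acked, "within_session", ("Countdown", "NAM")
        )
        cd = ses1[ses1["task"] == "Countdown"].sort_values("onset_scan")
        # the 2nd Countdown block must be gone even though it was acknowledged
        assert ("ses01", int(cd["block_index"].iloc[1])) not in keep
        assert len(keep) == 4  # 2 surviving pairs

    def test_all_acknowledged_keeps_three_pairs_per_session(self):
        ev = _events_with_rts(DesignSpec())
        typeA = ev[ev["session_id"].isin([f"ses{i:02d}" for i in (1, 3, 5, 7, 9, 11)])]
        keep = balance_blocks(typeA, screen_blocks(typeA), "within_session", ("Countdown", "NAM"))
        per_session = pd.Series([k[0] for k in keep]).value_counts()
        assert (per_session == 6).all()

    def test_counting_oracle_one_miss_in_six_sessions(self):
        """One missed block in one of six sessions -> (18-1)*16 = 272 valid scans/class."""
        ev = _events_with_rts(DesignSpec())
        typeA_ids = [f"ses{i:02d}" for i in (1, 3, 5, 7, 9, 11)]
        typeA = ev[ev["session_id"].isin(typeA_ids)].copy()
        nam = typeA[(typeA["session_id"] == "ses03") & (typeA["task"] == "NAM")]
        typeA.loc[nam.index[0], "response_time_ms"] = np.nan
        keep = balance_blocks(
            typeA, screen_blocks(typeA), "within_session", ("Countdown", "NAM")
        )
        rows = extract_task_scans(typeA, keep)
        counts = rows.groupby("task").size()
        assert counts["Countdown"] == 272
        assert counts["NAM"] == 272

    def test_paired_sessions_for_memory_tasks(self):
        ev = _events_with_rts(DesignSpec())
        pairs = adjacent_session_pairs([f"ses{i:02d}" for i in range(1, 13)])
        nam = ev[(ev["session_id"] == "ses01") & (ev["task"] == "NAM")]
        ev.loc[nam.index[2], "response_time_ms"] = np.nan
        keep = balance_blocks(ev, screen_blocks(ev), "paired_sessions", ("NAM", "PAM"),
                              session_pairs=pairs)
        # the 3rd PAM block of the paired session ses02 is dropped too
        pam = ev[(ev["session_id"] == "ses02") & (ev["task"] == "PAM")].sort_values("onset_scan")
        assert ("ses02", int(pam["block_index"].iloc[2])) not in keep
        # 18 NAM + 18 PAM blocks, one cross-session pair dropped
        assert len(keep) == 34

    def test_dangling_counterpart_raises(self):
        ev = _events_with_rts(DesignSpec(n_sessions=2))
        # remove one Countdown block entirely -> structural mismatch
        cd = ev[(ev["session_id"] == "ses01") & (ev["task"] == "Countdown")]
        broken = ev.drop(index=cd.index[0])
        with pytest.raises(ValueError, match="counterpart"):
            balance_blocks(broken, screen_blocks(broken), "within_session", ("Countdown", "NAM"))


class TestExtractScans:
    def test_shift_arithmetic(self):
        ev = pd.DataFrame(
            [dict(session_id="s", block_index=0, task="NAM", onset_scan=24, n_scans=16,
                  response_time_ms=500.0)]
        )
        rows = extract_task_scans(ev, {("s", 0)}, shift_trs=2)
        assert rows["scan_index"].tolist() == list(range(26, 42))
        rows0 = extract_task_scans(ev, {("s", 0)}, shift_trs=0)
        assert rows0["scan_index"].tolist() == list(range(24, 40))

    def test_full_design_scan_totals(self):
        """All cues acknowledged: 576 Countdown and 288 scans per memory task."""
        ev = _events_with_rts(DesignSpec())
        keep = screen_blocks(ev)
        rows = extract_task_scans(ev, keep)
        counts = rows.groupby("task").size()
        assert counts["Countdown"] == 576
        assert counts["NAM"] == 288
        assert counts["PAM"] == 288

    def test_no_scan_in_two_blocks(self):
        ev = _events_with_rts(DesignSpec())
        rows = extract_task_scans(ev, screen_blocks(ev))
        dup = rows.duplicated(subset=["session_id", "scan_index"])
        assert not dup.any()

    def test_window_beyond_session_end_raises(self):
        ev = pd.DataFrame(
            [dict(session_id="s", block_index=0, task="NAM", onset_scan=130, n_scans=16,
                  response_time_ms=500.0)]
        )
        with pytest.raises(ValueError, match="exceeds"):
            extract_task_scans(ev, {("s", 0)}, shift_trs=2, session_lengths={"s": 144})


class TestEncodings:
    def test_voxel_width_equals_mask_with_data(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject
        coords = voxel_feature_index(subj.runs, tiny_mask)
        assert len(coords) == tiny_mask.sum()  # synthetic data fill the mask
        ds = build_dataset(subj, pair="cd-nam", encoding="voxel", mask=tiny_mask)
        assert ds.n_features == len(coords)

    def test_all_zero_voxels_dropped(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject
        mask = tiny_mask.copy()
        dead = tuple(np.argwhere(tiny_mask)[0])
        runs = [r.copy_with(r.data.copy()) for r in subj.runs]
        for r in runs:
            r.data[dead] = 0.0
        coords = voxel_feature_index(runs, mask)
        assert len(coords) == tiny_mask.sum() - 1

    def test_region_mean_matches_brute_force(self, preprocessed_subject, tiny_atlas):
        subj, _ = preprocessed_subject
        rows = pd.DataFrame(
            [dict(session_id=subj.runs[0].session_id, block_index=0, task="NAM", scan_index=5)]
        )
        ds = encode_regions(subj.runs, rows, tiny_atlas)
        vol = subj.runs[0].data[..., 5]
        for j in range(ds.n_features):
            sel = tiny_atlas == (j + 1)
            if sel.any():
                assert ds.matrix[0, j] == pytest.approx(vol[sel].mean())

    def test_single_region_equals_mask_mean(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject
        atlas = tiny_mask.astype(int)  # one region covering the mask
        rows = pd.DataFrame(
            [dict(session_id=subj.runs[0].session_id, block_index=0, task="NAM", scan_index=3)]
        )
        ds = encode_regions(subj.runs, rows, atlas, n_regions=1)
        vol = subj.runs[0].data[..., 3]
        assert ds.matrix[0, 0] == pytest.approx(vol[tiny_mask].mean())

    def test_constant_regions_give_their_values(self):
        from blockmvpa.datatypes import BoldRun

        data = np.zeros((2, 1, 1, 4))
        data[0, 0, 0] = 1.0
        data[1, 0, 0] = 5.0
        run = BoldRun(data=data, tr=2.0, session_id="s", session_type="A", affine=np.eye(4))
        atlas = np.array([[[1]], [[2]]])
        rows = pd.DataFrame(
            [dict(session_id="s", block_index=0, task="NAM", scan_index=0)]
        )
        ds = encode_regions([run], rows, atlas, n_regions=2)
        np.testing.assert_allclose(ds.matrix[0], [1.0, 5.0])

    def test_empty_region_flagged_zero(self):
        from blockmvpa.datatypes import BoldRun

        run = BoldRun(
            data=np.ones((2, 1, 1, 2)), tr=2.0, session_id="s", session_type="A", affine=np.eye(4)
        )
        atlas = np.array([[[1]], [[1]]])  # region 2 has no voxels
        rows = pd.DataFrame([dict(session_id="s", block_index=0, task="NAM", scan_index=0)])
        ds = encode_regions([run], rows, atlas, n_regions=2)
        assert 2 in ds.empty_regions
        assert ds.matrix[0, 1] == 0.0

    def test_region_encoding_commutes_with_voxel_averaging(
        self, preprocessed_subject, tiny_mask, tiny_atlas
    ):
        subj, _ = preprocessed_subject
        ds_v = build_dataset(subj, pair="cd-nam", encoding="voxel", mask=tiny_mask)
        ds_r = build_dataset(subj, pair="cd-nam", encoding="region", atlas=tiny_atlas)
        coords = ds_v.feature_index
        labels_of = tiny_atlas[coords[:, 0], coords[:, 1], coords[:, 2]]
        for j in range(1, ds_r.n_features + 1):
            sel = labels_of == j
            if sel.any():
                np.testing.assert_allclose(
                    ds_v.matrix[:, sel].mean(axis=1), ds_r.matrix[:, j - 1], atol=1e-10
                )


class TestFolds:
    def test_loso_session_fold_count(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject  # 6 sessions -> 3 of type A
        ds = build_dataset(subj, pair="cd-nam", encoding="voxel", mask=tiny_mask)
        plan = make_folds(ds, "loso-session")
        assert len(plan) == 3
        for train, test in plan.folds:
            assert set(train) & set(test) == set()
            y = ds.labels[test]
            assert (y == "Countdown").sum() == (y == "NAM").sum()

    def test_adjacent_pairs_fold_count(self, tiny_grid, tiny_mask):
        design = DesignSpec(p_missed_block=0.0)  # 12 sessions
        truth = default_ground_truth(grid=tiny_grid, mask=tiny_mask, seed=0)
        subj = simulate_subject(design, truth, seed=1)
        ds = build_dataset(subj, pair="nam-pam", encoding="voxel", mask=tiny_mask)
        plan = make_folds(ds, "adjacent-pairs")
        assert len(plan) == 6  # 12 sessions -> 6 pairs
        # every fold's train/test balanced
        for train, test in plan.folds:
            for idx in (train, test):
                y = ds.labels[idx]
                assert (y == "NAM").sum() == (y == "PAM").sum()

    def test_loso_subject_fold_count(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject
        ds = build_dataset(subj, pair="cd-nam", encoding="voxel", mask=tiny_mask)
        pooled = concat_datasets([ds, ds, ds])
        pooled.subject_id = np.repeat(["sub01", "sub02", "sub03"], ds.n_scans)
        plan = make_folds(pooled, "loso-subject")
        assert len(plan) == 3

    def test_too_few_units_raises(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject
        ds = build_dataset(subj, pair="cd-nam", encoding="voxel", mask=tiny_mask)
        one = ds.session_id == ds.session_id[0]
        import dataclasses

        sub = dataclasses.replace(
            ds,
            matrix=ds.matrix[one],
            labels=ds.labels[one],
            block_id=ds.block_id[one],
            session_id=ds.session_id[one],
            subject_id=ds.subject_id[one],
            group_id=ds.group_id[one],
        )
        with pytest.raises(ValueError, match="at least 2"):
            make_folds(sub, "loso-session")


class TestMaskIntersection:
    def test_identity_and_set_arithmetic(self):
        a = np.array([[0, 0, 1], [0, 0, 2], [0, 0, 3]])
        b = np.array([[0, 0, 2], [0, 0, 3], [0, 0, 4]])
        out = intersect_subject_masks([a, b])
        np.testing.assert_array_equal(out, [[0, 0, 2], [0, 0, 3]])
        same = intersect_subject_masks([a, a])
        np.testing.assert_array_equal(same, a)

    def test_random_dropout_matches_brute_force(self):
        rng = np.random.default_rng(0)
        full = np.argwhere(np.ones((5, 5, 5), dtype=bool))
        subs = [full[rng.random(len(full)) > 0.2] for _ in range(4)]
        out = intersect_subject_masks(subs)
        brute = [
            tuple(v)
            for v in full
            if all(any((s == v).all(axis=1)) for s in subs)
        ]
        assert [tuple(v) for v in out] == sorted(brute)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            intersect_subject_masks([np.array([[0, 0, 0]]), np.array([[1, 1, 1]])])

    def test_restrict_to_voxels(self, preprocessed_subject, tiny_mask):
        subj, _ = preprocessed_subject
        ds = build_dataset(subj, pair="cd-nam", encoding="voxel", mask=tiny_mask)
        keep = ds.feature_index[::3]
        sub = restrict_to_voxels(ds, keep)
        assert sub.n_features == len(keep)
        np.testing.assert_allclose(sub.matrix, ds.matrix[:, ::3])
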