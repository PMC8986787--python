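"""Auto-labeling decision layer: mode selection, calibration sampling,
PPV/NPV curves, threshold selection, retraining selection."""

import numpy as np
import pandas as pd
import pytest

import psimlabel as pl
from psimlabel.labeler import (ModeSelectionConfig, default_grid, mode_select,
                               ppv_npv_curves, select_for_retraining,
                               select_thresholds, stratified_bin_sample,
                               tpcr_at_capture, tpcr_by_scoring_mode)
from psimlabel.psim import PSimRecord


def rec(image_id, label=0, y=0.9, psim_pos=0.5, conf_n=0.0, patch=0.5, conf_p=0.5):
    return PSimRecord(image_id=image_id, label=label, predicted_prob=y,
                      patch_similarity=patch, confidence_P=conf_p,
                      confidence_N=conf_n, psim_positive=psim_pos,
                      psim_negative=conf_n)


def cfg(th_pos=0.5, tp=0.5, tn=0.9, L=1):
    return ModeSelectionConfig(th_pos=th_pos,
                               theta_ppv1=np.full(L, tp),
                               theta_npv1=np.full(L, tn),
                               ppv1_attainable=np.ones(L, bool),
                               npv1_attainable=np.ones(L, bool))


class TestModeSelect:
    def test_positive_above_threshold_self_annotates(self):
        d = mode_select(rec("a", y=0.9, psim_pos=0.8), cfg(tp=0.5))
        assert (d.mode, d.assigned) == ("self-annotation", 1)

    def test_positive_below_threshold_defers(self):
        d = mode_select(rec("a", y=0.9, psim_pos=0.3), cfg(tp=0.5))
        assert (d.mode, d.assigned) == ("re-annotation", -1)

    def test_negative_branch_uses_confidence_n(self):
        d = mode_select(rec("a", y=0.2, conf_n=0.95), cfg(tn=0.9))
        assert (d.mode, d.assigned) == ("self-annotation", 0)
        d2 = mode_select(rec("a", y=0.2, conf_n=0.85), cfg(tn=0.9))
        assert (d2.mode, d2.assigned) == ("re-annotation", -1)

    def test_boundary_is_inclusive(self):
        d = mode_select(rec("a", y=0.5, psim_pos=0.5), cfg(th_pos=0.5, tp=0.5))
        assert d.assigned == 1

    def test_reannotation_iff_minus_one(self):
        rng = np.random.default_rng(0)
        c = cfg(tp=0.4, tn=0.6)
        for _ in range(50):
            r = rec("x", y=rng.uniform(), psim_pos=rng.uniform(),
                    conf_n=rng.uniform())
            d = mode_select(r, c)
            assert (d.assigned == -1) == (d.mode == "re-annotation")


class TestStratifiedBinSample:
    def _records(self, psims, y=0.9):
        return [rec(f"r{i}", y=y, psim_pos=p) for i, p in enumerate(psims)]

    def test_single_bin_caps_at_per_bin(self):
        records = self._records(np.full(30, 0.55))
        s = stratified_bin_sample(records, per_bin=10, rng_seed=0)
        assert len(s.positive_candidates) == 10

    def test_full_bins_give_exactly_100(self):
        rng = np.random.default_rng(1)
        psims = np.concatenate([rng.uniform(b / 10, (b + 1) / 10 - 1e-6, size=15)
                                for b in range(10)])
        s = stratified_bin_sample(self._records(psims), per_bin=10, rng_seed=0)
        assert len(s.positive_candidates) == 100

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        records = self._records(rng.uniform(size=60))
        a = stratified_bin_sample(records, rng_seed=5)
        b = stratified_bin_sample(records, rng_seed=5)
        assert [r.image_id for r in a.positive_candidates] == \
               [r.image_id for r in b.positive_candidates]

    def test_positive_negative_sampled_separately(self):
        records = (self._records(np.full(5, 0.5), y=0.9)
                   + [rec(f"n{i}", y=0.1, conf_n=0.5) for i in range(5)])
        s = stratified_bin_sample(records, per_bin=10, rng_seed=0)
        assert len(s.positive_candidates) == 5
        assert len(s.negative_candidates) == 5
        assert all(r.predicted_prob >= 0.5 for r in s.positive_candidates)


class TestCurvesAndThresholds:
    def test_all_correct_gives_ppv_one_everywhere(self):
        records = [rec(f"p{i}", y=0.9, psim_pos=0.1 * i) for i in range(1, 8)]
        gt = {r.image_id: 1 for r in records}
        t = ppv_npv_curves(records, gt, grid=default_grid(0.05))
        captured = t.captured_pos > 0
        assert np.all(t.ppv[captured] == 1.0)
        assert t.theta_ppv1 == 0.0 and t.ppv1_attainable

    def test_false_positive_with_top_psim_blocks_threshold(self):
        records = [rec("fp", y=0.9, psim_pos=0.95),
                   rec("tp1", y=0.9, psim_pos=0.5),
                   rec("tp2", y=0.9, psim_pos=0.6)]
        gt = {"fp": 0, "tp1": 1, "tp2": 1}
        t = ppv_npv_curves(records, gt, grid=default_grid(0.05))
        below = (t.grid <= 0.95) & (t.captured_pos > 0)
        assert np.all(t.ppv[below] < 1.0)
        assert not t.ppv1_attainable and t.theta_ppv1 == 1.0

    def test_hand_built_fixture_matches_bruteforce_counts(self):
        rng = np.random.default_rng(3)
        records, gt = [], {}
        for i in range(10):
            y = rng.uniform()
            r = rec(f"r{i}", y=y, psim_pos=round(rng.uniform(), 2),
                    conf_n=round(rng.uniform(), 2))
            records.append(r)
            gt[r.image_id] = int(rng.integers(0, 2))
        grid = default_grid(0.1)
        t = ppv_npv_curves(records, gt, grid=grid, th_pos=0.5)
        n_gt_pos = sum(gt.values())
        n_gt_neg = 10 - n_gt_pos
        for k, theta in enumerate(grid):
            cap_p = [r for r in records if r.predicted_prob >= 0.5
                     and r.psim_positive >= theta]
            tp = sum(1 for r in cap_p if gt[r.image_id] == 1)
            assert t.captured_pos[k] == len(cap_p)
            if cap_p:
                assert t.ppv[k] == tp / len(cap_p)
            else:
                assert np.isnan(t.ppv[k])
            if n_gt_pos:
                assert t.tpcr[k] == tp / n_gt_pos
            cap_n = [r for r in records if r.predicted_prob < 0.5
                     and r.psim_negative >= theta]
            tn = sum(1 for r in cap_n if gt[r.image_id] == 0)
            assert t.captured_neg[k] == len(cap_n)
            if cap_n:
                assert t.npv[k] == tn / len(cap_n)
            if n_gt_neg:
                assert t.tncr[k] == tn / n_gt_neg

    def test_threshold_first_reached_at_known_point(self):
        # constructed so PPV first hits 1 exactly at theta = 0.63
        records = [rec("fp", y=0.9, psim_pos=0.62),
                   rec("tp1", y=0.9, psim_pos=0.63),
                   rec("tp2", y=0.9, psim_pos=0.9)]
        gt = {"fp": 0, "tp1": 1, "tp2": 1}
        t = ppv_npv_curves(records, gt, grid=default_grid(0.01))
        assert t.theta_ppv1 == pytest.approx(0.63)

    def test_capture_set_inclusion_as_theta_grows(self):
        rng = np.random.default_rng(4)
        records = [rec(f"r{i}", y=rng.uniform(), psim_pos=rng.uniform(),
                       conf_n=rng.uniform()) for i in range(60)]
        grid = default_grid(0.05)
        prev_p, prev_n = None, None
        for theta in grid:
            cap_p = {r.image_id for r in records
                     if r.predicted_prob >= 0.5 and r.psim_positive >= theta}
            cap_n = {r.image_id for r in records
                     if r.predicted_prob < 0.5 and r.psim_negative >= theta}
            if prev_p is not None:
                assert cap_p <= prev_p and cap_n <= prev_n
            prev_p, prev_n = cap_p, cap_n

    def test_missing_gt_lists_ids(self):
        records = [rec("a"), rec("b")]
        with pytest.raises(ValueError, match="b"):
            ppv_npv_curves(records, {"a": 1})

    def test_sentinel_when_no_positive_candidates(self):
        records = [rec("a", y=0.1, conf_n=0.9)]
        t = ppv_npv_curves(records, {"a": 0})
        assert t.theta_ppv1 == 1.0 and not t.ppv1_attainable
        assert select_thresholds(t) == (t.theta_ppv1, t.theta_npv1)


class TestScoringModes:
    def test_degenerate_equality_gives_identical_curves(self):
        records = [rec(f"r{i}", y=0.9, psim_pos=0.4, patch=0.4, conf_p=0.4)
                   for i in range(10)]
        gt = {r.image_id: 1 for r in records}
        out = tpcr_by_scoring_mode(records, gt, grid=default_grid(0.1))
        assert np.allclose(out["confidence"][0], out["patch_similarity"][0])
        assert np.allclose(out["confidence"][0], out["psim"][0])

    def test_matched_capture_is_rank_based(self):
        records = [rec("a", y=0.9, conf_p=0.9, patch=0.1),
                   rec("b", y=0.9, conf_p=0.5, patch=0.9),
                   rec("c", y=0.9, conf_p=0.1, patch=0.5),
                   rec("d", y=0.9, conf_p=0.7, patch=0.7)]
        gt = {"a": 0, "b": 1, "c": 1, "d": 0}
        got = tpcr_at_capture(records, gt, "patch_similarity", [0.5])
        # top-2 by patch similarity = b (0.9), d (0.7) -> 1 of 2 GT positives
        assert got[0] == pytest.approx(0.5)
        got_c = tpcr_at_capture(records, gt, "confidence", [0.5])
        # top-2 by confidence = a (0.9), d (0.7) -> 0 of 2
        assert got_c[0] == 0.0


class TestRetrainingSelection:
    def _decisions(self, rows):
        return pd.DataFrame(rows, columns=["image_id", "label", "mode",
                                           "assigned", "psim"])

    def _dataset(self, n=6, L=2):
        rng = np.random.default_rng(0)
        return pl.LabeledImageSet(
            images=rng.uniform(size=(n, 16, 16)).astype(np.float32),
            true_labels=np.zeros((n, L), dtype=np.int8),
            train_labels=np.zeros((n, L), dtype=np.int8),
            view=np.ones(n, dtype=np.int8),
            ids=[f"im{i}" for i in range(n)])

    def test_only_negative_self_annotations_excluded(self):
        ds = self._dataset()
        dec = self._decisions([
            ("im0", 0, "self-annotation", 0, 0.9),
            ("im0", 1, "self-annotation", 0, 0.9),
            ("im1", 0, "self-annotation", 1, 0.9),
            ("im1", 1, "re-annotation", -1, 0.1),
        ])
        out = select_for_retraining(dec, ds)
        assert out.ids == ["im1"]
        assert out.train_labels.tolist() == [[1, -1]]

    def test_test_set_membership_excludes(self):
        ds = self._dataset()
        dec = self._decisions([("im2", 0, "self-annotation", 1, 0.9),
                               ("im2", 1, "self-annotation", 0, 0.9)])
        out = select_for_retraining(dec, ds, test_ids={"im2"})
        assert out.n_images == 0

    def test_twenty_decision_fixture_matches_bruteforce_filter(self):
        rng = np.random.default_rng(6)
        ds = self._dataset(n=10, L=2)
        rows = []
        for i in range(10):
            for c in range(2):
                a = int(rng.choice([1, 0, -1]))
                rows.append((f"im{i}", c,
                             "re-annotation" if a == -1 else "self-annotation",
                             a, rng.uniform()))
        dec = self._decisions(rows)
        test_ids = {"im3", "im7"}
        out = select_for_retraining(dec, ds, test_ids=test_ids)
        assigned = {f"im{i}": [None, None] for i in range(10)}
        for r in rows:
            assigned[r[0]][r[1]] = r[3]
        expect = [i for i in (f"im{k}" for k in range(10))
                  if i not in test_ids and any(v == 1 for v in assigned[i])]
        assert out.ids == expect
        for img_id, lab in zip(out.ids, out.train_labels):
            assert list(lab) == assigned[img_id]


class TestAutolabelEndToEnd:
    def test_sentinel_thresholds_label_nothing_positive(self, small_fit):
        from psimlabel.labeler import autolabel_records
        model, res = small_fit
        records = res.score(model.test_set.images[:10], model.test_set.ids[:10])
        c = ModeSelectionConfig(th_pos=0.5,
                                theta_ppv1=np.ones(2) * 1.0 + 1e-9,
                                theta_npv1=np.ones(2) * 1.0 + 1e-9,
                                ppv1_attainable=np.zeros(2, bool),
                                npv1_attainable=np.zeros(2, bool))
        df, summary = autolabel_records(records, c)
        assert (df.assigned == -1).all()

    def test_zero_thresholds_capture_everything(self, small_fit):
        from psimlabel.labeler import autolabel_records
        model, res = small_fit
        records = res.score(model.test_set.images[:10], model.test_set.ids[:10])
        c = cfg(tp=0.0, tn=0.0, L=2)
        df, summary = autolabel_records(records, c)
        assert (df.assigned != -1).all()
        assert all(v["capture_fraction"] == 1.0 for v in summary.values())

    def test_decisions_match_bruteforce_box_rule(self, small_fit):
        from psimlabel.labeler import autolabel_records
        model, res = small_fit
        records = res.score(model.test_set.images[:20], model.test_set.ids[:20])
        c = cfg(tp=0.3, tn=0.6, L=2)
        df, _ = autolabel_records(records, c)
        for r, row in zip(records, df.itertuples()):
            if r.predicted_prob >= 0.5:
                expect = 1 if r.psim_positive >= 0.3 else -1
            else:
                expect = 0 if r.psim_negative >= 0.6 else -1
            assert row.assigned == expect
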