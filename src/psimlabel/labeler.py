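"""The auto-labeling decision layer.

Mode selection follows the two-branch rule: an image is a *positive
candidate* for label c when its predicted probability y^c >= TH_pos, in
which case the positive-side pSim (harmonic mean of Confidence_P and patch
similarity) is compared against the label's calibrated threshold
theta_PPV1; otherwise the negative-side pSim (Confidence_N) is compared
against theta_NPV1.  Above threshold the label is emitted (*self-annotation*:
1 or 0); below it the cell is deferred to a human (*re-annotation*: -1).

Thresholds are calibrated on a small reader-labeled subset sampled evenly
from ten pSim bins, by taking the lowest grid threshold at which PPV
(positive side) or NPV (negative side) reaches 1 with at least one captured
record; they are then frozen and applied to full datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthgen import LabeledImageSet

__all__ = [
    "ModeSelectionConfig",
    "ModeDecision",
    "ThresholdTable",
    "CalibrationSample",
    "mode_select",
    "stratified_bin_sample",
    "ppv_npv_curves",
    "select_thresholds",
    "tpcr_by_scoring_mode",
    "tpcr_at_capture",
    "autolabel_records",
    "autolabel_dataset",
    "select_for_retraining",
    "default_grid",
]

SENTINEL_THRESHOLD = 1.0   # used when PPV/NPV = 1 is unattainable
DEFAULT_TH_POS = 0.5


def default_grid(step: float = 0.01) -> np.ndarray:
    """Threshold grid 0.00..1.00; two-decimal steps by default."""
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


@dataclass
class ModeSelectionConfig:
    """TH_pos plus the per-label calibrated pSim thresholds."""

    th_pos: float = DEFAULT_TH_POS
    theta_ppv1: np.ndarray = None   # (L,)
    theta_npv1: np.ndarray = None   # (L,)
    ppv1_attainable: np.ndarray = None
    npv1_attainable: np.ndarray = None

    def __post_init__(self):
        if not 0.0 < self.th_pos < 1.0:
            raise ValueError("th_pos must lie in (0, 1)")


@dataclass(frozen=True)
class ModeDecision:
    image_id: str
    label: int
    mode: str          # "self-annotation" | "re-annotation"
    assigned: int      # 1 | 0 | -1
    psim_used: float


def mode_select(record, config: ModeSelectionConfig) -> ModeDecision:
    """Apply the two-branch auto-labeling rule to one scored record."""
    c = record.label
    if record.predicted_prob >= config.th_pos:
        psim = record.psim_positive
        if psim >= config.theta_ppv1[c]:
            return ModeDecision(record.image_id, c, "self-annotation", 1, psim)
        return ModeDecision(record.image_id, c, "re-annotation", -1, psim)
    psim = record.psim_negative
    if psim >= config.theta_npv1[c]:
        return ModeDecision(record.image_id, c, "self-annotation", 0, psim)
    return ModeDecision(record.image_id, c, "re-annotation", -1, psim)


# ---------------------------------------------------------------------------
# calibration sampling


@dataclass
class CalibrationSample:
    positive_candidates: list    # records with y >= TH_pos, sampled by psim_positive bin
    negative_candidates: list    # records with y < TH_pos, sampled by psim_negative bin

    @property
    def all(self) -> list:
        return self.positive_candidates + self.negative_candidates


def _bin_sample(records, scores, per_bin: int, rng) -> list:
    """Sample up to per_bin records from each of the ten bins
    [0,0.1), ..., [0.8,0.9), [0.9,1.0] without replacement."""
    edges = np.linspace(0.0, 1.0, 11)
    out = []
    scores = np.asarray(scores)
    for b in range(10):
        lo, hi = edges[b], edges[b + 1]
        if b == 9:
            mask = (scores >= lo) & (scores <= hi)
        else:
            mask = (scores >= lo) & (scores < hi)
        idx = np.flatnonzero(mask)
        if len(idx) > per_bin:
            idx = rng.choice(idx, size=per_bin, replace=False)
        out.extend(records[i] for i in sorted(idx))
    return out


def stratified_bin_sample(records, per_bin: int = 10, rng_seed: int = 0,
                          th_pos: float = DEFAULT_TH_POS) -> CalibrationSample:
    """Ten-bin stratified calibration subset for one label, drawn separately
    for model-positive and model-negative candidates (up to 100 each)."""
    rng = np.random.default_rng(rng_seed)
    pos = [r for r in records if r.predicted_prob >= th_pos]
    neg = [r for r in records if r.predicted_prob < th_pos]
    pos_sample = _bin_sample(pos, [r.psim_positive for r in pos], per_bin, rng)
    neg_sample = _bin_sample(neg, [r.psim_negative for r in neg], per_bin, rng)
    return CalibrationSample(pos_sample, neg_sample)


# ---------------------------------------------------------------------------
# PPV/NPV/TPCR/TNCR curves and threshold selection


@dataclass
class ThresholdTable:
    """Per-label curves over the pSim threshold grid.

    PPV = TP/captured positives, NPV = TN/captured negatives (NaN at zero
    capture — never reported as 1), TPCR/TNCR = captured true positives
    (negatives) over all ground-truth positives (negatives) in the record
    set.  theta_ppv1/theta_npv1 are the lowest grid thresholds reaching
    PPV = 1 / NPV = 1 with at least one captured record; unattainable sides
    get the sentinel 1.0 and a False flag.
    """

    label: int
    grid: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    tpcr: np.ndarray
    tncr: np.ndarray
    captured_pos: np.ndarray
    captured_neg: np.ndarray
    theta_ppv1: float = SENTINEL_THRESHOLD
    theta_npv1: float = SENTINEL_THRESHOLD
    ppv1_attainable: bool = False
    npv1_attainable: bool = False


def _lookup_gt(gt, records) -> np.ndarray:
    if isinstance(gt, dict):
        missing = [r.image_id for r in records if r.image_id not in gt]
        if missing:
            raise ValueError(f"missing ground truth for ids {missing[:10]}")
        return np.array([gt[r.image_id] for r in records], dtype=int)
    gt = np.asarray(gt, dtype=int)
    if len(gt) != len(records):
        raise ValueError("gt must align with records")
    return gt


def ppv_npv_curves(records, gt, grid=None, th_pos: float = DEFAULT_TH_POS) -> ThresholdTable:
    """Compute all four curves for one label's records against ground truth.

    ``gt`` is a dict image_id -> {0,1} or an aligned array.  Model-positive
    records are captured by psim_positive >= theta, model-negative records
    by psim_negative >= theta.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    truth = _lookup_gt(gt, records)
    y = np.array([r.predicted_prob for r in records])
    s_pos = np.array([r.psim_positive for r in records])
    s_neg = np.array([r.psim_negative for r in records])
    is_pos_cand = y >= th_pos

    total_gt_pos = int((truth == 1).sum())
    total_gt_neg = int((truth == 0).sum())

    n_grid = len(grid)
    ppv = np.full(n_grid, np.nan)
    npv = np.full(n_grid, np.nan)
    tpcr = np.zeros(n_grid)
    tncr = np.zeros(n_grid)
    cap_pos = np.zeros(n_grid, dtype=int)
    cap_neg = np.zeros(n_grid, dtype=int)
    for i, theta in enumerate(grid):
        captured_p = is_pos_cand & (s_pos >= theta)
        tp = int((captured_p & (truth == 1)).sum())
        cap_pos[i] = int(captured_p.sum())
        if cap_pos[i] > 0:
            ppv[i] = tp / cap_pos[i]
        if total_gt_pos > 0:
            tpcr[i] = tp / total_gt_pos
        captured_n = (~is_pos_cand) & (s_neg >= theta)
        tn = int((captured_n & (truth == 0)).sum())
        cap_neg[i] = int(captured_n.sum())
        if cap_neg[i] > 0:
            npv[i] = tn / cap_neg[i]
        if total_gt_neg > 0:
            tncr[i] = tn / total_gt_neg

    table = ThresholdTable(label=records[0].label, grid=grid, ppv=ppv, npv=npv,
                           tpcr=tpcr, tncr=tncr, captured_pos=cap_pos,
                           captured_neg=cap_neg)
    select_thresholds(table)
    return table


def select_thresholds(table: ThresholdTable) -> tuple:
    """Lowest grid threshold with PPV = 1 (resp. NPV = 1) and >= 1 captured
    record; sentinel 1.0 with the attainable flag False otherwise.  Updates
    the table in place and returns (theta_ppv1, theta_npv1)."""
    ok_p = np.flatnonzero((table.ppv == 1.0) & (table.captured_pos >= 1))
    ok_n = np.flatnonzero((table.npv == 1.0) & (table.captured_neg >= 1))
    if ok_p.size:
        table.theta_ppv1 = float(table.grid[ok_p[0]])
        table.ppv1_attainable = True
    else:
        table.theta_ppv1, table.ppv1_attainable = SENTINEL_THRESHOLD, False
    if ok_n.size:
        table.theta_npv1 = float(table.grid[ok_n[0]])
        table.npv1_attainable = True
    else:
        table.theta_npv1, table.npv1_attainable = SENTINEL_THRESHOLD, False
    return table.theta_ppv1, table.theta_npv1


_MODE_SCORES = {
    "confidence": lambda r: r.confidence_P,
    "patch_similarity": lambda r: r.patch_similarity,
    "psim": lambda r: r.psim_positive,
}


def tpcr_by_scoring_mode(records, gt, grid=None, mode: str = "all",
                         th_pos: float = DEFAULT_TH_POS):
    """True-positive capture-rate curves with the capture score swapped:
    confidence alone, patch similarity alone, or their harmonic mean (pSim).

    Returns {mode: (tpcr_curve, captured_counts)} over the grid; ``mode``
    may name a single scorer or ``"all"``.
    """
    records = list(records)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    truth = _lookup_gt(gt, records)
    y = np.array([r.predicted_prob for r in records])
    is_pos_cand = y >= th_pos
    total_gt_pos = int((truth == 1).sum())
    modes = list(_MODE_SCORES) if mode == "all" else [mode]
    out = {}
    for m in modes:
        score = np.array([_MODE_SCORES[m](r) for r in records])
        tpcr = np.zeros(len(grid))
        cap = np.zeros(len(grid), dtype=int)
        for i, theta in enumerate(grid):
            captured = is_pos_cand & (score >= theta)
            cap[i] = int(captured.sum())
            if total_gt_pos > 0:
                tpcr[i] = int((captured & (truth == 1)).sum()) / total_gt_pos
        out[m] = (tpcr, cap)
    return out


def tpcr_at_capture(records, gt, mode: str, fractions,
                    th_pos: float = DEFAULT_TH_POS) -> np.ndarray:
    """TPCR at matched capture levels: among positive candidates ranked by
    the mode's score, capture the top ceil(f * n) and count the ground-truth
    positives captured, per requested fraction f.  This compares scorers at
    identical labeling effort."""
    records = [r for r in records if r.predicted_prob >= th_pos]
    truth = _lookup_gt(gt, records)
    score = np.array([_MODE_SCORES[mode](r) for r in records])
    total_gt_pos = int((truth == 1).sum())
    if total_gt_pos == 0 or len(records) == 0:
        return np.zeros(len(list(fractions)))
    order = np.argsort(-score, kind="stable")
    out = []
    for f in fractions:
        k = int(np.ceil(f * len(records)))
        captured = order[:k]
        out.append(int((truth[captured] == 1).sum()) / total_gt_pos)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# dataset-level auto-labeling


def autolabel_records(records, config: ModeSelectionConfig):
    """Apply mode selection to every scored record; returns the decision
    table and a per-label capture summary."""
    decisions = [mode_select(r, config) for r in records]
    df = pd.DataFrame([dict(image_id=d.image_id, label=d.label, mode=d.mode,
                            assigned=d.assigned, psim=d.psim_used) for d in decisions])
    summary = {}
    for c, grp in df.groupby("label"):
        n = len(grp)
        summary[int(c)] = dict(
            n=n,
            self_positive=int((grp.assigned == 1).sum()),
            self_negative=int((grp.assigned == 0).sum()),
            reannotation=int((grp.assigned == -1).sum()),
            capture_fraction=float((grp.assigned != -1).mean()) if n else 0.0,
        )
    return df, summary


def autolabel_dataset(ensemble, patch_atlas, dist_atlas, data: LabeledImageSet,
                      config: ModeSelectionConfig):
    """Score every image then apply mode selection (convenience wrapper)."""
    from .psim import score_dataset

    records = score_dataset(ensemble, patch_atlas, dist_atlas, data.images, data.ids)
    return autolabel_records(records, config)


def select_for_retraining(decisions: pd.DataFrame, dataset: LabeledImageSet,
                          test_ids=()) -> LabeledImageSet:
    """Build the fine-tuning set from auto-label decisions.

    Keeps images with at least one self-annotated *positive* label, drops
    anything whose id appears in the test set, and emits training labels
    with re-annotation cells set to ignore (-1)."""
    test_ids = set(test_ids)
    id_to_row = {img_id: i for i, img_id in enumerate(dataset.ids)}
    L = dataset.n_labels
    assigned = {}
    for rec in decisions.itertuples():
        assigned.setdefault(rec.image_id, [-1] * L)[rec.label] = rec.assigned
    keep_ids, keep_rows, labels = [], [], []
    for img_id, cells in assigned.items():
        if img_id in test_ids or img_id not in id_to_row:
            continue
        if not any(v == 1 for v in cells):
            continue
        keep_ids.append(img_id)
        keep_rows.append(id_to_row[img_id])
        labels.append(cells)
    if not keep_rows:
        return LabeledImageSet(
            images=dataset.images[:0], true_labels=dataset.true_labels[:0],
            train_labels=dataset.train_labels[:0], view=dataset.view[:0],
            ids=[], label_names=list(dataset.label_names))
    rows = np.asarray(keep_rows)
    return LabeledImageSet(
        images=dataset.images[rows],
        true_labels=dataset.true_labels[rows],
        train_labels=np.asarray(labels, dtype=np.int8),
        view=dataset.view[rows],
        ids=keep_ids,
        label_names=list(dataset.label_names),
    )
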