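"""Model/Results facade and the end-to-end pipeline.

:class:`AtlasAutoLabeler` is built from a training set and a reader-labeled
calibration set; ``fit()`` trains the classifier ensemble, builds the
distribution and patch atlases, scores the calibration set, draws the
ten-bin stratified calibration subsets and selects the per-label pSim
thresholds at PPV/NPV = 1.  The returned :class:`AutoLabelResults` carries
the fitted artifacts and exposes scoring, auto-labeling, retraining-set
selection, fine-tuning, evaluation and a ``summary()`` table.

:func:`run_pipeline` chains synthesis, fitting, test evaluation,
auto-labeling of a fresh pool, fine-tuning and statistics into a single
machine-readable report, with every stage seeded from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import backbone, labeler, psim, stats, synthgen

__all__ = ["PipelineConfig", "AtlasAutoLabeler", "AutoLabelResults", "run_pipeline"]

DEFAULT_READER_ERRORS = (
    (0.02, 0.04), (0.03, 0.06), (0.04, 0.08), (0.05, 0.10),
    (0.03, 0.05), (0.06, 0.08), (0.04, 0.06),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions and tuning knobs of the desk-scale pipeline.

    The synthetic corpus defaults mirror the intended regime: three labels
    (one focal, one global, one mixed finding), prevalence 0.3, NLP-style
    label-noise rate 0.1, a seven-reader consensus panel on the calibration
    set, 2000/400/400 train/calibration/test images at 64 x 64.
    """

    # synthetic corpus
    image_height: int = 64
    image_width: int = 64
    n_labels: int = 3
    finding_kinds: tuple = ("focal", "global", "mixed")
    prevalence: float = 0.3
    label_noise_rate: float = 0.1
    ignore_rate: float = 0.0
    view_fraction: float = 0.8
    n_train: int = 2000
    n_calibration: int = 400
    n_test: int = 400
    n_pool: int = 400
    n_readers: int = 7
    reader_error_rates: tuple = DEFAULT_READER_ERRORS
    # backbone
    omegas: tuple = (1.1, 1.5)
    epochs: int = 16
    batch_size: int = 32
    learning_rate: float = 3e-3
    augmentation: bool = False
    # atlases
    tau: float = atlas_mod.DEFAULT_TAU
    inclusion_threshold: float = atlas_mod.DEFAULT_INCLUSION_THRESHOLD
    K: int = atlas_mod.DEFAULT_K
    D: int = atlas_mod.DEFAULT_D
    embedding_kind: str = "umap"
    # labeler
    th_pos: float = labeler.DEFAULT_TH_POS
    per_bin: int = 10
    grid_step: float = 0.01
    # fine-tuning
    finetune_learning_rate: float = 1e-5
    finetune_epochs: int = 1
    # statistics
    bootstrap_resamples: int = 200
    ci_level: float = 0.95
    binomial_method: str = "wald"
    # seeding
    master_seed: int = 0

    def stage_seeds(self) -> dict:
        """Deterministic per-stage seeds fanned out from the master seed."""
        state = np.random.SeedSequence(self.master_seed).generate_state(8) % (2 ** 31)
        names = ["synth_train", "synth_calibration", "synth_test", "synth_pool",
                 "training", "embedding", "calibration_sampling", "bootstrap"]
        return {k: int(v) for k, v in zip(names, state)}

    def train_config(self, seed: int) -> backbone.TrainConfig:
        return backbone.TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, augmentation=self.augmentation, rng_seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("finding_kinds", "omegas"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "reader_error_rates" in d:
            d["reader_error_rates"] = tuple(tuple(p) for p in d["reader_error_rates"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _synth_config(cfg: PipelineConfig, seed: int, with_readers: bool) -> synthgen.SynthConfig:
    return synthgen.SynthConfig(
        image_height=cfg.image_height, image_width=cfg.image_width,
        n_labels=cfg.n_labels, finding_kind_per_label=tuple(cfg.finding_kinds),
        prevalence_per_label=tuple([cfg.prevalence] * cfg.n_labels),
        label_noise_rate=cfg.label_noise_rate, ignore_rate=cfg.ignore_rate,
        n_readers=cfg.n_readers if with_readers else 0,
        reader_error_rates=tuple(cfg.reader_error_rates[:cfg.n_readers]) if with_readers else (),
        view_fraction=cfg.view_fraction, rng_seed=seed)


def generate_study_data(cfg: PipelineConfig):
    """Train / calibration / test / pool sets under the configured study
    conditions; only the calibration set carries the reader panel."""
    seeds = cfg.stage_seeds()
    train = synthgen.generate_dataset(_synth_config(cfg, seeds["synth_train"], False),
                                      cfg.n_train, id_prefix="tr")
    cal = synthgen.generate_dataset(_synth_config(cfg, seeds["synth_calibration"], True),
                                    cfg.n_calibration, id_prefix="ca")
    test = synthgen.generate_dataset(_synth_config(cfg, seeds["synth_test"], False),
                                     cfg.n_test, id_prefix="te")
    pool = synthgen.generate_dataset(_synth_config(cfg, seeds["synth_pool"], False),
                                     cfg.n_pool, id_prefix="po")
    return train, cal, test, pool


class AtlasAutoLabeler:
    """Auto-labeling model: ensemble + atlases + calibrated thresholds.

    Parameters
    ----------
    train_set : LabeledImageSet
        Images with (possibly noisy) tri-valued training labels; used to
        train the ensemble and build both atlases.
    calibration_set : LabeledImageSet
        Independent images with reader-consensus (or otherwise trusted)
        ground truth; used only to select the pSim thresholds.
    config : PipelineConfig
    """

    def __init__(self, train_set: synthgen.LabeledImageSet,
                 calibration_set: synthgen.LabeledImageSet,
                 config: PipelineConfig = PipelineConfig()):
        self.train_set = train_set
        self.calibration_set = calibration_set
        self.config = config

    @classmethod
    def from_config(cls, config: PipelineConfig):
        """Generate the synthetic study data and build the model from it."""
        train, cal, test, pool = generate_study_data(config)
        m = cls(train, cal, config)
        m.test_set, m.pool_set = test, pool
        return m

    def fit(self, ensemble: backbone.EnsembleModel | None = None) -> "AutoLabelResults":
        cfg = self.config
        seeds = cfg.stage_seeds()
        if ensemble is None:
            ensemble = backbone.build_ensemble(
                self.train_set, cfg.omegas, cfg.train_config(seeds["training"]))
        dist_atlas = atlas_mod.build_distribution_atlas(ensemble, self.train_set)
        patch_atlas = atlas_mod.build_patch_atlas(
            ensemble, self.train_set, inclusion_threshold=cfg.inclusion_threshold,
            K=cfg.K, tau=cfg.tau, embed_seed=seeds["embedding"], D=cfg.D,
            embedding_kind=cfg.embedding_kind)
        cal_records = psim.score_dataset(ensemble, patch_atlas, dist_atlas,
                                         self.calibration_set.images,
                                         self.calibration_set.ids)
        gt_matrix = (self.calibration_set.consensus_gt
                     if self.calibration_set.consensus_gt is not None
                     else self.calibration_set.true_labels)
        grid = labeler.default_grid(cfg.grid_step)
        tables, samples = [], []
        theta_p = np.ones(cfg.n_labels)
        theta_n = np.ones(cfg.n_labels)
        att_p = np.zeros(cfg.n_labels, dtype=bool)
        att_n = np.zeros(cfg.n_labels, dtype=bool)
        id_to_row = {img_id: i for i, img_id in enumerate(self.calibration_set.ids)}
        for c in range(cfg.n_labels):
            recs_c = [r for r in cal_records if r.label == c]
            sample = labeler.stratified_bin_sample(
                recs_c, per_bin=cfg.per_bin,
                rng_seed=seeds["calibration_sampling"] + c, th_pos=cfg.th_pos)
            gt = {r.image_id: int(gt_matrix[id_to_row[r.image_id], c]) for r in sample.all}
            table = labeler.ppv_npv_curves(sample.all, gt, grid, th_pos=cfg.th_pos)
            tables.append(table)
            samples.append(sample)
            theta_p[c], theta_n[c] = table.theta_ppv1, table.theta_npv1
            att_p[c], att_n[c] = table.ppv1_attainable, table.npv1_attainable
        mode_config = labeler.ModeSelectionConfig(
            th_pos=cfg.th_pos, theta_ppv1=theta_p, theta_npv1=theta_n,
            ppv1_attainable=att_p, npv1_attainable=att_n)
        return AutoLabelResults(
            model=self, ensemble=ensemble, patch_atlas=patch_atlas,
            dist_atlas=dist_atlas, threshold_tables=tables,
            calibration_samples=samples, calibration_records=cal_records,
            mode_config=mode_config)


@dataclass
class AutoLabelResults:
    """Fitted auto-labeler: the ensemble, both atlases, the per-label
    threshold tables and the frozen mode-selection configuration."""

    model: AtlasAutoLabeler
    ensemble: backbone.EnsembleModel
    patch_atlas: atlas_mod.PatchAtlas
    dist_atlas: atlas_mod.DistributionAtlas
    threshold_tables: list
    calibration_samples: list
    calibration_records: list
    mode_config: labeler.ModeSelectionConfig
    finetuned: bool = False

    @property
    def label_names(self) -> list:
        return self.dist_atlas.label_names

    # -- scoring and labeling ---------------------------------------------

    def score(self, images, ids=None) -> list:
        return psim.score_dataset(self.ensemble, self.patch_atlas,
                                  self.dist_atlas, images, ids)

    def score_frame(self, images, ids=None) -> pd.DataFrame:
        return psim.records_to_frame(self.score(images, ids))

    def autolabel(self, dataset: synthgen.LabeledImageSet):
        return labeler.autolabel_dataset(self.ensemble, self.patch_atlas,
                                         self.dist_atlas, dataset, self.mode_config)

    def select_for_retraining(self, decisions: pd.DataFrame,
                              dataset: synthgen.LabeledImageSet,
                              test_ids=()) -> synthgen.LabeledImageSet:
        return labeler.select_for_retraining(decisions, dataset, test_ids)

    def finetune(self, autolabeled: synthgen.LabeledImageSet,
                 test_ids=()) -> "AutoLabelResults":
        """Continue training on original + auto-labeled data at the small
        fine-tuning rate; atlases and thresholds stay frozen (they describe
        the validated model that produced the labels)."""
        cfg = self.model.config
        new_ensemble = backbone.finetune(
            self.ensemble, self.model.train_set, autolabeled,
            cfg.finetune_learning_rate, test_ids=test_ids,
            epochs=cfg.finetune_epochs,
            config=cfg.train_config(cfg.stage_seeds()["training"]))
        return replace(self, ensemble=new_ensemble, finetuned=True)

    # -- evaluation ---------------------------------------------------------

    def evaluate_auroc(self, dataset: synthgen.LabeledImageSet) -> dict:
        """Per-label AUROC of the ensemble probability against true labels."""
        probs = self.ensemble.predict_proba(dataset.images)[:, :self.ensemble.n_labels]
        return {self.label_names[c]: stats.auroc(probs[:, c], dataset.true_labels[:, c])
                for c in range(self.ensemble.n_labels)}

    def summary(self) -> str:
        """Human-readable per-label calibration summary."""
        cfg = self.model.config
        lines = [
            "Atlas-based auto-labeler" + (" (fine-tuned)" if self.finetuned else ""),
            f"  members: {len(self.ensemble.members)} (omegas "
            f"{list(self.ensemble.member_omegas)}), TH_pos = {cfg.th_pos}",
            f"  patch atlas: K={self.patch_atlas.K}, tau={self.patch_atlas.tau}, "
            f"inclusion >= {self.patch_atlas.inclusion_threshold}",
            "",
            f"  {'label':<12}{'atlas n':>8}{'theta_PPV1':>12}{'theta_NPV1':>12}"
            f"{'PPV@theta':>11}{'NPV@theta':>11}",
        ]
        for c, table in enumerate(self.threshold_tables):
            ip = int(np.searchsorted(table.grid, table.theta_ppv1))
            iq = int(np.searchsorted(table.grid, table.theta_npv1))
            ppv_at = table.ppv[ip] if table.ppv1_attainable else float("nan")
            npv_at = table.npv[iq] if table.npv1_attainable else float("nan")
            tp = f"{table.theta_ppv1:.2f}" + ("" if table.ppv1_attainable else "*")
            tn = f"{table.theta_npv1:.2f}" + ("" if table.npv1_attainable else "*")
            lines.append(
                f"  {self.label_names[c]:<12}{len(self.patch_atlas.patches[c]):>8}"
                f"{tp:>12}{tn:>12}{ppv_at:>11.3f}{npv_at:>11.3f}")
        if not (self.mode_config.ppv1_attainable.all()
                and self.mode_config.npv1_attainable.all()):
            lines.append("  * PPV/NPV = 1 unattainable on the calibration subset; "
                         "sentinel 1.0 (nothing auto-labeled on that side)")
        return "\n".join(lines)

    def plot_threshold_curves(self, label: int, path) -> None:
        """Export the four calibration curves for one label as a PNG."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.threshold_tables[label]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(t.grid, t.ppv, label="PPV")
        ax.plot(t.grid, t.npv, label="NPV")
        ax.plot(t.grid, t.tpcr, label="TPCR", ls="--")
        ax.plot(t.grid, t.tncr, label="TNCR", ls="--")
        ax.axvline(t.theta_ppv1, color="k", lw=0.8)
        ax.set_xlabel("pSim threshold")
        ax.set_ylabel("rate")
        ax.set_title(self.label_names[label])
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.ensemble.save(d / "ensemble")
        self.patch_atlas.save(d / "patch_atlas")
        self.dist_atlas.save(d / "dist_atlas")
        thresholds = dict(
            th_pos=self.mode_config.th_pos,
            theta_ppv1=[float(x) for x in self.mode_config.theta_ppv1],
            theta_npv1=[float(x) for x in self.mode_config.theta_npv1],
            ppv1_attainable=[bool(x) for x in self.mode_config.ppv1_attainable],
            npv1_attainable=[bool(x) for x in self.mode_config.npv1_attainable],
            label_names=self.label_names)
        (d / "thresholds.json").write_text(json.dumps(thresholds, indent=2))


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _round(x, nd=10):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _round(x.tolist(), nd)
    return x


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class _stage:
    def __init__(self, name):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineStageError):
            raise PipelineStageError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Synthesize -> train -> atlases -> calibrate -> evaluate -> autolabel
    -> fine-tune -> statistics; returns (and optionally writes) the report.

    Identical configs produce byte-identical reports.  A failing stage
    aborts with the stage name and cause.
    """
    cfg = config
    seeds = cfg.stage_seeds()
    with _stage("synth"):
        train, cal, test, pool = generate_study_data(cfg)

    with _stage("fit"):
        model = AtlasAutoLabeler(train, cal, cfg)
        res = model.fit()
    label_names = res.label_names

    auroc_before = res.evaluate_auroc(test)

    # held-out test diagnostics at the frozen thresholds
    with _stage("score-test"):
        test_records = res.score(test.images, test.ids)
    grid = labeler.default_grid(cfg.grid_step)
    id_to_row = {img_id: i for i, img_id in enumerate(test.ids)}
    fractions = np.arange(0.1, 1.0, 0.1)
    test_eval, tpcr_modes = {}, {}
    for c, name in enumerate(label_names):
        recs = [r for r in test_records if r.label == c]
        gt = {r.image_id: int(test.true_labels[id_to_row[r.image_id], c]) for r in recs}
        table = labeler.ppv_npv_curves(recs, gt, grid, th_pos=cfg.th_pos)
        ip = int(np.searchsorted(grid, res.mode_config.theta_ppv1[c]))
        iq = int(np.searchsorted(grid, res.mode_config.theta_npv1[c]))
        test_eval[name] = dict(
            theta_ppv1=float(res.mode_config.theta_ppv1[c]),
            theta_npv1=float(res.mode_config.theta_npv1[c]),
            ppv1_attainable=bool(res.mode_config.ppv1_attainable[c]),
            npv1_attainable=bool(res.mode_config.npv1_attainable[c]),
            ppv_at_zero=float(table.ppv[0]),
            ppv_at_theta=float(table.ppv[ip]) if table.captured_pos[ip] else None,
            npv_at_zero=float(table.npv[0]),
            npv_at_theta=float(table.npv[iq]) if table.captured_neg[iq] else None,
            capture_pos_at_zero=int(table.captured_pos[0]),
            capture_pos_at_theta=int(table.captured_pos[ip]),
            capture_neg_at_zero=int(table.captured_neg[0]),
            capture_neg_at_theta=int(table.captured_neg[iq]),
            tpcr_at_theta=float(table.tpcr[ip]),
            tncr_at_theta=float(table.tncr[iq]),
        )
        tpcr_modes[name] = {
            m: [float(v) for v in labeler.tpcr_at_capture(recs, gt, m, fractions,
                                                          th_pos=cfg.th_pos)]
            for m in ("confidence", "patch_similarity", "psim")}

    # auto-label a fresh pool and fine-tune on the selected exams
    with _stage("autolabel"):
        decisions, capture_summary = res.autolabel(pool)
        retrain = res.select_for_retraining(decisions, pool, test_ids=test.ids)
    with _stage("finetune"):
        res_ft = res.finetune(retrain, test_ids=test.ids)
    auroc_after = res_ft.evaluate_auroc(test)

    # statistics
    probs = res.ensemble.predict_proba(test.images)[:, :cfg.n_labels]
    boot_cfg = stats.BootstrapConfig(n_resamples=cfg.bootstrap_resamples,
                                     ci_level=cfg.ci_level,
                                     rng_seed=seeds["bootstrap"])
    auroc_ci = {}
    for c, name in enumerate(label_names):
        point, lo, hi = stats.bootstrap_ci(probs[:, c], test.true_labels[:, c],
                                           config=boot_cfg)
        auroc_ci[name] = dict(point=point, lower=lo, upper=hi)
    kappa = {}
    if cal.reader_ratings is not None:
        for c, name in enumerate(label_names):
            km = stats.pairwise_kappa(cal.reader_ratings[:, c, :])
            off = km.matrix[~np.eye(len(km.raters), dtype=bool)]
            kappa[name] = dict(matrix=km.matrix.tolist(),
                               mean_pairwise=float(off.mean()))

    report = dict(
        config=cfg.to_dict(),
        seeds=seeds,
        label_names=label_names,
        ensemble=dict(n_members=len(res.ensemble.members),
                      member_omegas=[float(w) for w in res.ensemble.member_omegas]),
        atlas_counts=[len(p) for p in res.patch_atlas.patches],
        auroc_before_finetune=auroc_before,
        auroc_after_finetune=auroc_after,
        auroc_bootstrap_ci=auroc_ci,
        binomial_ci_method=cfg.binomial_method,
        test_thresholds=test_eval,
        tpcr_at_matched_capture=tpcr_modes,
        capture_fractions=[float(f) for f in fractions],
        pool_capture_summary={label_names[c]: v for c, v in capture_summary.items()},
        n_retrain_selected=int(retrain.n_images),
        reader_kappa=kappa,
    )
    report = _round(report)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
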