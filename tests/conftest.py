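"""Shared fixtures: tiny synthetic datasets, stub models, a small fitted
pipeline reused by scoring/labeling tests."""

from __future__ import annotations

import numpy as np
import pytest

import psimlabel as pl
from psimlabel.atlas import PatchAtlas
from psimlabel.model import AtlasAutoLabeler, PipelineConfig


class IdentityEmbedding:
    """Deterministic stand-in embedding: first two vector components."""

    def fit(self, X):
        return self

    def transform(self, X):
        return np.asarray(X, dtype=np.float64)[:, :2]

    def fit_transform(self, X):
        return self.transform(X)


def make_patch_atlas(coords_per_label, K=2, D=4):
    """Build a PatchAtlas directly from 2-D coordinates (identity embedding);
    vectors are the coordinates padded to length D."""
    from psimlabel.atlas import Patch, _leave_self_out_fd

    patches, coords, fd = [], [], []
    for c, pts in enumerate(coords_per_label):
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
        plist = []
        for i, p in enumerate(pts):
            vec = np.zeros(D)
            vec[:2] = p
            plist.append(Patch(bbox=(0, 0, 2, 2), vector=vec,
                               source_image_id=f"atlas{c}_{i}", label=c))
        patches.append(plist)
        coords.append(pts)
        fd.append(_leave_self_out_fd(pts, K) if len(pts) >= K + 1 else np.zeros(0))
    return PatchAtlas(embedding=IdentityEmbedding(), patches=patches, coords=coords,
                      fd_reference=fd, K=K, D=D, tau=0.0, inclusion_threshold=0.9,
                      embed_seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = pl.SynthConfig(image_height=32, image_width=32, n_labels=2,
                         finding_kind_per_label=("focal", "global"),
                         prevalence_per_label=(0.4, 0.4), label_noise_rate=0.0,
                         rng_seed=11)
    return pl.generate_dataset(cfg, 80)


@pytest.fixture(scope="session")
def small_fit():
    """A small but real fitted auto-labeler (fast projection embedding)."""
    cfg = PipelineConfig(
        image_height=32, image_width=32, n_labels=2,
        finding_kinds=("focal", "global"), prevalence=0.4,
        label_noise_rate=0.05, n_train=240, n_calibration=120, n_test=80,
        n_pool=80, n_readers=3,
        reader_error_rates=((0.02, 0.04), (0.03, 0.06), (0.04, 0.08)),
        epochs=6, embedding_kind="projection", bootstrap_resamples=20,
        master_seed=5)
    model = AtlasAutoLabeler.from_config(cfg)
    res = model.fit()
    return model, res
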