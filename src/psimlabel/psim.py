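"""Per-image, per-label pSim scoring.

For each pathology label the pipeline computes:

* the ensemble predicted probability y^c;
* the **prediction basis** — the K atlas patches nearest (Euclidean, in the
  shared 2-D embedding) to the input image's CAM patch, the evidence shown
  to a user;
* **patch similarity** = 1 - f_D(mean distance to the K-basis), where f_D is
  the percentile function of the atlas's own leave-self-out mean K-NN
  distances — near 1 when the input patch sits inside the atlas cloud,
  near 0 when it is an outlier;
* **confidence** — the rectified gap between the percentile of y^c in the
  positive training distribution and one minus its percentile in the
  negative distribution (at most one side is nonzero);
* **pSim** — for the positive side, the harmonic mean of Confidence_P and
  patch similarity; for the negative side, Confidence_N alone (a negative
  prediction asserts the absence of a finding, so there is no patch to
  match).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DistributionAtlas, PatchAtlas, ensemble_cam, extract_patches

__all__ = [
    "PSimRecord",
    "BasisRef",
    "prediction_basis",
    "patch_similarity",
    "confidence",
    "psim_value",
    "score_image",
    "score_dataset",
    "records_to_frame",
]


@dataclass(frozen=True)
class BasisRef:
    """One prediction-basis element: an atlas patch and its distance."""

    atlas_index: int
    source_image_id: str
    distance: float
    coord: tuple


@dataclass
class PSimRecord:
    image_id: str
    label: int
    predicted_prob: float
    patch_similarity: float          # 0 when no patch; see patch_available
    confidence_P: float
    confidence_N: float
    psim_positive: float
    psim_negative: float
    patch_available: bool = True     # False when the label's atlas is unavailable
    basis: list = field(default_factory=list)   # list[BasisRef]

    def validate(self) -> None:
        assert self.confidence_P * self.confidence_N == 0.0
        if self.patch_available:
            lo = min(self.confidence_P, self.patch_similarity)
            hi = max(self.confidence_P, self.patch_similarity)
            assert lo - 1e-12 <= self.psim_positive <= hi + 1e-12
        assert self.psim_negative == self.confidence_N


def psim_value(confidence_side: float, patch_sim: float) -> float:
    """Harmonic mean 2ab/(a+b), with 0 when a + b == 0 (annihilator)."""
    a, b = float(confidence_side), float(patch_sim)
    if a + b == 0.0:
        return 0.0
    return 2.0 * a * b / (a + b)


def confidence(y: float, dist_atlas: DistributionAtlas, c: int) -> tuple:
    """(Confidence_P, Confidence_N) for predicted probability y on label c.

    Confidence_P = max(f_P(y) - (1 - f_N(y)), 0) and mirrored for the
    negative side; a label with an empty positive or negative sample yields
    (0, 0)."""
    if not dist_atlas.available(c):
        return 0.0, 0.0
    fp = dist_atlas.f_P(c, y)
    fn = dist_atlas.f_N(c, y)
    return max(fp - (1.0 - fn), 0.0), max((1.0 - fn) - fp, 0.0)


def _knn_basis(coord: np.ndarray, atlas: PatchAtlas, c: int, K: int):
    """K nearest label-c atlas points to ``coord`` (stable ties by insertion
    order).  Returns (indices, distances)."""
    pts = atlas.coords[c]
    d = np.sqrt(((pts - coord) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:K]
    return order, d[order]


def prediction_basis(patch_vector: np.ndarray, atlas: PatchAtlas, c: int,
                     K: int | None = None):
    """The K atlas patches of label c nearest to the embedded input patch,
    ascending by distance; ``None`` when the label's atlas is unavailable."""
    if not atlas.available(c):
        return None
    K = K or atlas.K
    if K > len(atlas.coords[c]):
        raise ValueError(f"K={K} exceeds atlas size {len(atlas.coords[c])} for label {c}")
    coord = np.asarray(atlas.embedding.transform(np.asarray(patch_vector)[None, :]))[0]
    idx, dist = _knn_basis(coord, atlas, c, K)
    return [BasisRef(int(i), atlas.patches[c][i].source_image_id, float(dd),
                     tuple(atlas.coords[c][i])) for i, dd in zip(idx, dist)]


def _similarity_from_coords(coords: np.ndarray, atlas: PatchAtlas, c: int, K: int):
    """Per embedded patch: (similarity, basis indices, basis distances)."""
    out = []
    for coord in coords:
        idx, dist = _knn_basis(coord, atlas, c, K)
        sim = 1.0 - atlas.f_D(c, float(dist.mean()))
        out.append((sim, idx, dist))
    return out


def patch_similarity(patch_vectors, atlas: PatchAtlas, c: int,
                     K: int | None = None) -> float:
    """Patch similarity of an image from its 1-2 CAM patches: each patch is
    embedded, scored as 1 - f_D(mean distance to its K-basis), and the
    maximum over the image's patches is returned.  No patches -> 0."""
    vectors = list(patch_vectors)
    if not vectors:
        return 0.0
    if not atlas.available(c):
        raise ValueError(f"patch atlas unavailable for label {c}")
    K = K or atlas.K
    K = min(K, len(atlas.coords[c]))
    coords = np.asarray(atlas.embedding.transform(np.stack(vectors)))
    sims = [s for s, _, _ in _similarity_from_coords(coords, atlas, c, K)]
    return float(max(sims))


def _score_label_batch(ensemble, fmaps, images, ids, probs_c, c,
                       patch_atlas: PatchAtlas, dist_atlas: DistributionAtlas,
                       K: int, tau: float) -> list:
    """Score every image for one label; embedding transforms are batched."""
    n = len(images)
    weights = [m.class_weights(c) for m in ensemble.members]
    patch_lists = []
    for i in range(n):
        cams = [np.tensordot(w, fm[i], axes=1) for w, fm in zip(weights, fmaps)]
        ecam = ensemble_cam(cams, tau, label=c)
        patch_lists.append(extract_patches(ecam, images[i], 2, D=patch_atlas.D,
                                           source_image_id=ids[i], label=c))
    available = patch_atlas.available(c)
    sims = np.zeros(n)
    bases: list = [[] for _ in range(n)]
    if available:
        k_eff = min(K, len(patch_atlas.coords[c]))
        flat = [(i, p) for i, plist in enumerate(patch_lists) for p in plist]
        if flat:
            coords = np.asarray(patch_atlas.embedding.transform(
                np.stack([p.vector for _, p in flat])))
            scored = _similarity_from_coords(coords, patch_atlas, c, k_eff)
            best = {}
            for (i, _), (sim, idx, dist) in zip(flat, scored):
                if sim > sims[i] or i not in best:
                    sims[i] = max(sims[i], sim)
                    best[i] = (idx, dist)
            for i, (idx, dist) in best.items():
                bases[i] = [BasisRef(int(j), patch_atlas.patches[c][j].source_image_id,
                                     float(dd), tuple(patch_atlas.coords[c][j]))
                            for j, dd in zip(idx, dist)]
    records = []
    for i in range(n):
        y = float(probs_c[i])
        conf_p, conf_n = confidence(y, dist_atlas, c)
        if available:
            psim_pos = psim_value(conf_p, float(sims[i]))
        else:
            psim_pos = conf_p    # degrade: no patch channel for this label
        records.append(PSimRecord(
            image_id=ids[i], label=c, predicted_prob=y,
            patch_similarity=float(sims[i]), confidence_P=conf_p,
            confidence_N=conf_n, psim_positive=psim_pos, psim_negative=conf_n,
            patch_available=available, basis=bases[i]))
    return records


def score_dataset(ensemble, patch_atlas: PatchAtlas, dist_atlas: DistributionAtlas,
                  images, ids=None, K: int | None = None,
                  tau: float | None = None) -> list:
    """Score a stack of images; returns records ordered image-major
    (all labels of image 0, then image 1, ...)."""
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    n = len(images)
    ids = list(ids) if ids is not None else [f"img{i:06d}" for i in range(n)]
    if patch_atlas.n_labels != dist_atlas.n_labels or patch_atlas.n_labels != ensemble.n_labels:
        raise ValueError("ensemble and atlases must share one label set")
    K = K or patch_atlas.K
    tau = patch_atlas.tau if tau is None else tau
    probs = ensemble.predict_proba(images)[:, :ensemble.n_labels]
    fmaps = [m.feature_maps(images) for m in ensemble.members]
    per_label = [_score_label_batch(ensemble, fmaps, images, ids, probs[:, c], c,
                                    patch_atlas, dist_atlas, K, tau)
                 for c in range(ensemble.n_labels)]
    records = []
    for i in range(n):
        for c in range(ensemble.n_labels):
            records.append(per_label[c][i])
    return records


def score_image(ensemble, patch_atlas: PatchAtlas, dist_atlas: DistributionAtlas,
                image: np.ndarray, image_id: str = "query",
                K: int | None = None, tau: float | None = None) -> list:
    """One PSimRecord per pathology label for a single image."""
    return score_dataset(ensemble, patch_atlas, dist_atlas,
                         np.asarray(image)[None], [image_id], K=K, tau=tau)


def records_to_frame(records) -> pd.DataFrame:
    """Tabular scoring output; basis patch ids are semicolon-joined."""
    rows = []
    for r in records:
        rows.append(dict(
            image_id=r.image_id, label=r.label, y=r.predicted_prob,
            patch_similarity=r.patch_similarity, confidence_P=r.confidence_P,
            confidence_N=r.confidence_N, psim_positive=r.psim_positive,
            psim_negative=r.psim_negative, patch_available=r.patch_available,
            basis_ids=";".join(b.source_image_id for b in r.basis)))
    return pd.DataFrame(rows)
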