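"""Reference atlases derived from a trained ensemble and its training data.

Two atlases back the pSim score:

* the **distribution atlas** — per label, the empirical distributions of
  ensemble predicted probabilities on training images labeled positive and
  negative, defining the percentile functions f_P and f_N used by the
  confidence score;
* the **patch atlas** — per label, CAM-derived patches from training images
  the ensemble is highly certain about (predicted probability >= 0.9 by
  default), embedded into a shared 2-D space with cosine neighborhoods, plus
  the reference distribution f_D of each atlas point's mean distance to its
  K nearest same-label neighbors.

The ensemble CAM combines member CAMs by zeroing per-member values below a
noise threshold tau, summing, and min-max rescaling to [0, 1], which
sharpens regions where members agree.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.transform import resize

from .embeddings import make_embedding
from .synthgen import LabeledImageSet

__all__ = [
    "EnsembleCAMMap",
    "Patch",
    "PatchAtlas",
    "DistributionAtlas",
    "ensemble_cam",
    "extract_patches",
    "patch_to_vector",
    "build_patch_atlas",
    "build_distribution_atlas",
    "percentile",
]

DEFAULT_TAU = 0.3                # per-member CAM noise threshold
DEFAULT_INCLUSION_THRESHOLD = 0.9
DEFAULT_K = 5                    # prediction-basis size
DEFAULT_D = 1024                 # patch vector dimension (32 x 32)
CONTOUR_BETA = 0.5               # binarize ensemble CAM at beta * max
MIN_AREA_FRACTION = 0.001        # component floor: 0.1% of image area


def _minmax(arr: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1]; constant maps have no spatial
    information and become all zeros (all ones if constant positive after
    thresholding is meaningful upstream)."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    if hi > 0:
        return np.ones_like(arr)
    return np.zeros_like(arr)


@dataclass
class EnsembleCAMMap:
    label: int
    map: np.ndarray          # values in [0, 1]
    tau: float
    source_ids: list = field(default_factory=list)


def ensemble_cam(cams, tau: float, label: int = 0, source_ids=None) -> EnsembleCAMMap:
    """Combine member CAMs: per-member min-max normalization, zeroing of
    values below tau (unit step, boundary kept), summation, then min-max
    rescale.  An all-zero sum stays all zeros."""
    cams = [np.asarray(c, dtype=np.float64) for c in cams]
    if not cams:
        raise ValueError("need at least one CAM")
    shape = cams[0].shape
    for c in cams:
        if c.shape != shape:
            raise ValueError("member CAMs must share one shape")
    total = np.zeros(shape)
    for c in cams:
        norm = _minmax(c)
        total += norm * (norm >= tau)
    # the thresholded sum is non-negative, so the linear rescale to [0, 1]
    # divides by the peak; this preserves the support (zero stays zero), so
    # the ensemble CAM's support shrinks monotonically as tau grows
    peak = total.max()
    out = total / peak if peak > 0 else total
    return EnsembleCAMMap(label=label, map=out, tau=float(tau),
                          source_ids=list(source_ids or []))


@dataclass
class Patch:
    """A CAM-derived image patch: half-open bbox, its D-dim vector, and the
    provenance needed for explainability display."""

    bbox: tuple              # (row_min, col_min, row_max, col_max), half-open
    vector: np.ndarray
    source_image_id: str = ""
    label: int = -1
    predicted_prob: float = float("nan")


def patch_to_vector(image: np.ndarray, bbox, D: int = DEFAULT_D) -> np.ndarray:
    """Crop to bbox and bilinearly resample to sqrt(D) x sqrt(D), flattened
    row-major.  D must be a perfect square."""
    side = int(round(np.sqrt(D)))
    if side * side != D:
        raise ValueError(f"D must be a perfect square, got {D}")
    r0, c0, r1, c1 = bbox
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"degenerate bbox {bbox}")
    crop = np.asarray(image, dtype=np.float64)[r0:r1, c0:c1]
    if crop.shape == (side, side):
        return np.clip(crop, 0.0, 1.0).ravel()
    out = resize(crop, (side, side), order=1, mode="edge", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0).ravel()


def extract_patches(cam, image: np.ndarray, max_patches: int = 2, *,
                    beta: float = CONTOUR_BETA, min_area_fraction: float = MIN_AREA_FRACTION,
                    D: int = DEFAULT_D, source_image_id: str = "",
                    label: int = -1, predicted_prob: float = float("nan")) -> list:
    """Contour the ensemble CAM on the image grid and cut out up to
    ``max_patches`` bounding-box patches.

    The map is upsampled to image resolution (bilinear), binarized at
    ``beta * max``, and connected components above the minimum-area floor are
    kept largest-first (ties broken toward the top-left-most bbox).  An empty
    list is a valid outcome (blank CAM)."""
    cam_map = cam.map if isinstance(cam, EnsembleCAMMap) else np.asarray(cam, dtype=np.float64)
    h, w = image.shape
    if cam_map.shape != (h, w):
        cam_map = resize(cam_map, (h, w), order=1, mode="edge", anti_aliasing=False)
    peak = cam_map.max()
    if peak <= 0:
        return []
    mask = cam_map >= beta * peak
    labeled = measure.label(mask, connectivity=2)
    min_area = max(1.0, min_area_fraction * h * w)
    regions = [r for r in measure.regionprops(labeled) if r.area >= min_area]
    regions.sort(key=lambda r: (-r.area, r.bbox[0], r.bbox[1]))
    patches = []
    for r in regions[:max_patches]:
        bbox = tuple(int(b) for b in r.bbox)
        patches.append(Patch(bbox=bbox, vector=patch_to_vector(image, bbox, D),
                             source_image_id=source_image_id, label=label,
                             predicted_prob=predicted_prob))
    return patches


# ---------------------------------------------------------------------------
# percentile (right-continuous empirical CDF)


def percentile(sorted_sample: np.ndarray, value) -> float:
    """(# entries <= value) / n over an ascending sample; ties count as <=."""
    s = np.asarray(sorted_sample, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty sample")
    return float(np.searchsorted(s, value, side="right") / s.size)


def percentile_many(sorted_sample: np.ndarray, values: np.ndarray) -> np.ndarray:
    s = np.asarray(sorted_sample, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty sample")
    return np.searchsorted(s, values, side="right") / s.size


# ---------------------------------------------------------------------------
# atlases


@dataclass
class DistributionAtlas:
    """Per-label sorted positive/negative predicted-probability samples."""

    positive: list           # list over labels of ascending arrays
    negative: list
    label_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.label_names:
            self.label_names = [f"label{j}" for j in range(len(self.positive))]

    @property
    def n_labels(self) -> int:
        return len(self.positive)

    def available(self, c: int) -> bool:
        return len(self.positive[c]) > 0 and len(self.negative[c]) > 0

    def f_P(self, c: int, y) -> float:
        return percentile(self.positive[c], y)

    def f_N(self, c: int, y) -> float:
        return percentile(self.negative[c], y)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for c in range(self.n_labels):
            arrays[f"pos{c}"] = np.asarray(self.positive[c], dtype=np.float64)
            arrays[f"neg{c}"] = np.asarray(self.negative[c], dtype=np.float64)
        np.savez(d / "distributions.npz", **arrays)
        manifest = dict(kind="DistributionAtlas", label_names=self.label_names,
                        counts=[[len(p), len(n)] for p, n in zip(self.positive, self.negative)],
                        format_version=1)
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "DistributionAtlas":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        names = manifest["label_names"]
        with np.load(d / "distributions.npz") as z:
            pos = [z[f"pos{c}"].copy() for c in range(len(names))]
            neg = [z[f"neg{c}"].copy() for c in range(len(names))]
        return cls(pos, neg, names)


def build_distribution_atlas(ensemble, data: LabeledImageSet) -> DistributionAtlas:
    """Run ensemble inference on the training set and split the predicted
    probabilities by training label; ignore cells are skipped.  Labels with
    an empty side are flagged (confidence degrades to 0 downstream)."""
    probs = ensemble.predict_proba(data.images)[:, :ensemble.n_labels]
    pos, neg = [], []
    for c in range(ensemble.n_labels):
        t = data.train_labels[:, c]
        pos.append(np.sort(probs[t == 1, c]))
        neg.append(np.sort(probs[t == 0, c]))
        if pos[-1].size == 0 or neg[-1].size == 0:
            warnings.warn(f"label {c}: empty positive or negative probability sample; "
                          "confidence will be 0 for this label", stacklevel=2)
    return DistributionAtlas(pos, neg, list(data.label_names))


@dataclass
class PatchAtlas:
    """Per-label embedded patch coordinates plus the shared 2-D embedding.

    ``fd_reference[c]`` is the ascending list of each atlas point's
    leave-self-out mean distance to its K nearest same-label neighbors —
    the reference sample behind the f_D percentile in patch similarity.
    """

    embedding: object
    patches: list            # list over labels of list[Patch]
    coords: list             # list over labels of (n_c, 2) arrays
    fd_reference: list       # list over labels of ascending arrays
    K: int
    D: int
    tau: float
    inclusion_threshold: float
    embed_seed: int
    label_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.label_names:
            self.label_names = [f"label{j}" for j in range(len(self.coords))]

    @property
    def n_labels(self) -> int:
        return len(self.coords)

    def available(self, c: int) -> bool:
        return self.fd_reference[c].size > 0

    def f_D(self, c: int, mean_distance) -> float:
        return percentile(self.fd_reference[c], mean_distance)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for c in range(self.n_labels):
            arrays[f"coords{c}"] = np.asarray(self.coords[c], dtype=np.float64)
            arrays[f"fd{c}"] = np.asarray(self.fd_reference[c], dtype=np.float64)
            if self.patches[c]:
                arrays[f"vectors{c}"] = np.stack([p.vector for p in self.patches[c]])
                arrays[f"bboxes{c}"] = np.array([p.bbox for p in self.patches[c]], dtype=np.int64)
        np.savez(d / "atlas.npz", **arrays)
        manifest = dict(
            kind="PatchAtlas", label_names=self.label_names, K=self.K, D=self.D,
            tau=self.tau, inclusion_threshold=self.inclusion_threshold,
            embed_seed=self.embed_seed,
            counts=[len(p) for p in self.patches],
            source_ids=[[p.source_image_id for p in pl] for pl in self.patches],
            predicted_probs=[[float(p.predicted_prob) for p in pl] for pl in self.patches],
            format_version=1,
        )
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(d / "embedding.pkl", "wb") as fh:
            pickle.dump(self.embedding, fh)

    @classmethod
    def load(cls, directory) -> "PatchAtlas":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        names = manifest["label_names"]
        with open(d / "embedding.pkl", "rb") as fh:
            embedding = pickle.load(fh)
        patches, coords, fd = [], [], []
        with np.load(d / "atlas.npz") as z:
            for c in range(len(names)):
                coords.append(z[f"coords{c}"].copy() if f"coords{c}" in z else np.zeros((0, 2)))
                fd.append(z[f"fd{c}"].copy() if f"fd{c}" in z else np.zeros(0))
                plist = []
                if f"vectors{c}" in z:
                    vecs, bbs = z[f"vectors{c}"], z[f"bboxes{c}"]
                    sids = manifest["source_ids"][c]
                    pps = manifest["predicted_probs"][c]
                    for v, bb, sid, pp in zip(vecs, bbs, sids, pps):
                        plist.append(Patch(tuple(int(x) for x in bb), v.copy(), sid, c, pp))
                patches.append(plist)
        return cls(embedding, patches, coords, fd, manifest["K"], manifest["D"],
                   manifest["tau"], manifest["inclusion_threshold"],
                   manifest["embed_seed"], names)


def _leave_self_out_fd(coords: np.ndarray, K: int) -> np.ndarray:
    """Ascending reference sample: each point's mean distance to its K
    nearest *other* points (K clipped to n-1)."""
    n = len(coords)
    k = min(K, n - 1)
    if k < 1:
        return np.zeros(0)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    part = np.sort(dist, axis=1)[:, :k]
    return np.sort(part.mean(axis=1))


def build_patch_atlas(ensemble, data: LabeledImageSet, *,
                      inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD,
                      K: int = DEFAULT_K, tau: float = DEFAULT_TAU,
                      embed_seed: int = 0, D: int = DEFAULT_D,
                      max_patches: int = 2, embedding_kind: str = "umap") -> PatchAtlas:
    """Collect CAM patches from confidently predicted training images and
    embed them in one shared cosine-neighborhood 2-D space.

    A label with fewer than K+1 qualifying patches is flagged unavailable
    (patch similarity degrades downstream); this includes the degenerate case
    of no image reaching the inclusion threshold at all.
    """
    L = ensemble.n_labels
    probs = ensemble.predict_proba(data.images)[:, :L]
    fmaps = [m.feature_maps(data.images) for m in ensemble.members]

    per_label_patches: list = []
    for c in range(L):
        sel = np.flatnonzero(probs[:, c] >= inclusion_threshold)
        plist = []
        for i in sel:
            cams = [np.tensordot(m.class_weights(c), fm[i], axes=1)
                    for m, fm in zip(ensemble.members, fmaps)]
            ecam = ensemble_cam(cams, tau, label=c, source_ids=[data.ids[i]])
            plist.extend(extract_patches(
                ecam, data.images[i], max_patches, D=D,
                source_image_id=data.ids[i], label=c, predicted_prob=float(probs[i, c])))
        per_label_patches.append(plist)

    all_vectors = [p.vector for plist in per_label_patches for p in plist]
    coords_per_label = [np.zeros((0, 2)) for _ in range(L)]
    fd_per_label = [np.zeros(0) for _ in range(L)]
    embedding = make_embedding(embedding_kind, random_state=embed_seed)
    if len(all_vectors) >= 4:
        stacked = np.stack(all_vectors)
        all_coords = embedding.fit_transform(stacked)
        offset = 0
        for c in range(L):
            n_c = len(per_label_patches[c])
            coords_per_label[c] = all_coords[offset:offset + n_c]
            offset += n_c
            if n_c >= K + 1:
                fd_per_label[c] = _leave_self_out_fd(coords_per_label[c], K)
            else:
                warnings.warn(f"label {c}: only {n_c} qualifying patches (< K+1 = {K + 1}); "
                              "patch similarity unavailable", stacklevel=2)
    else:
        warnings.warn("fewer than 4 qualifying patches in total; patch atlas empty "
                      "for every label", stacklevel=2)

    return PatchAtlas(embedding=embedding, patches=per_label_patches,
                      coords=coords_per_label, fd_reference=fd_per_label,
                      K=K, D=D, tau=tau, inclusion_threshold=inclusion_threshold,
                      embed_seed=embed_seed, label_names=list(data.label_names))
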