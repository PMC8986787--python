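"""Synthetic multi-label image datasets with focal/global findings and noisy labels.

Emulates the data regime of multi-label chest-radiograph labeling at desk
scale: grayscale images carry label-specific findings that are either *focal*
(a localized high-conspicuity region, like cardiomegaly or an effusion),
*global* (a diffuse shift of whole-image texture, like edema haze) or *mixed*
(either, per image).  Training labels are corrupted the way report-mined NLP
labels are: random flips plus "ignore" (-1) cells, while ground truth stays
clean.  An optional simulated reader panel provides majority-consensus labels
for calibration, mirroring expert-panel ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SynthConfig",
    "LabeledImageSet",
    "ConfigError",
    "generate_dataset",
    "render_image",
    "simulate_readers",
    "write_dataset",
]

FOCAL_CONTRAST = 0.45       # additive peak intensity of a focal ellipse
GLOBAL_HAZE_SHIFT = 0.10    # additive brightness of the diffuse "haze" finding
GLOBAL_CONTRAST_SCALE = 0.65  # multiplier on deviations from the image mean
BACKGROUND_BASE = 0.40
GRADIENT_AMPLITUDE = 0.10
NOISE_SIGMA = 0.04          # sd of band-limited background noise
VIEW_BAND_SCALE = 0.70      # non-target views get a darkened top band

MIN_IMAGE_SIDE = 16


class ConfigError(ValueError):
    """Invalid synthetic-dataset configuration; the message names the field."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study population.

    ``finding_kind_per_label`` takes one of ``focal``/``global``/``mixed`` per
    label; ``label_noise_rate`` is the probability a training label is flipped
    (NLP mining error) and ``ignore_rate`` the probability it is replaced by
    the ignore code -1 (inconclusive report).  ``reader_error_rates`` holds a
    (false-positive, false-negative) pair per simulated reader.
    """

    image_height: int = 64
    image_width: int = 64
    n_labels: int = 3
    finding_kind_per_label: tuple = ("focal", "global", "mixed")
    prevalence_per_label: tuple = (0.3, 0.3, 0.3)
    label_noise_rate: float = 0.1
    ignore_rate: float = 0.0
    n_readers: int = 0
    reader_error_rates: tuple = ()
    view_fraction: float = 0.8
    focal_contrast: float = FOCAL_CONTRAST
    rng_seed: int = 0

    def __post_init__(self):
        if self.image_height < MIN_IMAGE_SIDE:
            raise ConfigError(f"image_height must be >= {MIN_IMAGE_SIDE}, got {self.image_height}")
        if self.image_width < MIN_IMAGE_SIDE:
            raise ConfigError(f"image_width must be >= {MIN_IMAGE_SIDE}, got {self.image_width}")
        if self.n_labels < 1:
            raise ConfigError(f"n_labels must be positive, got {self.n_labels}")
        if len(self.finding_kind_per_label) != self.n_labels:
            raise ConfigError(
                "finding_kind_per_label must have exactly n_labels entries "
                f"({self.n_labels}), got {len(self.finding_kind_per_label)}"
            )
        for kind in self.finding_kind_per_label:
            if kind not in ("focal", "global", "mixed"):
                raise ConfigError(f"finding_kind_per_label entries must be focal/global/mixed, got {kind!r}")
        prevs = self.prevalence_per_label
        if np.isscalar(prevs):
            object.__setattr__(self, "prevalence_per_label", tuple([float(prevs)] * self.n_labels))
            prevs = self.prevalence_per_label
        if len(prevs) != self.n_labels:
            raise ConfigError("prevalence_per_label must have n_labels entries")
        for p in prevs:
            if not 0.0 < p < 1.0:
                raise ConfigError(f"prevalence_per_label entries must lie in (0,1), got {p}")
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ConfigError(f"label_noise_rate must lie in [0,1), got {self.label_noise_rate}")
        if not 0.0 <= self.ignore_rate < 1.0:
            raise ConfigError(f"ignore_rate must lie in [0,1), got {self.ignore_rate}")
        if self.n_readers < 0:
            raise ConfigError(f"n_readers must be non-negative, got {self.n_readers}")
        if self.n_readers and len(self.reader_error_rates) != self.n_readers:
            raise ConfigError("reader_error_rates must have one (fpr, fnr) pair per reader")
        for pair in self.reader_error_rates:
            fpr, fnr = pair
            if not (0.0 <= fpr < 0.5 and 0.0 <= fnr < 0.5):
                raise ConfigError(f"reader_error_rates entries must lie in [0, 0.5), got {pair}")
        if not 0.0 <= self.view_fraction <= 1.0:
            raise ConfigError(f"view_fraction must lie in [0,1], got {self.view_fraction}")


@dataclass
class LabeledImageSet:
    """Images plus tri-valued training labels, clean truth and optional readers.

    ``view`` is 1 for the target view (the analog of the PA projection the
    classifier is specialized for) and 0 otherwise.  ``train_labels`` cells are
    1/0/-1; -1 marks ignore cells excluded from losses and atlases.
    """

    images: np.ndarray            # (N, H, W) float32 in [0, 1]
    true_labels: np.ndarray       # (N, L) int8 in {0, 1}
    train_labels: np.ndarray      # (N, L) int8 in {1, 0, -1}
    view: np.ndarray              # (N,) int8, 1 = target view
    ids: list = field(default_factory=list)
    reader_ratings: np.ndarray | None = None   # (N, L, R) in {0, 1}
    consensus_gt: np.ndarray | None = None     # (N, L) in {0, 1}
    label_names: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.images)
        if not (len(self.true_labels) == len(self.train_labels) == len(self.view) == len(self.ids) == n):
            raise ValueError("images, labels, view and ids must share the same length N")
        if not self.label_names:
            self.label_names = [f"label{j}" for j in range(self.true_labels.shape[1])]
        self.validate()

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def n_labels(self) -> int:
        return self.true_labels.shape[1]

    def validate(self) -> None:
        if not np.isin(self.true_labels, (0, 1)).all():
            raise ValueError("true_labels cells must be 0 or 1")
        if not np.isin(self.train_labels, (-1, 0, 1)).all():
            raise ValueError("train_labels cells must be 1, 0 or -1")
        if self.reader_ratings is not None and self.consensus_gt is not None:
            maj = _majority(self.reader_ratings)
            if not np.array_equal(maj, self.consensus_gt):
                raise ValueError("consensus_gt must equal the per-cell reader majority")

    def subset(self, index) -> "LabeledImageSet":
        index = np.asarray(index)
        return LabeledImageSet(
            images=self.images[index],
            true_labels=self.true_labels[index],
            train_labels=self.train_labels[index],
            view=self.view[index],
            ids=[self.ids[i] for i in index],
            reader_ratings=None if self.reader_ratings is None else self.reader_ratings[index],
            consensus_gt=None if self.consensus_gt is None else self.consensus_gt[index],
            label_names=list(self.label_names),
        )

    def concat(self, other: "LabeledImageSet") -> "LabeledImageSet":
        if self.label_names != other.label_names:
            raise ValueError("label sets differ")
        return LabeledImageSet(
            images=np.concatenate([self.images, other.images]),
            true_labels=np.concatenate([self.true_labels, other.true_labels]),
            train_labels=np.concatenate([self.train_labels, other.train_labels]),
            view=np.concatenate([self.view, other.view]),
            ids=list(self.ids) + list(other.ids),
            label_names=list(self.label_names),
        )


def _majority(ratings: np.ndarray) -> np.ndarray:
    """Per-cell majority over readers; even-panel ties break toward positive."""
    r = ratings.shape[2]
    pos = ratings.sum(axis=2)
    return (2 * pos >= r).astype(np.int8)


def _focal_region(label_index: int, h: int, w: int):
    """Label k owns quadrant k (mod 4) of a 2x2 grid — a fixed spatial
    signature so the patch atlas has a consistent pattern to retrieve."""
    q = label_index % 4
    r0 = 0 if q < 2 else h // 2
    c0 = 0 if q % 2 == 0 else w // 2
    return r0, c0, r0 + h // 2, c0 + w // 2


def _focal_template(label_index: int, size, rng) -> np.ndarray:
    """Unit-peak intensity template for label k's focal finding.

    Each label has both a fixed home quadrant and a distinctive shape
    (blob / horizontal band / diagonal stripe / annulus, cycling with k) —
    mirroring how real focal findings differ in appearance, not merely in
    anatomic location.  The center jitters inside the quadrant.
    """
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r0, c0, r1, c1 = _focal_region(label_index, h, w)
    cy = rng.uniform(r0 + 0.30 * (r1 - r0), r0 + 0.70 * (r1 - r0))
    cx = rng.uniform(c0 + 0.30 * (c1 - c0), c0 + 0.70 * (c1 - c0))
    ay = rng.uniform(0.12, 0.20) * h
    ax = rng.uniform(0.12, 0.20) * w
    shape = label_index % 4
    if shape == 0:      # compact blob
        d2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        return np.exp(-0.5 * d2 * 4.0)
    if shape == 1:      # horizontal band across the quadrant
        band = np.exp(-0.5 * ((yy - cy) / (0.35 * ay)) ** 2 * 4.0)
        lateral = np.exp(-0.5 * ((xx - cx) / (2.2 * ax)) ** 2 * 4.0)
        return band * lateral
    if shape == 2:      # diagonal stripe
        u = ((yy - cy) - (xx - cx)) / np.sqrt(2.0)
        v = ((yy - cy) + (xx - cx)) / np.sqrt(2.0)
        return np.exp(-0.5 * ((u / (0.35 * ay)) ** 2 + (v / (2.2 * ax)) ** 2) * 4.0)
    # shape == 3: annulus
    r = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    return np.exp(-0.5 * ((r - 1.0) / 0.35) ** 2)


def render_image(finding_flags, kinds, size, rng, *, focal_contrast: float = FOCAL_CONTRAST,
                 haze_shift: float = GLOBAL_HAZE_SHIFT, target_view: bool = True) -> np.ndarray:
    """Render one grayscale image given per-label finding flags.

    Background is a smooth oriented gradient plus band-limited noise.  Each
    positive focal label adds a soft-edged bright ellipse inside its fixed
    quadrant; each positive global label shifts whole-image brightness and
    damps contrast (haze).  ``mixed`` labels draw focal or global per image.
    """
    if len(finding_flags) != len(kinds):
        raise ValueError("finding_flags and kinds must have the same length")
    h, w = size
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise ValueError(f"image size must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}")

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(theta) * (yy / h - 0.5) + np.sin(theta) * (xx / w - 0.5))
    img = BACKGROUND_BASE + GRADIENT_AMPLITUDE * ramp
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    std = noise.std()
    if std > 0:
        img = img + NOISE_SIGMA * noise / std

    # draw global findings first so focal ellipses keep full contrast
    for j, (flag, kind) in enumerate(zip(finding_flags, kinds)):
        if not flag:
            continue
        if kind == "mixed":
            kind = "focal" if rng.random() < 0.5 else "global"
        if kind == "global":
            mean = img.mean()
            img = mean + GLOBAL_CONTRAST_SCALE * (img - mean) + haze_shift
        elif kind == "focal":
            img = img + focal_contrast * _focal_template(j, (h, w), rng)
        else:
            raise ValueError(f"unknown finding kind {kind!r}")

    if not target_view:
        img[: max(1, h // 8), :] *= VIEW_BAND_SCALE
    return np.clip(img, 0.0, 1.0)


def simulate_readers(true_labels: np.ndarray, reader_error_rates, rng):
    """Simulate an expert panel: each reader independently flips truth at
    their own false-positive/false-negative rates; consensus is the per-cell
    majority (even panels break ties toward positive).
    """
    rates = list(reader_error_rates)
    if len(rates) < 1:
        raise ValueError("need at least one reader")
    for fpr, fnr in rates:
        if not (0.0 <= fpr < 0.5 and 0.0 <= fnr < 0.5):
            raise ValueError("reader error rates must lie in [0, 0.5)")
    t = np.asarray(true_labels)
    n, L = t.shape
    ratings = np.empty((n, L, len(rates)), dtype=np.int8)
    for r, (fpr, fnr) in enumerate(rates):
        u = rng.random((n, L))
        flip = np.where(t == 1, u < fnr, u < fpr)
        ratings[:, :, r] = np.where(flip, 1 - t, t)
    return ratings, _majority(ratings)


def generate_dataset(config: SynthConfig, n_images: int, *, id_prefix: str = "img") -> LabeledImageSet:
    """Generate a fully labeled synthetic image set.

    Deterministic: identical (config, n_images) yields bit-identical output.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    h, w, L = config.image_height, config.image_width, config.n_labels
    prevs = np.asarray(config.prevalence_per_label, dtype=float)

    true_labels = (rng.random((n_images, L)) < prevs).astype(np.int8)
    view = (rng.random(n_images) < config.view_fraction).astype(np.int8)

    images = np.empty((n_images, h, w), dtype=np.float32)
    for i in range(n_images):
        images[i] = render_image(
            true_labels[i], config.finding_kind_per_label, (h, w), rng,
            focal_contrast=config.focal_contrast, target_view=bool(view[i]),
        )

    train_labels = true_labels.astype(np.int8).copy()
    if config.ignore_rate > 0:
        ign = rng.random((n_images, L)) < config.ignore_rate
    else:
        ign = np.zeros((n_images, L), dtype=bool)
    if config.label_noise_rate > 0:
        flip = rng.random((n_images, L)) < config.label_noise_rate
        train_labels = np.where(flip, 1 - train_labels, train_labels).astype(np.int8)
    train_labels[ign] = -1

    reader_ratings = consensus = None
    if config.n_readers > 0:
        reader_ratings, consensus = simulate_readers(true_labels, config.reader_error_rates, rng)

    ids = [f"{id_prefix}{i:06d}" for i in range(n_images)]
    return LabeledImageSet(
        images=images,
        true_labels=true_labels,
        train_labels=train_labels,
        view=view,
        ids=ids,
        reader_ratings=reader_ratings,
        consensus_gt=consensus,
    )


def write_dataset(data: LabeledImageSet, outdir) -> "pd.DataFrame":
    """Write 8-bit grayscale PNGs plus a CSV manifest.

    Manifest columns: id, path, view, ``true_<label>``, ``train_<label>`` and,
    when a reader panel exists, ``reader<r>_<label>`` columns.
    """
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    imgdir = outdir / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img_id in enumerate(data.ids):
        arr = (np.clip(data.images[i], 0, 1) * 255).round().astype(np.uint8)
        path = imgdir / f"{img_id}.png"
        Image.fromarray(arr, mode="L").save(path)
        row = {"id": img_id, "path": str(path.relative_to(outdir)),
               "view": "target" if data.view[i] else "other"}
        for j, name in enumerate(data.label_names):
            row[f"true_{name}"] = int(data.true_labels[i, j])
            row[f"train_{name}"] = int(data.train_labels[i, j])
        if data.reader_ratings is not None:
            for r in range(data.reader_ratings.shape[2]):
                for j, name in enumerate(data.label_names):
                    row[f"reader{r + 1}_{name}"] = int(data.reader_ratings[i, j, r])
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_dataset(outdir) -> LabeledImageSet:
    """Load a dataset previously written by :func:`write_dataset`."""
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    label_names = [c[len("true_"):] for c in manifest.columns if c.startswith("true_")]
    images = np.stack([
        np.asarray(Image.open(outdir / p), dtype=np.float32) / 255.0 for p in manifest["path"]
    ])
    reader_cols = sorted({c.split("_")[0] for c in manifest.columns if c.startswith("reader")})
    ratings = None
    if reader_cols:
        ratings = np.stack(
            [manifest[[f"{rc}_{n}" for n in label_names]].to_numpy(dtype=np.int8) for rc in reader_cols],
            axis=2,
        )
    return LabeledImageSet(
        images=images,
        true_labels=manifest[[f"true_{n}" for n in label_names]].to_numpy(dtype=np.int8),
        train_labels=manifest[[f"train_{n}" for n in label_names]].to_numpy(dtype=np.int8),
        view=(manifest["view"] == "target").to_numpy(dtype=np.int8),
        ids=list(manifest["id"].astype(str)),
        reader_ratings=ratings,
        consensus_gt=None if ratings is None else _majority(ratings),
        label_names=label_names,
    )
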