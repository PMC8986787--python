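"""2-D patch embeddings preserving cosine-similarity neighborhoods.

The patch atlas stores patch vectors as coordinates in a 2-D embedding space
in which small Euclidean distance means high cosine similarity.  Any object
with ``fit(X)`` and ``transform(X) -> (n, 2)`` that honors that contract and
is deterministic under a fixed seed qualifies; two implementations are
provided:

* :class:`CosineUMAPEmbedding` — UMAP with the cosine metric (the default;
  a nonlinear neighborhood-preserving map with out-of-sample transform).
* :class:`CosineProjectionEmbedding` — unit-normalization followed by a
  2-component PCA.  Euclidean distance between unit vectors is a monotone
  function of cosine distance, so the PCA plane approximately preserves
  cosine neighborhoods.  Fast, exactly reproducible, convenient for tests
  and oracle comparisons where the embedding itself is not under scrutiny.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CosineUMAPEmbedding", "CosineProjectionEmbedding", "make_embedding"]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


class CosineProjectionEmbedding:
    """Unit-normalize rows, then project onto the top-2 principal axes."""

    def __init__(self, random_state: int = 0):
        self.random_state = int(random_state)
        self.mean_ = None
        self.components_ = None

    def fit(self, X) -> "CosineProjectionEmbedding":
        U = _unit_rows(X)
        self.mean_ = U.mean(axis=0)
        centered = U - self.mean_
        # deterministic SVD with a fixed sign convention
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        comps = vt[:2] if vt.shape[0] >= 2 else np.vstack([vt, np.zeros((2 - vt.shape[0], vt.shape[1]))])
        signs = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = comps * signs[:, None]
        return self

    def transform(self, X) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("embedding not fitted")
        return (_unit_rows(X) - self.mean_) @ self.components_.T

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


class CosineUMAPEmbedding:
    """Cosine-metric UMAP to 2-D with seeded, reproducible layout.

    ``n_neighbors`` is clipped to the training-set size; the underlying model
    supports out-of-sample ``transform`` for scoring new patches.
    """

    def __init__(self, random_state: int = 0, n_neighbors: int = 15, min_dist: float = 0.1):
        self.random_state = int(random_state)
        self.n_neighbors = int(n_neighbors)
        self.min_dist = float(min_dist)
        self._umap = None
        self._train_X = None
        self._train_coords = None

    def fit(self, X) -> "CosineUMAPEmbedding":
        import warnings

        import umap

        X = np.asarray(X, dtype=np.float64)
        n = len(X)
        if n < 4:
            raise ValueError("UMAP embedding needs at least 4 patch vectors")
        nn = max(2, min(self.n_neighbors, n - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._umap = umap.UMAP(
                n_components=2, metric="cosine", n_neighbors=nn,
                min_dist=self.min_dist, random_state=self.random_state,
                transform_seed=self.random_state,
            )
            self._train_coords = np.asarray(self._umap.fit_transform(X), dtype=np.float64)
        self._train_X = X.copy()
        return self

    def transform(self, X) -> np.ndarray:
        import warnings

        if self._umap is None:
            raise RuntimeError("embedding not fitted")
        X = np.asarray(X, dtype=np.float64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(self._umap.transform(X), dtype=np.float64)

    def fit_transform(self, X) -> np.ndarray:
        self.fit(X)
        return self._train_coords.copy()


def make_embedding(kind: str = "umap", random_state: int = 0, **kwargs):
    """Factory for the embedding kinds understood by the pipeline config."""
    if kind == "umap":
        return CosineUMAPEmbedding(random_state=random_state, **kwargs)
    if kind in ("projection", "cosine-pca"):
        return CosineProjectionEmbedding(random_state=random_state)
    raise ValueError(f"unknown embedding kind {kind!r}")
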