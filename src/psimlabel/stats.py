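"""Evaluation statistics: AUROC, bootstrap CIs, binomial CIs, Cohen's kappa.

AUROC is the Mann-Whitney probability P(score_pos > score_neg) + 0.5 *
P(equal).  Bootstrap CIs follow the resample-with-replacement recipe
(interval = 2.5/97.5 percentiles of the resampled metric, endpoints taken as
order statistics of the resample distribution).  Binomial proportion CIs
default to the Wald normal approximation with Wilson available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

__all__ = [
    "BootstrapConfig",
    "KappaMatrix",
    "auroc",
    "bootstrap_ci",
    "binomial_ci",
    "cohen_kappa",
    "pairwise_kappa",
]


def auroc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class BootstrapConfig:
    """Nonparametric bootstrap settings; the full-scale recipe is 2000
    resamples of 1000 cases at the 95% level."""

    n_resamples: int = 2000
    resample_size: int | None = None   # None -> size of the input sample
    ci_level: float = 0.95
    rng_seed: int = 0
    max_redraws: int = 100

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")


def bootstrap_ci(scores, labels, metric=auroc, config: BootstrapConfig = BootstrapConfig()):
    """(point, lower, upper): metric on the full sample plus the percentile
    bootstrap interval.  Resamples on which the metric is not computable
    (e.g. single-class) are redrawn up to ``max_redraws`` times so the
    number of resamples stays fixed."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    size = config.resample_size or n
    point = metric(scores, labels)
    rng = np.random.default_rng(config.rng_seed)
    stats = np.empty(config.n_resamples)
    for b in range(config.n_resamples):
        value = None
        for _ in range(config.max_redraws):
            idx = rng.integers(0, n, size=size)
            try:
                value = metric(scores[idx], labels[idx])
                break
            except ValueError:
                continue
        if value is None:
            raise RuntimeError("metric not computable on any resample")
        stats[b] = value
    alpha = (1.0 - config.ci_level) / 2.0
    stats.sort()
    # interval endpoints are order statistics of the resample distribution
    lower = float(np.quantile(stats, alpha, method="lower"))
    upper = float(np.quantile(stats, 1.0 - alpha, method="higher"))
    return float(point), lower, upper


def binomial_ci(successes: int, n: int, level: float = 0.95,
                method: str = "wald") -> tuple:
    """Binomial proportion CI, clipped to [0, 1].  ``method`` is ``wald``
    (default) or ``wilson``."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n with n >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    p = successes / n
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    if method == "wald":
        half = z * np.sqrt(p * (1.0 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "wilson":
        denom = 1.0 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
        return max(0.0, center - half), min(1.0, center + half)
    raise ValueError(f"unknown method {method!r}")


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Binary Cohen's kappa: (p_o - p_e)/(1 - p_e) with chance agreement p_e
    from the marginal positive rates.  Two identical constant raters have
    p_e = 1 and undefined kappa; the convention here is kappa = 1 (perfect
    observed agreement)."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("ratings must have equal length")
    if a.size == 0:
        raise ValueError("need at least one rating")
    p_o = float((a == b).mean())
    pa, pb = float((a == 1).mean()), float((b == 1).mean())
    p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class KappaMatrix:
    """Symmetric pairwise inter-rater agreement matrix with unit diagonal."""

    raters: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.raters), len(self.raters)):
            raise ValueError("matrix shape must match number of raters")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
            raise ValueError("kappa matrix must be symmetric with unit diagonal")
        self.matrix = m


def pairwise_kappa(ratings: np.ndarray, raters=None) -> KappaMatrix:
    """Pairwise kappas over an (N, R) rating matrix."""
    ratings = np.asarray(ratings)
    n, r = ratings.shape
    raters = list(raters) if raters is not None else [f"reader{i + 1}" for i in range(r)]
    mat = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            mat[i, j] = mat[j, i] = cohen_kappa(ratings[:, i], ratings[:, j])
    return KappaMatrix(raters, mat)
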