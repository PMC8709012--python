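"""ReliefF feature-importance weighting.

For each probe instance R_i, ReliefF finds its k nearest same-class
neighbours (hits H_j) and, per other class C, its k nearest neighbours of
that class (misses M_j).  Feature a's weight accumulates

    W(a) <- W(a) - sum_j diff(a, R_i, H_j) / (m k)
                 + sum_{C != class(R_i)} P(C) / (1 - P(class(R_i)))
                   * sum_j diff(a, R_i, M_j) / (m k)

over m probe instances, starting from zero.  ``diff`` is the range-normalised
absolute difference, so a feature that separates classes (large miss-diffs,
small hit-diffs) ends up with a large positive weight, and every weight is
bounded in [-1, 1].  Thresholding these weights is the second level of the
NCAR selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReliefFConfig",
    "ReliefFWeights",
    "diff",
    "relieff_weights",
    "select_by_importance",
]


@dataclass
class ReliefFConfig:
    k_neighbors: int = 10
    m_samples: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.m_samples != "all" and (not isinstance(self.m_samples, int) or self.m_samples < 1):
            raise ValueError("m_samples must be 'all' or a positive integer")


@dataclass
class ReliefFWeights:
    W: np.ndarray
    priors: dict = field(default_factory=dict)


def _ranges(X: np.ndarray) -> np.ndarray:
    return X.max(axis=0) - X.min(axis=0)


def diff(a: int, u: np.ndarray, v: np.ndarray, ranges: np.ndarray) -> float:
    """Range-normalised absolute difference of feature a between two instances.

    Zero-range (constant) features contribute 0 by convention.
    """
    r = ranges[a]
    if r == 0:
        return 0.0
    return float(abs(u[a] - v[a]) / r)


def relieff_weights(
    X: np.ndarray, y: np.ndarray, config: ReliefFConfig | None = None
) -> ReliefFWeights:
    """Compute ReliefF weights over all features.

    Deterministic when ``m_samples='all'`` (every instance probed once, in
    index order); with integer m, probes are sampled without replacement
    using the config seed.  Neighbour distances use Manhattan distance on
    range-normalised features, consistent with ``diff``; self-matches are
    excluded and ties broken by lowest instance index.
    """
    config = config or ReliefFConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least two classes")
    singletons = classes[counts < 2]
    if singletons.size:
        raise ValueError(
            f"class {singletons[0]!r} has a single member; hits are undefined"
        )
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    k = config.k_neighbors
    min_count = counts.min()
    if k > min_count - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds smallest class size minus one "
            f"({min_count - 1}); clipping",
            stacklevel=2,
        )
        k = min_count - 1

    ranges = _ranges(X)
    safe = np.where(ranges == 0, 1.0, ranges)
    Xn = (X - X.min(axis=0)) / safe
    Xn[:, ranges == 0] = 0.0

    if config.m_samples == "all":
        probes = np.arange(n)
    else:
        rng = np.random.default_rng([config.seed, 11])
        m = min(config.m_samples, n)
        probes = np.sort(rng.choice(n, size=m, replace=False))
    m = len(probes)

    by_class = {c: np.flatnonzero(y == c) for c in classes}
    W = np.zeros(p)
    for i in probes:
        d = np.abs(Xn - Xn[i]).sum(axis=1)
        ci = y[i]
        # hits: nearest same-class neighbours, self excluded
        pool = by_class[ci][by_class[ci] != i]
        hits = pool[np.lexsort((pool, d[pool]))][:k]
        kh = len(hits)
        if kh:
            W -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / (m * kh)
        miss_scale = 1.0 - priors[ci]
        for c in classes:
            if c == ci:
                continue
            pool = by_class[c]
            misses = pool[np.lexsort((pool, d[pool]))][:k]
            km = len(misses)
            if km:
                W += (priors[c] / miss_scale) * np.abs(Xn[misses] - Xn[i]).sum(axis=0) / (m * km)
    return ReliefFWeights(W=W, priors=priors)


def select_by_importance(W: np.ndarray | ReliefFWeights, threshold: float) -> np.ndarray:
    """Boolean keep-mask: features with importance >= threshold survive."""
    if isinstance(W, ReliefFWeights):
        W = W.W
    W = np.asarray(W, dtype=float)
    mask = W >= threshold
    if not mask.any():
        warnings.warn(
            f"threshold {threshold} removes every feature (max weight {W.max():.3g})",
            stacklevel=2,
        )
    return mask
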