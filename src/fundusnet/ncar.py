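"""NCAR: the two-level NCA -> ReliefF feature selector.

Level 1 fits NCA weights on all p features and keeps those with weight at
least ``thr1`` (default 0.0005).  Level 2 recomputes ReliefF importance
weights on the surviving columns only and keeps those with importance at
least ``thr2`` (default 0.01).  The final mask is expressed over the
original feature indices.  The two levels are complementary filters: NCA's
soft-neighbour objective prunes features that never help same-class
neighbourhoods, and ReliefF's hit/miss contrast then ranks the survivors by
local class separation.

``ratio_reduce`` is a separate, self-contained reduction of a single feature
vector by mean/standard-deviation ratio tests, kept alongside the canonical
selector for completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nca import NCAConfig, NCAWeights, fit_nca, select_by_weight
from .relieff import ReliefFConfig, ReliefFWeights, relieff_weights, select_by_importance

__all__ = ["SelectionResult", "ncar_select", "ratio_reduce"]


@dataclass
class SelectionResult:
    keep_mask: np.ndarray
    level1_weights: NCAWeights
    level1_survivors: np.ndarray
    level2_weights: ReliefFWeights
    thresholds: tuple[float, float]
    n_selected: int

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep_mask)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected_indices": self.selected_indices.tolist(),
                    "level1_survivors": self.level1_survivors.tolist(),
                    "thresholds": list(self.thresholds),
                    "n_selected": self.n_selected,
                },
                indent=2,
            )
        )


def ncar_select(
    X: np.ndarray,
    y: np.ndarray,
    nca_cfg: NCAConfig | None = None,
    relieff_cfg: ReliefFConfig | None = None,
    thr1: float = 0.0005,
    thr2: float = 0.01,
) -> SelectionResult:
    """Run both selection levels and map the final mask to original indices."""
    X = np.asarray(X, dtype=float)
    level1 = fit_nca(X, y, nca_cfg)
    mask1 = select_by_weight(level1.w, thr1)
    survivors = np.flatnonzero(mask1)
    if survivors.size == 0:
        raise ValueError(
            f"level-1 threshold {thr1} removed all {X.shape[1]} features "
            f"(max NCA weight {level1.w.max():.3g}); lower thr1"
        )
    level2 = relieff_weights(X[:, survivors], y, relieff_cfg)
    mask2 = select_by_importance(level2.W, thr2)
    keep = np.zeros(X.shape[1], dtype=bool)
    keep[survivors[mask2]] = True
    return SelectionResult(
        keep_mask=keep,
        level1_weights=level1,
        level1_survivors=survivors,
        level2_weights=level2,
        thresholds=(thr1, thr2),
        n_selected=int(keep.sum()),
    )


def ratio_reduce(fea: np.ndarray, thr: float) -> np.ndarray:
    """Drop elements of a feature vector by mean/std ratio tests.

    The mean and population standard deviation are computed once from the
    input.  Element i is removed iff both std/fea[i] > thr and
    avg/fea[i] > thr; zero elements make the ratios infinite and are removed
    for any finite threshold.
    """
    fea = np.asarray(fea, dtype=float).ravel()
    if fea.size == 0:
        raise ValueError("ratio_reduce requires a non-empty vector")
    avg = fea.mean()
    std = fea.std()  # population (1/N) convention
    with np.errstate(divide="ignore", invalid="ignore"):
        decision1 = np.where(fea != 0, std / fea, np.inf)
        decision2 = np.where(fea != 0, avg / fea, np.inf)
    remove = (decision1 > thr) & (decision2 > thr)
    return fea[~remove]
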