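"""Beta-diversity projection metrics.

Three map-level summaries of projected community change between a current
and a future epoch, all computed on the GDM-transformed predictor scale with
the model intercept removed (no change is predicted when the environment
does not change):

* compositional change — per-cell dissimilarity between a cell's present
  and future transformed environment;
* disappearing bioclimates — current cells whose minimum dissimilarity to
  *any* future cell meets the threshold (forward-looking);
* novel bioclimates — future cells whose minimum dissimilarity to *any*
  current cell meets the threshold (backward-looking).

Masks use a default 10% dissimilarity threshold; overlap between the
disappearing and novel masks is summarised by the Jaccard index and the
conditional probability that a disappearing cell is replaced by a novel
bioclimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .gdm import GDMModel
from .grids import TransformedGrid


@dataclass
class MetricConfig:
    dissimilarity_threshold: float = 0.10
    reference_fraction: float = 1.0  # all-cell scans are exact at package scale
    include_intercept: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dissimilarity_threshold < 1):
            raise ValueError("dissimilarity threshold must lie in (0, 1)")


@dataclass
class CellMetric:
    """A per-cell continuous metric with its mask-threshold summary."""

    values: np.ndarray  # 2-D, NaN outside mask
    mask: np.ndarray | None = None  # thresholded binary mask
    area_pct: float = float("nan")

    def summary(self) -> dict:
        v = self.values[np.isfinite(self.values)]
        return {
            "median": float(np.median(v)) if v.size else float("nan"),
            "iqr": (
                float(np.percentile(v, 75) - np.percentile(v, 25)) if v.size else float("nan")
            ),
            "area_pct": self.area_pct,
        }


def _common_mask(current: TransformedGrid, future: TransformedGrid) -> np.ndarray:
    if current.shape != future.shape:
        raise ValueError("current and future grids must share geometry")
    if current.predictors != future.predictors:
        raise ValueError("current and future grids come from different models")
    return current.mask & future.mask


def compositional_change(model: GDMModel, current: TransformedGrid,
                         future: TransformedGrid,
                         config: MetricConfig | None = None) -> CellMetric:
    """Per-cell present-vs-future dissimilarity (intercept removed by default)."""
    config = config or MetricConfig()
    mask = _common_mask(current, future)
    eta = np.zeros(current.shape)
    for p in current.predictors:
        eta += np.abs(current.data[p] - future.data[p])
    if config.include_intercept:
        eta += model.intercept
    values = np.where(mask, 1.0 - np.exp(-eta), np.nan)
    return CellMetric(values=values)


def _min_cross_dissimilarity(model: GDMModel, focal: TransformedGrid,
                             other: TransformedGrid, config: MetricConfig
                             ) -> CellMetric:
    """For each focal cell, min dissimilarity to any cell of the other epoch."""
    mask = _common_mask(focal, other)
    f_focal = np.column_stack(
        [focal.data[p].ravel()[mask.ravel()] for p in focal.predictors]
    )
    f_other = np.column_stack(
        [other.data[p].ravel()[mask.ravel()] for p in other.predictors]
    )
    if f_other.shape[0] == 0:
        raise ValueError("comparison epoch has no valid cells")
    if 0 < config.reference_fraction < 1:
        rng = np.random.default_rng(config.seed)
        n = max(1, int(round(config.reference_fraction * f_other.shape[0])))
        keep = rng.choice(f_other.shape[0], size=n, replace=False)
        f_other = f_other[keep]
    min_eta = np.empty(f_focal.shape[0])
    chunk = 2048
    for start in range(0, f_focal.shape[0], chunk):
        block = cdist(f_focal[start : start + chunk], f_other, metric="cityblock")
        min_eta[start : start + chunk] = block.min(axis=1)
    if config.include_intercept:
        min_eta = min_eta + model.intercept
    values = np.full(focal.shape, np.nan)
    values[mask] = 1.0 - np.exp(-min_eta)
    binary = np.zeros(focal.shape, bool)
    binary[mask] = values[mask] >= config.dissimilarity_threshold
    area = 100.0 * binary.sum() / max(mask.sum(), 1)
    return CellMetric(values=values, mask=binary, area_pct=float(area))


def disappearing_bioclimates(model: GDMModel, current: TransformedGrid,
                             future: TransformedGrid,
                             config: MetricConfig | None = None) -> CellMetric:
    """Current cells >= threshold dissimilar to every future cell."""
    return _min_cross_dissimilarity(model, current, future, config or MetricConfig())


def novel_bioclimates(model: GDMModel, current: TransformedGrid,
                      future: TransformedGrid,
                      config: MetricConfig | None = None) -> CellMetric:
    """Future cells >= threshold dissimilar to every current cell."""
    return _min_cross_dissimilarity(model, future, current, config or MetricConfig())


def overlap_summary(disappearing_mask: np.ndarray, novel_mask: np.ndarray) -> dict:
    """Jaccard overlap and P(novel | disappearing) between the two masks."""
    if disappearing_mask.shape != novel_mask.shape:
        raise ValueError("masks must share geometry")
    d = disappearing_mask.astype(bool)
    n = novel_mask.astype(bool)
    inter = int((d & n).sum())
    union = int((d | n).sum())
    jaccard = inter / union if union else 0.0
    conditional = inter / int(d.sum()) if d.sum() else float("nan")
    return {
        "jaccard": float(jaccard),
        "conditional_replacement": float(conditional),
        "n_disappearing": int(d.sum()),
        "n_novel": int(n.sum()),
        "n_both": inter,
    }


def map_rank_correlation(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Spearman rank correlation between two per-cell metric maps (ties averaged)."""
    ok = np.isfinite(values_a) & np.isfinite(values_b)
    if ok.sum() < 3:
        return float("nan")
    rho, _ = spearmanr(values_a[ok], values_b[ok])
    return float(rho)
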