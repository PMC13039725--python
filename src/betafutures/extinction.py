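"""Species heading for extinction via the species-area relationship.

For each grid cell i, the proportion of its original species expected to
persist anywhere in the region over the long term is

    p_i = [ sum_j Sim(i_cur, j_fut) * hab_fut[j]
          / sum_j Sim(i_cur, j_cur) * hab_cur[j] ] ** z

where Sim is the bioclimatic similarity exp(-sum_p |delta f_p|) on the
GDM-transformed scale (one minus the intercept-free predicted
dissimilarity), hab is habitat condition in [0, 1] (the current landscape is
benchmarked as intact, hab_cur = 1), and z is the species-area exponent
(default 0.25). The sums run over a seeded random reference subsample of
cells (default 20%, the same subsample in numerator and denominator).
Regional persistence is the weighted geometric mean of the p_i, and its
complement times the species total is the number of species heading for
extinction (the extinction debt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .gdm import GDMModel
from .grids import TransformedGrid


@dataclass
class ExtinctionConfig:
    z: float = 0.25
    reference_fraction: float = 0.20
    seed: int = 0
    geometric_mean_floor: float = 1e-9
    cell_weights: np.ndarray | None = None  # default uniform

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("species-area exponent z must be positive")
        if not (0 < self.reference_fraction <= 1):
            raise ValueError("reference_fraction must lie in (0, 1]")
        if self.geometric_mean_floor <= 0:
            raise ValueError("geometric mean floor must be positive")


@dataclass
class PersistenceResult:
    """Per-cell persistence and its regional aggregate for one scenario/slice."""

    p: np.ndarray  # per valid cell, in cell order
    persistence: float  # weighted geometric mean
    species_total: int
    heading_for_extinction: float  # unrounded S * (1 - persistence)
    scenario: str = ""
    time_slice: tuple[int, int] | None = None
    numerator: np.ndarray | None = None
    denominator: np.ndarray | None = None
    epsilon_sensitivity: dict = field(default_factory=dict)

    @property
    def heading_for_extinction_rounded(self) -> int:
        return int(round(self.heading_for_extinction))

    @property
    def percent_heading(self) -> float:
        return 100.0 * self.heading_for_extinction / self.species_total


def subsample_reference_cells(n_valid: int, fraction: float, seed: int) -> np.ndarray:
    """Seeded uniform sample (without replacement) of round(fraction * n) cells."""
    if n_valid < 1:
        raise ValueError("no valid cells to subsample")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n = max(1, int(round(fraction * n_valid)))
    if n >= n_valid:
        return np.arange(n_valid)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_valid, size=n, replace=False))


def bioclim_similarity(model: GDMModel, f_a: np.ndarray, f_b: np.ndarray
                       ) -> np.ndarray | float:
    """Sim = exp(-sum_p |f_a,p - f_b,p|), in (0, 1]; Sim(a, a) = 1."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_a.shape != f_b.shape:
        raise ValueError("transformed vectors must share a shape")
    out = np.exp(-np.abs(f_a - f_b).sum(axis=-1))
    return float(out) if np.ndim(out) == 0 else out


def species_persisting(model: GDMModel, current: TransformedGrid,
                       future: TransformedGrid, hab_future: np.ndarray,
                       config: ExtinctionConfig | None = None,
                       hab_current: np.ndarray | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell persistence p_i over the shared valid-cell set.

    ``hab_future`` is a 2-D habitat-condition map on the grid geometry (or a
    vector over valid cells). ``hab_current`` defaults to the intact
    benchmark (all ones). Returns (p, numerator, denominator) over valid
    cells in row-major order; the Eq. ratio is clipped at 1 before the
    species-area exponent is applied.
    """
    config = config or ExtinctionConfig()
    if current.shape != future.shape or current.predictors != future.predictors:
        raise ValueError("current/future grids must share geometry and model")
    mask = current.mask & future.mask
    flat_idx = np.flatnonzero(mask.ravel())
    n = flat_idx.size
    if n == 0:
        raise ValueError("no valid cells")

    def _stack(grid: TransformedGrid) -> np.ndarray:
        return np.column_stack([grid.data[p].ravel()[flat_idx] for p in grid.predictors])

    f_cur = _stack(current)
    f_fut = _stack(future)

    def _hab_vector(hab: np.ndarray | None) -> np.ndarray:
        if hab is None:
            return np.ones(n)
        hab = np.asarray(hab, dtype=float)
        vec = hab.ravel()[flat_idx] if hab.shape == mask.shape else hab
        if vec.shape != (n,):
            raise ValueError("habitat map does not match the valid-cell set")
        if np.nanmin(vec) < 0 or np.nanmax(vec) > 1:
            raise ValueError("habitat condition must lie in [0, 1]")
        return vec

    hab_fut = _hab_vector(hab_future)
    hab_cur = _hab_vector(hab_current)

    ref = subsample_reference_cells(n, config.reference_fraction, config.seed)
    sim_fut = np.exp(-cdist(f_cur, f_fut[ref], metric="cityblock"))
    sim_cur = np.exp(-cdist(f_cur, f_cur[ref], metric="cityblock"))
    numerator = sim_fut @ hab_fut[ref]
    denominator = sim_cur @ hab_cur[ref]
    if np.any(denominator <= 0):
        raise ValueError("zero denominator in the persistence ratio")
    ratio = np.clip(numerator / denominator, 0.0, 1.0)
    p = ratio**config.z
    return p, numerator, denominator


def aggregate_persistence(p: np.ndarray, species_total: int,
                          config: ExtinctionConfig | None = None,
                          weights: np.ndarray | None = None,
                          scenario: str = "",
                          time_slice: tuple[int, int] | None = None,
                          ) -> PersistenceResult:
    """Weighted geometric mean of p, species heading for extinction S(1 - P)."""
    config = config or ExtinctionConfig()
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("persistence proportions must lie in [0, 1]")
    if weights is None:
        weights = config.cell_weights
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")

    def _geomean(eps: float) -> float:
        return float(np.exp(np.sum(w * np.log(np.maximum(p, eps))) / w.sum()))

    pbar = _geomean(config.geometric_mean_floor)
    sensitivity = {
        eps: _geomean(eps) for eps in (config.geometric_mean_floor, 1e-6, 1e-3)
    }
    return PersistenceResult(
        p=p,
        persistence=pbar,
        species_total=int(species_total),
        heading_for_extinction=species_total * (1.0 - pbar),
        scenario=scenario,
        time_slice=time_slice,
        epsilon_sensitivity=sensitivity,
    )


def scenario_comparison(results: dict[str, float | int],
                        species_total: int,
                        historic_extinctions: int | None = None) -> pd.DataFrame:
    """Compare species-heading-for-extinction counts across scenarios.

    ``results`` maps scenario name -> N (count heading for extinction).
    Reports, per ordered scenario pair (A, B), the percent reduction
    100 (N_A - N_B) / N_A, plus per scenario the percent of the fauna and
    the ratio to historic extinctions. Percent values are rounded to
    integers and ratios to one decimal in the rounded columns; unrounded
    values are always reported alongside.
    """
    rows = []
    for name, n in results.items():
        ratio = (n / historic_extinctions) if historic_extinctions else np.nan
        rows.append(
            {
                "kind": "scenario",
                "scenario": name,
                "n_heading": n,
                "percent_of_fauna": 100.0 * n / species_total,
                "percent_of_fauna_rounded": int(round(100.0 * n / species_total)),
                "ratio_to_historic": ratio,
                "ratio_to_historic_rounded": round(ratio, 1) if np.isfinite(ratio) else np.nan,
            }
        )
    names = list(results)
    for a in names:
        for b in names:
            if a == b:
                continue
            if results[a] == 0:
                reduction = np.nan  # undefined relative change from zero
            else:
                reduction = 100.0 * (results[a] - results[b]) / results[a]
            rows.append(
                {
                    "kind": "reduction",
                    "scenario": f"{a}->{b}",
                    "reduction_pct": reduction,
                    "reduction_pct_rounded": (
                        int(round(reduction)) if np.isfinite(reduction) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
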