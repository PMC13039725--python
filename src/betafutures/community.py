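"""Incidence preparation: pooling, Jaccard dissimilarity, sample coverage,
site-pair tables and a collinearity screen.

Sites are pooled over survey years into incidence assemblages; sampling
completeness per site is estimated from singleton/doubleton year frequencies
(Chao incidence coverage) and used to weight site pairs in downstream
dissimilarity models. Sites surveyed fewer than two years are excluded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class CoverageStats:
    """Chao incidence-based sample-coverage summary for one site.

    T: sampled years; U: total incidence count (sum of year frequencies);
    Q1/Q2: species detected in exactly one/two years; C_hat: estimated
    coverage in [0, 1], NaN when unestimable (no incidences).
    """

    T: int
    U: int
    Q1: int
    Q2: int
    C_hat: float

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.C_hat)


@dataclass
class SitePairTable:
    """Unordered site pairs with observed dissimilarity, weight and predictors.

    ``table`` columns: site_i, site_j, distance, weight, then s1.<var> and
    s2.<var> for every predictor (the gdm site-pair layout).
    """

    table: pd.DataFrame
    predictors: list[str]

    def __len__(self) -> int:
        return len(self.table)

    def write_csv(self, path) -> None:
        cols = ["site_i", "site_j", "distance", "weight"]
        cols += [f"s1.{v}" for v in self.predictors] + [f"s2.{v}" for v in self.predictors]
        self.table[cols].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SitePairTable":
        frame = pd.read_csv(path)
        predictors = [c[3:] for c in frame.columns if c.startswith("s1.")]
        return cls(table=frame, predictors=predictors)


def pool_incidence(records: CommunityTable | pd.DataFrame, site_id: int
                   ) -> tuple[set[str], pd.Series]:
    """Pool one site's records over years.

    Returns the union assemblage and the per-species year frequency
    (number of distinct years each species was detected).
    """
    frame = records.records if isinstance(records, CommunityTable) else records
    sub = frame[(frame["site_id"] == site_id) & (frame["present"] == 1)]
    if isinstance(records, CommunityTable) and site_id not in set(records.sites):
        raise KeyError(f"unknown site {site_id!r}")
    if sub.empty and not isinstance(records, CommunityTable):
        if site_id not in set(frame["site_id"]):
            raise KeyError(f"unknown site {site_id!r}")
    freq = sub.groupby("species_id")["year"].nunique()
    return set(freq.index), freq


def jaccard_dissimilarity(assemblage_a: set, assemblage_b: set) -> float:
    """1 - |intersection| / |union|; undefined (error) when both sets are empty."""
    union = assemblage_a | assemblage_b
    if not union:
        raise ValueError("Jaccard dissimilarity undefined for two empty assemblages")
    return 1.0 - len(assemblage_a & assemblage_b) / len(union)


def incidence_sample_coverage(year_frequencies: pd.Series | np.ndarray,
                              n_years: int) -> CoverageStats:
    """Chao incidence coverage from per-species year frequencies.

    C_hat = 1 - (Q1/U) * [(T-1) Q1 / ((T-1) Q1 + 2 Q2)]. Sites with T < 2
    are rejected (coverage cannot be estimated from a single sampling unit);
    U = 0 yields NaN (unestimable, site to be dropped by the caller).
    """
    if n_years < 2:
        raise ValueError("sample coverage requires at least two sampled years")
    freqs = np.asarray(year_frequencies, dtype=int)
    T = int(n_years)
    U = int(freqs.sum())
    Q1 = int(np.sum(freqs == 1))
    Q2 = int(np.sum(freqs == 2))
    if U == 0:
        return CoverageStats(T=T, U=0, Q1=0, Q2=0, C_hat=float("nan"))
    if Q1 == 0:
        c_hat = 1.0
    else:
        denom = (T - 1) * Q1 + 2 * Q2
        c_hat = 1.0 - (Q1 / U) * ((T - 1) * Q1 / denom)
    return CoverageStats(T=T, U=U, Q1=Q1, Q2=Q2, C_hat=float(np.clip(c_hat, 0.0, 1.0)))


def site_coverages(community: CommunityTable, n_years: int) -> pd.Series:
    """Coverage per site; sites with unestimable coverage are dropped (logged)."""
    values = {}
    for site in community.sites:
        _, freq = pool_incidence(community, int(site))
        try:
            stats = incidence_sample_coverage(freq, n_years)
        except ValueError:
            logger.info("site %s excluded: fewer than two sampled years", site)
            continue
        if not stats.estimable:
            logger.info("site %s excluded: coverage unestimable (no incidences)", site)
            continue
        values[int(site)] = stats.C_hat
    return pd.Series(values, name="coverage")


def build_site_pair_table(assemblages: dict[int, set], env: pd.DataFrame,
                          coverages: pd.Series, max_pairs: int | None = None,
                          seed: int = 0) -> SitePairTable:
    """All (or a seeded uniform subset of) unordered site pairs.

    ``env`` is indexed by site with one column per predictor. Pair weight is
    the arithmetic mean of the two site coverages; distance is the Jaccard
    dissimilarity of the pooled assemblages. Pairs where both assemblages are
    empty are skipped.
    """
    sites = [s for s in assemblages if s in env.index and s in coverages.index]
    if len(sites) < 2:
        raise ValueError("need at least two sites with environment and coverage")
    pairs = list(itertools.combinations(sorted(sites), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]

    predictors = list(env.columns)
    rows = []
    for i, j in pairs:
        a, b = assemblages[i], assemblages[j]
        if not (a | b):
            continue
        d = jaccard_dissimilarity(a, b)
        w = 0.5 * (coverages[i] + coverages[j])
        rows.append((i, j, d, w, *env.loc[i, predictors], *env.loc[j, predictors]))
    cols = ["site_i", "site_j", "distance", "weight"]
    cols += [f"s1.{v}" for v in predictors] + [f"s2.{v}" for v in predictors]
    return SitePairTable(table=pd.DataFrame(rows, columns=cols), predictors=predictors)


def collinearity_screen(env: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Pairwise Pearson correlations with |r| >= threshold flagged.

    Diagnostic only: flagged variable pairs are retained by default (strongly
    correlated temperature variables are ecologically meaningful to keep).
    Zero-variance variables yield NaN correlations and are flagged undefined.
    """
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise ValueError("need at least two variables and three sites")
    rows = []
    names = list(env.columns)
    corr = env.corr(method="pearson")
    for a, b in itertools.combinations(names, 2):
        r = corr.loc[a, b]
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "pearson_r": r,
                "flagged": bool(np.isnan(r) or abs(r) >= threshold),
                "undefined": bool(np.isnan(r)),
            }
        )
    return pd.DataFrame(rows)


def read_community_csv(path, sites: np.ndarray | None = None) -> CommunityTable:
    """Read site_id,species_id,year,present records."""
    frame = pd.read_csv(path)
    required = {"site_id", "species_id", "year", "present"}
    if not required.issubset(frame.columns):
        raise ValueError(f"community file must have columns {sorted(required)}")
    if sites is None:
        sites = np.asarray(sorted(frame["site_id"].unique()))
    return CommunityTable(records=frame, sites=sites, niches=[], true_presence=None)
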