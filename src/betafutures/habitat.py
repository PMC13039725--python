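"""Habitat condition from land use and the Biodiversity Intactness Index.

Each harmonised land-use class carries a BII value in [0, 1]: the product of
a reference-relative total-abundance coefficient and a reference-relative
compositional-similarity coefficient. Class BIIs applied to yearly land-use
maps give per-cell habitat condition, averaged over forecast time slices.
Special rules: the urban BII is scaled by the pervious fraction (mean urban
imperviousness 30%), agroforestry averages three constituent classes, and
under the fossil-fuelled development pathway hyper-intensive classes decline
linearly between fixed year/BII endpoints then plateau.

A simplified BII estimator (fixed-effects least squares with per-study
intercepts in place of mixed models) recovers per-class coefficients from a
multi-study site x species abundance table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# elementary transforms


def standardise_and_rescale_abundance(abundances: pd.DataFrame,
                                      sites: pd.DataFrame) -> pd.Series:
    """Per-site total abundance / effort, rescaled to a max of 1 per study.

    ``abundances``: study, site, species, abundance (effort-sensitive counts);
    ``sites``: study, site, effort. All-zero studies are flagged and left
    unscaled at zero.
    """
    totals = abundances.groupby(["study", "site"])["abundance"].sum()
    effort = sites.set_index(["study", "site"])["effort"]
    if (effort <= 0).any():
        raise ValueError("sampling effort must be positive")
    standardised = (totals / effort).reindex(effort.index).fillna(0.0)
    out = {}
    for study, sub in standardised.groupby(level="study"):
        m = sub.max()
        if m <= 0:
            logger.warning("study %s has zero total abundance; rescale skipped", study)
            out.update(sub.to_dict())
        else:
            out.update((sub / m).to_dict())
    return pd.Series(out, name="rescaled_abundance").reindex(effort.index)


def bray_components(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """A = sum min, B = sum(x - min), C = sum(y - min)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must share a length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    m = np.minimum(x, y)
    return float(m.sum()), float((x - m).sum()), float((y - m).sum())


def bc_balanced_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    """Balanced-variation component of abundance-based Bray-Curtis.

    d_bal = min(B, C) / (A + min(B, C)). If either site has no individuals
    the similarity convention is 0, i.e. d_bal = 1.
    """
    a, b, c = bray_components(x, y)
    if a + b == 0 or a + c == 0:  # an empty site
        return 1.0
    mbc = min(b, c)
    denom = a + mbc
    return 0.0 if denom == 0 else mbc / denom


def logit_adjusted(s: np.ndarray | float, adj: float = 0.05) -> np.ndarray | float:
    """Compress [0,1] to [adj, 1-adj] then logit; handles exact 0 and 1."""
    if not (0 < adj < 0.5):
        raise ValueError("adjustment must lie in (0, 0.5)")
    s2 = adj + (1.0 - 2.0 * adj) * np.asarray(s, dtype=float)
    out = np.log(s2 / (1.0 - s2))
    return float(out) if np.ndim(out) == 0 else out


def inv_logit_adjusted(v: np.ndarray | float, adj: float = 0.05) -> np.ndarray | float:
    if not (0 < adj < 0.5):
        raise ValueError("adjustment must lie in (0, 0.5)")
    s2 = 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))
    out = (s2 - adj) / (1.0 - 2.0 * adj)
    return float(out) if np.ndim(out) == 0 else out


def gower_env_distance(site_a: dict[str, float], site_b: dict[str, float],
                       ranges: dict[str, float], cube_root: bool = False) -> float:
    """Range-normalised mean absolute difference over shared variables.

    Zero-range variables are dropped with a warning. With ``cube_root`` the
    distance is cube-root transformed (the modelling covariate variant).
    """
    shared = [v for v in site_a if v in site_b and v in ranges]
    terms = []
    for v in shared:
        if ranges[v] == 0:
            logger.warning("variable %s has zero range; dropped from Gower distance", v)
            continue
        terms.append(abs(site_a[v] - site_b[v]) / ranges[v])
    if not terms:
        raise ValueError("no usable shared variables for Gower distance")
    d = float(np.mean(terms))
    return d ** (1.0 / 3.0) if cube_root else d


# --------------------------------------------------------------------------
# BII table


@dataclass
class DynamicBii:
    """Linear BII decline between two (year, value) endpoints, then plateau."""

    year_start: int = 2037
    bii_start: float = 0.63
    year_end: int = 2070
    bii_end: float = 0.50

    def __post_init__(self) -> None:
        if self.bii_end > self.bii_start:
            raise ValueError("dynamic BII must not increase (bii_end <= bii_start)")

    def at(self, year: float) -> float:
        if year <= self.year_start:
            return self.bii_start
        if year >= self.year_end:
            return self.bii_end
        frac = (year - self.year_start) / (self.year_end - self.year_start)
        return self.bii_start + frac * (self.bii_end - self.bii_start)


@dataclass
class BiiTable:
    """Per-class BII values (static) plus dynamic hyper-intensive classes."""

    static: dict[str, float] = field(default_factory=dict)
    dynamic: dict[str, DynamicBii] = field(default_factory=dict)
    abundance_coefficients: dict[str, float] = field(default_factory=dict)
    similarity_coefficients: dict[str, float] = field(default_factory=dict)

    def classes(self) -> set[str]:
        return set(self.static) | set(self.dynamic)

    def bii(self, land_use: str, year: float | None = None) -> float:
        if land_use in self.dynamic:
            if year is None:
                raise ValueError(f"class {land_use!r} is dynamic; a year is required")
            return self.dynamic[land_use].at(year)
        if land_use not in self.static:
            raise KeyError(f"no BII entry for land-use class {land_use!r}")
        return self.static[land_use]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, b in sorted(self.static.items()):
            rows.append(
                {
                    "land_use": c,
                    "ab_coef": self.abundance_coefficients.get(c, np.nan),
                    "cs_coef": self.similarity_coefficients.get(c, np.nan),
                    "bii": b,
                    "year_start": np.nan, "bii_start": np.nan,
                    "year_end": np.nan, "bii_end": np.nan,
                }
            )
        for c, dyn in sorted(self.dynamic.items()):
            rows.append(
                {
                    "land_use": c, "ab_coef": np.nan, "cs_coef": np.nan, "bii": np.nan,
                    "year_start": dyn.year_start, "bii_start": dyn.bii_start,
                    "year_end": dyn.year_end, "bii_end": dyn.bii_end,
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "BiiTable":
        frame = pd.read_csv(path)
        table = cls()
        for _, row in frame.iterrows():
            if np.isfinite(row.get("bii", np.nan)):
                table.static[row["land_use"]] = float(row["bii"])
                if np.isfinite(row.get("ab_coef", np.nan)):
                    table.abundance_coefficients[row["land_use"]] = float(row["ab_coef"])
                if np.isfinite(row.get("cs_coef", np.nan)):
                    table.similarity_coefficients[row["land_use"]] = float(row["cs_coef"])
            else:
                table.dynamic[row["land_use"]] = DynamicBii(
                    year_start=int(row["year_start"]), bii_start=float(row["bii_start"]),
                    year_end=int(row["year_end"]), bii_end=float(row["bii_end"]),
                )
        return table


def adjust_urban(b_urban: float, imperviousness: float = 0.30) -> float:
    """Impermeable fraction contributes zero: adjusted = (1 - imperviousness) * b."""
    return (1.0 - imperviousness) * b_urban


def agroforestry_bii(b_sustainable_ag: float, b_extensive_pastoral: float,
                     b_productive_forestry: float) -> float:
    """Arithmetic mean of the three constituent class BIIs."""
    return float(np.mean([b_sustainable_ag, b_extensive_pastoral, b_productive_forestry]))


def hyper_intensive_bii(year: float,
                        endpoints: tuple[int, float, int, float] = (2037, 0.63, 2070, 0.50)
                        ) -> float:
    """Dynamic BII of a hyper-intensive class at a given year."""
    y0, b0, y1, b1 = endpoints
    return DynamicBii(year_start=y0, bii_start=b0, year_end=y1, bii_end=b1).at(year)


def hyper_intensive_from_distance_rule(b_intensive: float, b_extensive: float,
                                       fraction: float = 0.8) -> float:
    """Optional constructor for the hyper-intensive *maximum* BII.

    Interprets "intensive plus a fraction of the extensive-intensive gap" as
    b_intensive + fraction * (b_extensive - b_intensive); the caller decides
    whether that reading fits their coefficient table (the rule's direction
    is ambiguous, so the fixed year/BII endpoints remain the default path).
    """
    return b_intensive + fraction * (b_extensive - b_intensive)


# --------------------------------------------------------------------------
# estimation from a multi-study abundance table


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def estimate_bii_coefficients(sites: pd.DataFrame, abundances: pd.DataFrame,
                              reference_class: str = "reference",
                              adj: float = 0.05) -> BiiTable:
    """Estimate per-class abundance and similarity coefficients, combine to BII.

    Abundance: least squares of sqrt(rescaled site abundance) on land-use
    class + sqrt(NPP) with per-study intercepts (fixed-effects stand-in for
    the random-intercept model); class coefficient = squared ratio of the
    class to the reference prediction, clipped to [0, 1].

    Similarity: within each study, compositional similarity (1 - d_bal) of
    every site against every reference site, logit-adjusted, regressed on the
    class transition + cubic terms in log1p geographic distance and cube-root
    Gower-style environmental distance + sqrt(NPP) + study intercepts; class
    coefficient = back-transformed class effect at zero distance relative to
    the reference-to-reference prediction, clipped to [0, 1].
    """
    import statsmodels.api as sm

    rescaled = standardise_and_rescale_abundance(abundances, sites)
    info = sites.set_index(["study", "site"])
    classes = sorted(sites["land_use"].unique())
    non_ref = [c for c in classes if c != reference_class]

    # ----- abundance model
    y_ab = np.sqrt(rescaled.to_numpy(float))
    cls = info["land_use"].to_numpy()
    sqrt_npp = np.sqrt(info["npp"].to_numpy(float))
    sqrt_npp = sqrt_npp - sqrt_npp.mean()
    studies = info.index.get_level_values("study").to_numpy()
    study_levels = sorted(set(studies))
    X_cols = [np.ones(len(y_ab))]
    for c in non_ref:
        X_cols.append((cls == c).astype(float))
    X_cols.append(sqrt_npp)
    for s in study_levels[1:]:
        X_cols.append((studies == s).astype(float))
    X = np.column_stack(X_cols)
    res = sm.OLS(y_ab, X).fit()
    beta = res.params
    study_effects = np.concatenate([[0.0], beta[1 + len(non_ref) + 1 :]])
    base = beta[0] + study_effects.mean()  # predicted sqrt abundance, reference class
    ab_coef = {reference_class: 1.0}
    for i, c in enumerate(non_ref):
        ratio = (base + beta[1 + i]) / base if base > 0 else np.nan
        ab_coef[c] = float(np.clip(ratio**2, 0.0, 1.0)) if np.isfinite(ratio) else np.nan

    # ----- similarity model
    pair_rows = []
    env_vars = ["npp"]  # stand-in climate/elevation covariates for Gower distance
    ranges = {v: float(sites[v].max() - sites[v].min()) for v in env_vars}
    species_index = sorted(abundances["species"].unique())
    sp_pos = {s: i for i, s in enumerate(species_index)}
    for study, site_sub in sites.groupby("study"):
        refs = site_sub[site_sub["land_use"] == reference_class]
        if refs.empty:
            continue
        ab_sub = abundances[abundances["study"] == study]
        mats = {}
        for site, rows in ab_sub.groupby("site"):
            vec = np.zeros(len(species_index))
            vec[[sp_pos[s] for s in rows["species"]]] = rows["abundance"].to_numpy(float)
            eff = info.loc[(study, site), "effort"]
            mats[site] = vec / eff
        for _, ref_row in refs.iterrows():
            rv = mats.get(ref_row["site"], np.zeros(len(species_index)))
            for _, row in site_sub.iterrows():
                if row["site"] == ref_row["site"]:
                    continue
                ov = mats.get(row["site"], np.zeros(len(species_index)))
                sim = 1.0 - bc_balanced_dissimilarity(rv, ov)
                geo = float(np.hypot(row["x"] - ref_row["x"], row["y"] - ref_row["y"]))
                env_d = gower_env_distance(
                    {v: row[v] for v in env_vars},
                    {v: ref_row[v] for v in env_vars},
                    ranges, cube_root=True,
                )
                pair_rows.append(
                    (study, row["land_use"], sim, np.log1p(geo), env_d, row["npp"])
                )
    if not pair_rows:
        raise ValueError(f"no study has a {reference_class!r} site")
    pairs = pd.DataFrame(
        pair_rows, columns=["study", "land_use", "sim", "log_geo", "env_d", "npp"]
    )
    y_cs = logit_adjusted(pairs["sim"].to_numpy(float), adj=adj)
    cls2 = pairs["land_use"].to_numpy()
    sqrt_npp2 = np.sqrt(pairs["npp"].to_numpy(float))
    sqrt_npp2 = sqrt_npp2 - sqrt_npp2.mean()
    studies2 = pairs["study"].to_numpy()
    levels2 = sorted(set(studies2))
    cols = [np.ones(len(pairs))]
    for c in non_ref:
        cols.append((cls2 == c).astype(float))
    for k in (1, 2, 3):
        cols.append(pairs["log_geo"].to_numpy(float) ** k)
    for k in (1, 2, 3):
        cols.append(pairs["env_d"].to_numpy(float) ** k)
    cols.append(sqrt_npp2)
    for s in levels2[1:]:
        cols.append((studies2 == s).astype(float))
    X2 = np.column_stack(cols)
    beta2 = _ols(X2, y_cs)
    n_study2 = len(levels2) - 1
    study_eff2 = np.concatenate([[0.0], beta2[len(beta2) - n_study2 :]]) if n_study2 else np.zeros(1)
    eta_ref = beta2[0] + study_eff2.mean()  # ref->ref at zero distances, mean NPP
    s_ref = inv_logit_adjusted(eta_ref, adj=adj)
    cs_coef = {reference_class: 1.0}
    for i, c in enumerate(non_ref):
        s_c = inv_logit_adjusted(eta_ref + beta2[1 + i], adj=adj)
        cs_coef[c] = float(np.clip(s_c / s_ref, 0.0, 1.0)) if s_ref > 0 else np.nan

    table = BiiTable()
    for c in classes:
        a, s = ab_coef.get(c, np.nan), cs_coef.get(c, np.nan)
        table.abundance_coefficients[c] = a
        table.similarity_coefficients[c] = s
        table.static[c] = float(np.clip(a * s, 0.0, 1.0))
    missing = [c for c in classes if not np.isfinite(table.static.get(c, np.nan))]
    for c in missing:
        logger.warning("class %s absent or unestimable; BII flagged missing", c)
        table.static[c] = float("nan")
    return table


# --------------------------------------------------------------------------
# habitat condition maps


@dataclass
class HabitatConditionMap:
    """Per-cell habitat condition for one scenario x time slice."""

    values: np.ndarray  # slice-mean hab in [0, 1]
    yearly: dict[int, np.ndarray]
    scenario: str = ""
    time_slice: tuple[int, int] | None = None


def habitat_condition_map(landuse_by_year: dict[int, np.ndarray],
                          legend: dict[int, str], bii_table: BiiTable,
                          time_slice: tuple[int, int], scenario: str = "",
                          ) -> HabitatConditionMap:
    """hab(cell, year) = BII of the cell's class at that year; slice mean.

    Yearly maps are sampled annually across the slice, each year using the
    most recent available land-use map (decadal maps repeat forward) and
    evaluating dynamic class BIIs at that calendar year.
    """
    years_available = sorted(landuse_by_year)
    start, end = time_slice
    known = bii_table.classes()
    unmapped = set(legend.values()) - known
    if unmapped:
        raise KeyError(f"land-use classes without a BII entry: {sorted(unmapped)}")

    yearly: dict[int, np.ndarray] = {}
    for year in range(start, end + 1):
        usable = [y for y in years_available if y <= year]
        map_year = usable[-1] if usable else years_available[0]
        class_map = landuse_by_year[map_year]
        hab = np.empty(class_map.shape)
        for code, name in legend.items():
            hab[class_map == code] = np.clip(bii_table.bii(name, year=year), 0.0, 1.0)
        yearly[year] = hab
    values = np.mean(np.stack(list(yearly.values())), axis=0)
    return HabitatConditionMap(values=values, yearly=yearly,
                               scenario=scenario, time_slice=time_slice)
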