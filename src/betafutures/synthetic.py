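"""Synthetic inputs with known ground truth.

Everything the projection pipeline consumes can be generated here:
environmental landscapes (two topographic variables, one soil variable with
missing cells, seven climate variables), niche-structured plant/butterfly/
bird-like communities with imperfect multi-year detection, smoothly shifted
future climates of tunable severity, Markov land-use scenario maps, and
multi-study site x species abundance tables resembling a land-use impact
database with a reference land-use class and an NPP covariate.

Each generator is bit-reproducible under its seed and exposes its ground
truth (niches, per-class degradation factors, climate shifts) so downstream
estimators can be scored against it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvGrid

STATIC_VAR_NAMES = ("tri", "twi", "soil_ph")
CLIMATE_VAR_NAMES = (
    "tmin_annual",
    "tmax_annual",
    "diurnal_range_max",
    "precip_annual",
    "precip_seasonality",
    "peti_driest_month",
    "sunshine",
)

#: Harmonised land-use classes used by the scenario generator and the
#: habitat-condition module. "reference" stands for natural/semi-natural
#: vegetation against which the other classes are compared.
DEFAULT_LANDUSE_CLASSES = (
    "reference",
    "extensive_pastoral",
    "intensive_pastoral",
    "sustainable_agriculture",
    "intensive_agriculture",
    "productive_forestry",
    "urban",
)


@dataclass
class LandscapeSpec:
    """Specification of a synthetic environmental landscape."""

    grid_dims: tuple[int, int] = (20, 20)
    n_static_vars: int = 3
    n_climate_vars: int = 7
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.grid_dims
        if r <= 0 or c <= 0:
            raise ValueError(f"grid_dims must be positive, got {self.grid_dims}")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_static_vars < 1 or self.n_climate_vars < 1:
            raise ValueError("need at least one static and one climate variable")


@dataclass
class SpeciesNiche:
    """Product-Gaussian niche of one species over a subset of variables."""

    species_id: str
    optima: dict[str, float]
    tolerances: dict[str, float]
    max_occurrence_prob: float = 0.9
    detection_prob_per_year: float = 0.8

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be strictly positive")
        if not (0 < self.max_occurrence_prob <= 1):
            raise ValueError("max_occurrence_prob must be in (0, 1]")
        if not (0 < self.detection_prob_per_year <= 1):
            raise ValueError("detection_prob_per_year must be in (0, 1]")

    def occurrence_prob(self, env: dict[str, float]) -> float:
        logq = 0.0
        for var, opt in self.optima.items():
            tol = self.tolerances[var]
            logq -= (env[var] - opt) ** 2 / (2.0 * tol**2)
        return self.max_occurrence_prob * float(np.exp(logq))


@dataclass
class ScenarioSpec:
    """A coherent future: climate trend severity plus land-use dynamics."""

    name: str = "RCP8.5-SSP5"
    climate_shift_severity: dict[str, float] = field(default_factory=dict)
    landuse_transition_matrix: np.ndarray | None = None
    classes: tuple[str, ...] = DEFAULT_LANDUSE_CLASSES
    years: tuple[int, ...] = tuple(range(2015, 2081, 5))
    time_slices: tuple[tuple[int, int], ...] = (
        (2020, 2040),
        (2040, 2060),
        (2060, 2080),
    )

    def __post_init__(self) -> None:
        if self.landuse_transition_matrix is not None:
            P = np.asarray(self.landuse_transition_matrix, dtype=float)
            if P.shape != (len(self.classes), len(self.classes)):
                raise ValueError("transition matrix shape must match classes")
            if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition matrix rows must be probabilities summing to 1")
            self.landuse_transition_matrix = P
        lo, hi = min(self.years), max(self.years)
        for a, b in self.time_slices:
            if not (lo <= a < b <= hi):
                raise ValueError(f"time slice {(a, b)} outside scenario years [{lo}, {hi}]")


# --------------------------------------------------------------------------
# landscape generation


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  n_harmonics: int = 6, noise_sd: float = 0.05) -> np.ndarray:
    """Spatially autocorrelated field: superposed low-frequency harmonics + noise."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows) / max(rows, 2),
                         np.arange(cols) / max(cols, 2), indexing="ij")
    out = np.zeros(shape)
    for _ in range(n_harmonics):
        fx, fy = rng.uniform(0.3, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.normal(0, 1.0)
        out += amp * np.cos(2 * np.pi * (fx * rr + fy * cc) + phase)
    out += rng.normal(0, noise_sd, size=shape)
    return out


def generate_landscape(spec: LandscapeSpec) -> EnvGrid:
    """Generate an environmental landscape with smooth autocorrelated fields.

    The first static variable is a terrain ruggedness index derived from a
    generated elevation surface; the soil variable carries
    ``spec.missing_fraction`` masked (NaN) cells, mirroring a soil-pH layer
    that needs gap filling before modelling.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_dims

    static_names = list(STATIC_VAR_NAMES[: spec.n_static_vars])
    for i in range(len(static_names), spec.n_static_vars):
        static_names.append(f"static_{i}")
    climate_names = list(CLIMATE_VAR_NAMES[: spec.n_climate_vars])
    for i in range(len(climate_names), spec.n_climate_vars):
        climate_names.append(f"climate_{i}")

    data: dict[str, np.ndarray] = {}
    elevation = 300.0 + 150.0 * _smooth_field(rng, shape)
    for name in static_names:
        if name == "tri":
            data[name] = ruggedness_index(elevation)
        elif name == "soil_ph":
            soil = 5.5 + 0.8 * _smooth_field(rng, shape)
            n_missing = int(round(spec.missing_fraction * soil.size))
            if n_missing:
                holes = rng.choice(soil.size, size=n_missing, replace=False)
                soil.ravel()[holes] = np.nan
            data[name] = soil
        else:
            data[name] = _smooth_field(rng, shape)

    climate_scales = {
        "tmin_annual": (1.5, 1.2),
        "tmax_annual": (19.0, 1.5),
        "diurnal_range_max": (9.0, 1.0),
        "precip_annual": (900.0, 180.0),
        "precip_seasonality": (30.0, 6.0),
        "peti_driest_month": (55.0, 10.0),
        "sunshine": (1400.0, 120.0),
    }
    for name in climate_names:
        mean, sd = climate_scales.get(name, (0.0, 1.0))
        data[name] = mean + sd * _smooth_field(rng, shape)

    grid = EnvGrid(
        data=data,
        mask=np.ones(shape, bool),
        climate_vars=tuple(climate_names),
        epoch="current",
        attrs={"seed": spec.seed, "elevation": elevation},
    )
    # soil gaps do not invalidate cells for downstream use until a model
    # requires the variable; keep the full mask but record gap positions
    grid.attrs["soil_missing"] = (
        np.isnan(data["soil_ph"]) if "soil_ph" in data else np.zeros(shape, bool)
    )
    return grid


def derive_climate_variables(
    monthly_tmin: np.ndarray, monthly_tmax: np.ndarray, monthly_precip: np.ndarray
) -> dict[str, np.ndarray]:
    """Derive annual climate summaries from per-cell 12-month series.

    Arrays have shape (..., 12). Returns annual min/max temperature, the
    maximum monthly diurnal range, annual precipitation, and precipitation
    seasonality as 100 x population-sd / mean of the monthly totals
    (the bio15 convention). Zero mean precipitation leaves seasonality NaN.
    """
    for arr in (monthly_tmin, monthly_tmax, monthly_precip):
        if arr.shape[-1] != 12:
            raise ValueError("expected 12 monthly values on the last axis")
    out = {
        "tmin_annual": monthly_tmin.min(axis=-1),
        "tmax_annual": monthly_tmax.max(axis=-1),
        "diurnal_range_max": (monthly_tmax - monthly_tmin).max(axis=-1),
        "precip_annual": monthly_precip.sum(axis=-1),
    }
    mean = monthly_precip.mean(axis=-1)
    sd = monthly_precip.std(axis=-1)  # population sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    out["precip_seasonality"] = cv
    return out


def ruggedness_index(elevation: np.ndarray) -> np.ndarray:
    """Terrain ruggedness: mean |elevation difference| to up to 8 neighbours.

    Edge cells average over their existing neighbours only (no padding).
    """
    elevation = np.asarray(elevation, dtype=float)
    if elevation.ndim != 2 or min(elevation.shape) < 3:
        raise ValueError("elevation grid must be 2-D with at least 3x3 extent")
    total = np.zeros_like(elevation)
    count = np.zeros_like(elevation)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(elevation, np.nan)
            rs = slice(max(dr, 0), elevation.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), elevation.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), elevation.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), elevation.shape[1] + min(-dc, 0))
            shifted[rd, cd] = elevation[rs, cs]
            ok = np.isfinite(shifted)
            total[ok] += np.abs(elevation - shifted)[ok]
            count[ok] += 1
    return total / count


def idw_fill(grid: np.ndarray, power: float = 2.0,
             max_neighbours: int | None = None) -> np.ndarray:
    """Fill NaN cells by inverse-distance-weighted means of observed cells.

    Cells are unit squares; distances are Euclidean between cell centres.
    Observed cells are returned unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    missing = np.argwhere(np.isnan(grid))
    observed = np.argwhere(np.isfinite(grid))
    if observed.size == 0:
        raise ValueError("cannot interpolate: all cells missing")
    if missing.size == 0:
        return grid.copy()
    out = grid.copy()
    obs_vals = grid[observed[:, 0], observed[:, 1]]
    for r, c in missing:
        d2 = (observed[:, 0] - r) ** 2.0 + (observed[:, 1] - c) ** 2.0
        dist = np.sqrt(d2)
        if max_neighbours is not None and len(dist) > max_neighbours:
            nearest = np.argpartition(dist, max_neighbours)[:max_neighbours]
            dist_k, vals_k = dist[nearest], obs_vals[nearest]
        else:
            dist_k, vals_k = dist, obs_vals
        w = dist_k ** (-power)
        out[r, c] = np.sum(w * vals_k) / np.sum(w)
    return out


# --------------------------------------------------------------------------
# communities


@dataclass
class CommunityTable:
    """Site x species x year incidence records plus generator ground truth."""

    records: pd.DataFrame  # site_id, species_id, year, present
    sites: np.ndarray  # flat cell ids of surveyed sites
    niches: list[SpeciesNiche]
    true_presence: pd.DataFrame | None = None  # site x species booleans

    def assemblage(self, site_id: int) -> set[str]:
        sub = self.records[(self.records.site_id == site_id) & (self.records.present == 1)]
        return set(sub.species_id)

    def write_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def default_niches(env: EnvGrid, n_species: int, seed: int,
                   n_niche_vars: int = 3,
                   detection_prob: float = 0.8) -> list[SpeciesNiche]:
    """Draw product-Gaussian niches spanning the landscape's gradients."""
    rng = np.random.default_rng(seed)
    names = env.variables
    stats = {
        v: (np.nanmean(env.data[v]), max(np.nanstd(env.data[v]), 1e-6))
        for v in names
    }
    niches = []
    for i in range(n_species):
        chosen = rng.choice(names, size=min(n_niche_vars, len(names)), replace=False)
        optima, tols = {}, {}
        for v in chosen:
            mu, sd = stats[v]
            optima[v] = float(mu + rng.uniform(-1.5, 1.5) * sd)
            tols[v] = float(sd * rng.uniform(0.5, 1.5))
        niches.append(
            SpeciesNiche(
                species_id=f"sp{i:04d}",
                optima=optima,
                tolerances=tols,
                max_occurrence_prob=float(rng.uniform(0.6, 0.95)),
                detection_prob_per_year=detection_prob,
            )
        )
    return niches


def _env_uniform(seed: int, species_id: str, env_values: tuple[float, ...]) -> float:
    """Deterministic uniform in [0,1) from (seed, species, environment).

    Hashing the (rounded) environment rather than the cell index makes true
    occupancy a pure function of the environment: identical cells host
    identical true assemblages.
    """
    payload = f"{seed}|{species_id}|" + "|".join(f"{v:.9g}" for v in env_values)
    digest = hashlib.blake2b(payload.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0**64


def generate_communities(env: EnvGrid, niches: list[SpeciesNiche],
                         n_years: int, seed: int,
                         sites: np.ndarray | None = None) -> CommunityTable:
    """Sample niche-driven incidence communities with yearly imperfect detection.

    True presence at a cell is Bernoulli with the product-Gaussian niche
    probability; each survey year observes a present species with its
    detection probability. Jaccard dissimilarity between cells therefore
    grows with environmental separation.
    """
    if not niches:
        raise ValueError("niches must be non-empty")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if sites is None:
        sites = env.valid_indices()
    rng = np.random.default_rng(seed)

    var_order = env.variables
    flat = {v: env.data[v].ravel() for v in var_order}
    records = []
    truth = np.zeros((len(sites), len(niches)), dtype=bool)
    for si, cell in enumerate(sites):
        env_here = {v: float(flat[v][cell]) for v in var_order}
        env_key = tuple(env_here[v] for v in var_order)
        for pi, niche in enumerate(niches):
            prob = niche.occurrence_prob(env_here)
            present = _env_uniform(seed, niche.species_id, env_key) < prob
            truth[si, pi] = present
            if not present:
                continue
            detected_years = np.nonzero(
                rng.random(n_years) < niche.detection_prob_per_year
            )[0]
            for y in detected_years:
                records.append((int(cell), niche.species_id, int(y), 1))

    frame = pd.DataFrame(records, columns=["site_id", "species_id", "year", "present"])
    truth_frame = pd.DataFrame(
        truth, index=pd.Index(sites, name="site_id"),
        columns=[n.species_id for n in niches],
    )
    return CommunityTable(records=frame, sites=np.asarray(sites),
                          niches=niches, true_presence=truth_frame)


# --------------------------------------------------------------------------
# futures


def generate_future_climate(env: EnvGrid, scenario: ScenarioSpec,
                            time_slice: tuple[int, int]) -> EnvGrid:
    """Shift climate variables by severity x elapsed decades; statics unchanged.

    Elapsed time is measured from the first scenario year to the midpoint of
    the requested slice. Severity is the per-variable additive trend per
    decade from the scenario's ground truth.
    """
    if time_slice not in scenario.time_slices:
        lo, hi = min(scenario.years), max(scenario.years)
        a, b = time_slice
        if not (lo <= a < b <= hi):
            raise ValueError(f"slice {time_slice} outside scenario years")
    midpoint = 0.5 * (time_slice[0] + time_slice[1])
    decades = (midpoint - min(scenario.years)) / 10.0
    future = env.copy()
    for var, per_decade in scenario.climate_shift_severity.items():
        if var in future.data and var in env.climate_vars:
            future.data[var] = future.data[var] + per_decade * decades
    future.epoch = f"{scenario.name}:{time_slice[0]}-{time_slice[1]}"
    future.attrs["elapsed_decades"] = decades
    return future


def generate_landuse(scenario: ScenarioSpec, classes: tuple[str, ...],
                     seed: int, shape: tuple[int, int] = (20, 20),
                     initial_distribution: np.ndarray | None = None,
                     ) -> dict[int, np.ndarray]:
    """Markov evolution of per-cell land-use classes over the scenario years.

    Returns a mapping year -> integer class-code map (codes index ``classes``).
    The transition matrix applies per listed year step; maps are deterministic
    under the seed.
    """
    P = scenario.landuse_transition_matrix
    if P is None:
        raise ValueError("scenario has no land-use transition matrix")
    if tuple(scenario.classes) != tuple(classes):
        raise ValueError("classes do not match the scenario transition matrix")
    rng = np.random.default_rng(seed)
    k = len(classes)
    if initial_distribution is None:
        initial_distribution = np.full(k, 1.0 / k)
    state = rng.choice(k, size=shape, p=initial_distribution)
    maps = {int(scenario.years[0]): state.copy()}
    cum = np.cumsum(P, axis=1)
    for year in scenario.years[1:]:
        u = rng.random(shape)
        # vectorised categorical draw: first cumulative bin exceeding u
        state = (u[..., None] > cum[state]).sum(axis=-1)
        maps[int(year)] = state.copy()
    return maps


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix via the unit left eigenvector."""
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# land-use impact database emulation


@dataclass
class PredictsLikeData:
    """Multi-study site x species abundance table with generator truth."""

    sites: pd.DataFrame  # study, site, land_use, npp, effort, x, y
    abundances: pd.DataFrame  # study, site, species, abundance
    truth: pd.DataFrame  # land_use, abundance_factor, similarity_factor, bii


DEFAULT_CLASS_FACTORS = {
    # (abundance factor, compositional-similarity factor) relative to reference
    "reference": (1.0, 1.0),
    "extensive_pastoral": (0.95, 0.9),
    "intensive_pastoral": (0.75, 0.8),
    "sustainable_agriculture": (0.9, 0.85),
    "intensive_agriculture": (0.6, 0.65),
    "productive_forestry": (0.85, 0.8),
    "urban": (0.55, 0.6),
}


def generate_predicts_like(classes: tuple[str, ...] = DEFAULT_LANDUSE_CLASSES,
                           n_studies: int = 30, sites_per_study: int = 14,
                           n_species: int = 40, seed: int = 0,
                           class_factors: dict[str, tuple[float, float]] | None = None,
                           noise_sd: float = 0.05) -> PredictsLikeData:
    """Emulate a multi-study land-use impact database.

    Each study has its own species pool and at least two reference-class
    sites. A site of class c carries total abundance ``a_c`` times the
    reference total and keeps a fraction ``s_c`` of its abundance on the
    reference species set (the rest moves to class-specific species), so the
    balanced-variation Bray-Curtis similarity to a reference site is ``s_c``
    and the effort-standardised abundance ratio is ``a_c`` up to noise.
    NPP is higher around agricultural classes; effort varies per site.
    """
    factors = dict(DEFAULT_CLASS_FACTORS if class_factors is None else class_factors)
    for c in classes:
        factors.setdefault(c, (1.0, 1.0))
    rng = np.random.default_rng(seed)
    agri = {"sustainable_agriculture", "intensive_agriculture",
            "intensive_pastoral", "hyper_intensive_agriculture",
            "hyper_intensive_pastoral"}

    site_rows, ab_rows = [], []
    for s in range(n_studies):
        study = f"study{s:03d}"
        base = rng.lognormal(mean=1.0, sigma=0.8, size=n_species)
        novel = rng.lognormal(mean=1.0, sigma=0.8, size=n_species)
        n_ref = 2
        labels = ["reference"] * n_ref + [
            str(classes[i]) for i in rng.integers(0, len(classes), size=sites_per_study - n_ref)
        ]
        cx, cy = rng.uniform(0, 100, size=2)
        for j, cls in enumerate(labels):
            a_c, s_c = factors[cls]
            effort = float(rng.uniform(0.5, 2.0))
            npp = float(
                np.clip(0.5 + (0.25 if cls in agri else 0.0) + rng.normal(0, 0.08), 0.05, 1.5)
            )
            x, y = cx + rng.normal(0, 2.0), cy + rng.normal(0, 2.0)
            site = f"{study}_site{j:02d}"
            site_rows.append((study, site, cls, npp, effort, x, y))
            mult = np.exp(rng.normal(0, noise_sd, size=n_species))
            kept = a_c * s_c * base * mult
            moved = a_c * (1 - s_c) * novel * np.exp(rng.normal(0, noise_sd, size=n_species))
            for k in range(n_species):
                if kept[k] > 1e-12:
                    ab_rows.append((study, site, f"sp{k:03d}", kept[k] * effort))
                if moved[k] > 1e-12:
                    ab_rows.append((study, site, f"nv{k:03d}", moved[k] * effort))

    sites = pd.DataFrame(
        site_rows, columns=["study", "site", "land_use", "npp", "effort", "x", "y"]
    )
    abundances = pd.DataFrame(ab_rows, columns=["study", "site", "species", "abundance"])
    truth = pd.DataFrame(
        [
            (c, factors[c][0], factors[c][1], factors[c][0] * factors[c][1])
            for c in classes
        ],
        columns=["land_use", "abundance_factor", "similarity_factor", "bii"],
    )
    return PredictsLikeData(sites=sites, abundances=abundances, truth=truth)
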