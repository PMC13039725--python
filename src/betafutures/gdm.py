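"""Generalised dissimilarity models.

A GDM regresses pairwise compositional dissimilarity d_ij in [0, 1] on
environmental separation through monotone I-spline transforms of each
predictor and a negative-exponential link:

    d_ij = 1 - exp(-eta_ij),
    eta_ij = a0 + sum_{p,k} beta_{p,k} |I_{p,k}(x_pi) - I_{p,k}(x_pj)|

with a0 >= 0 and beta >= 0, so the fitted turnover function
f_p(x) = sum_k beta_{p,k} I_{p,k}(x) is non-decreasing in every predictor.
Three quadratic I-spline basis functions per predictor are knotted at the
minimum, median and maximum of the training values. The model is fitted by
iteratively reweighted non-negative least squares on the response scale and
reports explained deviance against an intercept-only null.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .community import SitePairTable
from .grids import EnvGrid, TransformedGrid

logger = logging.getLogger(__name__)

_CLAMP = 1e-6  # keeps observed/fitted dissimilarities away from {0, 1} in deviance


@dataclass
class SplineBasisDef:
    """Three-knot quadratic I-spline basis for one predictor.

    Knots sit at the (min, median, max) of the training values. The basis is
    built from degree-2 B-splines on the clamped knot vector
    (t1, t1, t1, t2, t3, t3, t3); the K = 3 I-splines are the reverse
    cumulative sums of the non-boundary B-splines, each rising monotonically
    from 0 at t1 to 1 at t3. A constant predictor (t1 == t3) degenerates to
    an all-zero, inert basis.
    """

    knots: tuple[float, float, float]
    order: int = 2
    n_basis: int = 3

    def __post_init__(self) -> None:
        t1, t2, t3 = self.knots
        if not (t1 <= t2 <= t3):
            raise ValueError(f"knots must be non-decreasing, got {self.knots}")

    @property
    def inert(self) -> bool:
        return self.knots[0] == self.knots[2]

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SplineBasisDef":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        return cls(knots=(float(np.min(v)), float(np.median(v)), float(np.max(v))))


def ispline_basis(x: np.ndarray | float, basis: SplineBasisDef) -> np.ndarray:
    """Evaluate the K I-spline basis functions at x (clamped to the knot span).

    Returns an array of shape x.shape + (K,), each value in [0, 1] and
    non-decreasing in x.
    """
    t1, t2, t3 = basis.knots
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.zeros(x.shape + (basis.n_basis,))
    if basis.inert:
        return out[0] if scalar else out
    xc = np.clip(x, t1, t3)
    tv = np.array([t1, t1, t1, t2, t3, t3, t3], dtype=float)
    # degree-2 B-splines: 4 of them; I_k = sum of B_m for m >= k (skip B_0)
    bvals = np.empty(x.shape + (4,))
    for m in range(4):
        coef = np.zeros(4)
        coef[m] = 1.0
        spl = BSpline(tv, coef, 2, extrapolate=False)
        bm = spl(xc)
        bvals[..., m] = np.nan_to_num(bm, nan=0.0)
    # at the right boundary scipy reports 0 for the last spline; force closure
    at_max = xc == t3
    bvals[at_max] = 0.0
    bvals[at_max, 3] = 1.0
    for k in range(basis.n_basis):
        out[..., k] = bvals[..., k + 1 :].sum(axis=-1)
    out = np.clip(out, 0.0, 1.0)
    return out[0] if scalar else out


@dataclass
class GDMModel:
    """Fitted generalised dissimilarity model.

    ``coefficients[p]`` holds the K non-negative spline weights of predictor
    p; the predictor's fitted turnover function is their weighted I-spline
    sum. ``explained_deviance_pct`` is measured against an intercept-only
    null with binomial-form deviance by default.
    """

    intercept: float
    coefficients: dict[str, np.ndarray]
    bases: dict[str, SplineBasisDef]
    null_deviance: float = float("nan")
    model_deviance: float = float("nan")
    explained_deviance_pct: float = float("nan")
    deviance_form: str = "binomial"
    converged: bool = True
    n_pairs: int = 0
    dropped_predictors: tuple[str, ...] = field(default_factory=tuple)

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)

    def predictor_total(self, name: str) -> float:
        """Maximum height sum_k beta_{p,k} of one predictor's turnover curve."""
        return float(np.sum(self.coefficients[name]))

    def transform_values(self, name: str, x: np.ndarray) -> np.ndarray:
        return ispline_basis(x, self.bases[name]) @ self.coefficients[name]

    # ------------------------------------------------------------- serialise

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "deviance_form": self.deviance_form,
            "null_deviance": self.null_deviance,
            "model_deviance": self.model_deviance,
            "explained_deviance_pct": self.explained_deviance_pct,
            "converged": self.converged,
            "n_pairs": self.n_pairs,
            "dropped_predictors": list(self.dropped_predictors),
            "predictors": {
                p: {
                    "knots": list(self.bases[p].knots),
                    "coefficients": [float(c) for c in self.coefficients[p]],
                }
                for p in self.coefficients
            },
        }

    def save(self, path: str | Path) -> None:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        Path(path).write_text(payload + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GDMModel":
        raw = json.loads(Path(path).read_text())
        coefficients = {
            p: np.asarray(entry["coefficients"], dtype=float)
            for p, entry in raw["predictors"].items()
        }
        bases = {
            p: SplineBasisDef(knots=tuple(entry["knots"]))
            for p, entry in raw["predictors"].items()
        }
        return cls(
            intercept=raw["intercept"],
            coefficients=coefficients,
            bases=bases,
            null_deviance=raw["null_deviance"],
            model_deviance=raw["model_deviance"],
            explained_deviance_pct=raw["explained_deviance_pct"],
            deviance_form=raw["deviance_form"],
            converged=raw["converged"],
            n_pairs=raw["n_pairs"],
            dropped_predictors=tuple(raw["dropped_predictors"]),
        )


# --------------------------------------------------------------------------
# fitting


def _design_matrix(pairs: SitePairTable, bases: dict[str, SplineBasisDef]
                   ) -> tuple[np.ndarray, list[str]]:
    """Columns: intercept, then |I_{p,k}(x_i) - I_{p,k}(x_j)| per predictor/basis."""
    frame = pairs.table
    cols = [np.ones(len(frame))]
    active = []
    for p, basis in bases.items():
        ii = ispline_basis(frame[f"s1.{p}"].to_numpy(float), basis)
        ij = ispline_basis(frame[f"s2.{p}"].to_numpy(float), basis)
        cols.append(np.abs(ii - ij))
        active.append(p)
    return np.concatenate([c.reshape(len(frame), -1) for c in cols], axis=1), active


def _wls_objective(beta: np.ndarray, X: np.ndarray, d: np.ndarray,
                   w: np.ndarray) -> float:
    mu = 1.0 - np.exp(-X @ beta)
    return float(np.sum(w * (d - mu) ** 2))


def _fit_nnls_irls(X: np.ndarray, d: np.ndarray, w: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 200
                   ) -> tuple[np.ndarray, bool]:
    """Minimise sum w (d - (1 - e^{-X b}))^2 s.t. b >= 0.

    Gauss-Newton on the linearised link with a damped non-negative
    least-squares step; deterministic (initialised from the link-transformed
    observations).
    """
    d_clamped = np.clip(d, _CLAMP, 1.0 - _CLAMP)
    eta0 = -np.log1p(-d_clamped)
    sw = np.sqrt(w)
    beta, _ = nnls(X * sw[:, None], eta0 * sw)
    obj = _wls_objective(beta, X, d, w)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        g = np.exp(-eta)  # d mu / d eta
        mu = 1.0 - g
        z = eta + (d - mu) / np.maximum(g, 1e-12)
        ww = np.sqrt(w) * g
        target, _ = nnls(X * ww[:, None], z * ww)
        step = 1.0
        new_obj = obj
        cand = beta
        while step > 1e-6:
            trial = beta + step * (target - beta)
            trial_obj = _wls_objective(trial, X, d, w)
            if trial_obj < obj:
                cand, new_obj = trial, trial_obj
                break
            step *= 0.5
        if new_obj >= obj - tol * max(1.0, obj):
            beta = cand
            converged = True
            break
        beta, obj = cand, new_obj
    return beta, converged


def _deviance(d: np.ndarray, mu: np.ndarray, w: np.ndarray, form: str) -> float:
    if form == "squared":
        return float(np.sum(w * (d - mu) ** 2))
    dc = np.clip(d, _CLAMP, 1.0 - _CLAMP)
    mc = np.clip(mu, _CLAMP, 1.0 - _CLAMP)
    dev = dc * np.log(dc / mc) + (1.0 - dc) * np.log((1.0 - dc) / (1.0 - mc))
    return float(2.0 * np.sum(w * dev))


def fit_gdm(pairs: SitePairTable, deviance_form: str = "binomial") -> GDMModel:
    """Fit a GDM to a weighted site-pair table.

    Constant predictors are dropped with a warning. A fully degenerate table
    (no predictor variation) yields an intercept-only model.
    """
    frame = pairs.table
    d = frame["distance"].to_numpy(float)
    w = frame["weight"].to_numpy(float)
    if np.any(~np.isfinite(d)) or np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("distances/weights must be finite and weights non-negative")

    bases: dict[str, SplineBasisDef] = {}
    dropped = []
    for p in pairs.predictors:
        values = np.concatenate(
            [frame[f"s1.{p}"].to_numpy(float), frame[f"s2.{p}"].to_numpy(float)]
        )
        basis = SplineBasisDef.from_values(values)
        if basis.inert:
            dropped.append(p)
            warnings.warn(f"predictor {p!r} is constant; dropped from the GDM")
        else:
            bases[p] = basis
    if not bases:
        warnings.warn("no predictor variation: fitting an intercept-only model")

    X, active = _design_matrix(pairs, bases)
    if len(frame) < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} pairs for {len(active)} predictors, got {len(frame)}"
        )
    beta, converged = _fit_nnls_irls(X, d, w)

    intercept = float(beta[0])
    coefficients = {
        p: beta[1 + 3 * i : 4 + 3 * i].copy() for i, p in enumerate(active)
    }

    mu = 1.0 - np.exp(-(X @ beta))
    model_dev = _deviance(d, mu, w, deviance_form)
    # intercept-only null fitted with the same objective
    null_beta, _ = _fit_nnls_irls(np.ones((len(d), 1)), d, w)
    null_mu = 1.0 - np.exp(-null_beta[0]) * np.ones_like(d)
    null_dev = _deviance(d, null_mu, w, deviance_form)
    explained = 0.0 if null_dev <= 0 else 100.0 * (1.0 - model_dev / null_dev)

    return GDMModel(
        intercept=intercept,
        coefficients=coefficients,
        bases=bases,
        null_deviance=null_dev,
        model_deviance=model_dev,
        explained_deviance_pct=float(explained),
        deviance_form=deviance_form,
        converged=converged,
        n_pairs=len(frame),
        dropped_predictors=tuple(dropped),
    )


def explained_deviance(model: GDMModel, pairs: SitePairTable,
                       form: str | None = None) -> float:
    """Percent deviance explained relative to an intercept-only null fit."""
    form = form or model.deviance_form
    frame = pairs.table
    d = frame["distance"].to_numpy(float)
    w = frame["weight"].to_numpy(float)
    X, active = _design_matrix(pairs, model.bases)
    beta = np.concatenate(
        [[model.intercept]] + [model.coefficients[p] for p in active]
    )
    mu = 1.0 - np.exp(-(X @ beta))
    model_dev = _deviance(d, mu, w, form)
    null_beta, _ = _fit_nnls_irls(np.ones((len(d), 1)), d, w)
    null_mu = 1.0 - np.exp(-null_beta[0]) * np.ones_like(d)
    null_dev = _deviance(d, null_mu, w, form)
    if null_dev <= 0:
        return 0.0
    return float(100.0 * (1.0 - model_dev / null_dev))


# --------------------------------------------------------------------------
# prediction


def gdm_transform(model: GDMModel, env: EnvGrid) -> TransformedGrid:
    """Map every cell's predictors onto the fitted turnover scale f_p(x).

    Values outside the training range are clamped to the boundary knots;
    masked cells stay masked.
    """
    missing = [p for p in model.predictors if p not in env.data]
    if missing:
        raise KeyError(f"environment grid lacks model predictors: {missing}")
    data = {}
    for p in model.predictors:
        arr = env.data[p]
        f = np.full(arr.shape, np.nan)
        ok = env.mask & np.isfinite(arr)
        f[ok] = model.transform_values(p, arr[ok])
        data[p] = f
    mask = env.mask.copy()
    for p in model.predictors:
        mask &= np.isfinite(data[p])
    return TransformedGrid(data=data, mask=mask, epoch=env.epoch)


def predict_dissimilarity(model: GDMModel, f_a: np.ndarray, f_b: np.ndarray,
                          include_intercept: bool = True) -> np.ndarray | float:
    """Dissimilarity between transformed predictor vectors (rows if 2-D).

    d = 1 - exp(-(a0 [if included] + sum_p |f_a,p - f_b,p|)); symmetric.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_a.shape != f_b.shape:
        raise ValueError("transformed vectors must share a shape")
    eta = np.abs(f_a - f_b).sum(axis=-1)
    if include_intercept:
        eta = eta + model.intercept
    out = 1.0 - np.exp(-eta)
    return float(out) if np.ndim(out) == 0 else out
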