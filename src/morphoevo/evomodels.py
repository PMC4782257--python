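"""Multivariate evolutionary-model fitting by covariance transformation.

Five models of continuous trait evolution on a time-calibrated tree are
supported, each defined by a transform of the Brownian-motion covariance
``C`` (shared root-to-MRCA path lengths, total depth ``T``):

``BM``
    Unconstrained drift at constant rate sigma^2: ``V = C``.
``OU``
    Drift with attraction of strength alpha toward a single optimum.  For
    an ultrametric tree ``V[i,j] = exp(-2 alpha (T - s_ij)) *
    (1 - exp(-2 alpha s_ij)) / (2 alpha)`` with ``s_ij`` the shared path
    length; this parameterisation recovers ``C`` as alpha -> 0 so sigma^2
    stays comparable across models.
``EB``
    Early burst: rate sigma^2 e^{r t}; a shared path of length ``s``
    contributes ``(e^{r s} - 1)/r``.
``delta``
    Pagel's power transform of node depths, rescaled to preserve total
    depth: ``V = T^{1-delta} C^{delta}`` (element-wise power).  delta < 1
    concentrates change near the root, delta > 1 near the tips.
``delta_OU``
    The delta depth transform applied first, then the OU transform on the
    delta-rescaled tree; (delta, alpha) are optimised jointly.

The likelihood is the pooled-rate multivariate form: traits are independent
with a single shared rate, so per trait the GLS root is profiled out and
``sigma^2_hat = sum_j r_j' V^{-1} r_j / (N p)`` — the multivariate rate
sigma^2_mult when the model is BM.  Model choice is by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .errors import DegenerateDataError, DegenerateGeometryError, InvalidArgumentError
from .phylo import PhyloTree, phylo_covariance, _as_trait_frame

__all__ = [
    "MODELS",
    "EvoModelFit",
    "transform_covariance",
    "pooled_loglik",
    "fit_model",
    "select_model",
    "sigma_mult",
    "ShapeEvolution",
    "ShapeEvolutionResults",
]

MODELS = ("BM", "OU", "EB", "delta", "delta_OU")

_DELTA_BOUNDS = (0.01, 3.0)


def _ou_from_shared(S: np.ndarray, T: float, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return S.copy()
    a2 = 2.0 * alpha
    return np.exp(-a2 * (T - S)) * (-np.expm1(-a2 * S)) / a2


def transform_covariance(tree: PhyloTree, model: str, params: dict | None = None) -> np.ndarray:
    """Among-species covariance (unit rate) implied by a model's tree transform."""
    params = dict(params or {})
    C = phylo_covariance(tree).to_numpy()
    T = float(np.max(np.diag(C)))
    if model == "BM":
        return C
    if model == "delta":
        delta = float(params.get("delta", 1.0))
        if delta <= 0:
            raise InvalidArgumentError("delta must be > 0")
        return T ** (1.0 - delta) * C**delta
    if model == "EB":
        r = float(params.get("r", 0.0))
        if r == 0.0:
            return C
        return np.expm1(r * C) / r
    if model in ("OU", "delta_OU"):
        if not tree.is_ultrametric():
            raise InvalidArgumentError(f"{model} requires an ultrametric tree")
        alpha = float(params.get("alpha", 0.0))
        if alpha < 0:
            raise InvalidArgumentError("alpha must be >= 0")
        S = C
        if model == "delta_OU":
            delta = float(params.get("delta", 1.0))
            if delta <= 0:
                raise InvalidArgumentError("delta must be > 0")
            S = T ** (1.0 - delta) * C**delta
        return _ou_from_shared(S, T, alpha)
    raise InvalidArgumentError(f"unknown model {model!r}; choose from {MODELS}")


def _profiled(data: pd.DataFrame, V: np.ndarray):
    """Profiled pooled-rate Gaussian likelihood on covariance V.

    Returns (loglik, sigma2_hat, roots).
    """
    X = data.to_numpy()
    n, p = X.shape
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"singular model covariance: {exc}") from exc
    ones = np.ones(n)
    iV1 = cho_solve(cf, ones)
    denom = iV1 @ ones
    roots = (iV1 @ X) / denom
    R = X - ones[:, None] * roots[None, :]
    rss = float(np.sum(R * cho_solve(cf, R)))
    sigma2 = rss / (n * p)
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise DegenerateDataError(
            "zero (or invalid) residual variance: data equal the GLS root at every tip"
        )
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * (n * p * np.log(2.0 * np.pi * sigma2) + p * logdet + n * p)
    return ll, sigma2, roots


def pooled_loglik(data, tree: PhyloTree, model: str, params: dict | None = None) -> float:
    """Profiled pooled-rate log-likelihood of ``data`` under a model transform."""
    X = _as_trait_frame(tree, data)
    V = transform_covariance(tree, model, params)
    ll, _, _ = _profiled(X, V)
    return ll


@dataclass
class EvoModelFit:
    """One fitted evolutionary model: parameters, likelihood and AIC."""

    model: str
    sigma2: float
    loglik: float
    n_params: int
    aic: float
    alpha: float | None = None
    delta: float | None = None
    r: float | None = None

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "sigma2": self.sigma2,
            "alpha": np.nan if self.alpha is None else self.alpha,
            "delta": np.nan if self.delta is None else self.delta,
            "r": np.nan if self.r is None else self.r,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
        }


_N_PARAMS = {"BM": 2, "OU": 3, "EB": 3, "delta": 3, "delta_OU": 4}


def fit_model(data, tree: PhyloTree, model: str, combined: str = "joint") -> EvoModelFit:
    """Maximum-likelihood fit of one model by deterministic bounded search.

    1-D models use bounded Brent; the combined delta+OU model is optimised
    jointly over (delta, alpha) by Nelder-Mead started from the best point
    of a fixed grid (``combined="plugin"`` instead evaluates the combined
    model at the separately fitted delta and OU estimates).
    """
    X = _as_trait_frame(tree, data)
    C = phylo_covariance(tree).to_numpy()
    T = float(np.max(np.diag(C)))
    if T <= 0:
        raise InvalidArgumentError("tree has zero depth")

    def ll_at(params: dict) -> tuple[float, float]:
        V = transform_covariance(tree, model, params)
        ll, s2, _ = _profiled(X, V)
        return ll, s2

    if model == "BM":
        ll, s2, _ = _profiled(X, C)
        return _make_fit("BM", s2, ll)

    if model in ("OU", "EB", "delta"):
        key, lo, hi = {
            "OU": ("alpha", 1e-8, 50.0 / T),
            "EB": ("r", -10.0 / T, 10.0 / T),
            "delta": ("delta", _DELTA_BOUNDS[0], _DELTA_BOUNDS[1]),
        }[model]
        res = minimize_scalar(
            lambda v: -ll_at({key: v})[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9 * (hi - lo)},
        )
        if not np.isfinite(res.fun):
            raise DegenerateGeometryError(f"{model} optimisation failed at {key}={res.x}")
        ll, s2 = ll_at({key: res.x})
        return _make_fit(model, s2, ll, **{key: float(res.x)})

    if model == "delta_OU":
        a_hi = 50.0 / T
        if combined == "plugin":
            d_hat = fit_model(X, tree, "delta").delta
            a_hat = fit_model(X, tree, "OU").alpha
            ll, s2 = ll_at({"delta": d_hat, "alpha": a_hat})
            return _make_fit("delta_OU", s2, ll, delta=d_hat, alpha=a_hat)

        d_lo, d_hi = _DELTA_BOUNDS

        def unpack(u):
            d = d_lo + (d_hi - d_lo) * expit(u[0])
            a = a_hi * expit(u[1])
            return d, a

        def nll(u):
            d, a = unpack(u)
            try:
                return -ll_at({"delta": d, "alpha": a})[0]
            except (DegenerateGeometryError, DegenerateDataError):
                return np.inf

        grid_d = (0.3, 0.7, 1.0, 1.5, 2.0, 2.6)
        grid_a = (0.01 / T, 0.1 / T, 0.5 / T, 2.0 / T, 5.0 / T, 20.0 / T)
        best_u, best_f = None, np.inf
        for d0 in grid_d:
            for a0 in grid_a:
                u = np.array(
                    [
                        logit(np.clip((d0 - d_lo) / (d_hi - d_lo), 1e-6, 1 - 1e-6)),
                        logit(np.clip(a0 / a_hi, 1e-6, 1 - 1e-6)),
                    ]
                )
                f = nll(u)
                if f < best_f:
                    best_u, best_f = u, f
        res = minimize(
            nll,
            best_u,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
        )
        u_star = res.x if res.fun <= best_f else best_u
        d_star, a_star = unpack(u_star)
        ll, s2 = ll_at({"delta": d_star, "alpha": a_star})
        return _make_fit("delta_OU", s2, ll, delta=float(d_star), alpha=float(a_star))

    raise InvalidArgumentError(f"unknown model {model!r}; choose from {MODELS}")


def _make_fit(model, sigma2, loglik, **params) -> EvoModelFit:
    n_par = _N_PARAMS[model]
    return EvoModelFit(
        model=model,
        sigma2=float(sigma2),
        loglik=float(loglik),
        n_params=n_par,
        aic=2.0 * n_par - 2.0 * float(loglik),
        **params,
    )


def select_model(fits) -> tuple[EvoModelFit, pd.DataFrame]:
    """Pick the minimum-AIC fit (ties broken toward fewer parameters).

    Returns the winning fit and a table sorted by AIC with a ``delta_aic``
    column.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InvalidArgumentError("need at least two fits to select among")
    best = min(fits, key=lambda f: (f.aic, f.n_params))
    table = pd.DataFrame([f.as_row() for f in fits]).sort_values(
        ["aic", "n_params"], kind="stable"
    )
    table["delta_aic"] = table["aic"] - best.aic
    return best, table.reset_index(drop=True)


def sigma_mult(data, tree: PhyloTree) -> float:
    """Multivariate Brownian rate sigma^2_mult (pooled per-dimension rate)."""
    X = _as_trait_frame(tree, data)
    C = phylo_covariance(tree).to_numpy()
    _, s2, _ = _profiled(X, C)
    return s2


class ShapeEvolution:
    """Evolutionary model comparison for a multivariate trait block.

    statsmodels-style front end: construct from tip data and a tree, call
    :meth:`fit` to obtain a :class:`ShapeEvolutionResults` holding every
    candidate fit, the AIC table and the AIC-best model.

    Parameters
    ----------
    data : DataFrame
        Tip values (rows indexed by species label).
    tree : PhyloTree
        Time-calibrated, ultrametric for OU-family models.
    models : sequence of str
        Candidate menu, default all of :data:`MODELS`.
    """

    def __init__(self, data, tree: PhyloTree, models=MODELS):
        self.data = _as_trait_frame(tree, data)
        self.tree = tree
        bad = set(models) - set(MODELS)
        if bad:
            raise InvalidArgumentError(f"unknown models: {sorted(bad)}")
        self.models = tuple(models)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, tree: PhyloTree, **kw) -> "ShapeEvolution":
        return cls(data, tree, **kw)

    def fit(self, combined: str = "joint") -> "ShapeEvolutionResults":
        fits = {m: fit_model(self.data, self.tree, m, combined=combined) for m in self.models}
        if len(fits) >= 2:
            best, table = select_model(fits.values())
        else:
            (best,) = fits.values()
            table = pd.DataFrame([best.as_row()])
            table["delta_aic"] = 0.0
        return ShapeEvolutionResults(self, fits, best, table)


class ShapeEvolutionResults:
    """Container for a fitted model menu: fits, AIC table, best model."""

    def __init__(self, model: ShapeEvolution, fits, best, aic_table):
        self.model = model
        self.fits = dict(fits)
        self.best = best
        self.aic_table = aic_table
        self.sigma2_mult = sigma_mult(model.data, model.tree)

    def summary(self) -> str:
        n, p = self.model.data.shape
        lines = [
            "Evolutionary model comparison (pooled multivariate rate)",
            f"  species: {n}    traits: {p}    tree depth: {self.model.tree.depth:.6g}",
            f"  best model (AIC): {self.best.model}",
            f"  sigma2_mult (BM pooled rate): {self.sigma2_mult:.6g}",
            "",
            self.aic_table.to_string(
                index=False, float_format=lambda v: f"{v:.6g}", na_rep="-"
            ),
        ]
        return "\n".join(lines)
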