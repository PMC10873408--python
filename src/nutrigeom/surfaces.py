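"""Scheffé mixture-polynomial response surfaces with AIC model selection.

Mixture experiments constrain the covariates to a simplex (here protein +
carb + fat = 1 on the proportion scale), so the canonical regression forms
have no intercept: the linear Scheffé polynomial is y = Σ βᵢxᵢ and the
quadratic (second-order) form adds the pairwise products Σ_{i<j} βᵢⱼxᵢxⱼ.
Because Σxᵢ = 1 the linear coefficients are interpretable as predicted
responses at the pure-component vertices.

Candidate models (null = grand mean, linear, quadratic, optionally special
cubic) are compared by AIC; the simplest model within 2 points of the
minimum AIC is selected.  Predictions from the selected model over an RMT
lattice give the response surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import DietDesign, RmtGrid, make_grid

__all__ = [
    "ScheffeRegressor",
    "ScheffeModelFit",
    "ResponseSurface",
    "SingularDesignError",
    "fit_scheffe",
    "select_model",
    "predict_surface",
    "surface_extrema",
]

ORDERS = ("null", "linear", "quadratic", "special_cubic")
_PAIRS = ((0, 1), (0, 2), (1, 2))  # (protein,carb), (protein,fat), (carb,fat)
_PAIR_NAMES = ("protein:carb", "protein:fat", "carb:fat")


class SingularDesignError(ValueError):
    """The diet design cannot identify the requested polynomial order."""


def _n_terms(order: str) -> int:
    return {"null": 1, "linear": 3, "quadratic": 6, "special_cubic": 7}[order]


def _design_matrix(props: np.ndarray, order: str) -> np.ndarray:
    """Model matrix on the proportion scale for a Scheffé polynomial."""
    props = np.asarray(props, dtype=float)
    if order == "null":
        return np.ones((props.shape[0], 1))
    cols = [props[:, 0], props[:, 1], props[:, 2]]
    if order in ("quadratic", "special_cubic"):
        cols += [props[:, i] * props[:, j] for i, j in _PAIRS]
    if order == "special_cubic":
        cols.append(props[:, 0] * props[:, 1] * props[:, 2])
    return np.column_stack(cols)


def _as_proportions(X: np.ndarray) -> np.ndarray:
    """Accept percent- or proportion-scale compositions; return proportions."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X must be (n, 3) compositions (protein, carb, fat)")
    sums = X.sum(axis=1)
    if np.allclose(sums, 100.0, atol=1e-4):
        X = X / 100.0
    elif not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("composition rows must sum to 1 (or 100 on percent scale)")
    return X


class ScheffeRegressor(RegressorMixin, BaseEstimator):
    """Least-squares Scheffé mixture polynomial of a fixed order.

    Parameters
    ----------
    order : {"null", "linear", "quadratic", "special_cubic"}
        Polynomial order.  "null" is the grand-mean (intercept-only) model;
        the others have no intercept.

    Attributes
    ----------
    coef_ : ndarray
        Model coefficients in design-matrix column order.
    rss_, loglik_, aic_, k_ : float
        Residual sum of squares, Gaussian profile log-likelihood, AIC and
        parameter count (the error variance counts as one parameter).
    """

    def __init__(self, order: str = "linear"):
        self.order = order

    def fit(self, X, y):
        if self.order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}")
        props = _as_proportions(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != props.shape[0]:
            raise ValueError("X and y length mismatch")
        p = _n_terms(self.order)
        n = y.shape[0]
        if n < p + 1:
            raise ValueError(f"{self.order} fit needs at least {p + 1} observations")
        distinct = np.unique(np.round(props, 10), axis=0).shape[0]
        M = _design_matrix(props, self.order)
        if distinct < p or np.linalg.matrix_rank(M) < p:
            raise SingularDesignError(
                f"design is rank-deficient for a {self.order} Scheffé fit"
            )
        coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ coef
        rss = float(resid @ resid)
        self.coef_ = coef
        self.n_obs_ = n
        self.rss_ = rss
        # Gaussian profile log-likelihood with sigma^2 = rss/n
        sigma2 = max(rss / n, 1e-300)
        self.loglik_ = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        self.k_ = p + 1  # + error variance
        self.aic_ = 2 * self.k_ - 2 * self.loglik_
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return _design_matrix(_as_proportions(X), self.order) @ self.coef_

    def to_fit(self, response_name: str = "") -> "ScheffeModelFit":
        check_is_fitted(self, "coef_")
        beta_i = None
        beta_ij = None
        if self.order == "null":
            beta_i = np.full(3, float(self.coef_[0]))  # flat surface
        else:
            beta_i = self.coef_[:3].copy()
            if self.order in ("quadratic", "special_cubic"):
                beta_ij = dict(zip(_PAIR_NAMES, self.coef_[3:6]))
        return ScheffeModelFit(
            order=self.order,
            beta_i=beta_i,
            beta_ij=beta_ij,
            n_obs=self.n_obs_,
            rss=self.rss_,
            loglik=self.loglik_,
            aic=self.aic_,
            k=self.k_,
            coef=self.coef_.copy(),
            response_name=response_name,
        )


@dataclass
class ScheffeModelFit:
    """A fitted mixture polynomial: coefficients plus fit statistics."""

    order: str
    beta_i: np.ndarray
    beta_ij: dict | None
    n_obs: int
    rss: float
    loglik: float
    aic: float
    k: int
    coef: np.ndarray
    response_name: str = ""

    @property
    def n_terms(self) -> int:
        return _n_terms(self.order)

    def predict(self, compositions) -> np.ndarray:
        return _design_matrix(_as_proportions(compositions), self.order) @ self.coef


@dataclass
class ResponseSurface:
    """Predictions of a fitted mixture model over an RMT lattice."""

    grid: RmtGrid
    predicted: np.ndarray
    response_name: str
    source_fit: ScheffeModelFit

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.predicted.shape[0] != self.grid.points.shape[0]:
            raise ValueError("one prediction per grid point required")
        if not np.all(np.isfinite(self.predicted)):
            raise ValueError("surface predictions must be finite")

    def as_frame(self):
        df = self.grid.as_frame()
        df["predicted"] = self.predicted
        return df


def fit_scheffe(y, design: DietDesign, order: str = "linear") -> ScheffeModelFit:
    """Fit one Scheffé polynomial of ``order`` to a per-sample response."""
    X = design.sample_proportions()
    reg = ScheffeRegressor(order=order).fit(X, y)
    return reg.to_fit()


def fit_all_orders(
    y, design: DietDesign, orders=("null", "linear", "quadratic")
) -> list[ScheffeModelFit]:
    """Fit every candidate order that the design can identify."""
    fits = []
    for order in orders:
        try:
            fits.append(fit_scheffe(y, design, order))
        except SingularDesignError:
            continue
    return fits


def select_model(fits: list[ScheffeModelFit]) -> ScheffeModelFit:
    """Simplest model (fewest terms) within 2 AIC points of the minimum.

    "Within" is inclusive: a model at exactly min(AIC) + 2 qualifies.
    """
    if not fits:
        raise ValueError("no candidate fits supplied")
    best_aic = min(f.aic for f in fits)
    eligible = [f for f in fits if f.aic <= best_aic + 2.0]
    return min(eligible, key=lambda f: f.n_terms)


def fit_surface_response(
    y, design: DietDesign, orders=("null", "linear", "quadratic")
) -> ScheffeModelFit:
    """Fit all candidate orders and return the AIC-selected model."""
    return select_model(fit_all_orders(y, design, orders))


def predict_surface(
    fit: ScheffeModelFit,
    grid: RmtGrid | None = None,
    response_name: str | None = None,
) -> ResponseSurface:
    """Evaluate a fitted polynomial at every grid point's implied composition."""
    if grid is None:
        grid = make_grid(resolution=1.0)
    comps = np.column_stack([grid.points, grid.implied_fat])
    pred = fit.predict(comps)
    return ResponseSurface(
        grid=grid,
        predicted=pred,
        response_name=response_name or fit.response_name,
        source_fit=fit,
    )


@dataclass
class SurfaceExtrema:
    argmax: tuple
    argmin: tuple
    max_value: float
    min_value: float
    degenerate: bool
    argmax_ties: list = field(default_factory=list)
    argmin_ties: list = field(default_factory=list)


def surface_extrema(surface: ResponseSurface, tol: float = 1e-9) -> SurfaceExtrema:
    """Grid points of maximal and minimal prediction.

    Ties are reported in lexicographic (protein, carb) order (the grid is
    constructed in that order); a flat surface is flagged degenerate.
    """
    pred = surface.predicted
    if pred.size == 0:
        raise ValueError("empty surface")
    comps = np.column_stack([surface.grid.points, surface.grid.implied_fat])
    vmax, vmin = float(pred.max()), float(pred.min())
    max_ties = [tuple(c) for c in comps[pred >= vmax - tol]]
    min_ties = [tuple(c) for c in comps[pred <= vmin + tol]]
    return SurfaceExtrema(
        argmax=max_ties[0],
        argmin=min_ties[0],
        max_value=vmax,
        min_value=vmin,
        degenerate=(vmax - vmin) <= tol,
        argmax_ties=max_ties,
        argmin_ties=min_ties,
    )


def plot_surface(surface: ResponseSurface, path=None, ax=None):
    """Render a surface in the RMT with a red-high/blue-low palette and fat isolines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = surface.grid.points
    tc = ax.tricontourf(
        pts[:, 0], pts[:, 1], surface.predicted, levels=24, cmap="RdBu_r"
    )
    ax.tricontour(
        pts[:, 0], pts[:, 1], surface.predicted, levels=10,
        colors="k", linewidths=0.4,
    )
    for fat in (0, 20, 40, 60, 80):
        ax.plot([0, 100 - fat], [100 - fat, 0], color="grey", lw=0.5, ls="--")
    ax.set_xlabel("protein (% energy)")
    ax.set_ylabel("carbohydrate (% energy)")
    ax.set_title(surface.response_name)
    plt.colorbar(tc, ax=ax, shrink=0.8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
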