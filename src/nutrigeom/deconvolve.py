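"""Cell-type deconvolution of bulk expression by dampened weighted least squares.

Bulk tissue expression is modeled as a nonnegative combination of cell-type
signature profiles: b ≈ S·p with p ≥ 0, Σp = 1.  Plain least squares is
dominated by highly expressed genes; DWLS reweights each gene inversely to
its squared fitted expression, capping (dampening) the weights at a quantile
so low-expression genes cannot dominate either, and iterates weighted NNLS
to a fixed point.  Cell types estimated above 1% in at least one sample are
retained for downstream correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .correlate import _pearson
from .expression import bh_fdr, FDR_THRESHOLD

__all__ = [
    "SignatureMatrix",
    "ProportionEstimate",
    "DWLS",
    "build_signature",
    "dwls_solve",
    "filter_cell_types",
    "proportion_gene_correlation",
]


@dataclass
class SignatureMatrix:
    """Mean expression per (gene, cell type)."""

    genes: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("signature shape must be (n_genes, n_cell_types)")
        if np.any(self.values < 0):
            raise ValueError("signature must be nonnegative")
        if len(self.cell_types) < 2:
            raise ValueError("signature needs at least 2 cell types")
        if np.any(self.values.sum(axis=1) == 0):
            raise ValueError("signature contains all-zero gene rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cell_types)


@dataclass
class ProportionEstimate:
    sample_id: str
    fractions: dict[str, float]
    converged: bool
    n_iter: int

    @property
    def vector(self) -> np.ndarray:
        return np.array(list(self.fractions.values()))


def build_signature(
    reference: pd.DataFrame,
    labels,
    markers_per_type: int = 50,
    min_fold: float = 2.0,
) -> SignatureMatrix:
    """Signature from a labeled single-cell reference (cells × genes).

    Markers per type are ranked by fold change of the type mean over the
    maximum other-type mean (requiring fold ≥ ``min_fold``); the signature is
    each type's mean expression over the union of selected markers.
    """
    labels = np.asarray(labels)
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 labeled cell types")
    for t in types:
        if (labels == t).sum() < 10:
            raise ValueError(f"cell type {t!r} has fewer than 10 cells")
    means = pd.DataFrame(
        {t: reference.loc[labels == t].mean(axis=0) for t in types}
    )  # genes × types
    eps = 1e-9
    markers: set = set()
    any_markers = False
    for t in types:
        other_max = means.drop(columns=t).max(axis=1)
        fold = (means[t] + eps) / (other_max + eps)
        qual = fold[fold >= min_fold].sort_values(ascending=False)
        if qual.empty:
            warnings.warn(f"no markers pass min_fold for cell type {t!r}")
            continue
        any_markers = True
        markers.update(qual.index[:markers_per_type])
    if not any_markers:
        raise ValueError("no cell type has qualifying marker genes")
    marker_list = sorted(markers)
    sig = means.loc[marker_list]
    sig = sig.loc[sig.sum(axis=1) > 0]
    return SignatureMatrix(
        genes=list(sig.index), cell_types=types, values=sig.to_numpy()
    )


class DWLS(BaseEstimator):
    """Dampened weighted least squares proportion estimator.

    ``fit`` stores the signature; ``transform`` maps bulk profiles
    (genes × samples) to cell-type fractions on the simplex.

    Parameters
    ----------
    damping_quantile : float
        Weights 1/max((S·p)², ε) are capped at this quantile of the current
        weights each iteration (the dampening).
    """

    def __init__(
        self,
        damping_quantile: float = 0.95,
        tol: float = 1e-10,
        max_iter: int = 200,
        eps: float = 1e-8,
    ):
        self.damping_quantile = damping_quantile
        self.tol = tol
        self.max_iter = max_iter
        self.eps = eps

    def fit(self, signature: SignatureMatrix, y=None):
        self.signature_ = signature
        return self

    def _solve_one(self, b: np.ndarray, S: np.ndarray):
        # unweighted NNLS start
        p, _ = nnls(S, b)
        if p.sum() == 0:
            p = np.full(S.shape[1], 1.0 / S.shape[1])
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            fitted = S @ p
            w = 1.0 / np.maximum(fitted**2, self.eps)
            w = np.minimum(w, np.quantile(w, self.damping_quantile))
            sw = np.sqrt(w)
            p_new, _ = nnls(S * sw[:, None], b * sw)
            if p_new.sum() == 0:
                p_new = p
            if np.max(np.abs(p_new - p)) < self.tol:
                p = p_new
                converged = True
                break
            p = p_new
        total = p.sum()
        frac = p / total if total > 0 else np.full_like(p, 1.0 / p.size)
        return frac, converged, it

    def transform(self, bulk: pd.DataFrame) -> list[ProportionEstimate]:
        S_df = self.signature_.to_frame()
        shared = [g for g in S_df.index if g in bulk.index]
        dropped = len(S_df.index) - len(shared)
        if dropped:
            warnings.warn(f"{dropped} signature genes absent from bulk; dropped")
        if not shared:
            raise ValueError("no shared genes between bulk and signature")
        S = S_df.loc[shared].to_numpy()
        out = []
        for sample in bulk.columns:
            b = bulk.loc[shared, sample].to_numpy(dtype=float)
            if np.any(b < 0):
                raise ValueError(f"bulk sample {sample!r} has negative values")
            frac, converged, it = self._solve_one(b, S)
            out.append(
                ProportionEstimate(
                    sample_id=str(sample),
                    fractions=dict(zip(self.signature_.cell_types, frac.tolist())),
                    converged=converged,
                    n_iter=it,
                )
            )
        return out


def dwls_solve(
    bulk: np.ndarray,
    signature: SignatureMatrix,
    damping_quantile: float = 0.95,
    tol: float = 1e-10,
    max_iter: int = 200,
    sample_id: str = "sample",
) -> ProportionEstimate:
    """Estimate one bulk sample's cell-type fractions; see :class:`DWLS`."""
    est = DWLS(damping_quantile=damping_quantile, tol=tol, max_iter=max_iter)
    est.fit(signature)
    frame = pd.DataFrame({sample_id: np.asarray(bulk, dtype=float)}, index=signature.genes)
    return est.transform(frame)[0]


def filter_cell_types(
    estimates: list[ProportionEstimate], threshold: float = 0.01
) -> list[str]:
    """Cell types estimated above ``threshold`` in at least one sample."""
    if not estimates:
        raise ValueError("no proportion estimates supplied")
    types = list(estimates[0].fractions)
    kept = []
    for t in types:
        if any(e.fractions[t] > threshold for e in estimates):
            kept.append(t)
    return kept


def proportion_gene_correlation(
    expr: pd.DataFrame,
    estimates: list[ProportionEstimate],
    genes: list[str],
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r / p / BH-FDR between each gene and each retained cell type."""
    if cell_types is None:
        cell_types = filter_cell_types(estimates)
    samples = [e.sample_id for e in estimates]
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression: {missing[:5]}")
    rows = []
    for t in cell_types:
        prop = np.array([e.fractions[t] for e in estimates])
        if np.std(prop) == 0:
            warnings.warn(f"constant proportions for cell type {t!r}; NA")
        for g in genes:
            x = expr.loc[g, samples].to_numpy(dtype=float)
            r, p = _pearson(x, prop)
            rows.append((g, t, r, p))
    df = pd.DataFrame(rows, columns=["gene_id", "cell_type", "r", "p_value"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < FDR_THRESHOLD
    return df
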