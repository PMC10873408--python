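"""Single-macronutrient correlations, Venn partitions and gene-set scores.

After the joint tests call features (genes or exons) diet-responsive, Pearson
correlation against each diet's percent fat, carb and protein attributes each
feature to individual macronutrients.  Because the three percentages sum to
100 per diet, the three per-sample nutrient vectors are linearly dependent —
a feature's three correlations are constrained by the design covariances, so
the Venn partition describes attribution, not independent evidence.

Gene-set scores are the per-sample sum of z-scored (across samples)
normalized expression over a gene set, e.g. the nine Bardet–Biedl syndrome
genes scored at the bulk level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import DietDesign
from .expression import bh_fdr, FDR_THRESHOLD

__all__ = [
    "CorrelationResult",
    "VennPartition",
    "GeneSetScore",
    "correlate_features",
    "venn_partition",
    "gene_set_score",
    "intake_correlation",
]

NUTRIENTS = ("fat", "carb", "protein")
_COL = {"fat": "fat_pct", "carb": "carb_pct", "protein": "protein_pct"}


@dataclass
class CorrelationResult:
    feature_id: str
    nutrient: str
    r: float
    p_value: float
    fdr: float = np.nan
    significant: bool = False


@dataclass
class VennPartition:
    """Counts of features per nonempty nutrient subset plus the none region."""

    counts: dict[frozenset, int]
    none_count: int
    n_features: int

    @property
    def multi_nutrient_fraction(self) -> float:
        multi = sum(c for s, c in self.counts.items() if len(s) > 1)
        return multi / self.n_features if self.n_features else 0.0

    def fraction(self, nutrient: str) -> float:
        """Fraction of features significantly correlated with ``nutrient``."""
        hits = sum(c for s, c in self.counts.items() if nutrient in s)
        return hits / self.n_features if self.n_features else 0.0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(s)), c) for s, c in sorted(
                self.counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        rows.append(("none", self.none_count))
        return pd.DataFrame(rows, columns=["region", "count"])


@dataclass
class GeneSetScore:
    sample_id: str
    score: float


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t-transform; NaN on zero variance."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_features(
    values: pd.DataFrame | np.ndarray,
    design: DietDesign,
    feature_ids: list[str] | None = None,
) -> list[CorrelationResult]:
    """Pearson correlation of each feature with each macronutrient percent.

    ``values`` is feature × sample (columns ordered as design samples when an
    array); the BH FDR family is all features × 3 nutrients.
    """
    pct = design.sample_percent_matrix()
    if isinstance(values, pd.DataFrame):
        missing = [s for s in values.columns if s not in pct.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing[:5]}")
        mat = values.to_numpy(dtype=float)
        feats = [str(f) for f in values.index]
        cov = pct.loc[values.columns]
    else:
        mat = np.asarray(values, dtype=float)
        feats = feature_ids or [f"f{i}" for i in range(mat.shape[0])]
        if mat.shape[1] != len(design.samples):
            raise ValueError("array values must have one column per design sample")
        cov = pct.loc[design.sample_ids]
    results = []
    for i, feat in enumerate(feats):
        row = mat[i]
        if np.nanstd(row) == 0:
            warnings.warn(f"feature {feat!r} has zero variance; correlations NA")
        for nutrient in NUTRIENTS:
            r, p = _pearson(row, cov[_COL[nutrient]].to_numpy(dtype=float))
            results.append(CorrelationResult(feat, nutrient, r, p))
    fdrs = bh_fdr([res.p_value for res in results])
    for res, q in zip(results, fdrs):
        res.fdr = float(q)
        res.significant = bool(np.isfinite(q) and q < FDR_THRESHOLD)
    return results


def venn_partition(
    results: list[CorrelationResult], features: list[str] | None = None
) -> VennPartition:
    """Partition features by the subset of nutrients they correlate with."""
    per_feature: dict[str, set] = {}
    for res in results:
        per_feature.setdefault(res.feature_id, set())
        if res.significant:
            per_feature[res.feature_id].add(res.nutrient)
    if features is None:
        features = list(per_feature)
    counts: dict[frozenset, int] = {
        frozenset(c): 0
        for k in (1, 2, 3)
        for c in combinations(NUTRIENTS, k)
    }
    none = 0
    for feat in features:
        region = frozenset(per_feature.get(feat, set()))
        if region:
            counts[region] += 1
        else:
            none += 1
    return VennPartition(counts=counts, none_count=none, n_features=len(features))


def gene_set_score(
    expr: pd.DataFrame, gene_set: list[str]
) -> list[GeneSetScore]:
    """Per-sample sum of z-scored (across samples) expression over a gene set.

    ``expr`` is a normalized gene × sample matrix (e.g. log2 CPM).
    """
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing}")
    sub = expr.loc[gene_set].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    scores = z.sum(axis=0)
    return [GeneSetScore(str(s), float(v)) for s, v in zip(expr.columns, scores)]


def intake_correlation(
    expr_values: np.ndarray, intake: np.ndarray, feature_id: str = "feature"
) -> CorrelationResult:
    """Pearson correlation between one gene's expression and food intake."""
    x = np.asarray(expr_values, dtype=float)
    y = np.asarray(intake, dtype=float)
    if np.nanstd(y) == 0:
        warnings.warn("constant food intake; correlation NA")
        return CorrelationResult(feature_id, "intake", np.nan, np.nan)
    r, p = _pearson(x, y)
    return CorrelationResult(feature_id, "intake", r, p)


def hypergeometric_enrichment(
    hits: list[str], gene_set: list[str], universe: list[str]
) -> dict:
    """Plain hypergeometric over-representation test of ``hits`` in ``gene_set``.

    A minimal utility for user-supplied gene sets; it performs no annotation
    lookups and does not reproduce any enrichment service's pipeline.
    """
    uni = set(universe)
    hits_u = set(hits) & uni
    set_u = set(gene_set) & uni
    k = len(hits_u & set_u)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(set_u), len(hits_u)))
    expected = len(hits_u) * len(set_u) / len(uni) if uni else np.nan
    return {
        "overlap": k,
        "expected": expected,
        "p_value": p,
        "n_hits": len(hits_u),
        "n_set": len(set_u),
        "n_universe": len(uni),
    }


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "nutrient": [r.nutrient for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
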