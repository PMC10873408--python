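"""Gene-level count filtering, normalization and differential-expression testing.

The design treats diet composition as continuous covariates: because percent
fat + carb + protein = 100 in every diet, only two of the three enter the
testable model (intercept + fat_pct + carb_pct); the third is redundant.  A
gene is called differentially expressed when the joint 2-df likelihood-ratio
test of the fat and carb coefficients survives Benjamini–Hochberg FDR < 0.05.

For clustering, the same genes are refitted with the no-intercept
three-coefficient parameterization (~0 + fat + carb + protein), identifiable
because the compositional constraint absorbs the intercept; only coefficient
contrasts are identifiable, which is what row-scaling before clustering uses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import glm
from .design import DietDesign

__all__ = [
    "CountMatrix",
    "DEResult",
    "NutrientCoefficients",
    "filter_low_genes",
    "normalize",
    "fit_de",
    "fit_nutrient_coefficients",
    "bh_fdr",
]

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


@dataclass
class CountMatrix:
    """Nonnegative integer counts, genes × samples, with normalization factors."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray = None
    norm_factors: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_genes, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.sample_ids))
        else:
            self.norm_factors = np.asarray(self.norm_factors, dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.norm_factors

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CountMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx],
            library_sizes=self.library_sizes.copy(),
            norm_factors=self.norm_factors.copy(),
        )

    def cpm(self, log2: bool = False, prior: float = 0.5) -> np.ndarray:
        """Counts per million on effective library sizes."""
        lib = np.clip(self.effective_library_sizes, 1.0, None)
        c = 1e6 * self.counts / lib[None, :]
        if log2:
            c = np.log2(c + prior)
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
        )

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, samples_path) -> "CountMatrix":
        """MatrixMarket triplet counts plus row (gene) and column (sample) name files."""
        from scipy.io import mmread

        counts = np.asarray(mmread(mtx_path).todense())
        genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
        samples = [ln.strip() for ln in open(samples_path) if ln.strip()]
        return cls(gene_ids=genes, sample_ids=samples, counts=counts)


@dataclass
class DEResult:
    gene_id: str
    coef_intercept: float
    coef_fat: float
    coef_carb: float
    lr_stat: float
    p_value: float
    fdr: float = np.nan
    significant: bool = False
    p_fat: float = np.nan
    p_carb: float = np.nan
    dispersion: float = np.nan
    converged: bool = True


@dataclass
class NutrientCoefficients:
    feature_id: str
    b_fat: float
    b_carb: float
    b_protein: float
    scaled: bool = False

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.b_fat, self.b_carb, self.b_protein])


def filter_low_genes(
    m: CountMatrix, min_count: int = 10, max_low_samples: int | None = None
) -> CountMatrix:
    """Drop lowly expressed genes.

    A gene is removed iff it has fewer than ``min_count`` reads in at least
    ``max_low_samples`` samples (default: n_samples − 4, i.e. the 53-of-57
    rule of the reference design).
    """
    if max_low_samples is None:
        max_low_samples = m.n_samples - 4
    if max_low_samples > m.n_samples:
        raise ValueError("max_low_samples exceeds the number of samples")
    n_low = (m.counts < min_count).sum(axis=1)
    keep = n_low < max_low_samples
    if not np.any(keep):
        warnings.warn("all genes removed by the low-expression filter")
    log.info("filter_low_genes: %d in, %d out", m.n_genes, int(keep.sum()))
    return CountMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        counts=m.counts[keep],
        library_sizes=m.library_sizes.copy(),
        norm_factors=m.norm_factors.copy(),
    )


def normalize(
    m: CountMatrix,
    method: str = "tmm",
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> CountMatrix:
    """Per-sample scale factors by trimmed mean of log ratios (TMM-style).

    Factors are normalized to geometric mean 1; effective library size is
    library_size × factor.
    """
    if m.n_samples < 2:
        raise ValueError("normalization needs at least 2 samples")
    zero_total = m.library_sizes <= 0
    if np.any(zero_total):
        bad = [s for s, z in zip(m.sample_ids, zero_total) if z]
        raise ValueError(f"samples with zero total counts: {bad}")
    if method not in ("tmm", "none"):
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "none":
        factors = np.ones(m.n_samples)
    else:
        counts = m.counts.astype(float)
        lib = m.library_sizes
        # reference: sample whose upper quartile of scaled counts is most typical
        uq = np.array(
            [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(m.n_samples)]
        )
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        factors = np.ones(m.n_samples)
        r = counts[:, ref]
        for j in range(m.n_samples):
            if j == ref:
                continue
            y = counts[:, j]
            ok = (y > 0) & (r > 0)
            if ok.sum() < 10:
                continue
            yy, rr = y[ok], r[ok]
            M = np.log2((yy / lib[j]) / (rr / lib[ref]))
            A = 0.5 * np.log2((yy / lib[j]) * (rr / lib[ref]))
            w = (lib[j] - yy) / (lib[j] * yy) + (lib[ref] - rr) / (lib[ref] * rr)
            lo_m, hi_m = np.quantile(M, [logratio_trim, 1 - logratio_trim])
            lo_a, hi_a = np.quantile(A, [abs_trim, 1 - abs_trim])
            keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
            if keep.sum() == 0 or w[keep].sum() == 0:
                continue
            factors[j] = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return CountMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        counts=m.counts,
        library_sizes=m.library_sizes.copy(),
        norm_factors=factors,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _design_covariates(m: CountMatrix, design: DietDesign) -> np.ndarray:
    pct = design.sample_percent_matrix()
    missing = [s for s in m.sample_ids if s not in pct.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing[:5]}")
    return pct.loc[m.sample_ids].to_numpy()


def _estimate_dispersions(
    counts: np.ndarray, X: np.ndarray, offset: np.ndarray, trend_weight: float = 0.75
) -> np.ndarray:
    alphas = np.empty(counts.shape[0])
    for i, y in enumerate(counts):
        alphas[i] = glm.estimate_dispersion(y, X, offset=offset)
    log_means = np.log(counts.mean(axis=1) + 0.5)
    shrunk, _ = glm.shrink_dispersions(alphas, log_means, trend_weight=trend_weight)
    return shrunk


def fit_de(
    m: CountMatrix,
    design: DietDesign,
    dispersion: float | np.ndarray | None = None,
    extra_covariate: np.ndarray | None = None,
    trend_weight: float = 0.75,
) -> list[DEResult]:
    """NB GLM differential-expression test against fat and carb percent.

    Per gene: log μ = offset + β₀ + β_fat·fat_pct + β_carb·carb_pct, with
    offset = log effective library size; joint 2-df LRT of
    (β_fat, β_carb) = (0, 0); BH FDR across genes.  ``extra_covariate`` adds
    one categorical batch column family to both models (e.g. collection date).
    """
    pct = _design_covariates(m, design)
    n = m.n_samples
    base_cols = [np.ones(n)]
    if extra_covariate is not None:
        codes, levels = pd.factorize(np.asarray(extra_covariate))
        for lev in range(1, len(levels)):
            base_cols.append((codes == lev).astype(float))
    X_null = np.column_stack(base_cols)
    X_full = np.column_stack(base_cols + [pct[:, 2], pct[:, 1]])  # fat, carb
    offset = np.log(np.clip(m.effective_library_sizes, 1e-12, None))
    counts = m.counts.astype(float)
    if dispersion is None:
        alphas = _estimate_dispersions(counts, X_full, offset, trend_weight)
    else:
        alphas = np.broadcast_to(np.asarray(dispersion, dtype=float), (m.n_genes,))
    results = []
    n_fail = 0
    for i, gene in enumerate(m.gene_ids):
        y = counts[i]
        a = float(alphas[i])
        lr, p, full, null = glm.nb_lrt(y, X_full, X_null, offset=offset, alpha=a)
        ok = full.converged and null.converged
        if not ok:
            n_fail += 1
        # per-covariate Wald tests from the observed information
        try:
            cov = np.linalg.inv(full.info)
            se = np.sqrt(np.clip(np.diag(cov)[-2:], 1e-300, None))
            zf, zc = full.beta[-2] / se[0], full.beta[-1] / se[1]
            p_fat = float(2 * stats.norm.sf(abs(zf)))
            p_carb = float(2 * stats.norm.sf(abs(zc)))
        except np.linalg.LinAlgError:
            p_fat = p_carb = np.nan
        results.append(
            DEResult(
                gene_id=gene,
                coef_intercept=float(full.beta[0]),
                coef_fat=float(full.beta[-2]),
                coef_carb=float(full.beta[-1]),
                lr_stat=float(lr) if ok else np.nan,
                p_value=float(p) if ok else np.nan,
                p_fat=p_fat,
                p_carb=p_carb,
                dispersion=a,
                converged=ok,
            )
        )
    if n_fail:
        log.warning("fit_de: %d genes failed to converge", n_fail)
    fdrs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
        r.significant = bool(np.isfinite(q) and q < FDR_THRESHOLD)
    return results


def fit_nutrient_coefficients(
    m: CountMatrix,
    design: DietDesign,
    features: list[str] | None = None,
    dispersion: float | np.ndarray | None = None,
) -> list[NutrientCoefficients]:
    """No-intercept NB fit on the three percent covariates (~0+fat+carb+protein).

    The three columns span the constant vector (they sum to 100), so the fit is
    identifiable; only coefficient contrasts are (the common level trades off
    against the absorbed intercept).
    """
    if features is not None:
        missing = set(features) - set(m.gene_ids)
        if missing:
            raise ValueError(f"features not in matrix: {sorted(missing)[:5]}")
        m = m.subset_genes(features)
    pct = _design_covariates(m, design)
    X = np.column_stack([pct[:, 2], pct[:, 1], pct[:, 0]])  # fat, carb, protein
    offset = np.log(np.clip(m.effective_library_sizes, 1e-12, None))
    counts = m.counts.astype(float)
    if dispersion is None:
        alphas = _estimate_dispersions(counts, X, offset)
    else:
        alphas = np.broadcast_to(np.asarray(dispersion, dtype=float), (m.n_genes,))
    out = []
    for i, gene in enumerate(m.gene_ids):
        fit = glm.nb_irls(counts[i], X, offset=offset, alpha=float(alphas[i]))
        out.append(
            NutrientCoefficients(
                feature_id=gene,
                b_fat=float(fit.beta[0]),
                b_carb=float(fit.beta[1]),
                b_protein=float(fit.beta[2]),
            )
        )
    return out


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "coef_fat": [r.coef_fat for r in results],
            "coef_carb": [r.coef_carb for r in results],
            "lr_stat": [r.lr_stat for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
            "p_fat": [r.p_fat for r in results],
            "p_carb": [r.p_carb for r in results],
            "dispersion": [r.dispersion for r in results],
        }
    )
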