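"""Exon usage and diet-dependent differential-usage testing.

Exon usage is the fraction of a gene's reads falling on one exon; testing it
against diet asks whether splicing — not overall expression — responds to
macronutrient composition.  Each exon is tested against the rest of its gene
with a conditional (exon versus rest-of-gene) binomial GLM whose usage logit
is linear in percent fat and percent carb; this is the exact conditional form
of a two-row count GLM with per-sample totals as offsets, with the per-sample
nuisance intercepts profiled out by conditioning on gene totals.  A 2-df LRT
on the two nutrient terms with BH FDR < 0.05 calls differential splicing.

Fold changes are reported between the design's extreme fat levels (15% and
60% of energy): log_fold_change_15_60 = 45 × u_fat on the usage-logit scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .design import DietDesign
from .expression import bh_fdr, FDR_THRESHOLD

__all__ = [
    "ExonCountMatrix",
    "ExonUsage",
    "DSResult",
    "filter_low_exons",
    "compute_usage",
    "test_differential_usage",
]

log = logging.getLogger(__name__)

#: extreme dietary-fat percentages of the ten-diet design, used to anchor
#: reported usage fold changes.
FAT_LOW, FAT_HIGH = 15.0, 60.0


@dataclass
class ExonCountMatrix:
    """Exon-level counts with rows grouped by gene."""

    gene_ids: list[str]  # per exon row
    exon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.exon_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_exons, n_samples)")
        if len(self.gene_ids) != len(self.exon_ids):
            raise ValueError("one gene_id per exon row required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        seen = set()
        for g, e in zip(self.gene_ids, self.exon_ids):
            if (g, e) in seen:
                raise ValueError(f"duplicate exon {e!r} in gene {g!r}")
            seen.add((g, e))

    @property
    def n_exons(self) -> int:
        return len(self.exon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_groups(self) -> dict[str, np.ndarray]:
        groups: dict[str, list[int]] = {}
        for i, g in enumerate(self.gene_ids):
            groups.setdefault(g, []).append(i)
        return {g: np.asarray(ix) for g, ix in groups.items()}

    def gene_totals(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df["gene_id"] = self.gene_ids
        return df.groupby("gene_id", sort=False).sum()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "exon_id", self.exon_ids)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExonCountMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("gene_id", "exon_id")]
        return cls(
            gene_ids=[str(g) for g in df["gene_id"]],
            exon_ids=[str(e) for e in df["exon_id"]],
            sample_ids=samples,
            counts=df[samples].to_numpy(),
        )


@dataclass
class ExonUsage:
    gene_id: str
    exon_id: str
    usage: np.ndarray  # per sample, NaN when gene total is 0
    scaled_usage: np.ndarray
    constant: bool = False


@dataclass
class DSResult:
    exon_id: str
    gene_id: str
    u_fat: float
    u_carb: float
    lr_stat: float
    p_value: float
    fdr: float = np.nan
    significant: bool = False
    log_fold_change_15_60: float = np.nan
    converged: bool = True


def filter_low_exons(e: ExonCountMatrix, min_total: int = 10) -> ExonCountMatrix:
    """Drop exons with < ``min_total`` reads summed over all samples, then
    genes left with fewer than 2 exons (usage is undefined for them)."""
    totals = e.counts.sum(axis=1)
    keep = totals >= min_total
    genes = np.asarray(e.gene_ids)[keep]
    counts_per_gene = pd.Series(genes).value_counts()
    multi = set(counts_per_gene[counts_per_gene >= 2].index)
    n_single = len(set(genes) - multi)
    if n_single:
        log.info("filter_low_exons: dropping %d single-exon genes", n_single)
    final = keep & np.isin(e.gene_ids, list(multi))
    return ExonCountMatrix(
        gene_ids=[g for g, k in zip(e.gene_ids, final) if k],
        exon_ids=[x for x, k in zip(e.exon_ids, final) if k],
        sample_ids=list(e.sample_ids),
        counts=e.counts[final],
    )


def compute_usage(e: ExonCountMatrix) -> list[ExonUsage]:
    """usage[exon, s] = count[exon, s] / gene total[s]; z-scored across samples.

    Samples where the gene total is 0 yield missing usage; an exon whose usage
    is constant across samples gets zero scaled usage and a constant flag.
    """
    groups = e.gene_groups()
    out = []
    for gene, idx in groups.items():
        if idx.size < 2:
            warnings.warn(f"gene {gene!r} has a single exon; usage skipped")
            continue
        block = e.counts[idx].astype(float)
        totals = block.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            usage = np.where(totals > 0, block / np.where(totals > 0, totals, 1.0), np.nan)
        for row, exon_i in enumerate(idx):
            u = usage[row]
            valid = np.isfinite(u)
            constant = False
            scaled = np.zeros_like(u)
            if valid.sum() >= 2:
                mu = np.nanmean(u)
                sd = np.nanstd(u, ddof=1)
                # usage lives in [0, 1]; treat float-noise spread as constant
                if sd > 1e-9:
                    scaled = np.where(valid, (u - mu) / sd, np.nan)
                else:
                    constant = True
                    scaled = np.where(valid, 0.0, np.nan)
            else:
                constant = True
                scaled = np.where(valid, 0.0, np.nan)
            out.append(
                ExonUsage(
                    gene_id=gene,
                    exon_id=e.exon_ids[exon_i],
                    usage=u,
                    scaled_usage=scaled,
                    constant=constant,
                )
            )
    return out


def usage_frame(usages: list[ExonUsage], sample_ids: list[str]) -> pd.DataFrame:
    rows = []
    for u in usages:
        for s, raw, sc in zip(sample_ids, u.usage, u.scaled_usage):
            rows.append((u.gene_id, u.exon_id, s, raw, sc))
    return pd.DataFrame(
        rows, columns=["gene_id", "exon_id", "sample_id", "usage", "scaled_usage"]
    )


def test_differential_usage(
    e: ExonCountMatrix, design: DietDesign
) -> list[DSResult]:
    """Per-exon 2-df LRT of diet-dependent usage (exon vs rest of gene).

    logit P(read on exon) = β₀ + u_fat·fat_pct + u_carb·carb_pct, binomial in
    (exon count, gene total); the null model drops both nutrient terms.
    """
    pct = design.sample_percent_matrix()
    missing = [s for s in e.sample_ids if s not in pct.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing[:5]}")
    cov = pct.loc[e.sample_ids].to_numpy()
    fat, carb = cov[:, 2], cov[:, 1]
    X_full = np.column_stack([np.ones(e.n_samples), fat, carb])
    X_null = X_full[:, :1]
    groups = e.gene_groups()
    results: list[DSResult] = []
    n_fail = 0
    for gene, idx in groups.items():
        if idx.size < 2:
            continue
        block = e.counts[idx].astype(float)
        totals = block.sum(axis=0)
        for row, exon_i in enumerate(idx):
            k = block[row]
            full = glm.binom_irls(k, totals, X_full)
            null = glm.binom_irls(k, totals, X_null)
            lr = max(2.0 * (full.loglik - null.loglik), 0.0)
            p = float(stats.chi2.sf(lr, 2))
            ok = full.converged and null.converged
            if not ok:
                n_fail += 1
            u_fat = float(full.beta[1])
            results.append(
                DSResult(
                    exon_id=e.exon_ids[exon_i],
                    gene_id=gene,
                    u_fat=u_fat,
                    u_carb=float(full.beta[2]),
                    lr_stat=float(lr) if ok else np.nan,
                    p_value=p if ok else np.nan,
                    log_fold_change_15_60=(FAT_HIGH - FAT_LOW) * u_fat,
                    converged=ok,
                )
            )
    if n_fail:
        log.warning("test_differential_usage: %d exons failed to converge", n_fail)
    fdrs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
        r.significant = bool(np.isfinite(q) and q < FDR_THRESHOLD)
    return results


def ds_results_frame(results: list[DSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "exon_id": [r.exon_id for r in results],
            "u_fat": [r.u_fat for r in results],
            "u_carb": [r.u_carb for r in results],
            "lr_stat": [r.lr_stat for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
            "log_fold_change_15_60": [r.log_fold_change_15_60 for r in results],
        }
    )
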