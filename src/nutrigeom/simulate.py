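"""Synthetic data with recorded ground truth for every pipeline stage.

Emulates the statistical structure of an isocaloric ten-diet mouse study:
Gaussian phenotypes around Scheffé mixture surfaces, negative-binomial gene
counts whose log-means are linear in the diet's macronutrient percentages,
multinomial exon counts whose usage logits respond to nutrients, and bulk
expression mixed from cell-type signatures.  Every generator records the
parameters it drew from (the truth manifest), so downstream estimates can be
scored against known coefficients, DE/DS flags, cluster topologies and
mixing proportions.

All randomness flows from one seed; per-stage substreams are derived
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import DietDesign, load_packaged_design
from .expression import CountMatrix
from .splicing import ExonCountMatrix
from .deconvolve import SignatureMatrix

__all__ = [
    "SurfaceTruth",
    "ExpressionTruth",
    "SplicingTruth",
    "MixtureTruth",
    "ScenarioBundle",
    "simulate_phenotypes",
    "simulate_gene_counts",
    "simulate_exon_counts",
    "simulate_bulk_mixture",
    "default_scenario",
    "default_phenotype_truths",
]

#: planted coefficient topologies (b_fat, b_carb, b_protein in log-mean change
#: per percent of energy) used by the default scenario; the label names follow
#: the response-surface gradients they generate.
TOPOLOGIES = {
    "fat_up": (1.0, 0.0, 0.0),
    "fat_down": (-1.0, 0.0, 0.0),
    "protein_up_fat_down": (-1.0, 0.0, 1.0),
    "carb_up_protein_down": (0.0, 1.0, -1.0),
    "protein_up": (0.0, 0.0, 1.0),
}
TOPOLOGY_ORDER = list(TOPOLOGIES)


@dataclass
class SurfaceTruth:
    """Generating mixture polynomial for one phenotype."""

    response_name: str
    order: str  # "null" | "linear" | "quadratic"
    beta_i: tuple[float, float, float] | None = None  # (protein, carb, fat) vertices
    beta_ij: dict | None = None  # e.g. {"protein:carb": 40.0}
    mean: float = 0.0  # null-model level
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.order == "quadratic" and self.beta_ij is None:
            raise ValueError("quadratic truth needs beta_ij")
        if self.order != "quadratic" and self.beta_ij:
            raise ValueError("beta_ij only valid for quadratic truths")

    def evaluate(self, proportions: np.ndarray) -> np.ndarray:
        """Noise-free surface value at (protein, carb, fat) proportions."""
        x = np.atleast_2d(np.asarray(proportions, dtype=float))
        if self.order == "null":
            return np.full(x.shape[0], self.mean)
        b = np.asarray(self.beta_i, dtype=float)
        y = x @ b
        if self.order == "quadratic":
            pairs = {"protein:carb": (0, 1), "protein:fat": (0, 2), "carb:fat": (1, 2)}
            for name, coef in (self.beta_ij or {}).items():
                i, j = pairs[name]
                y = y + coef * x[:, i] * x[:, j]
        return y


@dataclass
class ExpressionTruth:
    """Generating NB model for one gene."""

    gene_id: str
    baseline_log_mean: float  # natural-log counts at reference library size
    b_fat: float
    b_carb: float
    b_protein: float
    dispersion: float
    cluster_label: str | None = None

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def de_flag(self) -> bool:
        # a common shift of all three coefficients is absorbed by F+C+P=100
        return not np.isclose(self.b_fat, self.b_carb) or not np.isclose(
            self.b_carb, self.b_protein
        )


@dataclass
class SplicingTruth:
    """Generating usage-logit model for one exon."""

    exon_id: str
    gene_id: str
    baseline_usage_logit: float
    u_fat: float = 0.0
    u_carb: float = 0.0
    u_protein: float = 0.0

    @property
    def ds_flag(self) -> bool:
        return not (
            np.isclose(self.u_fat, self.u_carb)
            and np.isclose(self.u_carb, self.u_protein)
        )


@dataclass
class MixtureTruth:
    """Per-sample cell-type fractions behind a mixed bulk profile."""

    proportions: pd.DataFrame  # samples × cell types
    signature_noise_sd: float = 0.0

    def __post_init__(self):
        p = self.proportions.to_numpy(dtype=float)
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("per-sample fractions must be >= 0 and sum to 1")


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage substream seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def simulate_phenotypes(
    design: DietDesign, truths: list[SurfaceTruth], seed: int
) -> pd.DataFrame:
    """Sample × response table: Scheffé surface value + Gaussian noise."""
    rng = np.random.default_rng(seed)
    props = design.sample_proportions()
    data = {}
    for truth in truths:
        surface = truth.evaluate(props)
        data[truth.response_name] = surface + rng.normal(
            0.0, truth.noise_sd, size=len(surface)
        )
    return pd.DataFrame(data, index=design.sample_ids)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma–Poisson NB2 draw; exact Poisson when alpha == 0."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_gene_counts(
    design: DietDesign,
    truths: list[ExpressionTruth],
    library_sizes: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, list[ExpressionTruth]]:
    """NB counts with log-mean linear in macronutrient percentages.

    mean[g, s] = (lib_s / ref) · exp(baseline + b_fat·F_s + b_carb·C_s +
    b_protein·P_s) with ref the geometric-mean library size, so baselines are
    in reference-depth count units.
    """
    rng = np.random.default_rng(seed)
    n = len(design.samples)
    if library_sizes is None:
        library_sizes = np.exp(rng.normal(np.log(2e6), 0.15, size=n))
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be > 0")
    ref = np.exp(np.mean(np.log(library_sizes)))
    pct = design.sample_percent_matrix().loc[design.sample_ids].to_numpy()
    P, C, F = pct[:, 0], pct[:, 1], pct[:, 2]
    counts = np.empty((len(truths), n), dtype=np.int64)
    for i, t in enumerate(truths):
        eta = t.baseline_log_mean + t.b_fat * F + t.b_carb * C + t.b_protein * P
        mu = (library_sizes / ref) * np.exp(eta)
        counts[i] = _nb_draw(rng, mu, t.dispersion)
    m = CountMatrix(
        gene_ids=[t.gene_id for t in truths],
        sample_ids=list(design.sample_ids),
        counts=counts,
    )
    return m, truths


def simulate_exon_counts(
    design: DietDesign,
    gene_totals: CountMatrix | pd.DataFrame,
    truths: list[SplicingTruth],
    seed: int = 0,
) -> tuple[ExonCountMatrix, list[SplicingTruth]]:
    """Multinomial exon splits of gene totals with nutrient-driven usage logits.

    Per gene and sample, exon counts are drawn multinomially from the gene
    total with probabilities softmax over that gene's exon logits; exon counts
    therefore sum exactly to the gene total.
    """
    rng = np.random.default_rng(seed)
    totals = (
        gene_totals.to_frame() if isinstance(gene_totals, CountMatrix) else gene_totals
    )
    by_gene: dict[str, list[SplicingTruth]] = {}
    for t in truths:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene, exons in by_gene.items():
        if gene not in totals.index:
            raise ValueError(f"gene {gene!r} missing from gene totals")
        if len(exons) < 2:
            raise ValueError(f"gene {gene!r} has a single exon; usage undefined")
    pct = design.sample_percent_matrix().loc[list(totals.columns)].to_numpy()
    P, C, F = pct[:, 0], pct[:, 1], pct[:, 2]
    gene_ids, exon_ids, rows = [], [], []
    for gene, exons in by_gene.items():
        logits = np.stack(
            [
                t.baseline_usage_logit + t.u_fat * F + t.u_carb * C + t.u_protein * P
                for t in exons
            ]
        )  # exons × samples
        logits -= logits.max(axis=0, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=0, keepdims=True)
        tot = totals.loc[gene].to_numpy(dtype=np.int64)
        block = np.zeros((len(exons), len(tot)), dtype=np.int64)
        for s in range(len(tot)):
            if tot[s] > 0:
                block[:, s] = rng.multinomial(tot[s], probs[:, s])
        for t, row in zip(exons, block):
            gene_ids.append(gene)
            exon_ids.append(t.exon_id)
            rows.append(row)
    e = ExonCountMatrix(
        gene_ids=gene_ids,
        exon_ids=exon_ids,
        sample_ids=list(totals.columns),
        counts=np.asarray(rows),
    )
    return e, truths


def simulate_bulk_mixture(
    signature: SignatureMatrix, truth: MixtureTruth, seed: int = 0
) -> pd.DataFrame:
    """Bulk = signature · proportions + Gaussian noise, floored at 0."""
    rng = np.random.default_rng(seed)
    if list(truth.proportions.columns) != list(signature.cell_types):
        raise ValueError("mixture cell types must match signature columns")
    S = signature.values
    Pmat = truth.proportions.to_numpy(dtype=float)
    bulk = S @ Pmat.T
    if truth.signature_noise_sd > 0:
        bulk = bulk + rng.normal(0.0, truth.signature_noise_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, None)
    return pd.DataFrame(
        bulk, index=signature.genes, columns=list(truth.proportions.index)
    )


def default_phenotype_truths() -> list[SurfaceTruth]:
    """Generating surfaces for the five default phenotypes.

    Magnitudes are desk-scale conventions in plausible units (grams, iAUC
    units, grams/day); the qualitative gradients — interior body-weight/fat
    optimum, protein-driven lean mass, protein-positive glucose iAUC, elevated
    intake on low-protein diets — mirror the study system.
    """
    return [
        SurfaceTruth(
            "body_weight_g", "quadratic", beta_i=(30.0, 32.0, 24.0),
            beta_ij={"protein:carb": 40.0}, noise_sd=2.0,
        ),
        SurfaceTruth(
            "fat_mass_g", "quadratic", beta_i=(10.0, 14.0, 6.0),
            beta_ij={"protein:carb": 25.0}, noise_sd=1.5,
        ),
        SurfaceTruth("lean_mass_g", "linear", beta_i=(28.0, 22.0, 22.0), noise_sd=1.5),
        SurfaceTruth(
            "glucose_iauc", "linear", beta_i=(900.0, 500.0, 700.0), noise_sd=100.0
        ),
        SurfaceTruth(
            "food_intake_g_day", "linear", beta_i=(2.4, 3.4, 3.0), noise_sd=0.3
        ),
    ]


@dataclass
class ScenarioBundle:
    """A complete synthetic study with its generating truth."""

    seed: int
    design: DietDesign
    phenotypes: pd.DataFrame
    phenotype_truths: list[SurfaceTruth]
    gene_counts: CountMatrix
    expression_truths: list[ExpressionTruth]
    exon_counts: ExonCountMatrix
    splicing_truths: list[SplicingTruth]
    signature: SignatureMatrix
    bulk_mixture: pd.DataFrame
    mixture_truth: MixtureTruth
    stage_seeds: dict = field(default_factory=dict)

    def truth_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "phenotypes": [asdict(t) for t in self.phenotype_truths],
            "genes": [asdict(t) for t in self.expression_truths],
            "exons": [asdict(t) for t in self.splicing_truths],
            "mixture": {
                "signature_noise_sd": self.mixture_truth.signature_noise_sd,
                "proportions": self.mixture_truth.proportions.to_dict(orient="index"),
            },
            "topology_fractions": {
                lab: sum(1 for t in self.expression_truths if t.cluster_label == lab)
                / len(self.expression_truths)
                for lab in TOPOLOGY_ORDER + [None]
            },
        }


# default-scenario conventions (synthetic, not study-reported, magnitudes):
# per-percent log-mean effect for planted DE genes and per-percent usage-logit
# effect for planted DS exons.  Chosen once for comfortable detectability at
# n = 57; see docs/methods.md.
DEFAULT_GENE_EFFECT = 0.015
DEFAULT_EXON_EFFECT = 0.02
DEFAULT_DE_FRACTION = 0.5
DEFAULT_DS_GENE_FRACTION = 0.2


def default_scenario(
    seed: int,
    n_genes: int = 2000,
    n_splice_genes: int = 1250,
    exons_per_gene: int = 4,
    n_cell_types: int = 4,
    gene_effect: float = DEFAULT_GENE_EFFECT,
    exon_effect: float = DEFAULT_EXON_EFFECT,
) -> ScenarioBundle:
    """The reproducible end-to-end bundle driving the acceptance suite.

    Ten-diet design with the reference 57-sample replicate pattern; ~half of
    the genes are planted diet-responsive, split evenly over the five
    coefficient topologies; 20% of splicing genes carry one diet-responsive
    exon; bulk mixtures are drawn from a 4-type synthetic signature.
    """
    stage = dict(
        zip(
            ["phenotypes", "gene_truths", "gene_counts", "exon_truths",
             "exon_totals", "exon_counts", "signature", "mixture"],
            _sub_seeds(seed, 8),
        )
    )
    design = load_packaged_design()
    phen_truths = default_phenotype_truths()
    phenotypes = simulate_phenotypes(design, phen_truths, seed=stage["phenotypes"])

    # --- gene-level truths -------------------------------------------------
    rng = np.random.default_rng(stage["gene_truths"])
    n_de = int(round(n_genes * DEFAULT_DE_FRACTION))
    labels = [TOPOLOGY_ORDER[i % len(TOPOLOGY_ORDER)] for i in range(n_de)]
    labels += [None] * (n_genes - n_de)
    gene_truths = []
    for i, lab in enumerate(labels):
        base = rng.normal(np.log(200.0), 1.0)
        disp = float(np.exp(rng.normal(np.log(0.05), 0.3)))
        if lab is None:
            b = (0.0, 0.0, 0.0)
        else:
            direction = np.asarray(TOPOLOGIES[lab])
            scale = gene_effect * rng.uniform(0.8, 1.3)
            b = tuple(direction * scale)
        gene_truths.append(
            ExpressionTruth(
                gene_id=f"gene_{i:04d}",
                baseline_log_mean=float(base),
                b_fat=float(b[0]),
                b_carb=float(b[1]),
                b_protein=float(b[2]),
                dispersion=disp,
                cluster_label=lab,
            )
        )
    gene_counts, _ = simulate_gene_counts(design, gene_truths, seed=stage["gene_counts"])

    # --- exon-level truths -------------------------------------------------
    rng_e = np.random.default_rng(stage["exon_truths"])
    splice_totals_truths = [
        ExpressionTruth(
            gene_id=f"sgene_{i:04d}",
            baseline_log_mean=float(rng_e.normal(np.log(400.0), 0.8)),
            b_fat=0.0, b_carb=0.0, b_protein=0.0,
            dispersion=float(np.exp(rng_e.normal(np.log(0.05), 0.3))),
        )
        for i in range(n_splice_genes)
    ]
    splice_totals, _ = simulate_gene_counts(
        design, splice_totals_truths, seed=stage["exon_totals"]
    )
    n_ds_genes = int(round(n_splice_genes * DEFAULT_DS_GENE_FRACTION))
    exon_truths: list[SplicingTruth] = []
    for i in range(n_splice_genes):
        gene = f"sgene_{i:04d}"
        ds_here = i < n_ds_genes
        topo = TOPOLOGY_ORDER[i % len(TOPOLOGY_ORDER)] if ds_here else None
        for j in range(exons_per_gene):
            u = (0.0, 0.0, 0.0)
            if ds_here and j == 0:
                direction = np.asarray(TOPOLOGIES[topo])
                u = tuple(direction * exon_effect * rng_e.uniform(0.8, 1.3))
            exon_truths.append(
                SplicingTruth(
                    exon_id=f"{gene}:E{j:03d}",
                    gene_id=gene,
                    baseline_usage_logit=float(rng_e.normal(0.0, 0.5)),
                    u_fat=float(u[0]),
                    u_carb=float(u[1]),
                    u_protein=float(u[2]),
                )
            )
    exon_counts, _ = simulate_exon_counts(
        design, splice_totals, exon_truths, seed=stage["exon_counts"]
    )

    # --- deconvolution inputs ----------------------------------------------
    rng_s = np.random.default_rng(stage["signature"])
    cell_types = [f"type_{t}" for t in range(n_cell_types)]
    n_sig_genes = 60 * n_cell_types
    sig = rng_s.uniform(1.0, 20.0, size=(n_sig_genes, n_cell_types))
    for t in range(n_cell_types):  # distinct markers per type
        rows = slice(t * 60, t * 60 + 60)
        sig[rows, t] += rng_s.uniform(80.0, 200.0, size=60)
    signature = SignatureMatrix(
        genes=[f"mgene_{i:04d}" for i in range(n_sig_genes)],
        cell_types=cell_types,
        values=sig,
    )
    rng_m = np.random.default_rng(stage["mixture"])
    props = rng_m.dirichlet(np.full(n_cell_types, 2.0), size=len(design.samples))
    mixture_truth = MixtureTruth(
        proportions=pd.DataFrame(props, index=design.sample_ids, columns=cell_types),
        signature_noise_sd=0.5,
    )
    bulk = simulate_bulk_mixture(signature, mixture_truth, seed=stage["mixture"])

    return ScenarioBundle(
        seed=seed,
        design=design,
        phenotypes=phenotypes,
        phenotype_truths=phen_truths,
        gene_counts=gene_counts,
        expression_truths=gene_truths,
        exon_counts=exon_counts,
        splicing_truths=exon_truths,
        signature=signature,
        bulk_mixture=bulk,
        mixture_truth=mixture_truth,
        stage_seeds=stage,
    )
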