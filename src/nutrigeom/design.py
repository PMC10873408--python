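"""Diet compositions on the macronutrient simplex and the right-angled mixture triangle.

A diet is a point on the 2-simplex: percent of total energy from protein,
carbohydrate and fat, summing to 100 (isocaloric designs hold energy density
constant, so composition is the only dietary variable).  All response surfaces
are drawn in the right-angled mixture triangle (RMT): protein on the x-axis,
carbohydrate on the y-axis, and fat implied as the remainder to 100 — the
origin is a pure-fat diet and fat falls to zero along the x + y = 100 edge.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MacronutrientComposition",
    "DietDesign",
    "RmtGrid",
    "CompositionError",
    "load_design",
    "load_packaged_design",
    "rmt_project",
    "make_grid",
    "replicate_pattern",
]

#: replicate counts of the reference adipose study: 6 mice per diet except
#: diets 2, 3 and 4 which retain 5 after sample QC (57 samples total).
DEFAULT_REPLICATES = {1: 6, 2: 5, 3: 5, 4: 5, 5: 6, 6: 6, 7: 6, 8: 6, 9: 6, 10: 6}

_SUM_TOL = 1e-6


class CompositionError(ValueError):
    """A macronutrient composition violates the simplex constraint."""


@dataclass(frozen=True)
class MacronutrientComposition:
    """Percent of total energy from each macronutrient; components sum to 100."""

    protein_pct: float
    carb_pct: float
    fat_pct: float

    def __post_init__(self):
        vals = (self.protein_pct, self.carb_pct, self.fat_pct)
        if any(v < -_SUM_TOL or v > 100 + _SUM_TOL for v in vals):
            raise CompositionError(f"components must lie in [0, 100], got {vals}")
        total = sum(vals)
        if abs(total - 100.0) > _SUM_TOL:
            raise CompositionError(
                f"components must sum to 100 (got {total!r}): {vals}"
            )
        # renormalize exactly so the invariant is float-safe downstream
        object.__setattr__(self, "protein_pct", 100.0 * self.protein_pct / total)
        object.__setattr__(self, "carb_pct", 100.0 * self.carb_pct / total)
        object.__setattr__(
            self, "fat_pct", 100.0 - self.protein_pct - self.carb_pct
        )

    @property
    def proportions(self) -> np.ndarray:
        """(protein, carb, fat) on the 0–1 proportion scale (for Scheffé fits)."""
        return np.array([self.protein_pct, self.carb_pct, self.fat_pct]) / 100.0


@dataclass
class DietDesign:
    """Diet compositions plus the sample → diet assignment.

    The shared coordinate system of the whole pipeline: every downstream model
    (surfaces, differential expression, splicing, correlations) reads its
    covariates from here.
    """

    diets: list[tuple[object, MacronutrientComposition]]
    samples: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self):
        ids = [d for d, _ in self.diets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate diet_id in design")
        known = set(ids)
        for sample_id, diet_id in self.samples:
            if diet_id not in known:
                raise ValueError(
                    f"sample {sample_id!r} references unknown diet {diet_id!r}"
                )

    @property
    def diet_ids(self) -> list:
        return [d for d, _ in self.diets]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def replicate_counts(self) -> dict:
        counts: dict = {d: 0 for d in self.diet_ids}
        for _, diet_id in self.samples:
            counts[diet_id] += 1
        return counts

    def composition(self, diet_id) -> MacronutrientComposition:
        for d, comp in self.diets:
            if d == diet_id:
                return comp
        raise KeyError(diet_id)

    def sample_percent_matrix(self) -> pd.DataFrame:
        """Per-sample (protein_pct, carb_pct, fat_pct) covariate table."""
        lookup = dict(self.diets)
        rows = {
            s: (lookup[d].protein_pct, lookup[d].carb_pct, lookup[d].fat_pct)
            for s, d in self.samples
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["protein_pct", "carb_pct", "fat_pct"]
        )

    def sample_proportions(self) -> np.ndarray:
        """n_samples × 3 array of (protein, carb, fat) proportions."""
        return self.sample_percent_matrix().to_numpy() / 100.0


@dataclass
class RmtGrid:
    """Regular lattice over the right-angled mixture triangle."""

    points: np.ndarray  # (n, 2) array of (protein_pct, carb_pct)
    resolution: float
    clip_to_hull: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("grid points must be (n, 2)")
        if np.any(self.points.sum(axis=1) > 100 + _SUM_TOL):
            raise ValueError("grid point implies negative fat")

    @property
    def implied_fat(self) -> np.ndarray:
        return 100.0 - self.points.sum(axis=1)

    def compositions(self) -> list[MacronutrientComposition]:
        return [
            MacronutrientComposition(p, c, 100.0 - p - c) for p, c in self.points
        ]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_pct": self.points[:, 0],
                "carb_pct": self.points[:, 1],
                "fat_pct": self.implied_fat,
            }
        )


def rmt_project(c: MacronutrientComposition) -> tuple[float, float, float]:
    """Project a composition into RMT coordinates.

    Returns (x, y, implied_fat) = (protein_pct, carb_pct, 100 − x − y).  The
    origin maps to a 100%-fat diet and fat decreases to 0% along x + y = 100.
    """
    return c.protein_pct, c.carb_pct, 100.0 - c.protein_pct - c.carb_pct


def load_design(design_table, manifest=None) -> DietDesign:
    """Build a :class:`DietDesign` from delimited tables.

    Parameters
    ----------
    design_table
        Path or DataFrame with columns diet_id, protein_pct, carb_pct, fat_pct.
    manifest
        Optional path or DataFrame with columns sample_id, diet_id.  When
        omitted, samples are generated from the reference replicate pattern
        (6 per diet; 5 for diets 2–4) as ``d{diet}_r{rep}``.
    """
    df = (
        design_table
        if isinstance(design_table, pd.DataFrame)
        else pd.read_csv(design_table, sep=None, engine="python")
    )
    required = {"diet_id", "protein_pct", "carb_pct", "fat_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    diets = []
    for _, row in df.iterrows():
        try:
            comp = MacronutrientComposition(
                float(row["protein_pct"]), float(row["carb_pct"]), float(row["fat_pct"])
            )
        except CompositionError as exc:
            raise CompositionError(f"diet {row['diet_id']!r}: {exc}") from exc
        diets.append((row["diet_id"], comp))
    if manifest is None:
        samples = replicate_pattern([d for d, _ in diets])
    else:
        mdf = (
            manifest
            if isinstance(manifest, pd.DataFrame)
            else pd.read_csv(manifest, sep=None, engine="python")
        )
        if not {"sample_id", "diet_id"}.issubset(mdf.columns):
            raise ValueError("manifest needs columns sample_id, diet_id")
        samples = list(zip(mdf["sample_id"].astype(str), mdf["diet_id"]))
    return DietDesign(diets=diets, samples=samples)


def replicate_pattern(diet_ids: Sequence, replicates: dict | None = None):
    """Expand diet ids into (sample_id, diet_id) pairs.

    Defaults to the reference study's pattern where known; 6 replicates for
    unrecognized diet ids.
    """
    replicates = DEFAULT_REPLICATES if replicates is None else replicates
    samples = []
    for diet_id in diet_ids:
        n = replicates.get(diet_id, 6)
        for r in range(1, n + 1):
            samples.append((f"d{diet_id}_r{r}", diet_id))
    return samples


def load_packaged_design(manifest=None) -> DietDesign:
    """The ten-diet reference design shipped with the package."""
    with importlib.resources.files("nutrigeom.data").joinpath(
        "diet_design.csv"
    ).open() as fh:
        table = pd.read_csv(fh)
    return load_design(table, manifest=manifest)


def make_grid(
    design: DietDesign | None = None,
    resolution: float = 1.0,
    clip_to_hull: bool = False,
) -> RmtGrid:
    """Regular lattice over the triangle protein ≥ 0, carb ≥ 0, protein + carb ≤ 100.

    With ``clip_to_hull`` the lattice is restricted to the convex hull of the
    design's diet compositions (no extrapolation beyond tested diets).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    axis = np.arange(0.0, 100.0 + resolution / 2, resolution)
    px, cy = np.meshgrid(axis, axis, indexing="ij")
    pts = np.column_stack([px.ravel(), cy.ravel()])
    pts = pts[pts.sum(axis=1) <= 100 + _SUM_TOL]
    if clip_to_hull:
        if design is None:
            raise ValueError("clip_to_hull requires a design")
        from scipy.spatial import Delaunay

        verts = np.array(
            [(comp.protein_pct, comp.carb_pct) for _, comp in design.diets]
        )
        hull = Delaunay(verts)
        pts = pts[hull.find_simplex(pts) >= 0]
    # lexicographic (protein, carb) order for reproducible extrema tie-breaks
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return RmtGrid(points=pts[order], resolution=resolution, clip_to_hull=clip_to_hull)
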