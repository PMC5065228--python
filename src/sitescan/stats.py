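"""Occupancy normalization, affinity summaries and dynamics comparison.

The occupancy table counts pose→site assignments per ligand category and
normalizes by molecules × poses-per-molecule × receptor conformations, so
cells are comparable between categories of different size.  The dynamics
comparison is deliberately descriptive (means, SDs, variance ratio) — MD
frames are autocorrelated, so no p-values are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import ValidationError
from .geometry import DistanceSeries, block_average
from .sites import OVERLAP_LABELS, UNASSIGNED, SiteAssignment

__all__ = [
    "OccupancyTable",
    "CategorySummary",
    "DynamicsComparison",
    "occupancy_table",
    "affinity_summary",
    "compare_dynamics",
]


@dataclass
class OccupancyTable:
    """site-label × category pose frequencies, raw and normalized."""

    raw_counts: dict[tuple[str, str], int]
    cells: dict[tuple[str, str], float]
    n_molecules: dict[str, int]
    n_conformations: int
    n_poses_per_molecule: int

    @property
    def labels(self) -> list[str]:
        return sorted({lab for lab, _ in self.raw_counts})

    @property
    def categories(self) -> list[str]:
        return sorted(self.n_molecules)

    def normalized(self, label: str, category: str) -> float:
        return self.cells.get((label, category), 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label in self.labels:
            for cat in self.categories:
                rows.append(
                    {
                        "site": label,
                        "category": cat,
                        "raw_count": self.raw_counts.get((label, cat), 0),
                        "normalized": self.cells.get((label, cat), 0.0),
                    }
                )
        return pd.DataFrame(rows)


def occupancy_table(
    assignments: list[tuple[SiteAssignment, str]],
    categories: dict[str, str],
    n_conformations: int | None = None,
    n_poses_per_molecule: int | None = None,
) -> OccupancyTable:
    """Count assignments per (site label, category) and normalize.

    ``assignments`` pairs each :class:`~sitescan.sites.SiteAssignment` with
    its ligand id; ``categories`` maps ligand id → category.  The
    normalization denominator for a category is
    ``n_molecules(category) × n_poses_per_molecule × n_conformations``;
    both counts are derived from the data when not given (distinct
    conformation ids seen, and the maximum pose rank seen).  ``unassigned``
    is tracked as its own row.
    """
    if not assignments:
        raise ValidationError("no assignments to tabulate")
    for lig in {lig for _, lig in assignments}:
        if lig not in categories:
            raise ValidationError(f"ligand {lig!r} has no category")
    n_mol: dict[str, int] = {}
    for cat in categories.values():
        n_mol[cat] = n_mol.get(cat, 0) + 1
    if any(v == 0 for v in n_mol.values()) or not n_mol:
        raise ValidationError("every category must contain at least one molecule")

    if n_conformations is None:
        n_conformations = len({a.pose_ref[1] for a, _ in assignments})
    if n_poses_per_molecule is None:
        n_poses_per_molecule = max(a.pose_ref[2] for a, _ in assignments)
    if n_conformations < 1 or n_poses_per_molecule < 1:
        raise ValidationError("need at least one conformation and one pose")

    raw: dict[tuple[str, str], int] = {}
    for assignment, lig in assignments:
        key = (assignment.label, categories[lig])
        raw[key] = raw.get(key, 0) + 1

    cells = {
        (label, cat): count / (n_mol[cat] * n_poses_per_molecule * n_conformations)
        for (label, cat), count in raw.items()
    }
    return OccupancyTable(
        raw_counts=raw,
        cells=cells,
        n_molecules=n_mol,
        n_conformations=n_conformations,
        n_poses_per_molecule=n_poses_per_molecule,
    )


@dataclass
class CategorySummary:
    """Point summaries (kcal/mol) and optional kernel density of affinities."""

    category: str
    n: int
    mean: float
    median: float
    min: float
    density_grid: np.ndarray | None = None
    density: np.ndarray | None = None
    bandwidth_rule: str = "silverman"


def affinity_summary(pose_sets, grid_points: int = 200) -> dict[str, CategorySummary]:
    """Per-category affinity summaries with a Silverman-rule kernel density.

    The density is omitted (grid/density ``None``) when a category has a
    single pose or zero spread.
    """
    by_cat: dict[str, list[float]] = {}
    for ps in pose_sets:
        by_cat.setdefault(ps.category, []).extend(p.affinity for p in ps.poses)
    if not by_cat or any(len(v) == 0 for v in by_cat.values()):
        raise ValidationError("need at least one pose per category")
    out: dict[str, CategorySummary] = {}
    for cat, values in by_cat.items():
        arr = np.asarray(values, dtype=float)
        summary = CategorySummary(
            category=cat,
            n=arr.size,
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            min=float(arr.min()),
        )
        if arr.size > 1 and arr.std() > 0:
            kde = gaussian_kde(arr, bw_method="silverman")
            pad = 3.0 * arr.std()
            grid = np.linspace(arr.min() - pad, arr.max() + pad, grid_points)
            summary.density_grid = grid
            summary.density = kde(grid)
        out[cat] = summary
    return out


@dataclass
class DynamicsComparison:
    """Descriptive WT-vs-mutant comparison of block-averaged distances."""

    pair_id: str
    window: int
    wt_replicate_means: list[float]
    mut_replicate_means: list[float]
    wt_mean: float
    wt_sd: float
    mut_mean: float
    mut_sd: float
    delta_mean: float
    variance_ratio: float

    def __post_init__(self) -> None:
        if self.wt_sd < 0 or self.mut_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not self.variance_ratio > 0:
            raise ValidationError("variance_ratio must be positive")


def _pooled_blocks(replicates: list[DistanceSeries], window: int) -> list[np.ndarray]:
    return [block_average(r.values, window) for r in replicates]


def compare_dynamics(
    wt_replicates: list[DistanceSeries],
    mut_replicates: list[DistanceSeries],
    window: int = 10,
    pair_id: str = "",
) -> DynamicsComparison:
    """Block-average each replicate, then pool per condition and compare.

    ``delta_mean`` is mutant − wild type; ``variance_ratio`` is the ratio of
    pooled block-value variances (mutant / wild type).
    """
    if not wt_replicates or not mut_replicates:
        raise ValidationError("need at least one replicate per condition")
    wt_blocks = _pooled_blocks(wt_replicates, window)
    mut_blocks = _pooled_blocks(mut_replicates, window)
    wt_all = np.concatenate(wt_blocks)
    mut_all = np.concatenate(mut_blocks)
    if wt_all.size < 2 or mut_all.size < 2:
        raise ValidationError("need at least two block values per condition")
    wt_var = float(np.var(wt_all, ddof=1))
    mut_var = float(np.var(mut_all, ddof=1))
    if wt_var == 0.0:
        raise ValidationError("wild-type variance is zero; variance ratio undefined")
    if not pair_id:
        pair_id = "-".join(
            f"{c}:{r}" for c, r in wt_replicates[0].pair
        )
    return DynamicsComparison(
        pair_id=pair_id,
        window=window,
        wt_replicate_means=[float(b.mean()) for b in wt_blocks],
        mut_replicate_means=[float(b.mean()) for b in mut_blocks],
        wt_mean=float(wt_all.mean()),
        wt_sd=float(np.std(wt_all, ddof=1)),
        mut_mean=float(mut_all.mean()),
        mut_sd=float(np.std(mut_all, ddof=1)),
        delta_mean=float(mut_all.mean() - wt_all.mean()),
        variance_ratio=mut_var / wt_var,
    )
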