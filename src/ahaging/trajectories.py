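"""Per-protein LOESS age trajectories, trajectory clustering, and cluster
aging-protein enrichment.

Each protein's z-scored expression is smoothed against age with locally
weighted polynomial regression (tricube weights, degree 2 by default, span
0.75) on a fixed age grid; the fitted grid vectors are clustered with
agglomerative hierarchical clustering, and each cluster is tested for
over-representation of aging proteins with an upper-tail hypergeometric test
(BH-adjusted across clusters).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from ._stats import bh_adjust, hypergeom_upper_tail
from .core_data import AbundanceTable, CohortMetadata
from .errors import ConfigurationError, ValidationError

__all__ = [
    "TrajectoryProfile",
    "ClusterResult",
    "loess_smooth",
    "fit_loess_trajectory",
    "fit_trajectories",
    "profiles_to_frame",
    "cluster_trajectories",
    "cluster_ap_enrichment",
]

LINKAGE_METHODS = ("complete", "average", "ward")


@dataclass(frozen=True)
class TrajectoryProfile:
    """A protein's smoothed trajectory on an evenly spaced age grid."""

    protein_id: str
    grid_ages: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int

    def __post_init__(self):
        if not np.all(np.diff(self.grid_ages) > 0):
            raise ValidationError("grid ages must be strictly increasing")
        if not np.all(np.isfinite(self.fitted)):
            raise ValidationError("fitted values must be finite")


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignments (1..k) plus optional per-cluster enrichment table."""

    assignments: pd.Series
    k: int
    linkage: str
    table: pd.DataFrame | None = None


def loess_smooth(x, y, x_eval, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    For each evaluation point the ceil(span*n) nearest samples receive
    tricube weights scaled by the distance to the furthest of them, and a
    weighted degree-``degree`` polynomial is fit; the local fit is evaluated
    at the point. No robustness iterations are applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x.size
    if not 0 < span <= 1:
        raise ConfigurationError("span must lie in (0, 1]")
    if degree < 0:
        raise ConfigurationError("degree must be >= 0")
    q = max(int(math.ceil(span * n)), degree + 2)
    if n < q:
        raise ValidationError(f"need at least {q} samples for span={span}, degree={degree}")
    if np.ptp(x) == 0:
        raise ValidationError("ages must not all be identical")
    out = np.empty(x_eval.shape, dtype=float)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        h = max(h, 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3
        if np.count_nonzero(w) < degree + 1:
            # Duplicate-age guard: fall back to the q nearest with flat weights.
            nearest = np.argsort(d, kind="stable")[:q]
            w = np.zeros_like(w)
            w[nearest] = 1.0
        sw = np.sqrt(w)
        design = np.vander(x - x0, degree + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        out[i] = beta[0]
    return out


def fit_loess_trajectory(
    expr,
    ages,
    protein_id: str = "",
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 50,
) -> TrajectoryProfile:
    """Smooth one protein's per-sample z-scores over age.

    The grid spans the observed age range (no extrapolation).
    """
    ages = np.asarray(ages, dtype=float)
    grid = np.linspace(ages.min(), ages.max(), grid_size)
    fitted = loess_smooth(ages, np.asarray(expr, dtype=float), grid, span=span, degree=degree)
    return TrajectoryProfile(protein_id=protein_id, grid_ages=grid, fitted=fitted,
                             span=span, degree=degree)


def fit_trajectories(
    table: AbundanceTable,
    meta: CohortMetadata,
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Fit LOESS trajectories for every protein; rows are proteins, columns
    the shared age grid."""
    meta.check_matches(table)
    ages = meta.age.loc[table.sample_ids].to_numpy()
    grid = np.linspace(ages.min(), ages.max(), grid_size)
    fitted = np.empty((len(table.protein_ids), grid_size))
    values = table.data.to_numpy(dtype=float)
    for i in range(values.shape[0]):
        fitted[i] = loess_smooth(ages, values[i], grid, span=span, degree=degree)
    return pd.DataFrame(fitted, index=table.data.index, columns=grid)


def profiles_to_frame(profiles: Iterable[TrajectoryProfile]) -> pd.DataFrame:
    """Stack TrajectoryProfiles sharing one grid into a proteins x grid frame."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles given")
    grid = profiles[0].grid_ages
    for p in profiles[1:]:
        if p.grid_ages.shape != grid.shape or not np.allclose(p.grid_ages, grid):
            raise ValidationError("profiles do not share a common age grid")
    return pd.DataFrame(
        np.vstack([p.fitted for p in profiles]),
        index=[p.protein_id for p in profiles],
        columns=grid,
    )


def cluster_trajectories(
    profiles: pd.DataFrame,
    k: int,
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of fitted trajectories, tree cut at k clusters.

    Euclidean distance between fitted grid vectors; deterministic for a fixed
    input order (scipy's linkage ordering resolves distance ties).
    """
    if linkage not in LINKAGE_METHODS:
        raise ConfigurationError(f"linkage must be one of {LINKAGE_METHODS}")
    n = len(profiles)
    if not 2 <= k <= n:
        raise ValidationError(f"k must lie in [2, {n}]")
    if profiles.index.has_duplicates:
        raise ValidationError("duplicate protein ids in profiles")
    values = profiles.to_numpy(dtype=float)
    tree = hierarchy.linkage(values, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=profiles.index, name="cluster")
    return ClusterResult(assignments=assignments, k=int(assignments.max()), linkage=linkage)


def cluster_ap_enrichment(
    result: ClusterResult,
    ap_set: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> ClusterResult:
    """Test each cluster for over-representation of aging proteins.

    Upper-tail hypergeometric probability of observing >= the cluster's AP
    count given its size, the AP-set size and the universe size, BH-adjusted
    across the k clusters; a cluster is retained when adjusted p < alpha.
    """
    aps = set(ap_set)
    uni = set(universe)
    if not aps <= uni:
        raise ValidationError(f"AP set not contained in universe: {sorted(aps - uni)[:5]}")
    clustered = set(result.assignments.index)
    if not clustered <= uni:
        raise ValidationError("clustered proteins must be contained in the universe")
    rows = []
    for cluster_id, members in result.assignments.groupby(result.assignments).groups.items():
        size = len(members)
        ap_count = len(aps & set(members))
        p = hypergeom_upper_tail(ap_count, size, len(aps), len(uni))
        rows.append({"cluster": cluster_id, "size": size, "ap_count": ap_count, "p": p})
    table = pd.DataFrame(rows).set_index("cluster").sort_index()
    table["padj"] = bh_adjust(table["p"].to_numpy())
    table["retained"] = table["padj"] < alpha
    return replace(result, table=table)
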