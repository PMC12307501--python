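"""Aging-protein identification.

An aging protein (AP) must pass two independent tests with a concordant
direction: a two-sided Wilcoxon rank-sum comparison of the older vs young
groups (BH-adjusted), and a covariate-adjusted linear age association
(expression ~ age + sex + BMI, two-sided t-test on the age coefficient,
BH-adjusted). The module also correlates AP expression with ordinal
lens-opacity grade and compares directed AP sets between fluids.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust, ols_tstats
from .core_data import (
    AbundanceTable,
    CohortMetadata,
    GROUP_OLDER,
    GROUP_YOUNG,
    log2fc_by_group,
    zscore_per_protein,
)
from .errors import ValidationError

__all__ = [
    "wilcoxon_differential",
    "age_linear_model",
    "identify_aps",
    "differential_analysis",
    "opacity_correlation",
    "SetComparison",
    "compare_ap_sets",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

#: Largest group size for which the exact rank-sum null is enumerated.
EXACT_WILCOXON_MAX_N = 12


def _wilcoxon_p(older: np.ndarray, young: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when both groups are small and tie-free,
    otherwise normal approximation with continuity and tie correction."""
    combined = np.concatenate([older, young])
    no_ties = len(np.unique(combined)) == combined.size
    small = max(older.size, young.size) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(older, young, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def wilcoxon_differential(table: AbundanceTable, meta: CohortMetadata) -> pd.DataFrame:
    """Per-protein log2 fold change (older - young) and Wilcoxon rank-sum p."""
    meta.check_matches(table)
    older = [s for s in table.sample_ids if meta.group.get(s) == GROUP_OLDER]
    young = [s for s in table.sample_ids if meta.group.get(s) == GROUP_YOUNG]
    if len(older) < 2 or len(young) < 2:
        raise ValidationError("both groups need at least 2 samples")
    if table.has_missing():
        raise ValidationError("impute missing values before testing")
    fc = log2fc_by_group(table, meta)
    x = table.data[older].to_numpy(dtype=float)
    y = table.data[young].to_numpy(dtype=float)
    small = max(len(older), len(young)) <= EXACT_WILCOXON_MAX_N
    if small:
        pvals = np.array([_wilcoxon_p(x[i], y[i]) for i in range(x.shape[0])])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                   use_continuity=True, axis=1)
        pvals = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame({"log2fc": fc, "wilcoxon_p": pvals}, index=table.data.index)


def _design_matrix(meta: CohortMetadata, sample_ids: list[str]) -> np.ndarray:
    sub = meta.df.loc[sample_ids]
    bmi = sub["bmi"].to_numpy(dtype=float)
    if np.isnan(bmi).any():
        n_bad = int(np.isnan(bmi).sum())
        logger.warning("mean-imputing BMI for %d samples with missing values", n_bad)
        bmi = np.where(np.isnan(bmi), np.nanmean(bmi), bmi)
    return np.column_stack([
        np.ones(len(sample_ids)),
        sub["age"].to_numpy(dtype=float),
        sub["sex"].to_numpy(dtype=float),
        bmi,
    ])


def age_linear_model(table: AbundanceTable, meta: CohortMetadata) -> pd.DataFrame:
    """OLS of each protein on age + sex + BMI; t-test on the age coefficient.

    Returns age_beta (log2 units / year), age_p, and a ``not_estimable`` flag
    set for every record when the shared design matrix is rank deficient.
    """
    meta.check_matches(table)
    samples = table.sample_ids
    if len(samples) < 5:
        raise ValidationError("age model needs at least 5 samples")
    if table.has_missing():
        raise ValidationError("impute missing values before testing")
    X = _design_matrix(meta, samples)
    Y = table.data.to_numpy(dtype=float).T
    fit = ols_tstats(X, Y)
    out = pd.DataFrame(
        {"age_beta": fit.beta[1], "age_se": fit.se[1], "age_p": fit.pval[1]},
        index=table.data.index,
    )
    out["not_estimable"] = not fit.estimable
    if not fit.estimable:
        logger.warning("design matrix rank deficient; age effects not estimable")
    return out


def identify_aps(
    records: pd.DataFrame,
    alpha: float = 0.05,
    require_sign_concordance: bool = True,
) -> pd.DataFrame:
    """Apply the dual AP criterion to a merged differential table.

    ``records`` needs columns wilcoxon_padj, age_padj, log2fc, age_beta.
    AP <=> both adjusted p-values < alpha and (optionally) concordant signs;
    direction is ``up`` when log2fc > 0, ``down`` otherwise.
    """
    needed = {"wilcoxon_padj", "age_padj", "log2fc", "age_beta"}
    missing = needed - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    out = records.copy()
    significant = (out["wilcoxon_padj"] < alpha) & (out["age_padj"] < alpha)
    if require_sign_concordance:
        significant &= np.sign(out["log2fc"]) == np.sign(out["age_beta"])
    out["is_ap"] = significant.fillna(False)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def differential_analysis(
    table: AbundanceTable,
    meta: CohortMetadata,
    alpha: float = 0.05,
    require_sign_concordance: bool = True,
) -> pd.DataFrame:
    """Full differential record per protein: both tests, BH adjustment, AP call."""
    wil = wilcoxon_differential(table, meta)
    age = age_linear_model(table, meta)
    records = wil.join(age)
    records["wilcoxon_padj"] = bh_adjust(records["wilcoxon_p"].to_numpy())
    if records["not_estimable"].any():
        records["age_padj"] = np.nan
    else:
        records["age_padj"] = bh_adjust(records["age_p"].to_numpy())
    return identify_aps(records, alpha=alpha,
                        require_sign_concordance=require_sign_concordance)


def _strength_bin(r: float) -> str:
    a = abs(r)
    if a < 0.4:
        return "weak"
    if a < 0.6:
        return "moderate"
    return "strong"


def opacity_correlation(
    table: AbundanceTable,
    ap_directions: Mapping[str, str],
    meta: CohortMetadata,
) -> pd.DataFrame:
    """Spearman correlation of each AP (and up/down composite scores) with
    lens-opacity grade over the graded samples.

    Composites are the mean per-sample z-score over the up-APs and over the
    down-APs. BH adjustment spans all tested records; |r| bins at 0.4/0.6
    label weak/moderate/strong associations.
    """
    meta.check_matches(table)
    graded = [s for s in table.sample_ids if np.isfinite(meta.opacity_grade.get(s, np.nan))]
    if len(graded) < 3:
        raise ValidationError("need at least 3 graded samples")
    grade = meta.opacity_grade.loc[graded].to_numpy(dtype=float)
    aps = [p for p in ap_directions if p in table.data.index]
    missing = set(ap_directions) - set(aps)
    if missing:
        raise ValidationError(f"APs not in table: {sorted(missing)[:5]}")
    sub = table.subset_proteins(aps)
    rows = []
    for pid in aps:
        r, p = sps.spearmanr(sub.data.loc[pid, graded].to_numpy(), grade)
        rows.append({"record": pid, "r": r, "p": p})
    z = zscore_per_protein(table).data
    for direction in ("up", "down"):
        ids = [p for p, d in ap_directions.items() if d == direction and p in z.index]
        if ids:
            composite = z.loc[ids, graded].mean(axis=0).to_numpy()
            r, p = sps.spearmanr(composite, grade)
            rows.append({"record": f"composite_{direction}", "r": r, "p": p})
    out = pd.DataFrame(rows).set_index("record")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["strength_bin"] = [_strength_bin(r) for r in out["r"]]
    return out


@dataclass(frozen=True)
class SetComparison:
    """Outcome of comparing two directed protein sets."""

    concordant: tuple[str, ...]
    discordant: tuple[str, ...]
    a_only: tuple[str, ...]
    b_only: tuple[str, ...]

    @property
    def n_concordant(self) -> int:
        return len(self.concordant)

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)


def _as_direction_map(directed, label: str) -> dict[str, str]:
    if isinstance(directed, Mapping):
        items = list(directed.items())
    else:
        items = list(directed)
    out: dict[str, str] = {}
    for pid, direction in items:
        if direction not in ("up", "down"):
            raise ValidationError(f"{label}: direction must be 'up' or 'down', got {direction!r}")
        if pid in out:
            raise ValidationError(f"{label}: duplicate protein id {pid!r}")
        out[pid] = direction
    return out


def compare_ap_sets(set_a, set_b) -> SetComparison:
    """Partition two directed AP sets into concordant / discordant / exclusive ids.

    Concordant = shared id with equal direction; discordant = shared id with
    opposite direction. Mirrors a directed comparison of aging-protein lists
    between body fluids.
    """
    a = _as_direction_map(set_a, "set_a")
    b = _as_direction_map(set_b, "set_b")
    shared = sorted(set(a) & set(b))
    concordant = tuple(p for p in shared if a[p] == b[p])
    discordant = tuple(p for p in shared if a[p] != b[p])
    return SetComparison(
        concordant=concordant,
        discordant=discordant,
        a_only=tuple(sorted(set(a) - set(b))),
        b_only=tuple(sorted(set(b) - set(a))),
    )
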