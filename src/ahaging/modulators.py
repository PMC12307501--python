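"""Aging-modulator discovery.

Two Δage-aware linear models per aging protein: (1) expression ~ age + sex +
BMI + Δage, with a two-sided t-test on the Δage coefficient (a modulator has
raw p < alpha; BH-adjusted values are always reported so stricter filtering
stays possible); (2) expression ~ age + sex + BMI + ager group with the
chronological agers (CA) as reference, producing AA-CA and DA-CA contrasts
that label proteins as accelerating / decelerating candidates. Unclassified
samples (2 <= |Δage| < 5 years) are excluded from the group contrasts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, ols_tstats
from .core_data import AbundanceTable, CohortMetadata
from .differential import _design_matrix
from .errors import ValidationError

__all__ = ["delta_age_modulators", "ager_group_contrasts", "modulator_records"]


def delta_age_modulators(
    table: AbundanceTable,
    meta: CohortMetadata,
    delta_age: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein Δage association, adjusted for age, sex and BMI.

    Returns delta_beta (log2 units per Δage-year), delta_p, delta_padj, the
    coefficient sign, and the modulator call at raw p < alpha.
    """
    meta.check_matches(table)
    samples = table.sample_ids
    d = delta_age.loc[samples].to_numpy(dtype=float)
    if np.ptp(d) < 1e-12:
        raise ValidationError("degenerate Δage: no variance in the regressor")
    X = np.column_stack([_design_matrix(meta, samples), d])
    Y = table.data.to_numpy(dtype=float).T
    fit = ols_tstats(X, Y)
    out = pd.DataFrame(
        {"delta_beta": fit.beta[4], "delta_se": fit.se[4], "delta_p": fit.pval[4]},
        index=table.data.index,
    )
    out["not_estimable"] = not fit.estimable
    if fit.estimable:
        out["delta_padj"] = bh_adjust(out["delta_p"].to_numpy())
    else:
        out["delta_padj"] = np.nan
    out["sign"] = np.where(out["delta_beta"] > 0, "positive", "negative")
    out["is_modulator"] = (out["delta_p"] < alpha).fillna(False)
    return out


def ager_group_contrasts(
    table: AbundanceTable,
    meta: CohortMetadata,
    ager_classes: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """AA-CA and DA-CA expression contrasts adjusted for age, sex and BMI.

    Chronological agers are the reference level; unclassified samples are
    dropped. The label marks a protein ``decelerating`` when the DA contrast
    is significant, ``accelerating`` when the AA contrast is (the smaller p
    wins if both are); the contrast signs are reported alongside so the
    biological reading stays with the user.
    """
    meta.check_matches(table)
    classes = ager_classes.loc[table.sample_ids]
    keep = classes.isin(["DA", "AA", "CA"])
    samples = list(classes.index[keep])
    classes = classes.loc[samples]
    n_ca = int((classes == "CA").sum())
    n_aa = int((classes == "AA").sum())
    n_da = int((classes == "DA").sum())
    if n_ca == 0:
        raise ValidationError("no chronological agers (CA): reference level empty")
    if n_aa == 0 and n_da == 0:
        raise ValidationError("need at least one AA or DA sample to contrast")
    sub = table.subset_samples(samples)
    X_base = _design_matrix(meta, samples)
    cols, names = [], []
    if n_aa:
        cols.append((classes == "AA").to_numpy(dtype=float))
        names.append("AA")
    if n_da:
        cols.append((classes == "DA").to_numpy(dtype=float))
        names.append("DA")
    X = np.column_stack([X_base] + cols)
    Y = sub.data.to_numpy(dtype=float).T
    fit = ols_tstats(X, Y)
    out = pd.DataFrame(index=table.data.index)
    for offset, name in enumerate(names):
        out[f"{name.lower()}_vs_ca_beta"] = fit.beta[4 + offset]
        out[f"{name.lower()}_vs_ca_p"] = fit.pval[4 + offset]
    for name in ("aa", "da"):
        if f"{name}_vs_ca_beta" not in out.columns:
            out[f"{name}_vs_ca_beta"] = np.nan
            out[f"{name}_vs_ca_p"] = np.nan
    out["not_estimable"] = not fit.estimable
    aa_sig = (out["aa_vs_ca_p"] < alpha).fillna(False)
    da_sig = (out["da_vs_ca_p"] < alpha).fillna(False)
    label = np.full(len(out), "none", dtype=object)
    label[aa_sig.to_numpy()] = "accelerating"
    label[da_sig.to_numpy()] = "decelerating"
    both = (aa_sig & da_sig).to_numpy()
    aa_p = out["aa_vs_ca_p"].to_numpy()
    da_p = out["da_vs_ca_p"].to_numpy()
    label[both] = np.where(aa_p[both] < da_p[both], "accelerating", "decelerating")
    out["label"] = label
    return out


def modulator_records(
    table: AbundanceTable,
    meta: CohortMetadata,
    delta_age: pd.Series,
    ager_classes: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One merged record per aging protein from both modulator models."""
    delta = delta_age_modulators(table, meta, delta_age, alpha=alpha)
    groups = ager_group_contrasts(table, meta, ager_classes, alpha=alpha)
    merged = delta.drop(columns=["not_estimable"]).join(
        groups.drop(columns=["not_estimable"]), validate="one_to_one"
    )
    return merged
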