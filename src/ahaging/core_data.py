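"""Domain containers and shared preprocessing.

The package works on DIA-style protein quantification exports: a log2
abundance matrix (proteins in rows, samples in columns) with explicit missing
cells, and a per-sample metadata table (age, sex, BMI, cohort group, optional
lens-opacity grade). This module holds the two containers, TSV readers and
writers, left-censoring-aware missing-value imputation, per-protein
standardization, and the group log2 fold change.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "AbundanceTable",
    "CohortMetadata",
    "ImputationConfig",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "impute_missing",
    "zscore_per_protein",
    "log2fc_by_group",
    "MISSING_MARKERS",
]

logger = logging.getLogger(__name__)

#: Cell contents treated as missing when reading an abundance TSV.
MISSING_MARKERS = {"", "NA", "NaN", "nan", "na"}

IMPUTATION_METHODS = ("half_min", "min_prob", "knn", "median")

GROUP_OLDER = "older"
GROUP_YOUNG = "young"


class AbundanceTable:
    """A proteins x samples matrix of log2 abundances with explicit missingness.

    ``data`` is a float DataFrame indexed by unique protein ids with unique
    sample-id columns; missing cells are NaN and every present cell is finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError("abundance values must be finite where present")
        self.data = data.astype(float)
        self.data.index.name = "protein_id"

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def has_missing(self) -> bool:
        return self.n_missing > 0

    def subset_proteins(self, protein_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(protein_ids)
        missing = [p for p in ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"proteins not in table: {missing}")
        return AbundanceTable(self.data.loc[ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return AbundanceTable(self.data[ids])

    def equals(self, other: "AbundanceTable") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceTable({len(self.protein_ids)} proteins x "
            f"{len(self.sample_ids)} samples, {self.n_missing} missing)"
        )


class CohortMetadata:
    """Per-sample covariates: age (years), sex {0,1}, BMI, group, opacity grade.

    Indexed by unique sample id. ``group`` uses the levels ``older``/``young``;
    ``opacity_grade`` is an optional ordinal column (LOCS III-style) and may be
    missing for ungraded samples, as may ``bmi``.
    """

    REQUIRED = ("age", "sex", "bmi", "group")

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {missing_cols}")
        df = df.copy()
        df.index.name = "sample_id"
        df["age"] = df["age"].astype(float)
        df["sex"] = df["sex"].astype(int)
        df["bmi"] = df["bmi"].astype(float)
        if "opacity_grade" not in df.columns:
            df["opacity_grade"] = np.nan
        df["opacity_grade"] = df["opacity_grade"].astype(float)
        if (df["age"] <= 0).any():
            raise ValidationError("ages must be positive")
        if not set(df["sex"].unique()) <= {0, 1}:
            raise ValidationError("sex must be coded {0, 1}")
        bad = set(df["group"].unique()) - {GROUP_OLDER, GROUP_YOUNG}
        if bad:
            raise ValidationError(f"unknown group levels: {sorted(bad)}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def age(self) -> pd.Series:
        return self.df["age"]

    @property
    def sex(self) -> pd.Series:
        return self.df["sex"]

    @property
    def bmi(self) -> pd.Series:
        return self.df["bmi"]

    @property
    def group(self) -> pd.Series:
        return self.df["group"]

    @property
    def opacity_grade(self) -> pd.Series:
        return self.df["opacity_grade"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.df.index[self.df["group"] == group])

    def check_matches(self, table: AbundanceTable) -> None:
        """Every sample in the table must appear exactly once in the metadata."""
        missing = [s for s in table.sample_ids if s not in self.df.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")

    def subset(self, sample_ids: Iterable[str]) -> "CohortMetadata":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.df.index]
        if missing:
            raise ValidationError(f"samples not in metadata: {missing}")
        return CohortMetadata(self.df.loc[ids])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = self.df["group"].value_counts().to_dict()
        return f"CohortMetadata({len(self.df)} samples, groups={counts})"


@dataclass(frozen=True)
class ImputationConfig:
    """How to fill missing abundance cells.

    method
        ``half_min`` (half the protein's observed minimum), ``min_prob``
        (draws from a Gaussian centred at the protein's low quantile,
        emulating left-censored DIA missingness -- the default), ``knn``
        (average of the k nearest samples by Euclidean distance over
        co-observed proteins), or ``median`` (protein's observed median).
    q
        quantile used as the ``min_prob`` centre.
    k
        neighbour count for ``knn``.
    seed
        seed for the stochastic ``min_prob`` draw.
    max_missing_frac
        proteins missing more than this fraction of samples are dropped
        (and logged) before imputation.
    """

    method: str = "min_prob"
    q: float = 0.01
    k: int = 5
    seed: int = 0
    max_missing_frac: float = 0.5

    def __post_init__(self):
        if self.method not in IMPUTATION_METHODS:
            raise ConfigurationError(
                f"unknown imputation method {self.method!r}; choose from {IMPUTATION_METHODS}"
            )
        if not 0 < self.q < 0.5:
            raise ConfigurationError("q must lie in (0, 0.5)")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if not 0 < self.max_missing_frac <= 1:
            raise ConfigurationError("max_missing_frac must lie in (0, 1]")


def read_abundance_table(path, raw_intensity: bool = False) -> AbundanceTable:
    """Read a proteins-in-rows abundance TSV.

    First column holds protein ids, header row holds sample ids; empty cells
    and ``NA``/``NaN`` denote missing. With ``raw_intensity`` the values are
    treated as linear-scale intensities and transformed as log2(x + 1).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    parsed = raw.copy()
    for col in raw.columns:
        stripped = raw[col].str.strip()
        is_missing = stripped.isin(MISSING_MARKERS)
        numeric = pd.to_numeric(stripped.where(~is_missing), errors="coerce")
        bad = numeric.isna() & ~is_missing
        if bad.any():
            protein = raw.index[bad.to_numpy()][0]
            value = stripped[bad].iloc[0]
            raise ParseError(
                f"{path.name}: non-numeric value {value!r} for protein {protein!r}, sample {col!r}"
            )
        parsed[col] = numeric
    table = AbundanceTable(parsed)
    if raw_intensity:
        if (table.data < 0).any().any():
            raise ValidationError("raw intensities must be non-negative")
        table = AbundanceTable(np.log2(table.data + 1.0))
    return table


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write an abundance TSV; missing cells become ``NA``."""
    table.data.to_csv(path, sep="\t", na_rep="NA")


def read_metadata(path) -> CohortMetadata:
    """Read the sample metadata TSV (columns sample_id, age, sex, bmi, group,
    optional opacity_grade)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path) -> None:
    meta.df.to_csv(path, sep="\t", na_rep="NA")


def _knn_impute(values: np.ndarray, k: int) -> np.ndarray:
    """Fill NaNs in a proteins x samples matrix by averaging the k nearest
    samples (Euclidean over co-observed proteins) that observe the protein."""
    n_prot, n_samp = values.shape
    out = values.copy()
    observed = ~np.isnan(values)
    # Pairwise sample distances over shared proteins, scaled to per-protein units.
    dist = np.full((n_samp, n_samp), np.inf)
    for a in range(n_samp):
        for b in range(a + 1, n_samp):
            shared = observed[:, a] & observed[:, b]
            if shared.any():
                diff = values[shared, a] - values[shared, b]
                dist[a, b] = dist[b, a] = float(np.sqrt(np.mean(diff**2)))
    for i in range(n_prot):
        for j in np.where(~observed[i])[0]:
            donors = np.where(observed[i])[0]
            order = donors[np.argsort(dist[j, donors], kind="stable")]
            chosen = order[:k]
            out[i, j] = float(np.mean(values[i, chosen]))
    return out


def impute_missing(table: AbundanceTable, cfg: ImputationConfig | None = None) -> AbundanceTable:
    """Fill every missing cell; observed cells are never altered.

    Proteins missing in more than ``cfg.max_missing_frac`` of samples are
    dropped first (logged). A protein with zero observed values is an error.
    """
    cfg = cfg or ImputationConfig()
    data = table.data
    observed_counts = data.notna().sum(axis=1)
    all_missing = list(data.index[observed_counts == 0])
    if all_missing:
        raise ValidationError(f"proteins with zero observed values: {all_missing}")
    frac_missing = data.isna().mean(axis=1)
    dropped = list(data.index[frac_missing > cfg.max_missing_frac])
    if dropped:
        logger.warning(
            "dropping %d proteins with >%.0f%% missing: %s",
            len(dropped), 100 * cfg.max_missing_frac, dropped,
        )
        data = data.drop(index=dropped)
    if not data.isna().to_numpy().any():
        return AbundanceTable(data)

    values = data.to_numpy(dtype=float)
    missing = np.isnan(values)
    if cfg.method == "half_min":
        fill = np.nanmin(values, axis=1) / 2.0
        out = np.where(missing, fill[:, None], values)
    elif cfg.method == "median":
        fill = np.nanmedian(values, axis=1)
        out = np.where(missing, fill[:, None], values)
    elif cfg.method == "min_prob":
        rng = np.random.default_rng(cfg.seed)
        centre = np.nanquantile(values, cfg.q, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spread = 0.3 * np.nanstd(values, axis=1, ddof=0)
        spread = np.where(np.isfinite(spread) & (spread > 0), spread, 0.1)
        draws = centre[:, None] + spread[:, None] * rng.standard_normal(values.shape)
        out = np.where(missing, draws, values)
    else:  # knn
        out = _knn_impute(values, cfg.k)
    return AbundanceTable(pd.DataFrame(out, index=data.index, columns=data.columns))


def zscore_per_protein(table: AbundanceTable) -> AbundanceTable:
    """Standardize each protein to mean 0, sample SD 1 (denominator n-1).

    Requires a complete table with >= 2 samples; zero-variance proteins are
    dropped with a warning.
    """
    if len(table.sample_ids) < 2:
        raise ValidationError("z-scoring needs at least 2 samples")
    if table.has_missing():
        raise ValidationError("z-scoring requires an imputed (complete) table")
    values = table.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(table.data.index[constant])
        warnings.warn(f"dropping zero-variance proteins: {dropped}", stacklevel=2)
        values = values[~constant]
        index = table.data.index[~constant]
        sd = sd[~constant]
    else:
        index = table.data.index
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return AbundanceTable(pd.DataFrame(z, index=index, columns=table.data.columns))


def log2fc_by_group(table: AbundanceTable, meta: CohortMetadata) -> pd.Series:
    """Per-protein log2 fold change: mean(older) - mean(young) on the log2 scale."""
    meta.check_matches(table)
    older = [s for s in table.sample_ids if meta.group.get(s) == GROUP_OLDER]
    young = [s for s in table.sample_ids if meta.group.get(s) == GROUP_YOUNG]
    if not older or not young:
        raise ValidationError("both 'older' and 'young' groups need at least one sample")
    fc = table.data[older].mean(axis=1) - table.data[young].mean(axis=1)
    fc.name = "log2fc"
    return fc
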