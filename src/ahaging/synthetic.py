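"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
two-group cohort (older cataract-age donors vs young donors), log2-scale
protein abundances with Gaussian noise, planted age trajectories drawn from a
small library of archetype curves, sex and BMI covariate effects, a latent
per-subject biological-age offset delta driving "clock" proteins, and mixed
left-censored + completely-at-random missingness.

Trend proteins respond to chronological age; clock proteins respond to
biological age b_j = age_j + delta_j, which is what makes the Δage framework
identifiable and modulator recovery a meaningful test.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import AbundanceTable, CohortMetadata, GROUP_OLDER, GROUP_YOUNG
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ARCHETYPES",
    "MONOTONE_ARCHETYPES",
    "UP_ARCHETYPES",
    "CohortSimConfig",
    "GroundTruth",
    "archetype_curve",
    "generate_cohort",
]

#: The seven trajectory shapes the clustering stage is expected to resolve.
ARCHETYPES = (
    "linear_up",
    "linear_down",
    "plateau_up",
    "plateau_down",
    "late_rise",
    "late_fall",
    "nonmonotone",
)

#: Shapes with a defined direction of change across the age span.
MONOTONE_ARCHETYPES = ARCHETYPES[:6]

UP_ARCHETYPES = frozenset({"linear_up", "plateau_up", "late_rise"})

# Latent biological-age offset thresholds used for the planted ager classes,
# matching the default clock thresholds (DA <= -5, AA >= +5, CA |d| < 2).
_DA_THRESHOLD = -5.0
_AA_THRESHOLD = 5.0
_CA_BAND = 2.0


def _logistic_norm(t: np.ndarray, mid: float, scale: float) -> np.ndarray:
    """Logistic in normalized age t, rescaled so t=0 maps to 0 and t=1 to 1."""
    raw = 1.0 / (1.0 + np.exp(-(t - mid) / scale))
    r0 = 1.0 / (1.0 + np.exp(mid / scale))
    r1 = 1.0 / (1.0 + np.exp(-(1.0 - mid) / scale))
    return (raw - r0) / (r1 - r0)


def _curve_normalized(shape: str, t: np.ndarray) -> np.ndarray:
    """Archetype curve as a function of normalized age t = (age-lo)/(hi-lo).

    Valid for any real t (used with extrapolated biological ages); on [0, 1]
    the monotone shapes run from 0 to 1 (or 1 to 0) and the nonmonotone bump
    peaks at t = 0.5.
    """
    t = np.asarray(t, dtype=float)
    if shape == "linear_up":
        return t
    if shape == "linear_down":
        return 1.0 - t
    if shape == "plateau_up":
        return _logistic_norm(t, mid=0.3, scale=0.1)
    if shape == "plateau_down":
        return 1.0 - _logistic_norm(t, mid=0.3, scale=0.1)
    if shape == "late_rise":
        return _logistic_norm(t, mid=0.7, scale=0.1)
    if shape == "late_fall":
        return 1.0 - _logistic_norm(t, mid=0.7, scale=0.1)
    if shape == "nonmonotone":
        g = np.exp(-((t - 0.5) ** 2) / (2 * 0.18**2))
        g0 = np.exp(-0.25 / (2 * 0.18**2))
        return (g - g0) / (1.0 - g0)
    raise ConfigurationError(f"unknown archetype shape {shape!r}")


def archetype_curve(shape: str, age, age_span: tuple[float, float]):
    """Evaluate an archetype curve at ``age`` within ``age_span``.

    Returns values in [0, 1]; ``linear_up`` maps the span start to 0 and the
    span end to 1, ``linear_down`` is its mirror, plateau/late shapes are
    logistic with early/late midpoints, and ``nonmonotone`` is a centred bump.
    """
    lo, hi = age_span
    if hi <= lo:
        raise ConfigurationError("age_span must be an increasing interval")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < lo - 1e-9) or np.any(age_arr > hi + 1e-9):
        raise ValidationError(f"age outside span [{lo}, {hi}]")
    t = (age_arr - lo) / (hi - lo)
    out = _curve_normalized(shape, t)
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the cohort the analysis targets: 33 older (50-91 y) and
    19 young (19-35 y) donors, 634 proteins, log2-scale noise. 179 proteins
    carry true age signal (168 trend + 11 clock), echoing the aging-protein
    and signature counts the method is designed to resolve; effect sizes and
    rates are simulation defaults chosen for realism, not estimates.
    """

    n_young: int = 19
    n_old: int = 33
    age_range_young: tuple[float, float] = (19.0, 35.0)
    age_range_old: tuple[float, float] = (50.0, 91.0)
    n_proteins: int = 634
    n_trend_proteins: int = 168
    n_clock_proteins: int = 11
    trend_effect: float = 1.5
    sigma_noise: float = 0.5
    sigma_delta: float = 6.0
    sex_effect: float = 0.25
    bmi_effect: float = 0.02
    missing_rate_mcar: float = 0.05
    censor_quantile: float = 0.05
    archetypes: Sequence[str] = MONOTONE_ARCHETYPES
    baseline_mean: float = 16.0
    baseline_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_young, self.n_old, self.n_proteins,
               self.n_trend_proteins, self.n_clock_proteins) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.n_trend_proteins + self.n_clock_proteins > self.n_proteins:
            raise ConfigurationError("trend + clock proteins exceed n_proteins")
        if min(self.sigma_noise, self.sigma_delta) < 0:
            raise ConfigurationError("sigma values must be >= 0")
        for rate in (self.missing_rate_mcar, self.censor_quantile):
            if not 0 <= rate < 1:
                raise ConfigurationError("rates must lie in [0, 1)")
        for r in (self.age_range_young, self.age_range_old):
            if r[1] <= r[0] or r[0] <= 0:
                raise ConfigurationError("age ranges must be increasing and positive")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")

    @property
    def age_span(self) -> tuple[float, float]:
        return (self.age_range_young[0], self.age_range_old[1])


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    trend_slopes / clock_loadings map protein id to the signed total log2
    change over the age span (0 for the directionless nonmonotone bump);
    archetype_labels covers every planted protein; delta is the latent
    per-subject biological-age offset in years; true_ager_class derives from
    delta with the +/-5 / 2 year thresholds.
    """

    trend_slopes: dict[str, float]
    clock_loadings: dict[str, float]
    archetype_labels: dict[str, str]
    delta: pd.Series
    true_ager_class: pd.Series
    age_span: tuple[float, float]

    @property
    def trend_proteins(self) -> list[str]:
        return list(self.trend_slopes)

    @property
    def clock_proteins(self) -> list[str]:
        return list(self.clock_loadings)

    def slope_per_year(self, protein_id: str) -> float:
        """Planted linear slope in log2 units per year (linear archetypes)."""
        total = self.trend_slopes.get(protein_id, self.clock_loadings.get(protein_id))
        if total is None:
            raise ValidationError(f"{protein_id!r} is not a planted protein")
        lo, hi = self.age_span
        return total / (hi - lo)

    def to_json(self, path) -> None:
        payload = {
            "trend_slopes": self.trend_slopes,
            "clock_loadings": self.clock_loadings,
            "archetype_labels": self.archetype_labels,
            "delta": {k: float(v) for k, v in self.delta.items()},
            "true_ager_class": dict(self.true_ager_class),
            "age_span": list(self.age_span),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            trend_slopes=payload["trend_slopes"],
            clock_loadings=payload["clock_loadings"],
            archetype_labels=payload["archetype_labels"],
            delta=pd.Series(payload["delta"]),
            true_ager_class=pd.Series(payload["true_ager_class"]),
            age_span=tuple(payload["age_span"]),
        )


def _ager_class_from_delta(delta: np.ndarray) -> np.ndarray:
    out = np.full(delta.shape, "unclassified", dtype=object)
    out[np.abs(delta) < _CA_BAND] = "CA"
    out[delta <= _DA_THRESHOLD] = "DA"
    out[delta >= _AA_THRESHOLD] = "AA"
    return out


def generate_cohort(cfg: CohortSimConfig) -> tuple[AbundanceTable, CohortMetadata, GroundTruth]:
    """Simulate an abundance table, metadata, and ground truth from ``cfg``.

    Cell model: x_ij = baseline_i + f_i(a_j) + sex_effect*sex_j
    + bmi_effect*(bmi_j - mean bmi) + N(0, sigma_noise^2), where f_i is the
    protein's archetype curve scaled to ``trend_effect`` and a_j is
    chronological age for trend proteins or biological age for clock
    proteins. Left-censoring (per-protein low quantile) is applied before
    MCAR missingness so the two mechanisms stay separable. Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_young + cfg.n_old
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    groups = np.array([GROUP_OLDER] * cfg.n_old + [GROUP_YOUNG] * cfg.n_young)
    ages = np.concatenate([
        rng.uniform(*cfg.age_range_old, size=cfg.n_old),
        rng.uniform(*cfg.age_range_young, size=cfg.n_young),
    ])
    sex = rng.integers(0, 2, size=n)
    bmi = rng.normal(24.0, 3.0, size=n)
    while True:  # truncate BMI to a plausible clinical range
        out_of_range = (bmi < 15.0) | (bmi > 40.0)
        if not out_of_range.any():
            break
        bmi[out_of_range] = rng.normal(24.0, 3.0, size=int(out_of_range.sum()))
    delta = rng.normal(0.0, cfg.sigma_delta, size=n) if cfg.sigma_delta > 0 else np.zeros(n)
    bio_age = ages + delta

    lo, hi = cfg.age_span
    span_len = hi - lo
    protein_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    trend_ids = protein_ids[: cfg.n_trend_proteins]
    clock_ids = protein_ids[cfg.n_trend_proteins: cfg.n_trend_proteins + cfg.n_clock_proteins]

    shapes = list(cfg.archetypes) or ["linear_up"]
    archetype_labels: dict[str, str] = {}
    trend_slopes: dict[str, float] = {}
    clock_loadings: dict[str, float] = {}

    signal = np.zeros((cfg.n_proteins, n))
    t_chron = (ages - lo) / span_len
    t_bio = (bio_age - lo) / span_len
    for idx, pid in enumerate(trend_ids):
        shape = shapes[idx % len(shapes)]
        archetype_labels[pid] = shape
        signal[idx] = cfg.trend_effect * _curve_normalized(shape, t_chron)
        sign = 0.0 if shape == "nonmonotone" else (1.0 if shape in UP_ARCHETYPES else -1.0)
        trend_slopes[pid] = sign * cfg.trend_effect
    for j, pid in enumerate(clock_ids):
        idx = cfg.n_trend_proteins + j
        shape = shapes[j % len(shapes)]
        archetype_labels[pid] = shape
        signal[idx] = cfg.trend_effect * _curve_normalized(shape, t_bio)
        sign = 0.0 if shape == "nonmonotone" else (1.0 if shape in UP_ARCHETYPES else -1.0)
        clock_loadings[pid] = sign * cfg.trend_effect

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    noise = rng.normal(0.0, cfg.sigma_noise, size=(cfg.n_proteins, n))
    values = (
        baseline[:, None]
        + signal
        + cfg.sex_effect * sex[None, :]
        + cfg.bmi_effect * (bmi - bmi.mean())[None, :]
        + noise
    )

    # Left-censoring first, then MCAR, so the mechanisms are separable.
    missing = np.zeros_like(values, dtype=bool)
    if cfg.censor_quantile > 0:
        thresholds = np.quantile(values, cfg.censor_quantile, axis=1)
        missing |= values < thresholds[:, None]
    if cfg.missing_rate_mcar > 0:
        missing |= rng.random(values.shape) < cfg.missing_rate_mcar
    observed = values.copy()
    observed[missing] = np.nan
    # Never censor a protein completely: keep its largest cell observed.
    empty_rows = np.where(np.isnan(observed).all(axis=1))[0]
    for row in empty_rows:
        observed[row, int(np.argmax(values[row]))] = values[row].max()

    table = AbundanceTable(pd.DataFrame(observed, index=protein_ids, columns=sample_ids))

    grade = np.full(n, np.nan)
    older_mask = groups == GROUP_OLDER
    if older_mask.any():
        o_lo, o_hi = cfg.age_range_old
        raw = 1.0 + 4.0 * (ages[older_mask] - o_lo) / (o_hi - o_lo)
        raw = raw + rng.normal(0.0, 0.5, size=int(older_mask.sum()))
        grade[older_mask] = np.clip(np.round(raw), 1, 5)
    meta = CohortMetadata(pd.DataFrame(
        {"age": ages, "sex": sex, "bmi": bmi, "group": groups, "opacity_grade": grade},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    truth = GroundTruth(
        trend_slopes=trend_slopes,
        clock_loadings=clock_loadings,
        archetype_labels=archetype_labels,
        delta=pd.Series(delta, index=sample_ids, name="delta"),
        true_ager_class=pd.Series(_ager_class_from_delta(delta), index=sample_ids,
                                  name="true_ager_class"),
        age_span=(lo, hi),
    )
    return table, meta, truth
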