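"""Synthetic case-control cohorts for pulmonary-embolism risk work.

The study cohort behind this package (139 patients split into an
intermediate-low-risk group of 70 and a high-risk group of 69, with 11
binary clinical characteristics and 12 continuous blood/gas/vital
measurements) is single-centre hospital data and is not publicly
deposited. This module generates synthetic stand-ins whose per-group
marginal distributions match the published group summaries: binary
features as independent Bernoulli draws with the per-group yes-rates,
continuous features as per-group normals clipped at physiological
floors (and 100% / 1.0 ceilings for saturation and neutrophil
fraction). Features are independent within group — the published
summaries carry no covariance information — which is the generator's
main departure from real cohorts.

``planted_signal_cohort`` builds a recovery-testing fixture: a cohort
in which a known subset of continuous features differ between groups by
a chosen standardized effect size, the rest being pure noise, together
with the ground-truth informative mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "default_pe_spec",
    "generate_cohort",
    "planted_signal_cohort",
    "FEATURE_ORDER",
]

#: Column order of the cohort table (the study's F1-F23 numbering).
FEATURE_ORDER = [
    "Age", "Gender", "Dyspnea", "CP", "Hemoptysis", "Syncope", "CPR", "AMS",
    "CHF", "CLD", "HOT", "SBP", "DBP", "PR", "T", "RR", "WBC", "NEUT%",
    "HGB", "PLT", "PH", "SaO2%", "RHD",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's per-group marginal distribution.

    Binary features carry per-group yes-probabilities; continuous
    features carry per-group (mean, sd) with optional floor/ceiling
    clipping for physiological validity.
    """

    name: str
    kind: str  # 'binary' | 'continuous'
    p_low: float = 0.0
    p_high: float = 0.0
    mean_low: float = 0.0
    sd_low: float = 0.0
    mean_high: float = 0.0
    sd_high: float = 0.0
    floor: float | None = None
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError("kind must be 'binary' or 'continuous'")
        if self.kind == "binary" and not (
            0 <= self.p_low <= 1 and 0 <= self.p_high <= 1
        ):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.kind == "continuous" and (self.sd_low < 0 or self.sd_high < 0):
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes plus the feature list."""

    n_low: int = 70
    n_high: int = 69
    features: tuple[FeatureSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("group sizes must be >= 1")


def _binary(name, yes_low, yes_high, n_low=70, n_high=69) -> FeatureSpec:
    return FeatureSpec(name, "binary", p_low=yes_low / n_low, p_high=yes_high / n_high)


def _cont(name, mean_low, sd_low, mean_high, sd_high, floor=0.0, ceiling=None):
    return FeatureSpec(
        name, "continuous", mean_low=mean_low, sd_low=sd_low,
        mean_high=mean_high, sd_high=sd_high, floor=floor, ceiling=ceiling,
    )


def default_pe_spec() -> CohortSpec:
    """Cohort spec matching the published two-group PE summaries.

    Binary yes-counts and continuous mean ± SD are per group (low-risk
    n = 70, high-risk n = 69); Gender is coded male = 1. The high-risk
    SBP mean sits below the 90 mmHg threshold that defines the group.
    """
    features = (
        _cont("Age", 65.30, 13.380, 64.65, 11.732),
        _binary("Gender", 40, 30),           # male = 1: 40/70 vs 30/69
        _binary("Dyspnea", 40, 43),
        _binary("CP", 13, 8),
        _binary("Hemoptysis", 4, 2),
        _binary("Syncope", 3, 20),
        _binary("CPR", 0, 8),
        _binary("AMS", 4, 14),
        _binary("CHF", 13, 14),
        _binary("CLD", 14, 8),
        _binary("HOT", 11, 22),
        _cont("SBP", 119.00, 21.404, 86.90, 8.168),
        _cont("DBP", 70.64, 12.059, 54.51, 9.646),
        _cont("PR", 89.49, 14.589, 92.13, 25.532),
        _cont("T", 37.16, 0.578, 37.20, 1.291),
        _cont("RR", 20.11, 2.579, 21.09, 5.412),
        _cont("WBC", 8.40, 4.866, 10.36, 6.128),
        _cont("NEUT%", 0.67, 0.135, 0.73, 0.142, ceiling=1.0),
        _cont("HGB", 124.63, 20.391, 112.13, 25.903),
        _cont("PLT", 232.67, 137.808, 216.57, 115.283),
        _cont("PH", 7.42, 0.039, 7.41, 0.081),
        _cont("SaO2%", 95.52, 3.068, 92.69, 11.078, ceiling=100.0),
        _binary("RHD", 13, 18),
    )
    assert [f.name for f in features] == FEATURE_ORDER
    return CohortSpec(n_low=70, n_high=69, features=features)


def generate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Sample a cohort table from a spec; deterministic per seed.

    Returns a DataFrame with one column per feature plus a
    ``risk_group`` label column ('low' / 'high'), exact group sizes and
    no missing values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0F0]))
    columns: dict[str, np.ndarray] = {}
    for f in spec.features:
        if f.kind == "binary":
            low = (rng.random(spec.n_low) < f.p_low).astype(int)
            high = (rng.random(spec.n_high) < f.p_high).astype(int)
            columns[f.name] = np.concatenate([low, high])
        else:
            low = rng.normal(f.mean_low, f.sd_low, size=spec.n_low)
            high = rng.normal(f.mean_high, f.sd_high, size=spec.n_high)
            vals = np.concatenate([low, high])
            if f.floor is not None:
                vals = np.maximum(vals, f.floor)
            if f.ceiling is not None:
                vals = np.minimum(vals, f.ceiling)
            columns[f.name] = vals
    df = pd.DataFrame(columns)
    df["risk_group"] = ["low"] * spec.n_low + ["high"] * spec.n_high
    return df


def planted_signal_cohort(
    n_per_group: int = 70,
    n_informative: int = 5,
    n_noise: int = 18,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cohort with a known informative feature subset.

    Informative continuous features are N(0, 1) in the low group and
    N(effect_size, 1) in the high group; noise features are N(0, 1) in
    both. Returns the table (informative columns first) and the
    boolean ground-truth mask.
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51C4A1]))
    n_total = n_informative + n_noise
    low = rng.normal(0.0, 1.0, size=(n_per_group, n_total))
    high = rng.normal(0.0, 1.0, size=(n_per_group, n_total))
    high[:, :n_informative] += effect_size
    data = np.vstack([low, high])
    names = [f"signal{i+1}" for i in range(n_informative)] + [
        f"noise{i+1}" for i in range(n_noise)
    ]
    df = pd.DataFrame(data, columns=names)
    df["risk_group"] = ["low"] * n_per_group + ["high"] * n_per_group
    mask = np.zeros(n_total, dtype=bool)
    mask[:n_informative] = True
    return df, mask
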