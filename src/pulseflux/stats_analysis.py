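"""Nonparametric discrimination and correlation ranking of features.

Stiffness classes are compared pairwise with the Kruskal--Wallis rank test
(tie-corrected H against a chi-square with k-1 degrees of freedom; for the
PPG features the per-window values of the three wavelengths are pooled so a
single p-value is reported per feature and pair).  Features are ranked by
the Pearson correlation of their per-window values against the vessel's
Young's modulus (0.82 / 1.48 / 2.06 MPa), retaining correlations
significant at the chosen alpha and ordering by |r| descending.

No multiple-testing correction is applied by default (raw p-values against
alpha = 0.05); Holm adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_io import PHANTOM_CLASSES
from .ppg_features import PPG_FEATURE_NAMES

__all__ = [
    "KWResult",
    "CorrResult",
    "CLASS_PAIRS",
    "kruskal_wallis",
    "pairwise_kw",
    "pearson",
    "rank_features",
    "holm_adjust",
]

#: Pairwise comparisons in reporting order.
CLASS_PAIRS = (
    ("healthy", "intermediate"),
    ("intermediate", "unhealthy"),
    ("healthy", "unhealthy"),
)


@dataclass(frozen=True)
class KWResult:
    feature: str
    group_a: str
    group_b: str
    H: float
    p: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.H < 0 or not (0.0 <= self.p <= 1.0):
            raise ValueError(f"invalid test outcome H={self.H}, p={self.p}")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("group sizes must be >= 1")


@dataclass(frozen=True)
class CorrResult:
    feature: str
    wavelength_nm: int | None
    bmf: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12) or not (0.0 <= self.p <= 1.0):
            raise ValueError(f"invalid correlation r={self.r}, p={self.p}")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal--Wallis H and chi-square p for >= 2 groups.

    All-identical pooled values are a degenerate but legal input and return
    ``(0.0, 1.0)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must be nonempty")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValueError("kruskal_wallis requires total n >= 3")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sstats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_kw(
    table: pd.DataFrame,
    feature: str,
    bmf: str,
    pool_wavelengths: bool = True,
) -> list[KWResult]:
    """The three pairwise class comparisons for one feature and BMF regime.

    For PPG features the per-window values are pooled across the three
    wavelengths (72 values per class at defaults); LDF flux tables carry no
    wavelength column and use the per-window values directly (24 per class).
    """
    sub = table[table["bmf"] == bmf]
    present = set(sub["phantom_class"].unique())
    missing = [c for c in PHANTOM_CLASSES if c not in present]
    if missing:
        raise ValueError(f"feature table is missing phantom class(es): {missing}")
    if not pool_wavelengths and "wavelength_nm" in sub.columns:
        raise ValueError("per-wavelength pairwise tests are not part of this analysis")
    values = {
        cls: sub.loc[sub["phantom_class"] == cls, feature].dropna().to_numpy()
        for cls in PHANTOM_CLASSES
    }
    results = []
    for a, b in CLASS_PAIRS:
        h, p = kruskal_wallis([values[a], values[b]])
        results.append(
            KWResult(
                feature=feature,
                group_a=a,
                group_b=b,
                H=h,
                p=p,
                n_a=len(values[a]),
                n_b=len(values[b]),
            )
        )
    return results


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"pearson requires n >= 3, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson requires nonzero variance in both variables")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def rank_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank features by |Pearson r| against Young's modulus, per wavelength and BMF.

    The elasticity covariate is the recording's Young's modulus repeated per
    window.  Correlations with p >= alpha are dropped; remaining rows are
    ordered by |r| descending with ties broken by feature name.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if "young_modulus_mpa" not in table.columns:
        raise ValueError("table must carry a young_modulus_mpa column")
    if features is None:
        features = [f for f in PPG_FEATURE_NAMES if f in table.columns]
        if "dc_mean_flux" in table.columns:
            features = list(features) + ["dc_mean_flux"]
    group_cols = ["bmf"]
    if "wavelength_nm" in table.columns:
        group_cols.append("wavelength_nm")
    rows = []
    for keys, group in table.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        info = dict(zip(group_cols, keys))
        for feature in features:
            values = group[feature].dropna()
            r, p = pearson(
                group.loc[values.index, "young_modulus_mpa"].to_numpy(),
                values.to_numpy(),
            )
            rows.append(
                {
                    "feature": feature,
                    "wavelength_nm": info.get("wavelength_nm"),
                    "bmf": info["bmf"],
                    "r": r,
                    "p": p,
                    "n": len(values),
                }
            )
    frame = pd.DataFrame(rows)
    frame = frame[frame["p"] < alpha]
    frame = frame.sort_values(
        by=["r", "feature"], key=lambda s: -s.abs() if s.name == "r" else s
    ).reset_index(drop=True)
    return frame
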