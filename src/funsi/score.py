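"""Centsum and FunSI: the composite centile-based stretch score.

An eye's decimal centile position per feature (from the centile charts)
is combined into a single index.  Features whose worst centile is the
95th enter as Cent; features whose worst centile is the 5th enter as
1 - Cent, so every term points the same way: larger means a fundus that
looks more myopic than expected for its SER.

    Centsum = sum of directed centile terms over the k features
    FunSI   = (Centsum - 0.05 k) / (0.9 k)

With the full 10-feature registry this is (Centsum - 0.5) / 9, a
min-max normalisation to [0, 1]: 0.5 is an average-looking fundus,
1 an eye ranked in the worst centile on every feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .charts import ChartSet
from .features import REGISTRY, FeatureSpec

__all__ = [
    "FunSIResult",
    "centsum",
    "funsi",
    "leave_one_feature_out",
    "score_eyes",
    "standardize",
    "quantile_groups",
]


@dataclass(frozen=True)
class FunSIResult:
    """FunSI for one eye (or one person after eye selection)."""

    person_id: object
    centsum: float
    funsi: float
    n_features: int
    omitted_feature: str | None = None


def _directed_terms(
    cents: Mapping[str, float], registry: Iterable[FeatureSpec]
) -> list[float]:
    terms = []
    for spec in registry:
        if spec.name not in cents:
            raise KeyError(f"centile profile is missing feature {spec.name!r}")
        c = float(cents[spec.name])
        terms.append(c if spec.worst_centile == 0.95 else 1.0 - c)
    return terms


def centsum(
    cents: Mapping[str, float], registry: Iterable[FeatureSpec] = REGISTRY
) -> float:
    """Sum of direction-aware centile terms (Cent or 1 - Cent)."""
    return float(sum(_directed_terms(cents, registry)))


def funsi(
    cents: Mapping[str, float],
    registry: Iterable[FeatureSpec] = REGISTRY,
    *,
    person_id: object = None,
    omitted_feature: str | None = None,
) -> FunSIResult:
    """Min-max normalised Centsum over the registry (subset) in use.

    Each directed term lies in [0.05, 0.95], so for k features Centsum
    spans [0.05 k, 0.95 k] and FunSI = (Centsum - 0.05 k) / (0.9 k)
    spans [0, 1]; at k = 10 this is exactly (Centsum - 0.5) / 9.
    """
    registry = tuple(registry)
    k = len(registry)
    cs = centsum(cents, registry)
    value = (cs - 0.05 * k) / (0.9 * k)
    return FunSIResult(
        person_id=person_id,
        centsum=cs,
        funsi=value,
        n_features=k,
        omitted_feature=omitted_feature,
    )


def leave_one_feature_out(
    cents: Mapping[str, float],
    registry: Iterable[FeatureSpec] = REGISTRY,
    *,
    person_id: object = None,
) -> dict[str, FunSIResult]:
    """FunSI recomputed with each feature omitted in turn.

    Each of the k results uses the remaining k - 1 features with the
    renormalised min-max form, so every value stays in [0, 1] and 0.5
    keeps its average-fundus interpretation.
    """
    registry = tuple(registry)
    out = {}
    for omitted in registry:
        sub = tuple(s for s in registry if s.name != omitted.name)
        out[omitted.name] = funsi(
            cents, sub, person_id=person_id, omitted_feature=omitted.name
        )
    return out


def score_eyes(
    charts: ChartSet,
    records: pd.DataFrame,
    registry: Iterable[FeatureSpec] = REGISTRY,
    *,
    loo: bool = False,
) -> pd.DataFrame:
    """Score a one-record-per-person eye table against a chart set.

    Returns a DataFrame with ``person_id``, ``ser``, one ``cent_<feature>``
    column per feature, ``centsum`` and ``funsi``; with ``loo=True`` ten
    additional ``funsi_wo_<feature>`` columns are appended.
    """
    registry = tuple(registry)
    ser = records["ser"].to_numpy(dtype=float)
    out = pd.DataFrame({"person_id": records["person_id"].to_numpy(), "ser": ser})

    # Vectorised nearest-curve lookup: evaluate each chart's 19 curves at
    # every eye's SER in one design-matrix product.  np.argmin takes the
    # first minimiser, which is the stated lower-tau tie-break.
    cent_cols = {}
    for spec in registry:
        chart = charts[spec.name]
        curves = chart.evaluate_grid(ser)  # (n, 19)
        values = records[spec.name].to_numpy(dtype=float)[:, None]
        idx = np.argmin(np.abs(curves - values), axis=1)
        cent_cols[spec.name] = chart.taus[idx]
        out[f"cent_{spec.name}"] = cent_cols[spec.name]

    directed = np.column_stack(
        [
            cent_cols[s.name] if s.worst_centile == 0.95 else 1.0 - cent_cols[s.name]
            for s in registry
        ]
    )
    k = len(registry)
    cs = directed.sum(axis=1)
    out["centsum"] = cs
    out["funsi"] = (cs - 0.05 * k) / (0.9 * k)
    if loo:
        for j, spec in enumerate(registry):
            cs_wo = cs - directed[:, j]
            out[f"funsi_wo_{spec.name}"] = (cs_wo - 0.05 * (k - 1)) / (
                0.9 * (k - 1)
            )
    return out


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardise to zero mean, unit sample SD (n - 1 denominator).

    Returns ``(z, mean, sd)``; the SD is what makes a hazard ratio for
    the standardised score interpretable "per 1 SD".
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to standardize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise ValueError("values have zero variance")
    return (v - mean) / sd, mean, sd


def quantile_groups(values: np.ndarray, g: int = 4) -> np.ndarray:
    """Assign 1..g quantile-group labels (default quartiles).

    Cut points are the empirical quantiles at i/g (linear
    interpolation); a value equal to a cut point joins the group below
    it, so fully tied data all land in group 1.
    """
    v = np.asarray(values, dtype=float)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if v.size < g:
        raise ValueError(f"cannot form {g} groups from {v.size} values")
    cuts = np.quantile(v, np.arange(1, g) / g)
    return 1 + np.searchsorted(cuts, v, side="left")
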