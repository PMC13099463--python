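"""Fundus centile charts: noncrossing quantile curves of a feature vs SER.

A centile chart is the retinal analogue of a pediatric growth chart:
for one imaging feature it holds 19 conditional quantile curves (the
5th to 95th centiles in 5-centile increments) as smooth functions of
spherical equivalent refraction (SER).  Each curve is a penalized cubic
B-spline fitted by minimising the pinball (check) loss, which makes no
assumption about the conditional distribution of the feature given SER.
All 19 curves of a chart are estimated jointly, with an ordering
(noncrossing) constraint enforced on a dense SER grid so that a higher
centile curve never falls below a lower one.

An eye's decimal centile position for a feature is the quantile level
of the curve closest to its observed value at its own SER, which caps
positions at 0.05 and 0.95 automatically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline

from ._quantile_solver import SolverError, pinball_loss, solve_weighted_quantile
from .features import FEATURE_NAMES, SER_RANGE

__all__ = [
    "DEFAULT_TAUS",
    "ChartConfig",
    "CentileChart",
    "ChartSet",
    "ChartFitError",
    "ChartParseError",
    "fit_chart",
    "fit_chart_set",
    "centile_position",
    "save_chart_set",
    "load_chart_set",
]

FORMAT_VERSION = 1

#: 5th to 95th centile in 5-centile increments.
DEFAULT_TAUS: tuple[float, ...] = tuple(np.round(np.arange(1, 20) * 0.05, 2))


class ChartFitError(RuntimeError):
    """Raised when a chart cannot be fitted."""


class ChartParseError(ValueError):
    """Raised when a serialized chart set is malformed."""


@dataclass(frozen=True)
class ChartConfig:
    """Settings for the quantile-curve fitter.

    n_basis : cubic B-spline basis dimension over the SER domain.
    penalty : roughness penalty weight lambda; the objective per curve is
        mean pinball loss + lambda * sum |second differences of the
        spline coefficients|, so lambda = 0 is an unpenalized fit and
        large lambda shrinks each curve toward a straight line.
    grid_size : number of SER grid points at which the noncrossing
        ordering is imposed (and later validated).
    constraint_weight : multiplier on the exact-penalty weight of the
        ordering rows, expressed per observation.
    """

    n_basis: int = 10
    degree: int = 3
    penalty: float = 0.1
    grid_size: int = 201
    domain: tuple[float, float] = SER_RANGE
    constraint_weight: float = 2.0

    def knots(self) -> np.ndarray:
        lo, hi = self.domain
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate(
            [[lo] * (self.degree + 1), interior, [hi] * (self.degree + 1)]
        )


def _design(x: np.ndarray, knots: np.ndarray, degree: int, domain) -> sp.csr_matrix:
    lo, hi = domain
    return BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).tocsr()


@dataclass
class CentileChart:
    """Nineteen noncrossing quantile curves of one feature over SER."""

    feature_name: str
    taus: np.ndarray  # (m,), strictly increasing
    knots: np.ndarray
    degree: int
    coef: np.ndarray  # (m, p): spline coefficients per quantile level
    ser_domain: tuple[float, float]
    fit_meta: dict = field(default_factory=dict)

    def evaluate(self, ser: float) -> np.ndarray:
        """Curve values at one SER, ordered by quantile level.

        SER outside the chart domain is clamped to the nearest boundary
        with a warning; the chart carries no information beyond it.
        """
        lo, hi = self.ser_domain
        if not np.isfinite(ser):
            raise ValueError("ser must be finite")
        if ser < lo or ser > hi:
            warnings.warn(
                f"SER {ser:+.2f} D outside chart domain [{lo}, {hi}]; clamped",
                stacklevel=2,
            )
            ser = min(max(ser, lo), hi)
        phi = _design(np.array([ser]), self.knots, self.degree, self.ser_domain)
        return np.asarray((phi @ self.coef.T)).ravel()

    def evaluate_grid(self, ser: np.ndarray) -> np.ndarray:
        """Curve values on an SER vector, shape (len(ser), m)."""
        phi = _design(np.asarray(ser, float), self.knots, self.degree, self.ser_domain)
        return np.asarray((phi @ self.coef.T))

    def validate(self, grid_size: int = 201) -> None:
        m = len(self.taus)
        if self.coef.shape[0] != m:
            raise ChartParseError(
                f"chart {self.feature_name!r}: {self.coef.shape[0]} curves "
                f"for {m} quantile levels"
            )
        if np.any(np.diff(self.taus) <= 0):
            raise ChartParseError(f"chart {self.feature_name!r}: taus not increasing")
        gx = np.linspace(*self.ser_domain, grid_size)
        vals = self.evaluate_grid(gx)
        if np.min(np.diff(vals, axis=1), initial=0.0) < -1e-9:
            raise ChartParseError(
                f"chart {self.feature_name!r}: centile curves cross"
            )


def fit_chart(
    ser: np.ndarray,
    values: np.ndarray,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    config: ChartConfig | None = None,
    *,
    feature_name: str = "feature",
) -> CentileChart:
    """Jointly fit noncrossing quantile curves of one feature against SER.

    All quantile levels are estimated in a single optimisation: the
    stacked pinball-loss problem over every curve's spline coefficients,
    with second-difference roughness penalties per curve and one-sided
    exact-penalty rows that keep adjacent curves ordered at every point
    of a dense SER grid.  Residual ordering violations at solver
    tolerance (typically < 1e-8) are removed by minimal constant upward
    shifts, working outward from the median.
    """
    cfg = config or ChartConfig()
    ser = np.asarray(ser, dtype=float)
    y = np.asarray(values, dtype=float)
    taus_arr = np.asarray(sorted(taus), dtype=float)
    if np.any(np.diff(taus_arr) <= 0):
        raise ValueError("taus must be distinct")
    if np.any((taus_arr <= 0) | (taus_arr >= 1)):
        raise ValueError("taus must lie strictly inside (0, 1)")
    n = len(ser)
    if len(y) != n:
        raise ValueError("ser and values must have the same length")
    if not np.all(np.isfinite(ser)) or not np.all(np.isfinite(y)):
        raise ChartFitError("non-finite values in fitting data")
    if n < cfg.n_basis:
        raise ChartFitError(
            f"{n} observations cannot identify a {cfg.n_basis}-dimensional basis"
        )
    if np.ptp(ser) == 0.0:
        raise ChartFitError("SER has no variation; quantile curves are undefined")

    m = len(taus_arr)
    knots = cfg.knots()
    B = _design(ser, knots, cfg.degree, cfg.domain)
    p = B.shape[1]
    gx = np.linspace(*cfg.domain, cfg.grid_size)
    G = _design(gx, knots, cfg.degree, cfg.domain)

    # Roughness penalty: second divided differences of the coefficients at
    # the Greville abscissae.  These vanish exactly on straight lines even
    # near the clamped boundary knots, so the penalty shrinks each curve
    # toward linearity without boundary bias.
    pw = p - 2
    greville = np.array(
        [knots[i + 1 : i + cfg.degree + 1].mean() for i in range(p)]
    )
    d1 = np.diff(greville)
    h2 = d1.mean() ** 2
    rows = np.repeat(np.arange(pw), 3)
    cols = (np.arange(pw)[:, None] + np.arange(3)).ravel()
    vals = np.column_stack(
        [h2 / d1[:-1], -h2 / d1[:-1] - h2 / d1[1:], h2 / d1[1:]]
    ).ravel()
    D2 = sp.csr_matrix((vals, (rows, cols)), shape=(pw, p))

    # Stacked design: one coefficient block per quantile level.
    blocks = [sp.block_diag([B] * m, format="csr")]
    ys = [np.tile(y, m)]
    tau_rows = [np.repeat(taus_arr, n)]
    w_rows = [np.ones(m * n)]

    if cfg.penalty > 0:
        blocks.append(sp.block_diag([D2] * m, format="csr"))
        ys.append(np.zeros(m * pw))
        tau_rows.append(np.full(m * pw, 0.5))
        # weight 2*lambda*n at tau 0.5 contributes lambda*n*|D2 beta|,
        # i.e. lambda per unit of mean pinball loss
        w_rows.append(np.full(m * pw, 2.0 * cfg.penalty * n))

    # Ordering rows: for adjacent levels, penalise G beta_j - G beta_{j+1} > 0.
    Ddiff = sp.diags([-np.ones(m - 1), np.ones(m - 1)], [0, 1], shape=(m - 1, m))
    blocks.append(sp.kron(Ddiff, G, format="csr"))
    ys.append(np.zeros((m - 1) * cfg.grid_size))
    # residual = 0 - G(beta_{j+1} - beta_j) is positive exactly when the
    # curves cross; tau = 1 penalises positive residuals only
    tau_rows.append(np.ones((m - 1) * cfg.grid_size))
    w_rows.append(np.full((m - 1) * cfg.grid_size, cfg.constraint_weight * n))

    X = sp.vstack(blocks, format="csr")
    try:
        beta = solve_weighted_quantile(
            X,
            np.concatenate(ys),
            np.concatenate(tau_rows),
            np.concatenate(w_rows),
        )
    except SolverError as exc:
        raise ChartFitError(f"quantile fit failed for {feature_name}: {exc}") from exc
    coef = beta.reshape(m, p)

    # Tolerance-level repair: minimal constant shifts outward from the median
    # so grid evaluations are exactly nondecreasing in tau.
    Gd = np.asarray(G.todense())
    vals = Gd @ coef.T  # (grid, m)
    mid = m // 2
    shift = 0.0
    for j in range(mid + 1, m):
        gap = np.min(vals[:, j] + shift - vals[:, j - 1])
        if gap < 0.0:
            shift += -gap
        if shift:
            coef[j] += shift
            vals[:, j] += shift
    shift = 0.0
    for j in range(mid - 1, -1, -1):
        gap = np.min(vals[:, j + 1] - (vals[:, j] - shift))
        if gap < 0.0:
            shift += -gap
        if shift:
            coef[j] -= shift
            vals[:, j] -= shift

    resid = np.tile(y, m) - np.asarray(
        sp.block_diag([B] * m, format="csr") @ coef.ravel()
    )
    loss = float(np.mean(pinball_loss(resid, np.repeat(taus_arr, n)).reshape(m, n).sum(axis=1) / n))
    meta = {
        "n_obs": int(n),
        "n_basis": int(cfg.n_basis),
        "penalty": float(cfg.penalty),
        "mean_pinball_loss": loss,
    }
    return CentileChart(
        feature_name=feature_name,
        taus=taus_arr,
        knots=knots,
        degree=cfg.degree,
        coef=coef,
        ser_domain=cfg.domain,
        fit_meta=meta,
    )


@dataclass
class ChartSet:
    """One centile chart per registry feature, plus fitting provenance."""

    charts: dict[str, CentileChart]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> CentileChart:
        return self.charts[name]


def fit_chart_set(
    records: pd.DataFrame,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    config: ChartConfig | None = None,
    provenance: Mapping | None = None,
) -> ChartSet:
    """Fit the full 10-chart set on a one-record-per-person eye table.

    ``records`` must already have passed eligibility, outlier filtering
    and per-person eye selection.
    """
    missing = [c for c in ("ser", *FEATURE_NAMES) if c not in records.columns]
    if missing:
        raise ValueError(f"eye table is missing columns: {missing}")
    ser = records["ser"].to_numpy(dtype=float)
    charts = {
        name: fit_chart(
            ser,
            records[name].to_numpy(dtype=float),
            taus,
            config,
            feature_name=name,
        )
        for name in FEATURE_NAMES
    }
    return ChartSet(charts=charts, provenance=dict(provenance or {}))


def centile_position(chart: CentileChart, ser: float, value: float) -> float:
    """Decimal centile position of an observed feature value at an SER.

    Returns the quantile level of the curve whose value at this SER is
    closest to the observation.  Observations beyond the extreme curves
    are thereby capped at the lowest/highest level (0.05 and 0.95 on the
    default grid); ties between adjacent curves resolve to the lower
    level.
    """
    if not np.isfinite(value):
        raise ValueError("feature value must be finite")
    curves = chart.evaluate(ser)
    return float(chart.taus[int(np.argmin(np.abs(curves - value)))])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_chart_set(charts: ChartSet, path) -> None:
    """Write a chart set as versioned JSON (lossless round trip)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "provenance": charts.provenance,
        "charts": {
            name: {
                "feature_name": c.feature_name,
                "taus": c.taus.tolist(),
                "knots": c.knots.tolist(),
                "degree": c.degree,
                "coef": c.coef.tolist(),
                "ser_domain": list(c.ser_domain),
                "fit_meta": c.fit_meta,
            }
            for name, c in charts.charts.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_chart_set(path, require_registry: bool = True) -> ChartSet:
    """Read and validate a chart set written by :func:`save_chart_set`."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ChartParseError(f"not valid JSON: {exc}") from exc
    if payload.get("format_version") != FORMAT_VERSION:
        raise ChartParseError(
            f"unsupported format_version {payload.get('format_version')!r}"
        )
    raw = payload.get("charts", {})
    if require_registry:
        missing = [f for f in FEATURE_NAMES if f not in raw]
        if missing:
            raise ChartParseError(f"missing feature charts: {missing}")
    charts = {}
    for name, d in raw.items():
        try:
            chart = CentileChart(
                feature_name=d["feature_name"],
                taus=np.asarray(d["taus"], float),
                knots=np.asarray(d["knots"], float),
                degree=int(d["degree"]),
                coef=np.asarray(d["coef"], float),
                ser_domain=tuple(d["ser_domain"]),
                fit_meta=d.get("fit_meta", {}),
            )
        except KeyError as exc:
            raise ChartParseError(f"chart {name!r}: missing field {exc}") from exc
        chart.validate()
        charts[name] = chart
    return ChartSet(charts=charts, provenance=payload.get("provenance", {}))
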