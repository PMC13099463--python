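"""Synthetic cohort generator: eyes, covariates and event histories.

The original charts and survival analyses were built on access-restricted
population data, so every downstream module here is exercised on
synthetic cohorts that emulate the study conditions:

* SER drawn from a Normal(-2.12, 2.23^2) truncated to [-12, 0] D, the
  baseline refraction distribution of the study population, with a small
  within-person (between-eye) anisometropia component;
* each feature linear in SER with Gaussian noise, the slope sign
  matching its direction of change with myopia;
* a single standard-normal latent "stretch" factor per person that
  shifts every feature toward its myopic direction, inducing the
  cross-feature correlation that gives FunSI its signal;
* demographic/clinical covariates matching the study's baseline table;
* event times from exponential proportional-hazards processes with
  administrative censoring, an independent competing event, censoring at
  cataract surgery (retinal-detachment analyses) and death/loss to
  follow-up.

The generator is a statistical emulation, not an image model: feature
values are unbounded below/above by the Gaussian noise even where the
physical quantity is bounded, and the linear trend is a convenience the
chart fitter must not (and does not) rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, get_spec

__all__ = [
    "FeatureTrend",
    "CovariateParams",
    "EventModel",
    "SimParams",
    "RD_EVENT_MODEL",
    "POAG_EVENT_MODEL",
    "simulate_eyes",
    "simulate_cohort",
    "simulate_events",
]


@dataclass(frozen=True)
class FeatureTrend:
    """Linear-in-SER generating model for one feature.

    ``slope`` is per diopter of SER.  A feature that decreases with
    myopia (more negative SER) has a positive slope, and vice versa.
    """

    intercept: float
    slope: float
    noise_sd: float


#: Typical magnitudes for the 10 dimensionless features.  Intercepts and
#: noise reflect the rough location/spread reported for fundus vascular
#: and disc metrics in adult populations; slopes encode the direction of
#: change with myopia and a plausible magnitude over the 12 D range.
DEFAULT_TRENDS: dict[str, FeatureTrend] = {
    "arterial_fd": FeatureTrend(1.25, +0.006, 0.030),
    "venous_fd": FeatureTrend(1.30, +0.006, 0.030),
    "avr": FeatureTrend(0.72, +0.004, 0.050),
    "arterial_tortuosity": FeatureTrend(0.55, +0.012, 0.080),
    "venous_tortuosity": FeatureTrend(0.60, +0.012, 0.080),
    "arterial_concavity": FeatureTrend(0.15, -0.010, 0.050),
    "venous_concavity": FeatureTrend(0.17, -0.010, 0.050),
    "dfd_dml": FeatureTrend(2.60, -0.040, 0.250),
    "disc_tilt": FeatureTrend(1.15, -0.015, 0.080),
    "abs_disc_torsion": FeatureTrend(26.0, +1.000, 8.000),
}


@dataclass(frozen=True)
class CovariateParams:
    """Baseline covariate distributions (study baseline table)."""

    age_mean: float = 54.3
    age_sd: float = 8.1
    age_range: tuple[float, float] = (40.0, 69.0)
    female_fraction: float = 0.54
    white_fraction: float = 0.909
    townsend_mean: float = -1.03
    townsend_sd: float = 2.95
    diabetes_rate: float = 0.044
    hypertension_rate: float = 0.22
    trauma_rate: float = 0.005
    iop_mean: float = 15.9
    iop_sd: float = 3.5
    ch_mean: float = 10.5
    ch_sd: float = 1.7
    cylinder_sd: float = 0.75  # |half-normal| cylindrical power, diopters


@dataclass(frozen=True)
class EventModel:
    """Exponential proportional-hazards event generator.

    The hazard for the event of interest is
    ``baseline_rate * exp(sum beta_c * (x_c - mean(x_c)) + beta_z * z)``
    with covariates centred at their cohort means, so ``baseline_rate``
    is the approximate marginal yearly event rate.  Competing events,
    death/loss to follow-up and (optionally) cataract surgery run as
    independent exponential processes; everyone is administratively
    censored at the horizon.
    """

    baseline_rate: float
    log_hrs: dict[str, float]
    stretch_log_hr: float
    admin_horizon: float = 13.0
    competing_rate: float = 2e-4
    death_loss_rate: float = 6e-3
    cataract_rate: float = 1.2e-2
    censor_at_cataract: bool = True

    def __post_init__(self) -> None:
        rates = (
            self.baseline_rate,
            self.competing_rate,
            self.death_loss_rate,
            self.cataract_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("hazard rates must be nonnegative")
        if self.admin_horizon <= 0:
            raise ValueError("admin_horizon must be positive")


def _log(x: float) -> float:
    return math.log(x)


#: Rhegmatogenous-retinal-detachment analysis conditions: marginal event
#: rate 4.9 per 10,000 person-years; covariate hazard ratios as reported
#: for the adjusted model.
RD_EVENT_MODEL = EventModel(
    baseline_rate=4.9e-4,
    log_hrs={
        "ser": _log(0.81),
        "age": _log(1.00),
        "male": _log(1.89),
        "townsend": _log(0.97),
        "white": _log(1.22),
        "diabetes": _log(1.05),
        "hypertension": _log(1.06),
        "trauma": _log(2.35),
    },
    stretch_log_hr=_log(1.26),
    censor_at_cataract=True,
)

#: Primary-open-angle-glaucoma analysis conditions: marginal rate 15.0
#: per 10,000 person-years; no cataract-surgery censoring, IOP and CH in
#: place of ocular trauma.
POAG_EVENT_MODEL = EventModel(
    baseline_rate=1.5e-3,
    log_hrs={
        "ser": _log(0.93),
        "age": _log(1.07),
        "male": _log(1.14),
        "townsend": _log(0.99),
        "white": _log(0.66),
        "diabetes": _log(1.58),
        "hypertension": _log(1.12),
        "iop": _log(1.21),
        "ch": _log(0.91),
    },
    stretch_log_hr=_log(1.11),
    censor_at_cataract=False,
)


@dataclass(frozen=True)
class SimParams:
    """Full parameterisation of the synthetic cohort."""

    n_persons: int = 1000
    seed: int = 0
    ser_mean: float = -2.12
    ser_sd: float = 2.23
    ser_range: tuple[float, float] = (-12.0, 0.0)
    anisometropia_sd: float = 0.25  # between-eye SER spread, diopters
    feature_trends: dict[str, FeatureTrend] = field(
        default_factory=lambda: dict(DEFAULT_TRENDS)
    )
    #: latent-stretch loading per feature, as a multiple of its noise SD
    stretch_loading_scale: float = 0.4
    covariates: CovariateParams = field(default_factory=CovariateParams)
    event_model: EventModel = RD_EVENT_MODEL

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.ser_sd <= 0 or self.anisometropia_sd < 0:
            raise ValueError("scale parameters must be positive")
        for name, tr in self.feature_trends.items():
            if tr.noise_sd <= 0:
                raise ValueError(f"noise_sd must be positive for {name}")
            expected = -get_spec(name).myopia_sign
            if tr.slope != 0 and math.copysign(1, tr.slope) != expected:
                raise ValueError(
                    f"slope sign for {name} contradicts its myopia direction"
                )


def _draw_person_ser(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Per-person pairs of eye SERs, both within the chart domain.

    The shared person-level refraction follows the truncated normal
    exactly (rejection sampling); each eye adds independent
    anisometropia noise, and only the noise is redrawn when it pushes
    an eye outside [-12, 0], so the eye-level marginal stays within a
    few hundredths of a diopter of the person-level truncated normal.
    """
    lo, hi = params.ser_range
    n = params.n_persons
    base = _truncated_normal(rng, params.ser_mean, params.ser_sd, lo, hi, n)
    eyes = np.empty((n, 2))
    todo_r, todo_c = np.nonzero(np.ones((n, 2), dtype=bool))
    while todo_r.size:
        draw = base[todo_r] + rng.normal(0.0, params.anisometropia_sd, todo_r.size)
        ok = (draw >= lo) & (draw <= hi)
        eyes[todo_r[ok], todo_c[ok]] = draw[ok]
        todo_r, todo_c = todo_r[~ok], todo_c[~ok]
    return eyes


def simulate_eyes(
    params: SimParams,
    rng: np.random.Generator,
    person_ids: np.ndarray | None = None,
    latent_stretch: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate two eyes per person with SER-dependent features.

    Each feature is intercept + slope * SER + loading * latent * sign +
    noise, where sign is +1 for features that increase with myopia and
    -1 otherwise, so a positive latent stretch moves every feature
    toward its worst centile.
    """
    n = params.n_persons
    if person_ids is None:
        person_ids = np.arange(n)
    if latent_stretch is None:
        latent_stretch = rng.standard_normal(n)
    ser_pairs = _draw_person_ser(params, rng)

    rows = {
        "person_id": np.repeat(person_ids, 2),
        "eye": np.tile(["L", "R"], n),
        "ser": ser_pairs.ravel(),
    }
    latent2 = np.repeat(latent_stretch, 2)
    for name in FEATURE_NAMES:
        tr = params.feature_trends[name]
        loading = params.stretch_loading_scale * tr.noise_sd
        sign = get_spec(name).myopia_sign
        rows[name] = (
            tr.intercept
            + tr.slope * rows["ser"]
            + loading * sign * latent2
            + rng.normal(0.0, tr.noise_sd, 2 * n)
        )
    return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean, sd, lo, hi, size
) -> np.ndarray:
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_cohort(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate persons (covariates + latent stretch) and their eyes.

    Returns ``(persons, eyes)``.  Event histories are added separately
    by :func:`simulate_events` once a stretch score is available.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_persons
    cp = params.covariates
    person_ids = np.arange(n)
    latent = rng.standard_normal(n)

    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "latent_stretch": latent,
            "age": _truncated_normal(
                rng, cp.age_mean, cp.age_sd, *cp.age_range, n
            ),
            "male": (rng.random(n) >= cp.female_fraction).astype(int),
            "white": (rng.random(n) < cp.white_fraction).astype(int),
            "townsend": rng.normal(cp.townsend_mean, cp.townsend_sd, n),
            "diabetes": (rng.random(n) < cp.diabetes_rate).astype(int),
            "hypertension": (rng.random(n) < cp.hypertension_rate).astype(int),
            "trauma": (rng.random(n) < cp.trauma_rate).astype(int),
            # implausible device readings are screened out upstream, so the
            # generator clips to the plausible ranges
            "iop": np.clip(rng.normal(cp.iop_mean, cp.iop_sd, n), 0.1, 45.0),
            "ch": np.clip(rng.normal(cp.ch_mean, cp.ch_sd, n), 0.1, 15.0),
            "cylinder": np.abs(rng.normal(0.0, cp.cylinder_sd, n)),
        }
    )
    eyes = simulate_eyes(params, rng, person_ids, latent)
    return persons, eyes


def simulate_events(
    persons: pd.DataFrame,
    stretch_z: np.ndarray,
    event_model: EventModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach latent event-process times and the observed follow-up.

    ``stretch_z`` is the standardised stretch covariate entering the
    hazard (typically standardised FunSI; the latent factor itself for
    chart-free simulations).  Adds latent columns ``t_event``,
    ``t_competing``, ``t_cataract``, ``t_death_loss`` plus the observed
    ``time_years``, ``status`` ({event, competing, censored}) and
    ``censor_reason``.
    """
    em = event_model or RD_EVENT_MODEL
    rng = rng or np.random.default_rng(0)
    z = np.asarray(stretch_z, dtype=float)
    n = len(persons)
    if len(z) != n:
        raise ValueError("stretch_z must have one value per person")

    lp = em.stretch_log_hr * z
    for cov, beta in em.log_hrs.items():
        if beta == 0.0:
            continue
        x = persons[cov].to_numpy(dtype=float)
        lp = lp + beta * (x - x.mean())
    hazard = em.baseline_rate * np.exp(lp)

    def draw(rates) -> np.ndarray:
        rates = np.broadcast_to(np.asarray(rates, float), (n,))
        e = rng.exponential(1.0, n)  # always drawn, keeps the stream aligned
        with np.errstate(divide="ignore"):
            return np.where(rates > 0, e / rates, np.inf)

    out = persons.copy()
    out["t_event"] = draw(hazard)
    out["t_competing"] = draw(em.competing_rate)
    out["t_death_loss"] = draw(em.death_loss_rate)
    out["t_cataract"] = draw(em.cataract_rate)

    candidates = {
        "event": out["t_event"].to_numpy(),
        "competing": out["t_competing"].to_numpy(),
        "death_loss": out["t_death_loss"].to_numpy(),
        "admin": np.full(n, em.admin_horizon),
    }
    if em.censor_at_cataract:
        candidates["cataract_surgery"] = out["t_cataract"].to_numpy()

    names = list(candidates)
    times = np.column_stack([candidates[k] for k in names])
    first = np.argmin(times, axis=1)  # ties resolve to the event of interest
    out["time_years"] = times[np.arange(n), first]
    reason = np.array(names, dtype=object)[first]
    out["status"] = np.where(
        reason == "event", "event", np.where(reason == "competing", "competing", "censored")
    )
    out["censor_reason"] = np.where(reason == "event", "none", reason)
    return out
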