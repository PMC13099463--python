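"""Feature registry, disc-geometry features, eligibility filters and
eye-selection policies.

FunSI is built from 10 dimensionless fundus imaging features.  Seven of
them (vessel fractal dimensions, tortuosities, concavities and the
arteriovenous ratio) come from upstream image-analysis pipelines and are
consumed here as numbers.  The three optic-disc geometry features are
fully defined by the best-fitting ellipse of the disc and are computed
in this module.

Each feature carries a direction of change as myopia increases (SER
becomes more negative), which determines its "worst" centile: the 95th
for features that increase with myopia, the 5th for features that
decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "REGISTRY",
    "FEATURE_NAMES",
    "EllipseFit",
    "SER_RANGE",
    "disc_tilt",
    "abs_disc_torsion",
    "dfd_dml",
    "apply_eligibility",
    "filter_feature_outliers",
    "select_per_person",
]

#: Closed SER interval (diopters) over which charts are defined.
SER_RANGE = (-12.0, 0.0)


@dataclass(frozen=True)
class FeatureSpec:
    """One dimensionless fundus feature and its myopia direction."""

    name: str
    direction_with_myopia: str  # "increases" | "decreases"

    def __post_init__(self) -> None:
        if self.direction_with_myopia not in ("increases", "decreases"):
            raise ValueError(
                f"direction_with_myopia must be 'increases' or 'decreases', "
                f"got {self.direction_with_myopia!r}"
            )

    @property
    def worst_centile(self) -> float:
        """Extreme centile in the myopic direction (0.95 or 0.05)."""
        return 0.95 if self.direction_with_myopia == "increases" else 0.05

    @property
    def myopia_sign(self) -> int:
        """+1 if the feature increases with myopia, -1 if it decreases."""
        return 1 if self.direction_with_myopia == "increases" else -1


#: The 10-feature registry.  Four features increase with myopia, six decrease.
REGISTRY: tuple[FeatureSpec, ...] = (
    FeatureSpec("arterial_fd", "decreases"),
    FeatureSpec("venous_fd", "decreases"),
    FeatureSpec("avr", "decreases"),
    FeatureSpec("arterial_tortuosity", "decreases"),
    FeatureSpec("venous_tortuosity", "decreases"),
    FeatureSpec("arterial_concavity", "increases"),
    FeatureSpec("venous_concavity", "increases"),
    FeatureSpec("dfd_dml", "increases"),
    FeatureSpec("disc_tilt", "increases"),
    FeatureSpec("abs_disc_torsion", "decreases"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(spec.name for spec in REGISTRY)

_REGISTRY_BY_NAME: dict[str, FeatureSpec] = {s.name: s for s in REGISTRY}


def get_spec(name: str) -> FeatureSpec:
    try:
        return _REGISTRY_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown feature {name!r}") from None


class InvalidGeometryError(ValueError):
    """Raised for degenerate ellipse parameters."""


@dataclass(frozen=True)
class EllipseFit:
    """Best-fitting ellipse of the optic disc in image coordinates.

    ``orientation_deg`` is the angle of the major axis measured from the
    image horizontal; the axis is undirected, so orientations theta and
    theta + 180 describe the same ellipse.
    """

    centroid: tuple[float, float]
    major_axis_length: float
    minor_axis_length: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not (self.minor_axis_length > 0 and self.major_axis_length > 0):
            raise InvalidGeometryError("axis lengths must be positive")
        if self.major_axis_length < self.minor_axis_length:
            raise InvalidGeometryError("major axis must be >= minor axis")
        if not math.isfinite(self.orientation_deg):
            raise InvalidGeometryError("orientation must be finite")


def disc_tilt(ellipse: EllipseFit) -> float:
    """Disc tilt: major-to-minor axis length ratio (>= 1).

    A perfectly circular disc has tilt 1; larger values indicate a more
    oval (tilted) disc.
    """
    return ellipse.major_axis_length / ellipse.minor_axis_length


def abs_disc_torsion(ellipse: EllipseFit) -> float:
    """Absolute disc torsion in degrees, folded into [0, 90].

    The major axis is undirected, so the raw orientation is reduced
    modulo 180 and reflected: min(theta mod 180, 180 - theta mod 180).
    A vertically oriented disc gives 90; a horizontal one gives 0.
    """
    theta = ellipse.orientation_deg % 180.0
    return min(theta, 180.0 - theta)


def dfd_dml(ellipse: EllipseFit, fovea: tuple[float, float]) -> float:
    """Disc-fovea distance divided by disc major axis length."""
    dx = ellipse.centroid[0] - fovea[0]
    dy = ellipse.centroid[1] - fovea[1]
    return math.hypot(dx, dy) / ellipse.major_axis_length


def features_from_ellipse(
    ellipse: EllipseFit, fovea: tuple[float, float]
) -> dict[str, float]:
    """All three disc-geometry features for one eye."""
    return {
        "disc_tilt": disc_tilt(ellipse),
        "abs_disc_torsion": abs_disc_torsion(ellipse),
        "dfd_dml": dfd_dml(ellipse, fovea),
    }


# ---------------------------------------------------------------------------
# Eligibility and outlier filtering (eye-level DataFrames)
# ---------------------------------------------------------------------------

_EYE_COLUMNS = ("person_id", "eye", "ser")


def _check_schema(eyes: pd.DataFrame) -> None:
    missing = [c for c in (*_EYE_COLUMNS, *FEATURE_NAMES) if c not in eyes.columns]
    if missing:
        raise ValueError(f"eye table is missing columns: {missing}")


def apply_eligibility(
    eyes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the SER-range and feature-completeness filters.

    Keeps eyes with -12 <= SER <= 0 (hyperopic eyes, SER > 0, and
    extreme myopia beyond -12 D are excluded) and all 10 features finite.

    Returns
    -------
    (kept, exclusion_log) : the retained eyes and a log with columns
    ``person_id, eye, reason`` (reasons: ``hyperopic_ser``,
    ``extreme_myopia``, ``incomplete_features``).
    """
    if eyes.empty:
        return eyes.copy(), pd.DataFrame(columns=["person_id", "eye", "reason"])
    _check_schema(eyes)
    feat = eyes[list(FEATURE_NAMES)].to_numpy(dtype=float)
    ser = eyes["ser"].to_numpy(dtype=float)

    hyperopic = ser > SER_RANGE[1]
    extreme = ser < SER_RANGE[0]
    incomplete = ~np.isfinite(feat).all(axis=1) | ~np.isfinite(ser)

    reason = np.full(len(eyes), "", dtype=object)
    # Order mirrors the screening sequence: refraction first, then features.
    reason[incomplete] = "incomplete_features"
    reason[extreme] = "extreme_myopia"
    reason[hyperopic] = "hyperopic_ser"

    excluded = reason != ""
    log = pd.DataFrame(
        {
            "person_id": eyes.loc[excluded, "person_id"].to_numpy(),
            "eye": eyes.loc[excluded, "eye"].to_numpy(),
            "reason": reason[excluded],
        }
    )
    return eyes.loc[~excluded].copy(), log


def filter_feature_outliers(
    eyes: pd.DataFrame, tail_fraction: float = 0.001
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop eyes in the extreme tails of any feature distribution.

    Per-feature empirical quantiles at ``tail_fraction`` and
    ``1 - tail_fraction`` are computed over the input (linear
    interpolation, numpy's default definition), and any eye strictly
    below the lower cut or strictly above the upper cut on any feature
    is removed.  The default 0.001 mirrors the 0.1% screening rule;
    0.0001 gives the 0.01% sensitivity variant.

    Returns ``(kept, exclusion_log)``.
    """
    if not (0.0 <= tail_fraction < 0.5):
        raise ValueError(f"tail_fraction must be in [0, 0.5), got {tail_fraction}")
    if eyes.empty:
        raise ValueError("cannot compute outlier cuts on an empty table")
    _check_schema(eyes)
    feat = eyes[list(FEATURE_NAMES)].to_numpy(dtype=float)
    lo = np.quantile(feat, tail_fraction, axis=0)
    hi = np.quantile(feat, 1.0 - tail_fraction, axis=0)
    out = ((feat < lo) | (feat > hi)).any(axis=1)
    log = pd.DataFrame(
        {
            "person_id": eyes.loc[out, "person_id"].to_numpy(),
            "eye": eyes.loc[out, "eye"].to_numpy(),
            "reason": "feature_outlier",
        }
    )
    return eyes.loc[~out].copy(), log


# ---------------------------------------------------------------------------
# Per-person eye selection
# ---------------------------------------------------------------------------

POLICIES = ("random_one", "average", "more_myopic")


def select_per_person(
    eyes: pd.DataFrame, policy: str = "random_one", seed: int = 0
) -> pd.DataFrame:
    """Reduce an eye-level table to one record per person.

    Policies
    --------
    random_one
        Pick one eye uniformly at random per person (seeded; the chart
        fitting default).
    average
        Average SER and every feature across the person's eyes (the
        survival-analysis default); the ``eye`` column becomes "both"
        for two-eyed persons.
    more_myopic
        Keep the eye with the more negative SER (sensitivity variant);
        ties resolve to the left eye.

    Single-eye persons pass through unchanged under every policy.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    _check_schema(eyes)
    value_cols = ["ser", *FEATURE_NAMES]
    df = eyes.sort_values(["person_id", "eye"], kind="mergesort").reset_index(
        drop=True
    )

    if policy == "average":
        grouped = df.groupby("person_id", sort=True)
        out = grouped[value_cols].mean().reset_index()
        n_eyes = grouped.size()
        first_eye = grouped["eye"].first()
        out["eye"] = np.where(n_eyes.to_numpy() > 1, "both", first_eye.to_numpy())
        return out[["person_id", "eye", *value_cols]]

    if policy == "more_myopic":
        idx = df.groupby("person_id", sort=True)["ser"].idxmin()
        return df.loc[idx].reset_index(drop=True)

    # random_one: a seeded uniform draw among each person's eyes, applied
    # to a canonically sorted table so the choice is order-independent.
    rng = np.random.default_rng(seed)
    counts = df.groupby("person_id", sort=True).size()
    offsets = np.concatenate([[0], np.cumsum(counts.to_numpy())[:-1]])
    picks = offsets + rng.integers(0, counts.to_numpy())
    return df.loc[picks].reset_index(drop=True)
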