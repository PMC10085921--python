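"""Synthetic cohorts and voxel phantoms for the third-molar age pipeline.

Real reference data for MRI-based dental age estimation are not publicly
deposited, so every downstream stage is exercised on simulated inputs that
carry the statistical structure the analysis assumes:

* the natural log of the soft-tissue ratio (pulp + predentine)/total is
  linear in chronological age with a common negative slope and sex-specific
  intercepts (males run slightly higher at a given age);
* residual variance grows with age (heteroscedastic, Var proportional to
  age by default), motivating the 1/age regression weighting;
* absolute tissue volumes sit near the medians reported for adolescent
  cohorts (hard tissue ~0.7-0.8 ml, pulp ~0.05-0.07 ml, predentine
  ~0.016-0.02 ml per sex);
* third molars can be congenitally absent (agenesis), producing missing
  teeth.

Voxel phantoms are concentric digital teeth (pulp core, predentine shell,
hard-tissue mantle) with class-banded intensities and optional additive
Gaussian noise; they exist to round-trip the threshold segmentation, not to
model MRI physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizeError
from .segmentation import FDI_TEETH, VoxelGrid

__all__ = [
    "GeneratorConfig",
    "EXCLUSION_REASONS",
    "EXCLUSION_COUNTS",
    "ENROLLED_N",
    "generate_cohort",
    "generate_phantom",
    "make_exclusion_fixture",
    "cohort_columns",
]

#: Exclusion categories in their priority order; a participant carries
#: exactly one reason (or "none").
EXCLUSION_REASONS = (
    "missing_molars",
    "unsuitable_tooth",
    "movement_artifact",
    "cotton_roll_error",
)

#: Counts of the enrollment fixture: 99 enrolled, 32 excluded, 67 analyzed.
ENROLLED_N = 99
EXCLUSION_COUNTS = {
    "missing_molars": 4,
    "unsuitable_tooth": 15,
    "movement_artifact": 7,
    "cotton_roll_error": 6,
}

VARIANCE_LAWS = ("constant", "proportional_to_age", "inverse_age")

#: Pulp share of the soft-tissue (pulp + predentine) compartment.  The
#: reported per-sex medians split roughly 76:24.
PULP_FRACTION = 0.76

#: SD of the per-tooth logit-normal jitter around the pulp share.  A
#: deterministic split would make pulp/total, predentine/total and their
#: sum exact scalar multiples (ln-correlation 1), which no real cohort
#: shows; modest independent variation in the split keeps only the truly
#: overlapping odds/proportion outcome pairs above the redundancy cut.
SPLIT_LOGIT_SD = 0.15

#: Log-scale SD of the hard-tissue volume draw (log-normal around the
#: per-sex median); modest anatomical variation between individuals.
HARD_LOG_SD = 0.15

_DEFAULT_TISSUE_SCALE = {
    "F": {"hard": 0.712, "pulp": 0.052, "predentine": 0.016},
    "M": {"hard": 0.788, "pulp": 0.065, "predentine": 0.020},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the cohort generator.

    Defaults describe a 67-participant adolescent/young-adult cohort
    (ages 14-24, about two-thirds female).  The generating law for each
    present tooth is

        ln r = intercept_sex + slope * age + eps,
        eps ~ Normal(0, sigma2 * v(age)),

    where ``r`` is the soft-tissue ratio (pulp + predentine)/total and
    ``v`` follows ``variance_law`` (v = age for ``proportional_to_age``,
    the default, matching a 1/age regression weighting).

    The intercept gap (males ~0.11 higher on the ln scale) is the gap
    implied by the per-sex median tissue volumes; slope -0.07/yr and the
    female intercept anchor the ratio to ~0.087 at age 18.  ``sigma2``
    = 8e-4 puts the residual SD at age 18 near 0.12 ln-units.
    """

    n_participants: int = 67
    sex_ratio: float = 45 / 67
    age_range_years: tuple[float, float] = (14.0, 24.0)
    slope: float = -0.07
    intercept_f: float = -1.18
    intercept_m: float = -1.07
    sigma2: float = 8e-4
    variance_law: str = "proportional_to_age"
    tissue_scale: dict = field(default_factory=lambda: {
        sex: dict(vals) for sex, vals in _DEFAULT_TISSUE_SCALE.items()
    })
    agenesis_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ConfigurationError("age_range_years must satisfy min < max")
        if self.sigma2 <= 0:
            raise ConfigurationError("sigma2 must be > 0")
        if not 0.0 <= self.agenesis_prob < 1.0:
            raise ConfigurationError("agenesis_prob must lie in [0, 1)")
        if self.variance_law not in VARIANCE_LAWS:
            raise ConfigurationError(
                f"variance_law must be one of {VARIANCE_LAWS}, got {self.variance_law!r}"
            )
        for sex in ("F", "M"):
            scale = self.tissue_scale.get(sex)
            if scale is None:
                raise ConfigurationError(f"tissue_scale missing entry for sex {sex!r}")
            for tissue in ("hard", "pulp", "predentine"):
                if scale.get(tissue, 0.0) <= 0:
                    raise ConfigurationError(
                        f"tissue_scale[{sex!r}][{tissue!r}] must be > 0"
                    )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def variance_scale(self, age_years: np.ndarray | float):
        """v(age): multiplier of sigma2 in the residual variance."""
        if self.variance_law == "constant":
            return np.ones_like(np.asarray(age_years, dtype=float))
        if self.variance_law == "proportional_to_age":
            return np.asarray(age_years, dtype=float)
        return 1.0 / np.asarray(age_years, dtype=float)


def cohort_columns() -> list[str]:
    """Column schema of a cohort table (delimited-text interchange format)."""
    cols = ["participant_id", "sex", "age_days", "age_years", "excluded_reason"]
    for tooth in FDI_TEETH:
        cols += [f"t{tooth}_pulp_ml", f"t{tooth}_predentine_ml", f"t{tooth}_hard_ml"]
    return cols


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a cohort table of per-participant tooth tissue volumes.

    Ages are uniform on ``age_range_years`` (recorded in whole days and in
    decimal years = days/365.25).  For each tooth that is present
    (per-tooth agenesis with probability ``agenesis_prob``), hard-tissue
    volume is drawn log-normally around the per-sex median, the soft-tissue
    ratio r is drawn from the generating ln-linear law, and the tooth's
    volumes are solved from (hard, r) and the fixed pulp:predentine split —
    so the headline outcome obeys the generating law exactly.  Absent teeth
    have NaN volumes.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    cols = cohort_columns()
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=("object" if c in ("participant_id", "sex", "excluded_reason") else "float64")) for c in cols})

    lo, hi = config.age_range_years
    age_days = np.round(rng.uniform(lo, hi, size=n) * 365.25).astype(int)
    age_years = age_days / 365.25
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")

    records: dict[str, object] = {
        "participant_id": [f"P{i + 1:04d}" for i in range(n)],
        "sex": sex,
        "age_days": age_days,
        "age_years": age_years,
        "excluded_reason": ["none"] * n,
    }
    v_age = np.asarray(config.variance_scale(age_years), dtype=float)
    for tooth in FDI_TEETH:
        present = rng.random(n) >= config.agenesis_prob
        intercept = np.where(sex == "F", config.intercept_f, config.intercept_m)
        eps = rng.normal(0.0, np.sqrt(config.sigma2 * v_age))
        ln_ratio = intercept + config.slope * age_years + eps
        # guard: ratio must stay below 1 for positive hard-tissue volume
        ratio = np.minimum(np.exp(ln_ratio), 0.95)
        hard_scale = np.array([config.tissue_scale[s]["hard"] for s in sex])
        hard = hard_scale * np.exp(rng.normal(0.0, HARD_LOG_SD, size=n))
        soft = hard * ratio / (1.0 - ratio)
        split_logit = math.log(PULP_FRACTION / (1.0 - PULP_FRACTION))
        pulp_share = 1.0 / (1.0 + np.exp(-(split_logit + rng.normal(0.0, SPLIT_LOGIT_SD, size=n))))
        pulp = pulp_share * soft
        predentine = (1.0 - pulp_share) * soft
        records[f"t{tooth}_pulp_ml"] = np.where(present, pulp, np.nan)
        records[f"t{tooth}_predentine_ml"] = np.where(present, predentine, np.nan)
        records[f"t{tooth}_hard_ml"] = np.where(present, hard, np.nan)
    return pd.DataFrame(records, columns=cols)


def make_exclusion_fixture() -> pd.DataFrame:
    """Enrollment ledger of 99 participants with the four exclusion
    categories (4 missing third molars, 15 unsuitable teeth, 7 movement
    artifacts, 6 cotton-roll errors) and 67 unflagged.

    Reasons are mutually exclusive and assigned in priority order.
    """
    reasons: list[str] = []
    for reason in EXCLUSION_REASONS:
        reasons += [reason] * EXCLUSION_COUNTS[reason]
    reasons += ["none"] * (ENROLLED_N - len(reasons))
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(ENROLLED_N)],
            "exclusion_reason": reasons,
        }
    )


def generate_phantom(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    class_counts: tuple[int, int, int],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelGrid:
    """Build a concentric digital tooth with known per-class voxel counts.

    ``class_counts`` gives (hard, predentine, pulp) voxel counts.  Voxels
    are ranked by distance from the grid centre; the innermost become pulp,
    then a predentine shell, then a hard-tissue mantle — mimicking real
    tooth anatomy.  Base intensities are drawn uniformly inside each
    class's threshold band (hard 0-63, predentine 64-100, pulp 101-200),
    so with ``noise_sd`` = 0 threshold segmentation recovers the counts
    exactly.  Gaussian noise (SD in intensity units) is then added, floored
    to integers and clipped at 0.  Voxels outside the mask are background
    (intensity 0, mask False).
    """
    shape = tuple(int(s) for s in shape)
    n_hard, n_pred, n_pulp = (int(c) for c in class_counts)
    if min(n_hard, n_pred, n_pulp) < 0:
        raise SizeError("class counts must be non-negative")
    total = n_hard + n_pred + n_pulp
    if total > math.prod(shape):
        raise SizeError(
            f"class counts total {total} exceed grid capacity {math.prod(shape)}"
        )
    if any(s <= 0 for s in spacing_mm):
        raise ConfigurationError("spacing_mm components must be > 0")

    rng = np.random.default_rng(seed)
    centre = (np.array(shape, dtype=float) - 1.0) / 2.0
    idx = np.indices(shape).reshape(3, -1).T
    dist2 = ((idx - centre) ** 2).sum(axis=1)
    order = np.argsort(dist2, kind="stable")
    chosen = order[:total]

    flat_int = np.zeros(math.prod(shape), dtype=float)
    mask_flat = np.zeros(math.prod(shape), dtype=bool)
    mask_flat[chosen] = True
    pulp_ix = chosen[:n_pulp]
    pred_ix = chosen[n_pulp : n_pulp + n_pred]
    hard_ix = chosen[n_pulp + n_pred :]
    flat_int[pulp_ix] = rng.integers(101, 201, size=n_pulp)
    flat_int[pred_ix] = rng.integers(64, 101, size=n_pred)
    flat_int[hard_ix] = rng.integers(0, 64, size=n_hard)
    if noise_sd > 0:
        flat_int[chosen] += rng.normal(0.0, noise_sd, size=total)
        flat_int = np.clip(np.floor(flat_int), 0, None)
    return VoxelGrid(
        intensities=flat_int.reshape(shape),
        spacing_mm=tuple(float(s) for s in spacing_mm),
        mask=mask_flat.reshape(shape),
    )
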