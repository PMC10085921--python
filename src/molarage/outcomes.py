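"""Transformation outcomes of tooth tissue volumes and redundancy filtering.

Ten candidate response variables ("outcomes") are built from the three
tissue volumes of a tooth, organised in four families:

    1      total = pulp + predentine + hard
    2a-c   x / (total - x)          (odds form)
    3a-c   x / total                (proportion form)
    4a-c   (x + y) / total          (two-tissue proportion form)

with x, y ranging over pulp, predentine and hard tissue.  Outcomes are
evaluated per tooth, averaged over a tooth set, and log-transformed; the
natural log linearises the strongly right-skewed ratios against age.

Because a tissue's share of the total is small for pulp and predentine,
the odds and proportion forms of the same tissue are almost perfectly
log-linearly related; a Pearson filter (|R| >= 0.999) removes such
duplicates, conventionally keeping the bounded proportion forms (families
1, 3, 4) over the odds forms (family 2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .segmentation import FDI_TEETH, ToothVolumes

__all__ = [
    "OutcomeSpec",
    "TISSUES",
    "OUTCOME_ORDER",
    "RETENTION_PRIORITY",
    "TOOTH_PAIRS",
    "enumerate_outcomes",
    "compute_outcome",
    "outcome_series",
    "redundancy_filter",
]

logger = logging.getLogger(__name__)

TISSUES = ("pulp", "predentine", "hard")

#: Enumeration order of the ten outcome labels.
OUTCOME_ORDER = ("1", "2a", "2b", "2c", "3a", "3b", "3c", "4a", "4b", "4c")

#: Preference order used when an overlapping pair must be thinned: the
#: bounded proportion forms (1, 3a-c, 4a-c) are kept over the odds forms
#: (2a-c).  Within a family, label order.
RETENTION_PRIORITY = ("1", "3a", "3b", "3c", "4a", "4b", "4c", "2a", "2b", "2c")

#: The seven multi-tooth combinations analysed as averages.
TOOTH_PAIRS = (
    (18, 28),
    (38, 48),
    (18, 48),
    (28, 38),
    (18, 38),
    (28, 48),
    (18, 28, 38, 48),
)

AVERAGING_MODES = ("ratio_mean", "volume_sum")


@dataclass(frozen=True)
class OutcomeSpec:
    """One transformation outcome: a symbolic ratio over the three tissues.

    ``family`` 1 takes no tissue argument (the total volume in ml);
    families 2 and 3 take one tissue ``x``; family 4 takes two tissues
    ``(x, y)``.
    """

    label: str
    family: int
    tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in OUTCOME_ORDER:
            raise ValueError(f"unknown outcome label {self.label!r}")
        expected_arity = {1: 0, 2: 1, 3: 1, 4: 2}[self.family]
        if len(self.tissues) != expected_arity:
            raise ValueError(
                f"family {self.family} takes {expected_arity} tissue(s), got {self.tissues}"
            )

    def describe(self) -> str:
        if self.family == 1:
            return "total"
        if self.family == 2:
            return f"{self.tissues[0]}/(total - {self.tissues[0]})"
        if self.family == 3:
            return f"{self.tissues[0]}/total"
        return f"({self.tissues[0]} + {self.tissues[1]})/total"


def enumerate_outcomes() -> list[OutcomeSpec]:
    """The ten outcome specs in enumeration order.

    Family 4 pairs the tissues as (pulp+predentine), (pulp+hard),
    (predentine+hard).
    """
    specs = [OutcomeSpec("1", 1, ())]
    for i, tissue in enumerate(TISSUES):
        specs.append(OutcomeSpec(f"2{'abc'[i]}", 2, (tissue,)))
    for i, tissue in enumerate(TISSUES):
        specs.append(OutcomeSpec(f"3{'abc'[i]}", 3, (tissue,)))
    for i, pair in enumerate(itertools.combinations(TISSUES, 2)):
        specs.append(OutcomeSpec(f"4{'abc'[i]}", 4, pair))
    return specs


def compute_outcome(volumes: ToothVolumes, spec: OutcomeSpec) -> float:
    """Evaluate one outcome on one tooth's volumes.

    All three tissue volumes must be strictly positive (a zero would break
    the downstream ln transform of some outcome).  Family 1 returns the
    total volume in ml; the other families return dimensionless ratios.
    """
    vols = {
        "pulp": volumes.pulp_ml,
        "predentine": volumes.predentine_ml,
        "hard": volumes.hard_ml,
    }
    if any(not v > 0 for v in vols.values()):
        raise DomainError(
            f"tooth {volumes.tooth_id}: all tissue volumes must be > 0, got {vols}"
        )
    total = volumes.total_ml
    if spec.family == 1:
        return total
    if spec.family == 2:
        x = vols[spec.tissues[0]]
        return x / (total - x)
    if spec.family == 3:
        return vols[spec.tissues[0]] / total
    x, y = (vols[t] for t in spec.tissues)
    return (x + y) / total


def _tooth_frame(cohort: pd.DataFrame, tooth: int) -> pd.DataFrame:
    cols = {t: f"t{tooth}_{t}_ml" for t in TISSUES}
    return cohort[list(cols.values())].rename(columns={v: k for k, v in cols.items()})


def _outcome_values(tooth_vols: pd.DataFrame, spec: OutcomeSpec) -> pd.Series:
    """Vectorised compute_outcome over a (pulp, predentine, hard) frame."""
    total = tooth_vols.sum(axis=1)
    if spec.family == 1:
        return total
    if spec.family == 2:
        x = tooth_vols[spec.tissues[0]]
        return x / (total - x)
    if spec.family == 3:
        return tooth_vols[spec.tissues[0]] / total
    return (tooth_vols[spec.tissues[0]] + tooth_vols[spec.tissues[1]]) / total


def outcome_series(
    cohort: pd.DataFrame,
    spec: OutcomeSpec,
    teeth: tuple[int, ...],
    averaging: str = "ratio_mean",
) -> pd.DataFrame:
    """ln-outcome per participant for a tooth set.

    Participants missing any member tooth are dropped (logged at INFO).
    With ``averaging='ratio_mean'`` (default) the outcome is computed per
    tooth and the ratios averaged before taking ln; ``'volume_sum'`` pools
    the member teeth's tissue volumes into one virtual tooth first.

    Returns a frame with columns participant_id, sex, age_years, y
    (y = ln outcome), indexed like the retained cohort rows.
    """
    teeth = tuple(teeth)
    if not teeth or any(t not in FDI_TEETH for t in teeth):
        raise ValueError(f"teeth must be a nonempty subset of {FDI_TEETH}, got {teeth}")
    if averaging not in AVERAGING_MODES:
        raise ValueError(f"averaging must be one of {AVERAGING_MODES}")

    frames = [_tooth_frame(cohort, t) for t in teeth]
    present = np.logical_and.reduce([f.notna().all(axis=1).to_numpy() for f in frames])
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info(
            "outcome %s, teeth %s: dropped %d participant(s) lacking a member tooth",
            spec.label, teeth, n_dropped,
        )
    if not present.any():
        raise InsufficientDataError(
            f"no participant has all of teeth {teeth} for outcome {spec.label}"
        )
    frames = [f[present].reset_index(drop=True) for f in frames]
    if any((f <= 0).any().any() for f in frames):
        raise DomainError("tissue volumes must be strictly positive")

    if averaging == "ratio_mean":
        vals = np.mean([_outcome_values(f, spec).to_numpy() for f in frames], axis=0)
    else:
        pooled = sum(frames[1:], frames[0].copy())
        vals = _outcome_values(pooled, spec).to_numpy()

    return pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy()[present],
            "sex": cohort["sex"].to_numpy()[present],
            "age_years": cohort["age_years"].to_numpy(dtype=float)[present],
            "y": np.log(vals),
        }
    )


def redundancy_filter(
    cohort: pd.DataFrame,
    specs: list[OutcomeSpec],
    teeth: tuple[int, ...],
    r_threshold: float = 0.999,
    averaging: str = "volume_sum",
) -> tuple[list[OutcomeSpec], pd.DataFrame]:
    """Drop outcomes whose ln-series near-duplicate a preferred one.

    Pairwise Pearson correlations of the ln-series are taken in absolute
    value (the hard-tissue odds form is a near-perfect *negative*
    log-linear image of the soft-tissue proportion, and both directions
    are redundant).  For each pair with |R| >= ``r_threshold`` the spec
    ranked lower in the retention-priority order (proportion families
    first, odds family last; duplicates by first occurrence) is removed.

    Redundancy between transformations is algebraic, so the filter series
    default to ``volume_sum`` pooling (one virtual tooth per participant):
    averaging per-tooth ratios instead would inject small Jensen-gap
    discrepancies between outcome pairs that are exact functions of each
    other on a single tooth.

    Returns the retained specs (input order) and the labelled correlation
    matrix.  Constant series make the correlation undefined: the entry is
    NaN, a warning is logged, and the pair is skipped.
    """
    if not specs:
        return [], pd.DataFrame()
    series = [outcome_series(cohort, s, teeth, averaging=averaging) for s in specs]
    n_obs = min(len(s) for s in series)
    if n_obs < 3:
        raise InsufficientDataError(
            f"redundancy filter needs >= 3 participants per series, have {n_obs}"
        )
    mat = np.column_stack([s["y"].to_numpy() for s in series])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    labels = [s.label for s in specs]
    report = pd.DataFrame(corr, index=labels, columns=labels)
    if report.isna().any().any():
        logger.warning("constant outcome series: correlation undefined for some pairs")

    def priority(position: int) -> tuple[int, int]:
        # retention rank, then input position (first duplicate wins)
        return (RETENTION_PRIORITY.index(specs[position].label), position)

    dropped: set[int] = set()
    for i, j in itertools.combinations(range(len(specs)), 2):
        if i in dropped or j in dropped:
            continue
        r = corr[i, j]
        if np.isnan(r):
            continue
        if abs(r) >= r_threshold:
            dropped.add(max(i, j, key=priority))
    retained = [s for k, s in enumerate(specs) if k not in dropped]
    return retained, report
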