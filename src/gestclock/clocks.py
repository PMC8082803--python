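"""Linear gestational epigenetic clocks and their accuracy metrics.

A clock predicts gestational age from methylation as
``intercept + sum_j w_j * beta_j`` over its CpG set.  Published gestational
clocks are plain linear predictors (no Horvath-style log-age transform);
clocks trained in days are converted to weeks by dividing by 7.

When a clock is applied to an array that lacks some of its CpGs, the
default policy follows common practice: missing CpGs are simply excluded
from the sum, with no reweighting of the remaining coefficients, and the
number excluded is reported per estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger("gestclock")

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class ClockModel:
    """A named linear clock: intercept + CpG weight map, in a native unit."""

    name: str
    intercept: float
    weights: dict[str, float]
    unit: str = "weeks"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("clock name must be non-empty")
        if self.unit not in ("weeks", "days"):
            raise ValueError(f"clock unit must be weeks or days, got {self.unit!r}")
        if not self.weights:
            raise ValueError("clock weight map is empty")
        object.__setattr__(self, "weights",
                           {str(k): float(v) for k, v in self.weights.items()})
        object.__setattr__(self, "intercept", float(self.intercept))
        vals = np.fromiter(self.weights.values(), dtype=float)
        if not (np.isfinite(vals).all() and np.isfinite(self.intercept)):
            raise ValueError("clock coefficients must be finite")

    @property
    def n_cpgs(self) -> int:
        return len(self.weights)

    def to_weeks(self, x: np.ndarray | float) -> np.ndarray | float:
        return x / DAYS_PER_WEEK if self.unit == "days" else x


@dataclass(frozen=True)
class AgeEstimate:
    sample_id: str
    dnam_ga_weeks: float
    clock: str
    n_cpgs_used: int
    n_cpgs_missing: int


@dataclass(frozen=True)
class ClockPerformance:
    """Accuracy of a clock against chronological GA.

    mean_delta / sd_delta: mean and sample SD of (DNAm GA - GA), weeks;
    mad: median absolute difference |DNAm GA - GA|, weeks (NOT the
    median-absolute-deviation-from-the-median); r: Pearson correlation of
    DNAm GA with GA, with its two-sided p-value.
    """

    mean_delta: float
    sd_delta: float
    mad: float
    r: float
    r_pvalue: float
    n: int
    r_undefined: bool = False


def apply_clock(clock: ClockModel, betas, missing_policy: str = "exclude"
                ) -> list[AgeEstimate]:
    """Apply a linear clock to a BetaMatrix.

    missing_policy "exclude" drops clock CpGs absent from the matrix from
    the weighted sum; "strict" raises if any clock CpG is absent.  Samples
    with missing (NaN) values among the retained clock CpGs are dropped
    with a logged warning.
    """
    if missing_policy not in ("exclude", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    col_index = {c: i for i, c in enumerate(betas.cpg_ids)}
    present = [c for c in clock.weights if c in col_index]
    absent = [c for c in clock.weights if c not in col_index]
    if not present:
        raise ValueError(
            f"none of the {clock.n_cpgs} CpGs of clock {clock.name!r} are "
            "present in the beta matrix")
    if missing_policy == "strict" and absent:
        raise ValueError(
            f"clock {clock.name!r}: {len(absent)} CpG(s) absent from the "
            f"beta matrix under strict policy: {absent[:10]}")
    cols = np.array([col_index[c] for c in present])
    w = np.array([clock.weights[c] for c in present])
    sub = betas.values[:, cols]
    complete = ~np.isnan(sub).any(axis=1)
    if not complete.all():
        dropped = [s for s, ok in zip(betas.sample_ids, complete) if not ok]
        log.warning("apply_clock(%s): dropped %d sample(s) with missing "
                    "retained CpGs: %s", clock.name, len(dropped), dropped[:5])
    native = clock.intercept + sub[complete] @ w
    ages = clock.to_weeks(native)
    kept = [s for s, ok in zip(betas.sample_ids, complete) if ok]
    return [
        AgeEstimate(sample_id=s, dnam_ga_weeks=float(a), clock=clock.name,
                    n_cpgs_used=len(present), n_cpgs_missing=len(absent))
        for s, a in zip(kept, ages)
    ]


def clock_metrics(estimates: list[AgeEstimate], ga_weeks) -> ClockPerformance:
    """The three clock accuracy metrics: mean +/- SD of the raw difference,
    median absolute difference, and Pearson r of DNAm GA vs GA.

    ga_weeks: mapping sample_id -> chronological GA (weeks), or an array
    aligned with ``estimates``.
    """
    dnam = np.array([e.dnam_ga_weeks for e in estimates], dtype=float)
    if hasattr(ga_weeks, "__getitem__") and not isinstance(ga_weeks, (list, np.ndarray)):
        ga = np.array([float(ga_weeks[e.sample_id]) for e in estimates])
    else:
        ga = np.asarray(ga_weeks, dtype=float)
    if dnam.shape != ga.shape:
        raise ValueError("DNAm GA and GA vectors differ in length")
    if len(dnam) < 3:
        raise ValueError("clock metrics need at least 3 paired observations")
    if not (np.isfinite(dnam).all() and np.isfinite(ga).all()):
        raise ValueError("non-finite value in DNAm GA or GA")
    delta = dnam - ga
    mean_delta = float(delta.mean())
    sd_delta = float(delta.std(ddof=1))
    mad = float(np.median(np.abs(delta)))
    if dnam.std() == 0 or ga.std() == 0:
        log.warning("clock_metrics: zero variance, Pearson r undefined")
        return ClockPerformance(mean_delta, sd_delta, mad, float("nan"),
                                float("nan"), len(dnam), r_undefined=True)
    r, p = stats.pearsonr(dnam, ga)
    return ClockPerformance(mean_delta, sd_delta, mad, float(r), float(p),
                            len(dnam))
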