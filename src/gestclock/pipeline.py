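"""Stage-chaining helpers: cohort -> DNAm GA -> EAAR -> standardized X/y.

These are thin glue functions used by the CLI, the examples and the tests;
all of the science lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clocks import AgeEstimate, ClockModel, apply_clock
from .eaar import EAARVector, eaar_from_phenotypes, zstandardize_frame
from .io_core import BetaMatrix, PhenotypeTable


@dataclass
class TissueAnalysisInput:
    """Everything the selection stage needs for one tissue/cohort."""

    estimates: list[AgeEstimate]
    dnam_ga: pd.Series
    eaar: EAARVector
    X: pd.DataFrame        # z-standardized predictors, complete cases
    y: pd.Series           # z-standardized EAAR aligned with X


def estimates_to_series(estimates: list[AgeEstimate]) -> pd.Series:
    return pd.Series({e.sample_id: e.dnam_ga_weeks for e in estimates},
                     name="dnam_ga_weeks")


def prepare_tissue(betas: BetaMatrix, phenotypes: PhenotypeTable,
                   clock: ClockModel, predictors=None,
                   missing_policy: str = "exclude") -> TissueAnalysisInput:
    """Apply the clock, residualize, and standardize for selection.

    Predictor columns and the EAAR outcome are z-standardized on the
    complete-case subset; rows missing any predictor or EAAR are dropped.
    """
    estimates = apply_clock(clock, betas, missing_policy=missing_policy)
    dnam_ga = estimates_to_series(estimates)
    eaar = eaar_from_phenotypes(dnam_ga, phenotypes)
    names = list(predictors or phenotypes.predictors)
    df = phenotypes.df.loc[eaar.residuals.index, names].copy()
    df["__eaar"] = eaar.residuals
    complete = df.dropna()
    X = zstandardize_frame(complete[names])
    y = zstandardize_frame(complete[["__eaar"]])["__eaar"].rename("eaar_std")
    return TissueAnalysisInput(estimates=estimates, dnam_ga=dnam_ga,
                               eaar=eaar, X=X, y=y)
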