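"""Epigenetic age acceleration residuals (EAAR).

EAAR is defined as the residual from an ordinary-least-squares regression of
DNAm GA on chronological GA, the tissue's estimated cell-type proportions,
and the first two genotype-derived ancestry components.  A positive residual
means the epigenetic age runs ahead of the chronological age (acceleration);
a negative residual means deceleration.  Residuals stay in week units here;
z-standardization happens only at the entry of the variable-selection step,
so that cross-tissue summaries remain interpretable.

Cell-type proportions are compositional (they sum to one), so one
proportion — the alphabetically last cell-type name — is dropped as the
reference before fitting; the residuals are invariant to which one is
dropped because the column space is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("gestclock")


@dataclass
class EAARVector:
    residuals: pd.Series  # sample_id -> EAAR, weeks
    design_columns: list[str]
    reference_cell_type: str | None
    n_complete: int
    n_dropped: int


def zstandardize(x) -> np.ndarray | pd.Series:
    """Center to mean 0 and scale to SD 1 (n-1 denominator)."""
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("zstandardize requires finite values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-standardize a constant vector")
    out = (arr - arr.mean()) / sd
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def zstandardize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-standardization of a predictor matrix."""
    return df.apply(zstandardize)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # columns whose QR R-diagonal is numerically zero
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    return [n for n, d in zip(names, diag) if d < 1e-10 * scale]


def compute_eaar(dnam_ga: pd.Series, ga: pd.Series,
                 cell_props: pd.DataFrame | None,
                 ancestry: pd.DataFrame | None) -> EAARVector:
    """OLS residuals of DNAm GA on GA, cell proportions and ancestry.

    All inputs are indexed by sample_id and aligned on their intersection;
    samples missing any regressor are dropped (complete-case) and counted.
    """
    pieces: dict[str, pd.Series] = {"ga_weeks": ga}
    reference = None
    if cell_props is not None and cell_props.shape[1] > 0:
        cols = sorted(cell_props.columns)
        reference = cols[-1]
        for c in cols[:-1]:
            pieces[c] = cell_props[c]
    if ancestry is not None:
        for c in ancestry.columns:
            pieces[c] = ancestry[c]
    design = pd.DataFrame(pieces)
    data = pd.concat([dnam_ga.rename("dnam_ga"), design], axis=1, join="inner")
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    n, k = len(complete), design.shape[1]
    if n < k + 2:
        raise ValueError(
            f"compute_eaar needs at least {k + 2} complete samples for "
            f"{k} regressors; got {n}")
    names = list(design.columns)
    X = np.column_stack([np.ones(n), complete[names].to_numpy(dtype=float)])
    y = complete["dnam_ga"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, ["(intercept)"] + names)
        raise ValueError(f"rank-deficient EAAR design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = y - X @ beta
    if n_dropped:
        log.info("compute_eaar: dropped %d incomplete sample(s)", n_dropped)
    return EAARVector(
        residuals=pd.Series(res, index=complete.index, name="eaar_weeks"),
        design_columns=names,
        reference_cell_type=reference,
        n_complete=n,
        n_dropped=n_dropped,
    )


def eaar_from_phenotypes(dnam_ga: pd.Series, phenotypes) -> EAARVector:
    """Convenience wrapper pulling GA, cell and ancestry columns from a
    PhenotypeTable."""
    df = phenotypes.df
    cells = df[phenotypes.cell_cols] if phenotypes.cell_cols else None
    anc_cols = [c for c in ("ancestry_c1", "ancestry_c2") if c in df.columns]
    anc = df[anc_cols] if anc_cols else None
    return compute_eaar(dnam_ga, df["ga_weeks"], cells, anc)
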