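"""Bootstrapped elastic-net variable selection with inclusion probabilities.

The procedure, run separately per tissue/cohort on z-standardized predictors
X and z-standardized EAAR y:

1. Draw B bootstrap resamples (n draws with replacement).  On each resample
   fit elastic nets over a grid of mixing values alpha (0 to 1 by 0.1) and,
   per alpha, a 100-value log-spaced lambda path; score every (alpha,
   lambda) by k-fold cross-validated mean squared error (cvm) with folds
   shared across the alpha grid within a bootstrap.
2. Group the fits by (bootstrap, nzero) where nzero is the number of
   non-zero coefficients of the fit on the full bootstrap resample, and
   keep only the minimum-cvm fit per group ("best model per size").
3. Per nzero, compute each variable's inclusion probability (VIP): the
   percentage of contributing bootstraps whose best model of that size has
   the variable non-zero; and the median cvm across bootstraps.
4. Choose the final nzero at the elbow of the (nzero, median cvm) curve —
   the interior point farthest from the chord joining its endpoints, on
   min-max normalized axes.
5. Declare variables with VIP strictly above 75% at the chosen nzero
   "stable", and summarize their coefficients by the median and 2.5/97.5
   percentiles across the bootstraps in which they were non-zero.

Predictors and outcome are standardized once on the full complete-case
dataset before resampling (not re-standardized per bootstrap) so that
coefficients are comparable across bootstraps for the median/CI summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._enet import bootstrap_grid

log = logging.getLogger("gestclock")

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass(frozen=True)
class EnetFitRecord:
    """Best model for one (bootstrap, nzero) group."""

    bootstrap_index: int
    alpha: float
    lam: float
    nzero: int
    cvm: float
    coefficients: tuple[float, ...]  # ordered as ``variables``
    variables: tuple[str, ...] = field(repr=False)


@dataclass
class VIPTable:
    """Per-nzero median cvm, bootstrap coverage and per-variable VIP (%)."""

    variables: tuple[str, ...]
    table: pd.DataFrame        # index nzero; columns: coverage, median_cvm, <vars>
    excluded: pd.DataFrame     # nzero values below the coverage rule
    B: int
    min_coverage: float

    @property
    def curve(self) -> list[tuple[int, float]]:
        return list(zip(self.table.index, self.table["median_cvm"]))


@dataclass(frozen=True)
class ElbowChoice:
    nzero: int
    method: str  # "elbow" | "argmin_fallback"
    note: str = ""


@dataclass
class SelectionResult:
    chosen_nzero: int
    stable_variables: list[str]
    median_coefficients: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    prediction_vector: pd.Series  # medians for stable variables, 0 elsewhere
    threshold: float
    B: int
    seed: int | None
    n_contributing: int
    notes: list[str]


def fit_bootstrap_enet(X, y, B: int = 1000,
                       alpha_grid=DEFAULT_ALPHA_GRID,
                       n_lambda: int = 100, k_folds: int = 10,
                       seed: int = 0) -> list[EnetFitRecord]:
    """Bootstrap the elastic-net grid and keep the best fit per (b, nzero).

    X: z-standardized predictor DataFrame (complete cases); y: z-standardized
    outcome.  All randomness (resampling and CV fold assignment) derives
    from ``seed``; fold assignments are redrawn per bootstrap and shared
    across the alpha grid.
    """
    if isinstance(X, pd.DataFrame):
        variables = tuple(str(c) for c in X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        variables = tuple(f"x{j}" for j in range(Xa.shape[1]))
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if len(ya) != n:
        raise ValueError("X and y length mismatch")
    if not (np.isfinite(Xa).all() and np.isfinite(ya).all()):
        raise ValueError("fit_bootstrap_enet requires complete, finite data")
    if ya.std() == 0:
        raise ValueError("outcome is constant; nothing to fit")
    if n < 5 * k_folds:
        raise ValueError(
            f"n={n} is below 5*k_folds={5 * k_folds}; use fewer folds")
    alpha_grid = tuple(float(a) for a in alpha_grid)
    alphas = np.asarray(alpha_grid, dtype=float)
    rng = np.random.default_rng(seed)
    records: list[EnetFitRecord] = []
    base_fold = np.arange(n) % k_folds
    for b in range(1, B + 1):
        idx = rng.integers(0, n, n)
        Xb = np.ascontiguousarray(Xa[idx])
        yb = np.ascontiguousarray(ya[idx])
        folds = rng.permutation(base_fold)
        all_lams, all_coefs, all_nzero, all_cvm = bootstrap_grid(
            Xb, yb, folds, k_folds, alphas, n_lambda)
        # best model per nzero: first minimum in (alpha asc, lambda desc) scan
        flat_nzero = all_nzero.ravel()
        flat_cvm = all_cvm.ravel()
        for nz in np.unique(flat_nzero):
            mask = flat_nzero == nz
            pos = np.flatnonzero(mask)[np.argmin(flat_cvm[mask])]
            ai, li = divmod(pos, n_lambda)
            records.append(EnetFitRecord(
                bootstrap_index=b, alpha=alpha_grid[ai],
                lam=float(all_lams[ai, li]), nzero=int(nz),
                cvm=float(flat_cvm[pos]),
                coefficients=tuple(all_coefs[ai, li]),
                variables=variables,
            ))
    log.info("fit_bootstrap_enet: B=%d, n=%d, p=%d -> %d retained records "
             "(seed=%d)", B, n, p, len(records), seed)
    return records


def summarize_vip(records: list[EnetFitRecord],
                  min_coverage: float = 0.5) -> VIPTable:
    """Per-nzero VIP percentages and median cvm across bootstraps.

    nzero values contributed by fewer than ``min_coverage`` of the
    bootstraps are excluded from the elbow curve but reported separately.
    """
    if not records:
        raise ValueError("summarize_vip: empty record set")
    variables = records[0].variables
    B = len({r.bootstrap_index for r in records})
    rows: dict[int, list[EnetFitRecord]] = {}
    for r in records:
        rows.setdefault(r.nzero, []).append(r)
    data = []
    for nz in sorted(rows):
        group = rows[nz]
        coefs = np.array([r.coefficients for r in group])
        vip = 100.0 * np.count_nonzero(coefs, axis=0) / len(group)
        data.append({"nzero": nz, "coverage": len(group),
                     "median_cvm": float(np.median([r.cvm for r in group])),
                     **dict(zip(variables, vip))})
    df = pd.DataFrame(data).set_index("nzero")
    keep = df["coverage"] >= min_coverage * B
    if (~keep).any():
        log.info("summarize_vip: nzero %s below coverage rule (<%d%% of B=%d)",
                 list(df.index[~keep]), int(100 * min_coverage), B)
    return VIPTable(variables=variables, table=df[keep],
                    excluded=df[~keep], B=B, min_coverage=min_coverage)


def select_nzero_elbow(curve) -> ElbowChoice:
    """Elbow of the (nzero, median_cvm) curve.

    Both axes are min-max scaled to [0, 1]; the chosen point is the interior
    point farthest below the chord between the first and last points
    (signed perpendicular distance: the rule looks for the position of most
    decreasing cvm, so bumps above the chord are never an elbow).  Ties
    break toward the smallest nzero.  Curves shorter than 3 points or with
    non-decreasing cvm fall back to the argmin of median cvm; curves with
    no interior point below the chord degenerate to the smallest interior
    nzero; both cases are flagged in the result.
    """
    if isinstance(curve, VIPTable):
        curve = curve.curve
    pts = [(int(nz), float(c)) for nz, c in curve]
    if not pts:
        raise ValueError("select_nzero_elbow: empty curve")
    pts.sort()
    nzs = np.array([p[0] for p in pts], dtype=float)
    cvm = np.array([p[1] for p in pts], dtype=float)
    if len(pts) < 3:
        nz = int(nzs[np.argmin(cvm)])
        return ElbowChoice(nz, "argmin_fallback", "curve shorter than 3 points")
    if np.all(np.diff(cvm) >= 0):
        nz = int(nzs[np.argmin(cvm)])
        return ElbowChoice(nz, "argmin_fallback", "non-decreasing cvm curve")
    xr = nzs[-1] - nzs[0]
    yspan = cvm.max() - cvm.min()
    x = (nzs - nzs[0]) / xr
    y = (cvm - cvm.min()) / yspan if yspan > 0 else np.zeros_like(cvm)
    # signed cross product with the chord (chord length is a common
    # factor): positive where the point lies below the chord
    chord_y = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    dist = chord_y - y
    interior = dist[1:-1]
    best = interior.max()
    note = ""
    if best <= 1e-12:
        note = "degenerate curve with no interior point below the chord; smallest interior nzero chosen"
    # first index within tie tolerance of the max -> smallest nzero
    pick = 1 + int(np.flatnonzero(interior >= best - 1e-12)[0])
    return ElbowChoice(int(nzs[pick]), "elbow", note)


def select_stable_variables(vip: VIPTable, chosen_nzero: int,
                            threshold: float = 0.75) -> list[str]:
    """Variables with VIP strictly above 100*threshold at the chosen nzero."""
    full = pd.concat([vip.table, vip.excluded])
    if chosen_nzero not in full.index:
        raise ValueError(f"nzero={chosen_nzero} not present in the VIP table")
    row = full.loc[chosen_nzero]
    return [v for v in vip.variables if row[v] > 100.0 * threshold]


def coefficient_summary(records: list[EnetFitRecord], chosen_nzero: int,
                        stable_variables: list[str],
                        threshold: float = 0.75, B: int | None = None,
                        seed: int | None = None) -> SelectionResult:
    """Median and 95% CI of each variable's coefficient across the
    bootstraps in which it was non-zero at the chosen nzero.

    Percentiles use linear interpolation between order statistics.  The
    exported prediction vector holds the medians of the stable variables
    and zero elsewhere.
    """
    group = [r for r in records if r.nzero == chosen_nzero]
    if not group:
        raise ValueError(f"no bootstrap contributes at nzero={chosen_nzero}")
    variables = group[0].variables
    coefs = np.array([r.coefficients for r in group])
    medians: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    notes: list[str] = []
    for j, v in enumerate(variables):
        vals = coefs[:, j][coefs[:, j] != 0]
        if vals.size == 0:
            log.info("coefficient_summary: %s never non-zero at nzero=%d",
                     v, chosen_nzero)
            notes.append(f"{v}: never non-zero, summary omitted")
            continue
        medians[v] = float(np.median(vals))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        ci95[v] = (float(lo), float(hi))
        if vals.size == 1:
            notes.append(f"{v}: single contributing bootstrap, degenerate CI")
    pred = pd.Series(0.0, index=list(variables))
    for v in stable_variables:
        if v in medians:
            pred[v] = medians[v]
    return SelectionResult(
        chosen_nzero=chosen_nzero, stable_variables=list(stable_variables),
        median_coefficients=medians, ci95=ci95, prediction_vector=pred,
        threshold=threshold, B=B if B is not None else len({r.bootstrap_index for r in records}),
        seed=seed, n_contributing=len(group), notes=notes,
    )


@dataclass
class VIPAnalysis:
    records: list[EnetFitRecord]
    vip: VIPTable
    elbow: ElbowChoice
    selection: SelectionResult


def run_vip(X, y, B: int = 1000, alpha_grid=DEFAULT_ALPHA_GRID,
            n_lambda: int = 100, k_folds: int = 10, seed: int = 0,
            threshold: float = 0.75, min_coverage: float = 0.5) -> VIPAnalysis:
    """The full selection pipeline on standardized (X, y)."""
    records = fit_bootstrap_enet(X, y, B=B, alpha_grid=alpha_grid,
                                 n_lambda=n_lambda, k_folds=k_folds, seed=seed)
    vip = summarize_vip(records, min_coverage=min_coverage)
    elbow = select_nzero_elbow(vip)
    stable = select_stable_variables(vip, elbow.nzero, threshold)
    selection = coefficient_summary(records, elbow.nzero, stable,
                                    threshold=threshold, B=B, seed=seed)
    if elbow.method != "elbow" or elbow.note:
        selection.notes.append(f"elbow: {elbow.method} {elbow.note}".strip())
    return VIPAnalysis(records=records, vip=vip, elbow=elbow,
                       selection=selection)
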