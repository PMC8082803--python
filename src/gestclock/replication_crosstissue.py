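"""Cross-cohort coefficient transfer and cross-tissue concordance.

Replication: the median coefficients selected in a discovery cohort are
applied as a fixed linear score to the standardized predictors of an
independent cohort, and the one-tailed Pearson correlation (alternative:
positive association) between predicted and observed standardized EAAR is
the replication statistic.

Cross-tissue: for individuals sampled in two tissues, Pearson correlations
of DNAm GA and of EAAR between the tissues, plus a paired location test on
the EAAR differences — Student's paired t when a Shapiro-Wilk test does not
reject normality of the differences at alpha = 0.05, the Wilcoxon
signed-rank test otherwise.  Both test results are always reported so the
normality gate is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("gestclock")

SHAPIRO_ALPHA = 0.05


@dataclass
class ReplicationResult:
    r: float
    p: float  # one-tailed, positive association
    n: int
    coefficients: dict[str, float]
    discovery_cohort: str = ""
    target_cohort: str = ""


@dataclass
class PairedTest:
    method: str  # "t" | "wilcoxon" | "degenerate"
    statistic: float
    p: float
    shapiro_p: float
    t_statistic: float
    t_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float


@dataclass
class CrossTissueResult:
    tissue_a: str
    tissue_b: str
    n: int
    r_dnamga: float
    p_dnamga: float
    r_eaar: float
    p_eaar: float
    paired: PairedTest
    eaar_mean_a: float
    eaar_sd_a: float
    eaar_mean_b: float
    eaar_sd_b: float


def predict_external(coefs: pd.Series | dict, X_external: pd.DataFrame
                     ) -> pd.Series:
    """Linear score X.coefs on an external cohort's standardized predictors.

    No intercept: both the coefficients and the outcome are on the
    standardized scale.  Every coefficient name must be a column of
    X_external.
    """
    coefs = pd.Series(coefs, dtype=float)
    missing = [c for c in coefs.index if c not in X_external.columns]
    if missing:
        raise ValueError(f"coefficient names absent from external predictor "
                         f"matrix: {missing}")
    score = X_external[list(coefs.index)].to_numpy(dtype=float) @ coefs.to_numpy()
    return pd.Series(score, index=X_external.index, name="predicted_eaar")


def correlate_one_tailed(pred, obs) -> tuple[float, float]:
    """One-tailed Pearson correlation (H1: positive association).

    p comes from the t-transform t = r*sqrt((n-2)/(1-r^2)) with the
    upper-tail probability of Student's t on n-2 df.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs differ in length")
    if len(pred) < 3:
        raise ValueError("one-tailed correlation needs n >= 3")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValueError("non-finite value in correlation input")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(pred, obs, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def one_tailed_p_from_r(r: float, n: int) -> float:
    """Closed-form one-tailed p for a Pearson r at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0 if r > 0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(stats.t.sf(t, df=n - 2))


def replicate(selection_coefs: pd.Series | dict, X_external: pd.DataFrame,
              eaar_external: pd.Series, discovery: str = "",
              target: str = "") -> ReplicationResult:
    """Coefficient-transfer replication of a selection in a new cohort."""
    pred = predict_external(selection_coefs, X_external)
    common = pred.index.intersection(eaar_external.index)
    r, p = correlate_one_tailed(pred.loc[common], eaar_external.loc[common])
    return ReplicationResult(r=r, p=p, n=len(common),
                             coefficients=dict(pd.Series(selection_coefs)),
                             discovery_cohort=discovery, target_cohort=target)


def _paired_test(diff: np.ndarray) -> PairedTest:
    if np.allclose(diff, 0.0):
        return PairedTest("degenerate", 0.0, 1.0, 1.0, np.nan, np.nan,
                          np.nan, np.nan)
    sw_p = float(stats.shapiro(diff).pvalue)
    t_stat, t_p = stats.ttest_rel(diff, np.zeros_like(diff))
    nonzero = diff[diff != 0]
    if nonzero.size:
        w_stat, w_p = stats.wilcoxon(nonzero)
    else:  # pragma: no cover - covered by the allclose branch above
        w_stat, w_p = np.nan, 1.0
    if sw_p >= SHAPIRO_ALPHA:
        method, statistic, p = "t", float(t_stat), float(t_p)
    else:
        method, statistic, p = "wilcoxon", float(w_stat), float(w_p)
    return PairedTest(method, statistic, p, sw_p, float(t_stat), float(t_p),
                      float(w_stat), float(w_p))


def cross_tissue_concordance(dnamga_a: pd.Series, dnamga_b: pd.Series,
                             eaar_a: pd.Series, eaar_b: pd.Series,
                             matched_ids=None,
                             tissue_a: str = "A", tissue_b: str = "B"
                             ) -> CrossTissueResult:
    """Concordance of DNAm GA and EAAR between two tissues of the same
    individuals, plus a paired location test on EAAR.

    Series are indexed by individual_id; ``matched_ids`` restricts the
    comparison (defaults to the index intersection).  Duplicate ids raise:
    the design assumes one sample per (individual, tissue).
    """
    for s, label in ((dnamga_a, "dnamga_a"), (dnamga_b, "dnamga_b"),
                     (eaar_a, "eaar_a"), (eaar_b, "eaar_b")):
        if s.index.duplicated().any():
            raise ValueError(f"duplicate individual_id in {label}")
    if matched_ids is None:
        matched_ids = dnamga_a.index.intersection(dnamga_b.index)
        matched_ids = matched_ids.intersection(eaar_a.index)
        matched_ids = matched_ids.intersection(eaar_b.index)
    ids = pd.Index(matched_ids)
    if len(ids) < 3:
        raise ValueError("cross-tissue concordance needs >= 3 matched "
                         "individuals")
    ga_a = dnamga_a.loc[ids].to_numpy(dtype=float)
    ga_b = dnamga_b.loc[ids].to_numpy(dtype=float)
    ea = eaar_a.loc[ids].to_numpy(dtype=float)
    eb = eaar_b.loc[ids].to_numpy(dtype=float)
    r_ga, p_ga = stats.pearsonr(ga_a, ga_b)
    if np.allclose(ea, eb):
        r_ea, p_ea = 1.0, 0.0
    else:
        r_ea, p_ea = stats.pearsonr(ea, eb)
    paired = _paired_test(ea - eb)
    return CrossTissueResult(
        tissue_a=tissue_a, tissue_b=tissue_b, n=len(ids),
        r_dnamga=float(r_ga), p_dnamga=float(p_ga),
        r_eaar=float(r_ea), p_eaar=float(p_ea), paired=paired,
        eaar_mean_a=float(ea.mean()), eaar_sd_a=float(ea.std(ddof=1)),
        eaar_mean_b=float(eb.mean()), eaar_sd_b=float(eb.std(ddof=1)),
    )
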