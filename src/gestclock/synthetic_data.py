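"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, with every planted quantity recorded in a :class:`SyntheticTruth`
oracle:

* chronological GA from a truncated normal (term birth: mean 39.9, SD 1.5,
  truncated to [33, 43] weeks; chorionic villus sampling: mean 12.8, SD 0.8,
  [10, 15] weeks);
* the 13/14 birth- and pregnancy-related predictors from a latent
  multivariate normal with a realistic correlation structure, binarized at
  prevalence-matched thresholds;
* per-individual age acceleration a_i = sum_k gamma_k * x_ik + eps_i on the
  standardized predictor scale (gamma in weeks per SD), with optional
  cross-tissue correlation rho of the eps component;
* cell-type proportions from tissue-specific Dirichlet distributions, with
  a compositional confound delta (weeks per SD of the first proportion)
  entering the target age so that the EAAR adjustment is exercised;
* beta values built rank-one around a linear clock: beta_ij = m_j + v_j *
  (t_i - c0 - w.m) + noise with w.v = 1, which guarantees that applying the
  clock to noise-free betas returns the planted target age t_i exactly.

With gamma = 0 the planted cross-tissue correlation of the total
acceleration equals rho exactly; with shared non-zero gamma the common
predictor component raises it above rho.
"""

from __future__ import annotations

import copy
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .clocks import ClockModel
from .eaar import zstandardize
from .io_core import (ANCESTRY_COLS, CELL_PREFIX, DEFAULT_PREDICTORS,
                      PREDICTOR_TYPES, BetaMatrix, PhenotypeTable)

log = logging.getLogger("gestclock")

# Table-1-style marginals: prevalence for binary, (mean, sd) for continuous.
PREDICTOR_MARGINALS: dict[str, float | tuple[float, float]] = {
    "child_sex": 0.49,
    "birth_weight_g": (3532.0, 489.0),
    "birth_length_cm": (50.2, 2.2),
    "head_circumference_cm": (35.1, 1.5),
    "maternal_age_years": (34.7, 4.8),
    "maternal_bmi": (23.9, 4.2),
    "maternal_smoking": 0.04,
    "parity": 0.45,
    "delivery_mode": 0.30,
    "induced_labor": 0.27,
    "maternal_diabetes": 0.22,
    "hypertensive_disorder": 0.06,
    "maternal_mental_disorders": 0.11,
    "maternal_alcohol_use": 0.10,
}

# modest, plausible latent correlations (anthropometrics cluster, obstetric
# cluster, metabolic cluster); everything else independent
DEFAULT_LATENT_CORR: dict[tuple[str, str], float] = {
    ("birth_weight_g", "birth_length_cm"): 0.70,
    ("birth_weight_g", "head_circumference_cm"): 0.50,
    ("birth_length_cm", "head_circumference_cm"): 0.45,
    ("maternal_age_years", "parity"): 0.35,
    ("maternal_bmi", "maternal_diabetes"): 0.30,
    ("maternal_bmi", "hypertensive_disorder"): 0.25,
    ("hypertensive_disorder", "induced_labor"): 0.20,
    ("induced_labor", "delivery_mode"): 0.25,
    ("maternal_smoking", "maternal_mental_disorders"): 0.20,
    ("maternal_smoking", "maternal_alcohol_use"): 0.25,
    ("child_sex", "birth_weight_g"): -0.15,
    ("child_sex", "birth_length_cm"): -0.15,
    ("maternal_age_years", "maternal_bmi"): 0.10,
}

GA_DEFAULTS: dict[str, dict[str, float]] = {
    "term": {"mean": 39.9, "sd": 1.5, "lo": 33.0, "hi": 43.0},
    "cvs": {"mean": 12.8, "sd": 0.8, "lo": 10.0, "hi": 15.0},
}

CELL_TYPES: dict[str, tuple[str, ...]] = {
    "cord_blood": ("nrbc", "granulocytes", "monocytes", "nk_cells",
                   "b_cells", "cd4_t", "cd8_t"),
    "cvs": ("nrbc", "trophoblasts", "syncytiotrophoblast", "stromal",
            "hofbauer", "endothelial"),
}
CELL_TYPES["placenta_fetal"] = CELL_TYPES["cvs"]
CELL_TYPES["placenta_decidual"] = CELL_TYPES["cvs"]

DIRICHLET_CONC: dict[str, tuple[float, ...]] = {
    "cord_blood": (4.0, 30.0, 5.0, 3.0, 4.0, 9.0, 5.0),
    "cvs": (3.0, 18.0, 21.0, 9.0, 4.0, 5.0),
}
DIRICHLET_CONC["placenta_fetal"] = DIRICHLET_CONC["cvs"]
DIRICHLET_CONC["placenta_decidual"] = DIRICHLET_CONC["cvs"]


@dataclass
class SimulationConfig:
    """Study-condition parameters of a synthetic cohort."""

    n: int = 400
    tissues: tuple[str, ...] = ("cord_blood",)
    cohort_id: str = "sim"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    marginals: dict = field(default_factory=lambda: dict(PREDICTOR_MARGINALS))
    latent_corr: dict | None = None  # (name, name) -> r; None = defaults
    gamma: dict = field(default_factory=dict)   # name -> weeks per SD
    gamma_per_tissue: dict = field(default_factory=dict)  # tissue -> gamma
    sigma_a: float = 0.7       # acceleration noise SD, weeks
    rho: float = 0.0           # cross-tissue correlation of the noise part
    delta: float = 1.0         # cell confound, weeks per SD of 1st proportion
    sigma_beta: float = 0.02   # beta-value noise SD
    n_clock_cpgs: int = 100
    clock: ClockModel | None = None  # explicit clock; None -> toy per tissue
    ga: dict = field(default_factory=dict)       # per-tissue overrides
    dirichlet: dict = field(default_factory=dict)
    seed: int | None = None    # default seed when none is passed explicitly

    def __post_init__(self) -> None:
        if self.sigma_a < 0 or self.sigma_beta < 0:
            raise ValueError("noise SDs must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")
        unknown = set(self.tissues) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown tissue(s): {sorted(unknown)}")
        for t, conc in self.dirichlet.items():
            if np.any(np.asarray(conc, dtype=float) <= 0):
                raise ValueError(f"Dirichlet concentrations for {t} must be > 0")

    def ga_params(self, tissue: str) -> dict[str, float]:
        if tissue in self.ga:
            return dict(self.ga[tissue])
        return dict(GA_DEFAULTS["cvs" if tissue == "cvs" else "term"])

    def tissue_gamma(self, tissue: str) -> dict[str, float]:
        return dict(self.gamma_per_tissue.get(tissue, self.gamma))

    def correlation_matrix(self) -> pd.DataFrame:
        names = list(self.predictors)
        R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        pairs = (DEFAULT_LATENT_CORR if self.latent_corr is None
                 else self.latent_corr)
        for (a, b), r in pairs.items():
            if a in names and b in names:
                R.loc[a, b] = R.loc[b, a] = r
        return R

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("tissues", "predictors"):
            if key in data:
                data[key] = tuple(data[key])
        if "latent_corr" in data and isinstance(data["latent_corr"], dict):
            data["latent_corr"] = {tuple(k.split("|")): float(v)
                                   for k, v in data["latent_corr"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        d = copy.deepcopy(self.__dict__)
        if d["latent_corr"] is not None:
            d["latent_corr"] = {"|".join(k): v
                                for k, v in d["latent_corr"].items()}
        for key in ("tissues", "predictors"):
            d[key] = list(d[key])
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for every recovery test."""

    acceleration: dict[str, np.ndarray]   # tissue -> a_i (weeks)
    target_age: dict[str, np.ndarray]     # tissue -> t_i (weeks)
    ga_weeks: dict[str, np.ndarray]
    gamma: dict[str, dict[str, float]]    # tissue -> planted effects
    standardized_effects: dict[str, dict[str, float]]
    rho: float
    clock_names: dict[str, str]
    clip_fraction: dict[str, float]
    individual_ids: list[str]
    seed: int
    clocks: dict[str, ClockModel] = field(default_factory=dict)

    def to_json(self, path) -> None:
        out = {
            "rho": self.rho, "seed": self.seed,
            "clock_names": self.clock_names,
            "gamma": self.gamma,
            "standardized_effects": self.standardized_effects,
            "clip_fraction": self.clip_fraction,
            "individual_ids": self.individual_ids,
            "acceleration": {t: a.tolist() for t, a in self.acceleration.items()},
            "target_age": {t: a.tolist() for t, a in self.target_age.items()},
            "ga_weeks": {t: a.tolist() for t, a in self.ga_weeks.items()},
        }
        with open(path, "w") as fh:
            json.dump(out, fh)


def make_toy_clock(n_cpgs: int = 100, center_weeks: float = 39.9,
                   seed: int = 0, name: str = "toy",
                   unit: str = "weeks", prefix: str = "cg") -> ClockModel:
    """A random linear clock whose intercept is matched to a GA range.

    Weights are uniform in magnitude on [0.4, 1.0] with random signs; the
    intercept is chosen so that a flat methylation profile of 0.5 maps to
    ``center_weeks``, keeping beta values generated around the clock well
    inside [0, 1].
    """
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.4, 1.0, n_cpgs)
    signs = rng.choice([-1.0, 1.0], n_cpgs)
    w = mags * signs
    cpgs = [f"{prefix}{seed % 1000:03d}{j:05d}" for j in range(n_cpgs)]
    center_native = center_weeks * (7.0 if unit == "days" else 1.0)
    intercept = center_native - 0.5 * w.sum()
    return ClockModel(name=name, intercept=float(intercept),
                      weights=dict(zip(cpgs, w)), unit=unit)


def _check_psd(R: np.ndarray) -> None:
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-10:
        clipped = np.linalg.eigvalsh(R).clip(min=0)
        raise ValueError(
            f"latent correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); project to the nearest PSD "
            f"matrix by clipping negative eigenvalues to zero "
            f"(spectrum after clipping: {np.round(clipped, 3).tolist()})")


def generate_predictors(config: SimulationConfig, seed) -> tuple[pd.DataFrame,
                                                                 pd.DataFrame]:
    """Raw-scale predictor matrix from a thresholded latent Gaussian.

    Returns (predictors, latent correlation matrix).  Binary variables are 1
    where the latent exceeds the quantile matching the configured
    prevalence; continuous variables are affine maps to the configured
    mean/SD.
    """
    names = list(config.predictors)
    R = config.correlation_matrix()
    Rm = R.to_numpy(dtype=float)
    _check_psd(Rm)
    rng = np.random.default_rng(seed)
    # eigen factorization tolerates the semi-definite boundary
    vals, vecs = np.linalg.eigh(Rm)
    A = vecs * np.sqrt(vals.clip(min=0.0))
    Z = rng.standard_normal((config.n, len(names))) @ A.T
    cols = {}
    for j, name in enumerate(names):
        marg = config.marginals[name]
        if PREDICTOR_TYPES[name] == "binary":
            prev = float(marg)
            cols[name] = (Z[:, j] > stats.norm.ppf(1.0 - prev)).astype(float)
        else:
            mean, sd = marg
            cols[name] = mean + sd * Z[:, j]
    return pd.DataFrame(cols), R


def _truncated_normal(rng, n, mean, sd, lo, hi) -> np.ndarray:
    """Rejection sampling; the default bounds are > 2 SD wide so the
    acceptance rate is high."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 16)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _fit_base_profile(w: np.ndarray, c0: float, t: np.ndarray, m0: np.ndarray,
                      clock_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Base methylation profile m and direction v with w.v = 1 such that
    all noise-free betas m + v*(t - c0 - w.m) lie in [0.05, 0.95]."""
    v = w / (w @ w)
    lo, hi = 0.05, 0.95
    m = m0.copy()
    for _ in range(20):
        s = t - c0 - w @ m
        smin, smax = float(s.min()), float(s.max())
        lo_m = lo - np.minimum(v * smin, v * smax)
        hi_m = hi - np.maximum(v * smin, v * smax)
        if np.any(lo_m > hi_m):
            raise ValueError(
                f"clock {clock_name!r} is incompatible with the target age "
                "range: noise-free betas cannot stay within [0.05, 0.95]; "
                "rescale the clock weights or narrow the GA range")
        m_new = np.clip(m, lo_m, hi_m)
        converged = np.abs(m_new - m).max() < 1e-13
        m = m_new
        if converged:
            break
    s = t - c0 - w @ m
    betas_nf = m + np.outer(s, v)
    if betas_nf.min() < lo - 1e-9 or betas_nf.max() > hi + 1e-9:
        raise ValueError(
            f"clock {clock_name!r}: could not fit noise-free betas into "
            "[0.05, 0.95]; rescale the clock weights or target range")
    return m, v


def _betas_for_tissue(rng, clock: ClockModel, t_native: np.ndarray,
                      sigma_beta: float, sample_ids: list[str]
                      ) -> tuple[BetaMatrix, float]:
    cpgs = list(clock.weights)
    w = np.array([clock.weights[c] for c in cpgs])
    m0 = rng.uniform(0.2, 0.8, len(cpgs))
    m, v = _fit_base_profile(w, clock.intercept, t_native, m0, clock.name)
    s = t_native - clock.intercept - w @ m
    betas = m + np.outer(s, v)
    if sigma_beta > 0:
        betas = betas + rng.normal(0.0, sigma_beta, betas.shape)
    clipped = float(np.mean((betas < 0) | (betas > 1)))
    betas = np.clip(betas, 0.0, 1.0)
    return (BetaMatrix(cpg_ids=cpgs, sample_ids=sample_ids, values=betas),
            clipped)


def generate_multi_tissue(config: SimulationConfig, seed=None
                          ) -> tuple[dict[str, tuple[BetaMatrix, PhenotypeTable]],
                                     SyntheticTruth]:
    """Per-tissue cohorts sharing individuals and planted accelerations.

    The acceleration noise vector eps_i across tissues is multivariate
    normal with pairwise correlation rho; each tissue can carry its own
    effect vector gamma and gets its own clock (intercept matched to the
    tissue's GA range), cell reference and — for CVS — sampling-time GA.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    tissues = list(config.tissues)
    T = len(tissues)
    ss = np.random.SeedSequence(seed)
    (ss_pred, ss_ga, ss_eps, ss_anc, ss_cells,
     ss_clock, ss_beta) = ss.spawn(7)
    n = config.n
    individual_ids = [f"{config.cohort_id}_{i:05d}" for i in range(n)]

    predictors, _ = generate_predictors(config, ss_pred)

    rng_ga = np.random.default_rng(ss_ga)
    birth_ga = None  # term tissues share the GA at birth
    ga_by_tissue: dict[str, np.ndarray] = {}
    for t in tissues:
        p = config.ga_params(t)
        if t == "cvs":
            ga_by_tissue[t] = _truncated_normal(rng_ga, n, p["mean"], p["sd"],
                                                p["lo"], p["hi"])
        else:
            if birth_ga is None:
                birth_ga = _truncated_normal(rng_ga, n, p["mean"], p["sd"],
                                             p["lo"], p["hi"])
            ga_by_tissue[t] = birth_ga

    # correlated acceleration noise across tissues
    rng_eps = np.random.default_rng(ss_eps)
    C = np.full((T, T), config.rho) + (1.0 - config.rho) * np.eye(T)
    _check_psd(C)
    vals, vecs = np.linalg.eigh(C)
    A = vecs * np.sqrt(vals.clip(min=0.0))
    eps = config.sigma_a * (rng_eps.standard_normal((n, T)) @ A.T)

    rng_anc = np.random.default_rng(ss_anc)
    ancestry = rng_anc.standard_normal((n, 2)) * 0.02  # MDS-style scale

    rng_cells = np.random.default_rng(ss_cells)
    clock_seeds = ss_clock.spawn(T)
    beta_seeds = ss_beta.spawn(T)

    cohorts: dict[str, tuple[BetaMatrix, PhenotypeTable]] = {}
    truth_a, truth_t, truth_ga = {}, {}, {}
    truth_gamma, truth_std, clocks_used, clip_frac = {}, {}, {}, {}
    clock_models: dict[str, ClockModel] = {}
    for ti, tissue in enumerate(tissues):
        ga = ga_by_tissue[tissue]
        gamma = config.tissue_gamma(tissue)
        unknown = set(gamma) - set(predictors.columns)
        if unknown:
            raise ValueError(f"gamma names not among predictors: "
                             f"{sorted(unknown)}")
        # effects act on the standardized predictor scale (weeks per SD);
        # only effect-carrying columns need standardizing
        a = eps[:, ti].copy()
        for name, g in gamma.items():
            if g != 0.0:
                a += g * np.asarray(zstandardize(predictors[name].to_numpy()))

        conc = np.asarray(config.dirichlet.get(tissue,
                                               DIRICHLET_CONC[tissue]),
                          dtype=float)
        cell_names = CELL_TYPES[tissue]
        if len(conc) != len(cell_names):
            raise ValueError(f"{tissue}: {len(conc)} Dirichlet concentrations "
                             f"for {len(cell_names)} cell types")
        cells = rng_cells.dirichlet(conc, size=n)
        confound = (config.delta * zstandardize(cells[:, 0])
                    if config.delta != 0 else np.zeros(n))
        t_age = ga + a + confound

        if config.clock is not None:
            clock = config.clock
        else:
            clock = make_toy_clock(
                n_cpgs=config.n_clock_cpgs,
                center_weeks=config.ga_params(tissue)["mean"],
                seed=int(clock_seeds[ti].generate_state(1)[0] % (2**31)),
                name=f"toy_{tissue}", prefix=f"cg{ti}")
        sample_ids = [f"{iid}_{tissue}" for iid in individual_ids]
        rng_beta = np.random.default_rng(beta_seeds[ti])
        t_native = t_age * (7.0 if clock.unit == "days" else 1.0)
        bm, clipped = _betas_for_tissue(rng_beta, clock, t_native,
                                        config.sigma_beta, sample_ids)

        pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
        pheno["individual_id"] = individual_ids
        pheno["cohort_id"] = config.cohort_id
        pheno["tissue"] = tissue
        pheno["ga_weeks"] = ga
        for c in predictors.columns:
            pheno[c] = predictors[c].to_numpy()
        for ci, cname in enumerate(cell_names):
            pheno[f"{CELL_PREFIX}{cname}"] = cells[:, ci]
        pheno[ANCESTRY_COLS[0]] = ancestry[:, 0]
        pheno[ANCESTRY_COLS[1]] = ancestry[:, 1]
        table = PhenotypeTable(
            df=pheno,
            predictor_types={c: PREDICTOR_TYPES[c] for c in predictors.columns})

        cohorts[tissue] = (bm, table)
        truth_a[tissue] = a
        truth_t[tissue] = t_age
        truth_ga[tissue] = ga
        truth_gamma[tissue] = dict(gamma)
        sd_a = float(a.std(ddof=1)) if a.std(ddof=1) > 0 else 1.0
        truth_std[tissue] = {k: v / sd_a for k, v in gamma.items()}
        clocks_used[tissue] = clock.name
        clip_frac[tissue] = clipped
        clock_models[tissue] = clock

    truth = SyntheticTruth(
        acceleration=truth_a, target_age=truth_t, ga_weeks=truth_ga,
        gamma=truth_gamma, standardized_effects=truth_std, rho=config.rho,
        clock_names=clocks_used, clip_fraction=clip_frac,
        individual_ids=individual_ids, seed=int(seed), clocks=clock_models)
    log.info("generate_multi_tissue: n=%d, tissues=%s, seed=%s, clip=%s",
             n, tissues, seed, clip_frac)
    return cohorts, truth


def generate_cohort(config: SimulationConfig, seed=None,
                    tissue: str | None = None
                    ) -> tuple[BetaMatrix, PhenotypeTable, SyntheticTruth]:
    """Single-tissue convenience front end of :func:`generate_multi_tissue`."""
    if tissue is None:
        tissue = config.tissues[0]
    cfg = copy.deepcopy(config)
    cfg.tissues = (tissue,)
    cohorts, truth = generate_multi_tissue(cfg, seed)
    bm, pheno = cohorts[tissue]
    return bm, pheno, truth


def load_scenario(name: str, **overrides) -> SimulationConfig:
    """Load one of the shipped scenario configurations by name
    (``null``, ``cordblood_like``, ``crosstissue_null``) or a path."""
    p = Path(name)
    if not p.exists():
        ref = importlib.resources.files("gestclock") / "scenarios" / f"{name}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(f"no scenario named {name!r}")
        p = ref
    return SimulationConfig.from_yaml(p, **overrides)
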