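"""Gamma/log-link GLM modelling of PVS volume fractions.

PVS volume fractions are positive, continuous and right-skewed, so the
conditional mean is modelled as ``E[y] = exp(X b)`` with a Gamma
response.  The module covers the study's model suite:

* main effects -- ``log E[pvsvf] = b0 + b1 marker + covariates``;
* physiological x inflammatory interactions (cortisol or ACE crossed
  with one inflammatory marker);
* sensitivity covariates (APOE4 positivity, diagnosis, medication
  factors) and within-diagnosis subgroup fits;
* model-fitted exposure curves at the minimum and maximum of the
  moderator, with pointwise 95% Wald confidence bands;
* deviance-residual diagnostics for the normality check.

Continuous predictors are median-centered (BMI z-scaled) before
fitting; coefficients are reported both on the log scale and
exponentiated (mean ratios).  Fitting is by iteratively reweighted
least squares; for the Gamma/log-link pair the IRLS working weights are
identically one, so each step is an ordinary least-squares solve on the
working response.  Dispersion is the Pearson chi-square estimate and
inference is Wald, with no multiple-testing correction (two-sided 0.05
rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from . import design

__all__ = [
    "ModelSpec",
    "GLMFit",
    "prepare_design",
    "fit_gamma_glm",
    "run_model_suite",
    "fitted_interaction_curves",
    "residual_diagnostics",
]

logger = logging.getLogger(__name__)

_BASE_COVARIATES = ["sex_male", "age", "bmi_z", "hippocampal_volume"]

_EXTRA_COVARIATES = {
    "apoe4": ["apoe4_positive"],
    "diagnosis": ["diagnosis_mci", "diagnosis_ad"],
    "medication_history": ["med_history_1", "med_history_2", "med_history_3"],
    "medication_current": ["med_current_1", "med_current_2"],
}


@dataclass
class ModelSpec:
    """One regression model of the suite.

    ``form`` is ``"main"`` (a single biomarker), ``"cortisol_interaction"``
    or ``"ace_interaction"`` (the physiological exposure crossed with one
    inflammatory ``biomarker``).  ``extra_covariates`` may include
    ``"apoe4"``, ``"diagnosis"``, ``"medication_history"`` and
    ``"medication_current"``; sex, age, z-scaled BMI and hippocampal
    volume are always included.  ``standardize`` switches continuous
    predictors from median-centered-only to fully standardized.
    """

    outcome: str = "pvsvf_cso"
    form: str = "main"
    biomarker: str = "crp"
    extra_covariates: list[str] = field(default_factory=list)
    subgroup: str = "ALL"
    standardize: bool = False

    def validate(self) -> None:
        if self.outcome not in ("pvsvf_cso", "pvsvf_bg"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.form not in ("main", "cortisol_interaction", "ace_interaction"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.biomarker not in design.BIOMARKERS:
            raise ValueError(f"unknown biomarker {self.biomarker!r}")
        if self.subgroup not in ("ALL", "CN", "MCI", "AD"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        for cov in self.extra_covariates:
            if cov not in _EXTRA_COVARIATES:
                raise ValueError(f"unknown extra covariate {cov!r}")

    @property
    def exposure(self) -> str | None:
        if self.form == "cortisol_interaction":
            return "cortisol"
        if self.form == "ace_interaction":
            return "ace"
        return None

    @property
    def terms(self) -> list[str]:
        """Model terms in reporting order (intercept first)."""
        t = ["intercept"]
        if self.form == "main":
            t.append(self.biomarker)
        else:
            exp = self.exposure
            t += [exp, self.biomarker, f"{exp}:{self.biomarker}"]
        t += _BASE_COVARIATES
        for cov in self.extra_covariates:
            t += _EXTRA_COVARIATES[cov]
        return t

    def label(self) -> str:
        bits = [self.outcome, self.form, self.biomarker]
        if self.subgroup != "ALL":
            bits.append(self.subgroup)
        return "/".join(bits)


def prepare_design(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Build (X, y) for one model.

    Subjects missing any required field are dropped (listwise deletion)
    with a logged count; continuous predictors are median-centered on
    the analysis sample (and scaled when ``spec.standardize``), the
    interaction column is the product of the two centered terms.
    Raises on a zero-variance predictor column.
    """
    spec.validate()
    df = cohort
    if spec.subgroup != "ALL":
        df = df[df["diagnosis"] == spec.subgroup]

    raw_needed = {"bmi", "sex", "age", "hippocampal_volume", spec.outcome, spec.biomarker}
    if spec.exposure:
        raw_needed.add(spec.exposure)
    for cov in spec.extra_covariates:
        raw_needed.add({"apoe4": "apoe4_copies",
                        "diagnosis": "diagnosis",
                        "medication_history": "medication_history",
                        "medication_current": "medication_current"}[cov])
    missing_cols = raw_needed - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {sorted(missing_cols)}")

    complete = df.dropna(subset=sorted(raw_needed))
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("%s: dropped %d subjects with missing fields", spec.label(), n_dropped)

    prepared = design.prepare_columns(complete, standardize=spec.standardize)
    X = pd.DataFrame(index=complete.index)
    for term in spec.terms:
        col = design.term_column(prepared, term)
        if term != "intercept" and float(np.std(col)) == 0.0:
            raise ValueError(f"zero-variance column: {term}")
        X[term] = col
    y = complete[spec.outcome].astype(float)
    return X, y


@dataclass
class GLMFit:
    """A fitted Gamma/log-link GLM."""

    names: list[str]
    b: np.ndarray             # log-scale coefficients
    se: np.ndarray            # standard errors (log scale)
    cov: np.ndarray           # coefficient covariance (log scale)
    dispersion: float         # Pearson chi-square / (n - p)
    loglik: float
    converged: bool
    n: int
    n_iter: int
    _y: np.ndarray = field(repr=False, default=None)
    _mu: np.ndarray = field(repr=False, default=None)

    @property
    def exp_b(self) -> np.ndarray:
        return np.exp(self.b)

    @property
    def zvalues(self) -> np.ndarray:
        return self.b / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.zvalues))

    def coef(self, name: str) -> float:
        return float(self.b[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        """Per-coefficient table in the published layout: exponentiated
        estimate ('std. Beta'), SE on both scales, Wald p."""
        return pd.DataFrame({
            "term": self.names,
            "b": self.b,
            "std_beta": self.exp_b,          # exponentiated coefficient
            "se": self.se,                   # log scale
            "se_exp": self.exp_b * self.se,  # delta-method, response-ratio scale
            "z": self.zvalues,
            "p": self.pvalues,
        })


def fit_gamma_glm(X, y, tol: float = 1e-8, max_iter: int = 100) -> GLMFit:
    """Fit a Gamma GLM with log link by IRLS.

    For the log link the working weights are constant, so each update
    solves OLS on the working response ``z = eta + (y - mu)/mu``.
    Convergence is declared when ``max|db| < tol`` (coefficient change),
    within ``max_iter`` iterations; the ``converged`` flag records the
    outcome.  Dispersion is the Pearson estimator; standard errors come
    from the scaled inverse Fisher information.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if Xm.ndim != 2 or Xm.shape[0] != yv.shape[0]:
        raise ValueError("X and y are incompatible")
    if np.any(yv <= 0) or not np.all(np.isfinite(yv)):
        raise ValueError("Gamma responses must be strictly positive and finite")
    n, p = Xm.shape
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("design matrix is rank deficient")

    q, r = np.linalg.qr(Xm)
    # start from the log-response least-squares solution
    b = np.linalg.solve(r, q.T @ np.log(yv))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ b
        mu = np.exp(eta)
        z = eta + (yv - mu) / mu
        b_new = np.linalg.solve(r, q.T @ z)
        step = np.max(np.abs(b_new - b))
        b = b_new
        if step < tol:
            converged = True
            break

    eta = Xm @ b
    mu = np.exp(eta)
    pearson = float(np.sum(((yv - mu) / mu) ** 2))
    dof = n - p
    dispersion = pearson / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(r.T @ r)
    cov = dispersion * xtx_inv
    se = np.sqrt(np.diag(cov))
    # Gamma log-likelihood at the moment-matched shape k = 1/dispersion
    if dispersion and np.isfinite(dispersion) and dispersion > 0:
        k = 1.0 / dispersion
        loglik = float(np.sum(
            k * np.log(k * yv / mu) - k * yv / mu - np.log(yv) - special.gammaln(k)
        ))
    else:
        loglik = np.inf
    return GLMFit(names=names, b=b, se=se, cov=cov, dispersion=dispersion,
                  loglik=loglik, converged=converged, n=n, n_iter=it,
                  _y=yv, _mu=mu)


def run_model_suite(
    cohort: pd.DataFrame,
    specs: list[ModelSpec],
    outlier_k: float | None = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit a list of models on the post-outlier-filter sample.

    Subjects whose PVS volume fraction falls outside the IQR fence in
    either region are excluded from every model (one analysis sample).
    Returns a tidy table with one row per coefficient per model.
    Subgroup models with too few subjects (< p + 2) are skipped with a
    logged reason.
    """
    from .quantify import iqr_outlier_filter

    df = cohort.reset_index(drop=True)
    if outlier_k is not None:
        flagged_any = np.zeros(len(df), dtype=bool)
        for col in ("pvsvf_cso", "pvsvf_bg"):
            if col in df.columns:
                _, flagged = iqr_outlier_filter(df[col].to_numpy(), k=outlier_k)
                flagged_any[flagged] = True
        n_out = int(flagged_any.sum())
        if n_out:
            logger.info("outlier filter: excluded %d subjects", n_out)
        df = df.loc[~flagged_any]

    rows = []
    for i, spec in enumerate(specs):
        X, y = prepare_design(df, spec)
        if len(y) < X.shape[1] + 2:
            logger.warning("skipping %s: n=%d too small for p=%d",
                           spec.label(), len(y), X.shape[1])
            continue
        fit = fit_gamma_glm(X, y)
        summary = fit.summary_frame()
        summary.insert(0, "model", spec.label())
        summary.insert(1, "outcome", spec.outcome)
        summary.insert(2, "form", spec.form)
        summary.insert(3, "biomarker", spec.biomarker)
        summary.insert(4, "subgroup", spec.subgroup)
        summary["n"] = fit.n
        summary["converged"] = fit.converged
        summary["significant"] = summary["p"] < alpha
        rows.append(summary)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def fitted_interaction_curves(
    fit: GLMFit,
    spec: ModelSpec,
    moderator_levels: dict[str, float],
    physio_grid: np.ndarray,
    z_crit: float = 1.96,
) -> dict[str, pd.DataFrame]:
    """Model-fitted exposure curves at fixed moderator levels.

    ``physio_grid`` and the moderator levels are on the *prepared*
    (centered) scale: 0 is the sample median.  All covariates sit at
    their reference (centered continuous at 0, indicators at 0), so at
    grid point 0 with the moderator at its median the fitted mean is
    ``exp(b0)``.  The band is ``exp(x'b +/- z * sqrt(x' Cov x))``.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to draw curves")
    if spec.form == "main":
        raise ValueError("interaction curves need an interaction model")
    exposure = spec.exposure
    inter = f"{exposure}:{spec.biomarker}"
    for needed in (exposure, spec.biomarker, inter):
        if needed not in fit.names:
            raise ValueError(f"fit lacks term {needed!r}")
    grid = np.asarray(physio_grid, dtype=float)
    curves: dict[str, pd.DataFrame] = {}
    for level_name, level in moderator_levels.items():
        Xg = np.zeros((grid.size, len(fit.names)))
        Xg[:, fit.names.index("intercept")] = 1.0
        Xg[:, fit.names.index(exposure)] = grid
        Xg[:, fit.names.index(spec.biomarker)] = level
        Xg[:, fit.names.index(inter)] = grid * level
        eta = Xg @ fit.b
        var = np.einsum("ij,jk,ik->i", Xg, fit.cov, Xg)
        half = z_crit * np.sqrt(np.maximum(var, 0.0))
        curves[level_name] = pd.DataFrame({
            "exposure_centered": grid,
            "mu": np.exp(eta),
            "lo": np.exp(eta - half),
            "hi": np.exp(eta + half),
        })
    return curves


def residual_diagnostics(fit: GLMFit) -> dict:
    """Deviance residuals with normality summaries.

    Returns the residuals, their skewness and excess kurtosis, and a
    normal-quantile table (theoretical vs sample quantiles) suitable for
    a QQ plot.  The published analyses eyeball these residuals for
    approximate normality; strong skew signals a misspecified response
    distribution.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    y, mu = fit._y, fit._mu
    unit_dev = 2.0 * (-np.log(y / mu) + (y - mu) / mu)
    resid = np.sign(y - mu) * np.sqrt(np.maximum(unit_dev, 0.0))
    order = np.sort(resid)
    n = resid.size
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    sd = resid.std(ddof=1)
    qq = pd.DataFrame({
        "theoretical": theo,
        "sample": order,
        "standardized_sample": (order - resid.mean()) / sd if sd > 0 else order * 0.0,
    })
    return {
        "deviance_residuals": resid,
        "skewness": float(sps.skew(resid)) if sd > 0 else 0.0,
        "excess_kurtosis": float(sps.kurtosis(resid)) if sd > 0 else 0.0,
        "qq": qq,
    }
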