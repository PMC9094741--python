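"""Method-agreement and regression statistics, plus the closed-form oracle.

Implements the comparison between device-estimated and transit-time PWV:
quadratic regressions with a single standardized beta for the composite
age polynomial, variance explained by age alone, Bland-Altman bias
analysis with an age trend, partial correlation given age, and Lilliefors-
corrected Kolmogorov-Smirnov normality checks.

The variance-decomposition oracle evaluates the generator's population
moments in closed form (exact truncated-normal age moments), providing an
independent benchmark for Monte-Carlo pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
import statsmodels.api as sm

from .cohort import (ModelConstants, PresetSpec, age_distribution,
                     calibrate_models, map_intercept)
from .errors import (DegenerateInputError, InvalidInputError,
                     SingularDesignError, UndefinedCorrelationError,
                     UnsupportedModelError)

__all__ = [
    "RegressionSummary",
    "AgreementSummary",
    "OracleReport",
    "quadratic_model",
    "r_squared_age_alone",
    "bland_altman",
    "partial_correlation_given_age",
    "ks_normality",
    "variance_decomposition_oracle",
]


@dataclass
class RegressionSummary:
    outcome: str
    predictors: list[str]
    coefficients: dict[str, float]        # raw OLS, includes "intercept"
    standardized_betas: dict[str, float]  # composite "age" + covariates
    r_squared: float
    p_values: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "predictors": self.predictors,
                "coefficients": self.coefficients,
                "standardized_betas": self.standardized_betas,
                "r_squared": self.r_squared, "p_values": self.p_values,
                "n": self.n}


@dataclass
class AgreementSummary:
    mean_difference: float       # m/s, estimated - measured
    sd_difference: float
    limits_of_agreement: tuple[float, float]
    diff_vs_age_slope: float     # m/s per year
    diff_vs_age_r_squared: float
    partial_r_given_age: float
    partial_p: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_difference": self.mean_difference,
                "sd_difference": self.sd_difference,
                "limits_of_agreement": list(self.limits_of_agreement),
                "diff_vs_age_slope": self.diff_vs_age_slope,
                "diff_vs_age_r_squared": self.diff_vs_age_r_squared,
                "partial_r_given_age": self.partial_r_given_age,
                "partial_p": self.partial_p, "n": self.n}


@dataclass
class OracleReport:
    """Closed-form population expectations for a calibrated preset."""

    preset: str
    e_estimated: float
    e_measured: float
    r2_est_age: float
    r2_meas_age: float
    r2_est_meas: float
    e_difference: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("preset", "e_estimated", "e_measured", "r2_est_age",
                 "r2_meas_age", "r2_est_meas", "e_difference")}


def _clean_xy(*arrays) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float) for a in arrays]
    n = {len(a) for a in out}
    if len(n) != 1:
        raise InvalidInputError(f"length mismatch: {sorted(len(a) for a in out)}")
    return out


def quadratic_model(outcome, age, covariates: pd.DataFrame | dict | None = None,
                    outcome_name: str = "outcome") -> RegressionSummary:
    """OLS of outcome on {age, age^2, covariates}, with standardized betas.

    The fitted age polynomial c1*age + c2*age^2 is treated as one composite
    predictor for its single standardized beta (the convention under which
    a quadratic model reports one beta for "age").
    """
    y, a = _clean_xy(outcome, age)
    if len(y) < 10:
        raise InvalidInputError(f"need n >= 10, got {len(y)}")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(a)):
        raise InvalidInputError("missing values are not allowed")
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame(index=range(len(y)))
    cov_cols = list(cov.columns)
    cov_num = cov.copy()
    for c in cov_cols:
        if cov_num[c].dtype == object:
            # encode binary categories (e.g. sex) as 0/1
            cats = sorted(cov_num[c].unique())
            cov_num[c] = cov_num[c].map({v: i for i, v in enumerate(cats)})
    X = np.column_stack([a, a**2] + [cov_num[c].to_numpy(dtype=float) for c in cov_cols])
    names = ["age", "age_sq"] + cov_cols
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    fit = sm.OLS(y, Xc).fit()

    coefficients = {"intercept": float(fit.params[0])}
    p_values = {}
    for i, name in enumerate(names, start=1):
        coefficients[name] = float(fit.params[i])
        p_values[name] = float(fit.pvalues[i])

    # composite age predictor for the standardized beta
    composite = coefficients["age"] * a + coefficients["age_sq"] * a**2
    def z(v):
        s = np.std(v, ddof=1)
        if s == 0:
            raise SingularDesignError("constant predictor; cannot standardize")
        return (v - np.mean(v)) / s
    Zcols = [z(composite)] + [z(cov_num[c].to_numpy(dtype=float)) for c in cov_cols]
    Z = sm.add_constant(np.column_stack(Zcols), has_constant="add")
    zfit = sm.OLS(z(y), Z).fit()
    standardized = {"age": float(zfit.params[1])}
    for i, c in enumerate(cov_cols, start=2):
        standardized[c] = float(zfit.params[i])

    return RegressionSummary(outcome=outcome_name,
                             predictors=["age", "age_sq"] + cov_cols,
                             coefficients=coefficients,
                             standardized_betas=standardized,
                             r_squared=float(fit.rsquared),
                             p_values=p_values, n=len(y))


def r_squared_age_alone(outcome, age) -> float:
    """R^2 of the quadratic-in-age-only model."""
    return quadratic_model(outcome, age).r_squared


def bland_altman(estimated, measured, age) -> AgreementSummary:
    """Bland-Altman agreement of estimated vs measured PWV, with age trend."""
    est, meas, a = _clean_xy(estimated, measured, age)
    if len(est) < 3:
        raise InvalidInputError(f"need n >= 3 pairs, got {len(est)}")
    diff = est - meas
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    loa = (mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff)
    if np.ptp(a) > 0 and sd_diff > 0:
        reg = sps.linregress(a, diff)
        slope, r2 = float(reg.slope), float(reg.rvalue**2)
    else:
        slope, r2 = 0.0, 0.0
    try:
        r, p = partial_correlation_given_age(est, meas, a)
    except (UndefinedCorrelationError, InvalidInputError):
        r, p = np.nan, np.nan
    return AgreementSummary(mean_difference=mean_diff, sd_difference=sd_diff,
                            limits_of_agreement=loa, diff_vs_age_slope=slope,
                            diff_vs_age_r_squared=r2, partial_r_given_age=r,
                            partial_p=p, n=len(est))


def partial_correlation_given_age(x, y, age) -> tuple[float, float]:
    """Pearson correlation of x and y after removing {age, age^2} from both.

    p-value from the t distribution with n - 4 degrees of freedom (two
    quadratic-regression parameters plus the intercept are consumed).
    """
    xv, yv, a = _clean_xy(x, y, age)
    n = len(xv)
    if n < 5:
        raise InvalidInputError(f"need n >= 5, got {n}")
    design = np.column_stack([np.ones(n), a, a**2])
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    scale = max(float(np.std(xv)), float(np.std(yv)), 1.0)
    if np.std(rx) < 1e-8 * scale or np.std(ry) < 1e-8 * scale:
        raise UndefinedCorrelationError("residuals are constant given age")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 4
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def ks_normality(values, lilliefors_correction: bool = True) -> dict:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    Uses the Lilliefors correction by default (the distribution parameters
    are estimated from the sample); the plain KS p-value is available via
    ``lilliefors_correction=False``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise InvalidInputError(f"need n >= 5, got {len(v)}")
    if np.std(v) == 0:
        raise DegenerateInputError("constant sample; normality undefined")
    if lilliefors_correction:
        stat, p = lilliefors(v, dist="norm")
    else:
        stat, p = sps.kstest(v, "norm", args=(np.mean(v), np.std(v, ddof=1)))
    return {"statistic": float(stat), "p": float(p),
            "normal_flag": bool(p > 0.05)}


def variance_decomposition_oracle(preset: PresetSpec,
                                  model: ModelConstants | None = None
                                  ) -> OracleReport:
    """Closed-form expectations for a preset under the calibrated generator.

    Uses exact truncated-normal age moments; the quadratic surrogate's
    variance decomposes via Var(a^2) = E[a^4] - E[a^2]^2 and
    Cov(a, a^2) = E[a^3] - E[a]E[a^2] (the normal-moment identities
    4*mu^2*sigma^2 + 2*sigma^4 and 2*mu*sigma^2 are the untruncated limit).
    """
    model = model or calibrate_models()
    if preset.age_sd == 0 or preset.map_sigma == 0:
        raise UnsupportedModelError(
            f"preset {preset.name!r} is degenerate; population R^2 undefined")
    dist = age_distribution(preset)
    m1, m2, m3, m4 = (float(dist.moment(k)) for k in range(1, 5))
    var_a = m2 - m1**2
    cov_a_a2 = m3 - m1 * m2
    var_a2 = m4 - m2**2

    l1 = model.c1 + model.map_slope * model.c3  # age slope incl. BP pathway
    vp = l1**2 * var_a + model.c2**2 * var_a2 + 2.0 * l1 * model.c2 * cov_a_a2
    noise = model.c3**2 * preset.map_sigma**2 + model.device_noise_var
    var_est = vp + noise
    m0 = map_intercept(preset, model)
    e_est = (model.c0 + model.c1 * m1 + model.c2 * m2
             + model.c3 * (m0 + model.map_slope * m1 - 90.0))

    var_meas = model.g1**2 * var_a + model.sigma_v**2
    e_meas = model.g0 + model.g1 * m1
    cov_em = model.g1 * (l1 * var_a + model.c2 * cov_a_a2)
    if var_est <= 0 or var_meas <= 0:
        raise UnsupportedModelError("degenerate variances in oracle")
    return OracleReport(preset=preset.name,
                        e_estimated=float(e_est), e_measured=float(e_meas),
                        r2_est_age=float(vp / var_est),
                        r2_meas_age=float(model.g1**2 * var_a / var_meas),
                        r2_est_meas=float(cov_em**2 / (var_est * var_meas)),
                        e_difference=float(e_est - e_meas))
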