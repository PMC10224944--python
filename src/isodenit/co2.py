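"""CO2 sensitivity of plant production (beta_NPP) by detrended-residual regression.

In historical simulations T, P and CO2 all trend upward together, so a
joint regression of NPP on the three is ill-conditioned.  The two-stage
procedure breaks the collinearity: (1) regress detrended NPP on detrended
T and P to get climate sensitivities alpha_T, alpha_P; (2) subtract
alpha_T*T + alpha_P*P + alpha_const from the raw NPP series and regress
the residual on CO2.  The slope is beta_NPP, reported as percent of
period-mean NPP per ppm.  Across models, beta_NPP is regressed on f_denit
to test whether overestimated denitrification exaggerates N limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegionalSeries:
    """Annual regional aggregates of NPP, T, P and the CO2 trajectory."""

    years: np.ndarray
    npp: np.ndarray
    t: np.ndarray
    p: np.ndarray
    co2: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        n = len(self.years)
        if n < 10:
            raise ValueError("need at least 10 years")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        for name in ("npp", "t", "p", "co2"):
            arr = np.asarray(getattr(self, name), float)
            if len(arr) != n:
                raise ValueError(f"series '{name}' length != years length")
            setattr(self, name, arr)

    @classmethod
    def from_csv(cls, path) -> "RegionalSeries":
        df = pd.read_csv(path)
        return cls(df["year"], df["npp"], df["t"], df["p"], df["co2"])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"year": self.years, "npp": self.npp, "t": self.t,
             "p": self.p, "co2": self.co2}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BetaEstimate:
    """beta_NPP with the first-stage climate sensitivities.

    beta_pct = 100 * beta_raw / period-mean NPP, in % per ppm.
    """

    alpha_t: float
    alpha_p: float
    alpha_const: float
    beta_raw: float
    beta_pct: float
    se_beta: float
    n: int

    def ci95(self) -> tuple[float, float]:
        """95% confidence interval on beta_raw (t distribution, n-2 df)."""
        half = stats.t.ppf(0.975, self.n - 2) * self.se_beta
        return (self.beta_raw - half, self.beta_raw + half)


def detrend(series: np.ndarray, years: np.ndarray | None = None) -> np.ndarray:
    """Residuals from an OLS linear fit against time."""
    y = np.asarray(series, float)
    x = np.arange(len(y)) if years is None else np.asarray(years, float)
    coeffs = np.polyfit(x, y, 1)
    return y - np.polyval(coeffs, x)


def fit_climate_sens(
    npp_de: np.ndarray, t_de: np.ndarray, p_de: np.ndarray
) -> tuple[float, float, float]:
    """OLS of detrended NPP on detrended T and P: (alpha_t, alpha_p, alpha_const)."""
    X = sm.add_constant(np.column_stack([t_de, p_de]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "detrended T and P are collinear; climate sensitivities not identifiable"
        )
    fit = sm.OLS(np.asarray(npp_de, float), X).fit()
    return float(fit.params[1]), float(fit.params[2]), float(fit.params[0])


def npp_residual(
    npp: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    alphas: tuple[float, float, float],
) -> np.ndarray:
    """NPP minus the climate terms: NPP - alpha_t*T - alpha_p*P - alpha_const.

    Computed on the raw (not detrended) series: the CO2-driven trend must
    survive into the residual.
    """
    alpha_t, alpha_p, alpha_const = alphas
    return (
        np.asarray(npp, float)
        - alpha_t * np.asarray(t, float)
        - alpha_p * np.asarray(p, float)
        - alpha_const
    )


def fit_beta(
    residual: np.ndarray, co2: np.ndarray, mean_npp: float
) -> BetaEstimate:
    """OLS of the NPP residual on CO2; slope is beta_NPP."""
    co2 = np.asarray(co2, float)
    if np.var(co2) == 0:
        raise ValueError("CO2 series has zero variance")
    if mean_npp == 0:
        raise ValueError("mean NPP is zero; percent normalization undefined")
    fit = sm.OLS(np.asarray(residual, float), sm.add_constant(co2)).fit()
    beta = float(fit.params[1])
    return BetaEstimate(
        alpha_t=np.nan,
        alpha_p=np.nan,
        alpha_const=np.nan,
        beta_raw=beta,
        beta_pct=100.0 * beta / float(mean_npp),
        se_beta=float(fit.bse[1]),
        n=len(co2),
    )


def beta_pipeline(series, years: tuple[int, int] | None = None) -> BetaEstimate:
    """Full two-stage beta_NPP estimate for one model's regional series.

    ``series`` is any object with ``years``, ``npp``, ``t``, ``p``,
    ``co2`` arrays (a :class:`RegionalSeries` or an ESM bundle).  ``years``
    optionally restricts to an inclusive (start, end) window.
    """
    yr = np.asarray(series.years, int)
    sel = (
        slice(None)
        if years is None
        else (yr >= years[0]) & (yr <= years[1])
    )
    npp, t, p, co2 = (
        np.asarray(a, float)[sel]
        for a in (series.npp, series.t, series.p, series.co2)
    )
    yr = yr[sel]
    npp_de, t_de, p_de = detrend(npp, yr), detrend(t, yr), detrend(p, yr)
    alphas = fit_climate_sens(npp_de, t_de, p_de)
    residual = npp_residual(npp, t, p, alphas)
    est = fit_beta(residual, co2, float(np.mean(npp)))

    # First-stage uncertainty leaks into the residual: the error in each
    # alpha multiplies that regressor's CO2-trend component.  Fold it into
    # the slope SE so the CI reflects the full two-stage uncertainty.
    stage1 = sm.OLS(npp_de, sm.add_constant(np.column_stack([t_de, p_de]))).fit()
    se_at, se_ap = float(stage1.bse[1]), float(stage1.bse[2])
    b_t = float(sm.OLS(t, sm.add_constant(co2)).fit().params[1])
    b_p = float(sm.OLS(p, sm.add_constant(co2)).fit().params[1])
    se_total = float(np.sqrt(est.se_beta**2 + (se_at * b_t) ** 2 + (se_ap * b_p) ** 2))
    return replace(
        est,
        alpha_t=alphas[0], alpha_p=alphas[1], alpha_const=alphas[2],
        se_beta=se_total,
    )


@dataclass(frozen=True)
class CrossModelFit:
    """Across-model regression of beta_NPP on f_denit with 95% CI band."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    x: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def cross_model_regression(
    betas: np.ndarray, fdenits: np.ndarray, n_grid: int = 50
) -> CrossModelFit:
    """OLS of beta_NPP against f_denit across models, with slope t-test.

    The CI band is the 95% confidence interval of the regression mean at
    each abscissa.
    """
    y = np.asarray(betas, float)
    x = np.asarray(fdenits, float)
    if len(x) < 3:
        raise ValueError("need at least 3 models (p-value undefined otherwise)")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    xg = np.linspace(x.min(), x.max(), n_grid)
    band = fit.get_prediction(sm.add_constant(xg)).conf_int(alpha=0.05)
    return CrossModelFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        x=xg,
        ci_low=band[:, 0],
        ci_high=band[:, 1],
    )
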