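"""Age-normative regression of regional T1 with percentile bands.

Five candidate regression families relate T1 to age x (years):

* linear            T1 = a*x + b
* logarithmic       T1 = a*ln(x) + b
* square_root       T1 = a*sqrt(x) + b
* exponential       T1 = a*exp(-x/tau) + b     (tau on a log grid)
* power_n10         T1 = a*x^(-n/10) + b       (integer n, exhaustive grid)

Each family is an ordinary least-squares fit of T1 on the transformed
covariate; the power family's "hyperbolic transformation" makes the
fractional-power law linear in (a, b).  Model comparison uses the adjusted
coefficient of determination.  Normative 2.5th/97.5th percentile bands are
population bands: prediction +/- z_0.975 times the residual SD, constant in
age (residuals are assumed normal; a Shapiro-Wilk p-value is reported as a
numeric surrogate of the quantile-plot check, without gating anything).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FAMILIES",
    "NormativeFit",
    "design_covariate",
    "fit_family",
    "select_model",
    "percentile_bands",
    "parameter_recovery_report",
]

FAMILIES = ("linear", "logarithmic", "square_root", "exponential", "power_n10")
#: Tie-break priority for model selection (first wins on exact ties).
_SELECTION_ORDER = ("power_n10", "exponential", "logarithmic", "square_root", "linear")

Z_975 = 1.959964  # standard-normal 97.5th percentile
N_GRID = range(1, 31)  # exponent grid: r = -n/10, n = 1..30
TAU_GRID = tuple(np.geomspace(0.1, 20.0, 41))  # years
#: Best adjusted R^2 below this flags a region as age-independent.
AGE_INDEPENDENT_ADJ_R2 = 0.2


@dataclass(frozen=True)
class NormativeFit:
    """One fitted age model for one region."""

    region: str
    family: str
    a: float  # slope on the transformed covariate
    b: float  # intercept
    n_tenths: int | None  # power_n10 only: exponent r = -n/10
    tau_years: float | None  # exponential only: decay constant
    adj_r2: float
    residual_sd_ms: float
    n_obs: int
    shapiro_p: float

    @property
    def age_independent(self) -> bool:
        """True when even the best family explains almost nothing."""
        return self.adj_r2 < AGE_INDEPENDENT_ADJ_R2

    def predict(self, ages) -> np.ndarray:
        x = design_covariate(ages, self.family, n=self.n_tenths, tau=self.tau_years)
        return self.a * x + self.b


def design_covariate(age_years, family: str, n: int | None = None,
                     tau: float | None = None) -> np.ndarray:
    """Transformed age covariate for one regression family."""
    x = np.asarray(age_years, dtype=float)
    if np.any(x <= 0):
        raise ValueError("age must be positive")
    if family == "linear":
        out = x
    elif family == "logarithmic":
        out = np.log(x)
    elif family == "square_root":
        out = np.sqrt(x)
    elif family == "power_n10":
        if n is None:
            raise ValueError("power_n10 requires n")
        out = x ** (-n / 10.0)
    elif family == "exponential":
        if tau is None:
            raise ValueError("exponential requires tau")
        out = np.exp(-x / tau)
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(out) if np.isscalar(age_years) else out


def _ols(x: np.ndarray, y: np.ndarray):
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate (zero variance)")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = res.params  # intercept, slope
    rss = float(res.ssr)
    adj = float(res.rsquared_adj)
    if not np.isfinite(adj):  # constant response: nothing to explain
        adj = 0.0
    return a, b, adj, rss, res.resid


def fit_family(ages, t1_values, family: str, region: str = "") -> NormativeFit:
    """OLS of T1 on the family's transformed covariate.

    For ``power_n10`` the integer exponent grid n = 1..30 is searched
    exhaustively and the n with maximal adjusted R^2 wins (ties -> smaller
    n); the exponential decay constant is likewise selected on a fixed
    logarithmic tau grid.  residual_sd = sqrt(RSS / (n_obs - 2)).
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(t1_values, dtype=float)
    if ages.size != y.size or ages.size < 4:
        raise ValueError("need >= 4 paired observations")
    n_sel: int | None = None
    tau_sel: float | None = None
    if family == "power_n10":
        best = None
        for n in N_GRID:
            fit = _ols(design_covariate(ages, family, n=n), y)
            if best is None or fit[2] > best[0][2] + 1e-15:
                best = (fit, n)
        fit, n_sel = best
    elif family == "exponential":
        best = None
        for tau in TAU_GRID:
            f = _ols(design_covariate(ages, family, tau=tau), y)
            if best is None or f[2] > best[0][2] + 1e-15:
                best = (f, tau)
        fit, tau_sel = best
    else:
        fit = _ols(design_covariate(ages, family), y)
    a, b, adj_r2, rss, resid = fit
    residual_sd = float(np.sqrt(rss / (ages.size - 2)))
    shapiro_p = float(stats.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 1.0
    return NormativeFit(
        region=region, family=family, a=a, b=b,
        n_tenths=n_sel, tau_years=tau_sel,
        adj_r2=adj_r2, residual_sd_ms=residual_sd,
        n_obs=int(ages.size), shapiro_p=shapiro_p,
    )


def select_model(ages, t1_values, region: str = "") -> NormativeFit:
    """Fit all five families and return the best by adjusted R^2.

    Exact ties resolve by the fixed priority power_n10 > exponential >
    logarithmic > square_root > linear.
    """
    best: NormativeFit | None = None
    for family in _SELECTION_ORDER:
        fit = fit_family(ages, t1_values, family, region=region)
        if best is None or fit.adj_r2 > best.adj_r2:
            best = fit
    return best


def percentile_bands(fit: NormativeFit, ages) -> pd.DataFrame:
    """Normative mean curve with 2.5th/97.5th percentile bands.

    Bands are prediction +/- 1.959964 * residual SD — population percentile
    bands of constant half-width, not standard-error confidence bands.
    """
    ages = np.asarray(ages, dtype=float)
    mean = fit.predict(ages)
    half = Z_975 * fit.residual_sd_ms
    return pd.DataFrame(
        {
            "age_years": ages,
            "mean_t1_ms": mean,
            "p2_5_ms": mean - half,
            "p97_5_ms": mean + half,
        }
    )


def parameter_recovery_report(
    regions, fits: dict[str, NormativeFit]
) -> pd.DataFrame:
    """Generator-vs-fit comparison, one row per age-dependent region.

    ``regions`` is the cohort's region table; ``fits`` maps region name to
    its selected model.
    """
    rows = []
    for region in regions:
        if region.age_independent or region.name not in fits:
            continue
        fit = fits[region.name]
        rows.append(
            {
                "region": region.name,
                "true_n": region.n_tenths,
                "fitted_family": fit.family,
                "fitted_n": fit.n_tenths,
                "true_a": region.growth_a,
                "fitted_a": fit.a,
                "a_error": fit.a - region.growth_a if fit.family == "power_n10" else np.nan,
                "true_b": region.growth_b,
                "fitted_b": fit.b,
                "b_error": fit.b - region.growth_b if fit.family == "power_n10" else np.nan,
                "adj_r2": fit.adj_r2,
            }
        )
    return pd.DataFrame(rows)
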