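"""Method-comparison and calibration statistics.

Three estimators follow the scikit-learn protocol (``fit`` + trailing-
underscore fitted attributes, ``get_params``/``set_params``):

* :class:`FixedRatioCalibration` — tests whether two measurement methods
  differ by a constant multiplicative ratio by regressing log10 of one on
  log10 of the other: slope 1 means a fixed ratio and the intercept b gives
  the ratio as 10**b.
* :class:`StandardCurve` — straight-line calibration of cyanogen standard
  mass against meter ppm, with inverse prediction of mass from a reading.
* :class:`PolynomialTrendError` — precision of a measurement series that
  follows a smooth trend: a quartic is fitted and the RMSE is expressed as a
  percentage of the fitted curve's range.

Plain functions cover the published-data comparison (dry→fresh unit
conversion and the paired t-test across species means).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import DEFAULT_DRY_TO_FRESH_COMBINED_FACTOR
from .units import HCN_MOLAR_MASS, AMYGDALIN, ChamberSpec, CyanogenStandard, standard_hcn_mass

__all__ = [
    "RatioFit",
    "StdCurveFit",
    "PolyErrorResult",
    "PairedComparison",
    "DryFreshConversion",
    "FixedRatioCalibration",
    "StandardCurve",
    "PolynomialTrendError",
    "fixed_ratio_fit",
    "standard_curve_fit",
    "polynomial_error",
    "convert_published",
    "paired_species_comparison",
    "InsufficientDataError",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class RatioFit:
    slope: float
    slope_se: float
    intercept: float  # log10 scale
    ratio: float  # 10 ** intercept
    r_squared: float
    n_pairs: int
    p_slope_vs_zero: float
    p_slope_vs_one: float


@dataclass(frozen=True)
class StdCurveFit:
    slope_mg_per_ppm: float
    slope_ug_hcn_per_ppm: float
    intercept_mg: float
    r_squared: float
    n: int
    chamber: ChamberSpec


@dataclass(frozen=True)
class PolyErrorResult:
    degree: int
    rmse: float
    curve_range: float
    pct_error: float  # 100 * rmse / curve_range
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairedComparison:
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class DryFreshConversion:
    """Converts published μg HCN / g dry weight to μmol HCN / g fresh weight.

    ``combined_factor = dry_to_fresh_mass_ratio / hcn_molar_mass`` bundles an
    assumed tissue water content with the molar mass of HCN.
    """

    combined_factor: float = DEFAULT_DRY_TO_FRESH_COMBINED_FACTOR

    def __post_init__(self) -> None:
        ratio = self.dry_to_fresh_mass_ratio
        if not 0 < ratio < 1:
            raise ValueError(
                f"implied dry:fresh mass ratio {ratio:.4f} outside (0, 1)"
            )

    @property
    def dry_to_fresh_mass_ratio(self) -> float:
        return self.combined_factor * HCN_MOLAR_MASS


class FixedRatioCalibration(BaseEstimator):
    """Fixed-ratio method comparison via log-log ordinary least squares.

    ``fit(reference, new_method)`` regresses log10(new_method) on
    log10(reference).  A slope of 1 supports a constant ratio between the
    methods, estimated as ``ratio_ = 10 ** intercept_``.  Pairs in which
    either value is non-positive are dropped (log undefined) with a logged
    count.

    Attributes (after fit): ``slope_``, ``slope_se_``, ``intercept_``,
    ``ratio_``, ``r_squared_``, ``n_pairs_``, ``p_slope_vs_zero_``,
    ``p_slope_vs_one_``, ``n_dropped_``.
    """

    def __init__(self, min_pairs: int = 3):
        self.min_pairs = min_pairs

    def fit(self, reference, new_method) -> "FixedRatioCalibration":
        x = np.asarray(reference, float).ravel()
        y = np.asarray(new_method, float).ravel()
        if x.shape != y.shape:
            raise ValueError("reference and new_method must have equal length")
        keep = (x > 0) & (y > 0)
        self.n_dropped_ = int((~keep).sum())
        if self.n_dropped_:
            logger.warning(
                "dropping %d pair(s) with non-positive values from log-log fit",
                self.n_dropped_,
            )
        x, y = x[keep], y[keep]
        if x.size < self.min_pairs:
            raise InsufficientDataError(
                f"need at least {self.min_pairs} positive pairs, have {x.size}"
            )
        res = sm.OLS(np.log10(y), sm.add_constant(np.log10(x))).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.slope_se_ = float(res.bse[1])
        self.ratio_ = 10.0 ** self.intercept_
        self.r_squared_ = float(res.rsquared)
        self.n_pairs_ = int(x.size)
        df = self.n_pairs_ - 2
        self.p_slope_vs_zero_ = float(res.pvalues[1])
        if self.slope_se_ > 0:
            t1 = (self.slope_ - 1.0) / self.slope_se_
            self.p_slope_vs_one_ = float(2 * stats.t.sf(abs(t1), df)) if df > 0 else math.nan
        else:
            self.p_slope_vs_one_ = 0.0 if self.slope_ != 1.0 else 1.0
        return self

    def result_(self) -> RatioFit:
        check_is_fitted(self, "ratio_")
        return RatioFit(
            slope=self.slope_,
            slope_se=self.slope_se_,
            intercept=self.intercept_,
            ratio=self.ratio_,
            r_squared=self.r_squared_,
            n_pairs=self.n_pairs_,
            p_slope_vs_zero=self.p_slope_vs_zero_,
            p_slope_vs_one=self.p_slope_vs_one_,
        )


class StandardCurve(BaseEstimator):
    """Linear calibration of cyanogen standard mass (mg) on meter ppm.

    After fitting, ``predict(ppm)`` returns the expected standard mass and
    ``predict_mass`` is its alias for inverse use: reading off the cyanogen
    (or, scaled by the standard's stoichiometry, HCN) mass that a ppm value
    corresponds to in the fitted chamber.
    """

    def __init__(self, standard: CyanogenStandard = AMYGDALIN):
        self.standard = standard

    def fit(self, ppm, mass_mg, chamber: ChamberSpec | None = None) -> "StandardCurve":
        x = np.asarray(ppm, float).ravel()
        y = np.asarray(mass_mg, float).ravel()
        if x.shape != y.shape:
            raise ValueError("ppm and mass arrays must have equal length")
        if x.size < 3:
            raise InsufficientDataError("need at least 3 calibration points")
        if (y < 0).any():
            raise ValueError("standard masses must be non-negative")
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError("all ppm values equal; calibration line is singular")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.r_squared_ = float(res.rsquared)
        self.n_ = int(x.size)
        self.chamber_ = chamber or ChamberSpec.cup()
        # μg HCN per ppm: scale the mg-cyanogen slope by HCN content per mg
        self.slope_ug_hcn_ = self.slope_ * standard_hcn_mass(1.0, self.standard)
        return self

    def predict(self, ppm) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * np.asarray(ppm, float)

    predict_mass = predict

    def result_(self) -> StdCurveFit:
        check_is_fitted(self, "slope_")
        return StdCurveFit(
            slope_mg_per_ppm=self.slope_,
            slope_ug_hcn_per_ppm=self.slope_ug_hcn_,
            intercept_mg=self.intercept_,
            r_squared=self.r_squared_,
            n=self.n_,
            chamber=self.chamber_,
        )


class PolynomialTrendError(BaseEstimator):
    """Repeatability of series data around a smooth positional trend.

    Fits a polynomial (default quartic) of value on position by ordinary
    least squares and reports the RMSE as a percentage of the fitted curve's
    range over the observed positions.  ``use_raw_range=True`` divides by the
    raw data range instead.
    """

    def __init__(self, degree: int = 4, use_raw_range: bool = False):
        self.degree = degree
        self.use_raw_range = use_raw_range

    def fit(self, positions, values) -> "PolynomialTrendError":
        x = np.asarray(positions, float).ravel()
        y = np.asarray(values, float).ravel()
        if x.shape != y.shape:
            raise ValueError("positions and values must have equal length")
        if np.unique(x).size < self.degree + 2:
            raise InsufficientDataError(
                f"need at least degree + 2 = {self.degree + 2} distinct positions"
            )
        coeffs = np.polynomial.polynomial.polyfit(x, y, self.degree)
        fitted = np.polynomial.polynomial.polyval(x, coeffs)
        resid = y - fitted
        n = x.size
        self.coefficients_ = coeffs
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.curve_range_ = float(np.ptp(y) if self.use_raw_range else np.ptp(fitted))
        self.pct_error_ = (
            100.0 * self.rmse_ / self.curve_range_ if self.curve_range_ > 0 else math.nan
        )
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
        k = self.degree
        df_resid = n - k - 1
        if df_resid > 0 and 0 <= self.r_squared_ < 1:
            f = (self.r_squared_ / k) / ((1 - self.r_squared_) / df_resid)
            self.p_value_ = float(stats.f.sf(f, k, df_resid))
        else:
            self.p_value_ = math.nan
        self.n_ = int(n)
        return self

    def result_(self) -> PolyErrorResult:
        check_is_fitted(self, "rmse_")
        return PolyErrorResult(
            degree=self.degree,
            rmse=self.rmse_,
            curve_range=self.curve_range_,
            pct_error=self.pct_error_,
            r_squared=self.r_squared_,
            p_value=self.p_value_,
            n=self.n_,
        )


def fixed_ratio_fit(method_a, method_b) -> RatioFit:
    """Fixed-ratio fit of method_a against method_b: ratio ≈ a / b."""
    return FixedRatioCalibration().fit(method_b, method_a).result_()


def standard_curve_fit(
    cyanogen_masses_mg,
    meter_ppm,
    chamber: ChamberSpec | None = None,
    standard: CyanogenStandard = AMYGDALIN,
) -> StdCurveFit:
    return StandardCurve(standard=standard).fit(meter_ppm, cyanogen_masses_mg, chamber).result_()


def polynomial_error(positions, values, degree: int = 4) -> PolyErrorResult:
    return PolynomialTrendError(degree=degree).fit(positions, values).result_()


def convert_published(dry_value_ug_per_g, conv: DryFreshConversion = DryFreshConversion()):
    """μg HCN / g dry weight → μmol HCN / g fresh weight."""
    v = np.asarray(dry_value_ug_per_g, float)
    if (v < 0).any():
        raise ValueError("published concentrations must be non-negative")
    out = v * conv.combined_factor
    return float(out) if out.ndim == 0 else out


def paired_species_comparison(published_means, cup_means) -> PairedComparison:
    """Paired t-test of published vs meter-derived species means, plus R².

    The difference is taken as (published - cup); the R² is from the OLS
    regression of one vector of species means on the other.
    """
    a = np.asarray(published_means, float).ravel()
    b = np.asarray(cup_means, float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("need at least 2 paired species means")
    d = a - b
    n = a.size
    if np.allclose(d, 0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a, b)
    res = sm.OLS(b, sm.add_constant(a)).fit()
    return PairedComparison(
        mean_difference=float(d.mean()),
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p),
        r_squared=float(res.rsquared),
        n=n,
    )
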