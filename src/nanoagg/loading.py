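"""Drug-loading and release-kinetics analytics.

Drug-loading capacity (DLC) is the weight of drug entrapped in the polymer
phase relative to the polymer weight; encapsulation efficiency (EE) is the
entrapped weight relative to the drug offered in the feed.  Both are
percentages.  Note that DLC and EE come from independent measurements of a
sample (entrapped vs. polymer mass, entrapped vs. feed mass) and a
(DLC, EE) pair reported for one preparation need not be mutually
consistent with a single set of masses.

Release curves are cumulative percent-released time series; the kinetic
fit models an initial zero-order (constant-rate) phase followed by a
saturating non-linear phase, with the changepoint chosen by residual
minimisation over candidate times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LoadingRecord",
    "CalibrationCurve",
    "ReleaseCurve",
    "KineticFit",
    "compute_dlc",
    "compute_ee",
    "loading_record",
    "absorbance_to_concentration",
    "cumulative_release",
    "fit_zero_order",
    "size_stats",
]


def compute_dlc(m_drug_entrapped: float, m_polymer: float) -> float:
    """DLC (%) = 100 * entrapped drug mass / polymer mass (same mass units)."""
    if m_polymer <= 0:
        raise ValueError("polymer mass must be positive")
    if m_drug_entrapped < 0:
        raise ValueError("entrapped drug mass cannot be negative")
    return 100.0 * m_drug_entrapped / m_polymer


def compute_ee(m_drug_entrapped: float, m_drug_feed: float) -> float:
    """EE (%) = 100 * entrapped drug mass / drug mass offered in the feed."""
    if m_drug_feed <= 0:
        raise ValueError("feed drug mass must be positive")
    if m_drug_entrapped < 0:
        raise ValueError("entrapped drug mass cannot be negative")
    if m_drug_entrapped > m_drug_feed:
        warnings.warn(
            "entrapped mass exceeds feed mass; EE > 100% indicates a "
            "measurement inconsistency", stacklevel=2,
        )
    return 100.0 * m_drug_entrapped / m_drug_feed


@dataclass(frozen=True)
class LoadingRecord:
    m_drug_feed: float  # mg
    m_polymer: float  # mg
    m_drug_entrapped: float  # mg
    dlc: float  # %
    ee: float  # %
    dlc_sd: float | None = None
    ee_sd: float | None = None


def loading_record(
    m_drug_feed: float, m_polymer: float, m_drug_entrapped: float,
) -> LoadingRecord:
    return LoadingRecord(
        m_drug_feed=m_drug_feed, m_polymer=m_polymer,
        m_drug_entrapped=m_drug_entrapped,
        dlc=compute_dlc(m_drug_entrapped, m_polymer),
        ee=compute_ee(m_drug_entrapped, m_drug_feed),
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear absorbance-vs-concentration calibration.

    ``slope`` is absorbance per (ug/mL); the valid range bounds the
    concentrations the calibration was established over.
    """

    slope: float
    intercept: float = 0.0
    range_low: float = 0.8  # ug/mL
    range_high: float = 6.0  # ug/mL
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.range_low >= self.range_high:
            raise ValueError("calibration range lower bound must be below the upper bound")

    def in_range(self, concentration: float) -> bool:
        return self.range_low <= concentration <= self.range_high

    @classmethod
    def from_standards(
        cls, concentrations, absorbances,
        range_low: float | None = None, range_high: float | None = None,
    ) -> "CalibrationCurve":
        """Least-squares calibration from standard solutions."""
        from scipy.stats import linregress

        c = np.asarray(concentrations, float)
        a = np.asarray(absorbances, float)
        fit = linregress(c, a)
        return cls(
            slope=float(fit.slope), intercept=float(fit.intercept),
            range_low=float(c.min() if range_low is None else range_low),
            range_high=float(c.max() if range_high is None else range_high),
            r_squared=float(fit.rvalue**2),
        )


def absorbance_to_concentration(
    a: float, cal: CalibrationCurve, warn_out_of_range: bool = True,
) -> float:
    """Invert the calibration: concentration (ug/mL) = (A - intercept)/slope."""
    c = (a - cal.intercept) / cal.slope
    if c < 0:
        raise ValueError(f"absorbance {a} is below the calibration blank")
    if warn_out_of_range and not cal.in_range(c) and c > 0:
        warnings.warn(
            f"concentration {c:.3g} ug/mL outside calibration range "
            f"[{cal.range_low}, {cal.range_high}] ug/mL", stacklevel=2,
        )
    return c


@dataclass
class ReleaseCurve:
    """Cumulative release (% of loaded drug) over time (h)."""

    times: np.ndarray
    released: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.released = np.asarray(self.released, float)
        if len(self.times) != len(self.released):
            raise ValueError("times and released must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def cumulative_release(
    samples, oil_volume_ml: float, loaded_mass_ug: float,
) -> ReleaseCurve:
    """Build a cumulative release curve from (time h, concentration ug/mL) samples.

    Percent released at time t is 100 * c(t) * V_oil / m_loaded.  The
    sampling protocol returns each aliquot to the vessel, so no depletion
    correction is applied.
    """
    if loaded_mass_ug <= 0:
        raise ValueError("loaded mass must be positive")
    samples = np.asarray(samples, float)
    times = samples[:, 0]
    conc = samples[:, 1]
    released = 100.0 * conc * oil_volume_ml / loaded_mass_ug
    if np.any(released > 110.0):
        raise ValueError(
            "cumulative release exceeds 110%: inconsistent loaded mass or volume"
        )
    return ReleaseCurve(times=times, released=released)


@dataclass(frozen=True)
class KineticFit:
    rate: float  # zero-order rate, %/h
    changepoint: float  # h
    r_squared: float  # of the linear (early) phase
    burst: bool
    burst_intercept: float  # % (unconstrained early-fit intercept)
    late_model: str
    late_params: tuple[float, ...]  # (y at changepoint, plateau, lambda) of the saturating phase
    rss: float


def _late_model(dt, y_cp, plateau, lam):
    # saturating exponential continuous with the linear phase at the changepoint
    return plateau - (plateau - y_cp) * np.exp(-lam * dt)


def fit_zero_order(curve: ReleaseCurve, burst_threshold: float = 5.0) -> KineticFit:
    """Fit a zero-order phase plus saturating tail with an unknown changepoint.

    Candidate changepoints are the observed times (at least 3 points on
    each side); for each, the early segment is fit by a through-origin
    line (release = k*t) and the late segment by a saturating exponential
    with asymptote capped at 100%.  The changepoint minimising the total
    residual sum of squares wins; among near-ties the latest changepoint is
    preferred (maximal extent of the linear phase).  A burst flag is set if
    an unconstrained early-segment fit has intercept above
    ``burst_threshold`` (%).
    """
    if len(curve) < 6:
        raise ValueError("need at least 6 points to fit release kinetics")
    t = curve.times
    y = curve.released
    if np.any(np.diff(y) < -5.0 * max(1e-9, np.std(np.diff(y)) / 2)):
        warnings.warn("release curve is non-monotone beyond noise tolerance", stacklevel=2)

    n = len(t)
    best = None
    for ci in range(2, n - 3):  # >=3 early points, >=3 late points
        tc = t[ci]
        early = slice(0, ci + 1)
        late = slice(ci + 1, n)
        te, ye = t[early], y[early]
        denom = float(np.sum(te**2))
        k = float(np.sum(te * ye) / denom) if denom > 0 else 0.0
        rss_early = float(np.sum((ye - k * te) ** 2))

        tl, yl = t[late], y[late]
        y_cp = min(k * tc, 100.0)
        try:
            p_lo = min(y_cp, 100.0 - 1e-9)
            p0 = (min(100.0, max(yl.max(), y_cp + 1e-6)), 0.05)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda dt, plateau, lam: _late_model(dt, y_cp, plateau, lam),
                    tl - tc, yl, p0=p0,
                    bounds=([p_lo, 0.0], [100.0, 10.0]),
                    maxfev=2000,
                )
            popt = (y_cp, float(popt[0]), float(popt[1]))
            rss_late = float(np.sum((yl - _late_model(tl - tc, *popt)) ** 2))
        except RuntimeError:
            popt = (y_cp, float(yl.mean()), 0.0)
            rss_late = float(np.sum((yl - yl.mean()) ** 2))
        rss = rss_early + rss_late
        # "<=" with a tiny slack prefers the latest changepoint among ties,
        # i.e. the maximal extent of the zero-order phase
        if best is None or rss <= best[0] * (1 + 1e-9) + 1e-12:
            best = (rss, tc, k, rss_early, tuple(float(v) for v in popt), early)

    rss, tc, k, rss_early, late_params, early = best
    ye = y[early]
    ss_tot = float(np.sum((ye - ye.mean()) ** 2))
    r2 = 1.0 - rss_early / ss_tot if ss_tot > 0 else 1.0

    # unconstrained early fit for the burst check
    te = t[early]
    A = np.column_stack([te, np.ones_like(te)])
    coef, *_ = np.linalg.lstsq(A, ye, rcond=None)
    intercept = float(coef[1])

    return KineticFit(
        rate=max(0.0, k), changepoint=float(tc), r_squared=float(r2),
        burst=intercept > burst_threshold, burst_intercept=intercept,
        late_model="saturating-exponential", late_params=late_params,
        rss=float(rss),
    )


def size_stats(diameters) -> tuple[float, float]:
    """Mean and sample standard deviation, for 'mean +/- sd' size reporting."""
    d = np.asarray(diameters, float)
    if len(d) < 2:
        raise ValueError("need at least 2 values for mean +/- sd")
    return float(np.mean(d)), float(np.std(d, ddof=1))
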