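"""Field-observation statistics: activity standardization, trend and threshold fits.

Video samples of fixed duration record fish entering a water volume whose
entrance area varies with visibility.  Activity is standardized to fish per
m^2 per hour so samples are comparable.  The relationship between activity
and current speed is fit by ordinary least squares on the square-root of
activity (variance-stabilizing for count-like data), or nonparametrically by
Spearman rank correlation.

Binary swimming behaviours (direction: along- vs counter-current; depth:
pelagic vs bottom) are modelled as logistic functions of current speed,
restricted to currents >= 0.5 m/s so the fit reflects behaviour in flows
relevant to operating turbines.  The *breaking point* of a fit is the current
speed where the modelled probability crosses 0.5, i.e. ``-beta0 / beta1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, ValidityError

__all__ = [
    "ActivityTrendFit",
    "LogisticFit",
    "standardize_activity",
    "fit_activity_trend",
    "spearman_activity_trend",
    "fit_logistic_threshold",
    "breaking_point",
    "MIN_PER_LEVEL",
]

#: Validity rule: logistic fits require at least this many observations in
#: each level of the binary outcome.
MIN_PER_LEVEL = 30

DIRECTION_LEVELS = ("counter", "along", "transverse")
DEPTH_LEVELS = ("bottom", "pelagic")


def standardize_activity(count: float, entrance_area: float, duration: float) -> float:
    """Standardize a sample count to fish per m^2 per hour.

    ``entrance_area`` in m^2, ``duration`` in minutes.
    """
    if not (math.isfinite(entrance_area) and entrance_area > 0):
        raise DomainError(f"entrance_area must be > 0, got {entrance_area}")
    if not (math.isfinite(duration) and duration > 0):
        raise DomainError(f"duration must be > 0, got {duration}")
    if count < 0:
        raise DomainError(f"count must be >= 0, got {count}")
    return (count / entrance_area) * (60.0 / duration)


@dataclass(frozen=True)
class ActivityTrendFit:
    """OLS fit of (transformed) activity on current speed."""

    slope: float
    intercept: float
    r2: float
    f_stat: float
    p_value: float
    n: int
    degenerate: bool = False


def fit_activity_trend(
    samples: pd.DataFrame,
    activity_col: str = "activity",
    current_col: str = "current_speed",
    sqrt_transform: bool = True,
) -> ActivityTrendFit:
    """OLS regression of sqrt(activity) on current speed across samples.

    The square-root transform stabilizes the variance of count-derived
    activities.  A constant predictor yields a ``degenerate`` fit with NaN
    statistics rather than an exception.
    """
    if len(samples) < 3:
        raise ValidityError(f"need >= 3 samples, got {len(samples)}")
    y = np.asarray(samples[activity_col], dtype=float)
    if np.any(y < 0):
        raise DomainError("activities must be >= 0")
    x = np.asarray(samples[current_col], dtype=float)
    if sqrt_transform:
        y = np.sqrt(y)
    if np.ptp(x) == 0.0:
        return ActivityTrendFit(
            slope=float("nan"), intercept=float("nan"), r2=float("nan"),
            f_stat=float("nan"), p_value=float("nan"), n=len(x), degenerate=True,
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ActivityTrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n=int(res.nobs),
    )


def spearman_activity_trend(
    samples: pd.DataFrame,
    activity_col: str = "activity",
    current_col: str = "current_speed",
) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) between activity and current speed."""
    rho, p = stats.spearmanr(samples[current_col], samples[activity_col])
    return float(rho), float(p)


@dataclass(frozen=True)
class LogisticFit:
    """A logistic regression of a binary behaviour on current speed.

    ``chi2`` and ``p_value`` are the likelihood-ratio test against the
    constant-only model (1 d.f.); ``auc`` the area under the ROC curve of the
    fitted probabilities against the observed outcomes (midrank ties).
    """

    beta0: float
    beta1: float
    n: int
    chi2: float
    auc: float
    p_value: float
    converged: bool = True
    separated: bool = False

    @property
    def breaking_point(self) -> float:
        return breaking_point(self)


def _midrank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def fit_logistic_threshold(
    records: pd.DataFrame,
    outcome: str = "direction",
    min_current: float = 0.5,
    current_col: str = "current_speed",
) -> LogisticFit:
    """Fit a logistic model of a binary swimming behaviour on current speed.

    ``outcome='direction'`` models along-current (1) vs counter-current (0),
    dropping transverse swimmers; ``outcome='depth'`` models pelagic (1) vs
    bottom (0).  Records at currents below ``min_current`` are excluded, and
    the fit refuses (ValidityError) unless both outcome levels retain at
    least ``MIN_PER_LEVEL`` observations.  Perfectly separated data yield a
    fit flagged ``separated`` / not converged instead of an exception.
    """
    if outcome == "direction":
        kept = records[records["direction"].isin(["along", "counter"])]
        y = (kept["direction"] == "along").to_numpy(dtype=float)
    elif outcome == "depth":
        kept = records[records["depth"].isin(list(DEPTH_LEVELS))]
        y = (kept["depth"] == "pelagic").to_numpy(dtype=float)
    else:
        raise DomainError(f"outcome must be 'direction' or 'depth', got {outcome!r}")
    x = kept[current_col].to_numpy(dtype=float)
    keep = x >= min_current
    x, y = x[keep], y[keep]
    n1 = int(y.sum())
    n0 = len(y) - n1
    if min(n0, n1) < MIN_PER_LEVEL:
        raise ValidityError(
            f"{outcome} logit requires >= {MIN_PER_LEVEL} observations per level "
            f"at currents >= {min_current}; got {n0} / {n1}"
        )
    X = sm.add_constant(x)
    nan_fit = dict(beta0=float("nan"), beta1=float("nan"), n=len(y),
                   chi2=float("nan"), auc=float("nan"), p_value=float("nan"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return LogisticFit(**nan_fit, converged=False, separated=True)
    beta0, beta1 = float(res.params[0]), float(res.params[1])
    separated = (not res.mle_retvals.get("converged", False)) or abs(beta1) > 1e3
    null = sm.Logit(y, np.ones_like(y)).fit(disp=0)
    chi2 = 2.0 * (res.llf - null.llf)
    p_value = float(stats.chi2.sf(chi2, df=1))
    auc = _midrank_auc(y, res.predict(X))
    return LogisticFit(
        beta0=beta0, beta1=beta1, n=len(y), chi2=float(chi2), auc=auc,
        p_value=p_value, converged=not separated, separated=separated,
    )


def breaking_point(fit: LogisticFit) -> float:
    """Current speed where the fitted probability crosses 0.5: ``-beta0/beta1``.

    Undefined (NaN) when the slope is zero; invariant under rescaling both
    coefficients by the same factor.
    """
    if fit.beta1 == 0 or not math.isfinite(fit.beta1):
        return float("nan")
    return -fit.beta0 / fit.beta1
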