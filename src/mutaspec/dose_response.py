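"""Single-hit multitarget (SHMT) dose-response analysis.

The survival (or fertility) rate of seeds exposed to an absorbed dose ``D``
of ionizing radiation is modelled with the classical single-hit multitarget
curve

    rate(D) = 1 - (1 - exp(-D / D0))**m

where ``D0`` is the dose at which single-hit survival falls to ``1/e``
(about 37%) and ``m`` is the extrapolation number.  The curve has a shoulder:
rates stay near 1 below the quasi-threshold (shoulder) dose

    Dq = D0 * ln(m)

and decline roughly exponentially above it.  Comparing the doses at which
two mutagens produce the same biological effect (e.g. the shoulder dose, or
the 50%-survival dose) gives the relative biological effectiveness

    RBE = reference_dose / test_dose

conventionally quoting the low-LET mutagen (gamma rays) as the reference and
the high-LET mutagen (a carbon-ion beam) as the test radiation.

The fitting entry point is :class:`ShmtCurve`, a scikit-learn style
regressor (``fit(dose, rate)`` / ``predict(dose)``); :func:`fit_shmt` is a
thin functional wrapper returning a plain :class:`ShmtFit` record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    InsufficientDataError,
    NoCrossingError,
    ParameterDomainError,
)

__all__ = [
    "DoseResponseObservation",
    "ShmtFit",
    "RbeResult",
    "ShmtCurve",
    "shmt_rate",
    "shoulder_dose",
    "fit_shmt",
    "dose_at_rate",
    "rbe",
    "fertility_rate",
    "r_squared",
    "yield_half_dose",
    "read_dose_table",
]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseObservation:
    """One dose point: ``n_effect`` of ``n_total`` units showing the effect.

    Either supply counts (``n_total``, ``n_effect``) or a precomputed
    ``rate``; when both are present they must agree.
    """

    dose: float
    n_total: int | None = None
    n_effect: int | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ParameterDomainError(f"dose must be >= 0, got {self.dose}")
        if self.n_total is not None:
            if self.n_total <= 0:
                raise ParameterDomainError("n_total must be a positive count")
            if self.n_effect is None or not 0 <= self.n_effect <= self.n_total:
                raise ParameterDomainError(
                    "n_effect must satisfy 0 <= n_effect <= n_total"
                )
            implied = self.n_effect / self.n_total
            if self.rate is None:
                object.__setattr__(self, "rate", implied)
            elif abs(self.rate - implied) > 1e-9:
                raise ParameterDomainError(
                    f"rate {self.rate} inconsistent with counts "
                    f"{self.n_effect}/{self.n_total}"
                )
        if self.rate is None:
            raise ParameterDomainError("either counts or rate must be given")
        if not 0.0 <= self.rate <= 1.0:
            raise ParameterDomainError(f"rate must lie in [0, 1], got {self.rate}")


@dataclass(frozen=True)
class ShmtFit:
    """Fitted SHMT parameters and goodness of fit.

    ``dq`` is always ``d0 * ln(m)``; ``r_squared`` is computed on the rate
    scale against the replicate-averaged observations.
    """

    d0: float
    m: float
    dq: float
    r_squared: float
    converged: bool

    def predict(self, dose):
        return shmt_rate(dose, self.d0, self.m)


@dataclass(frozen=True)
class RbeResult:
    """Relative biological effectiveness at one matched endpoint."""

    reference_dose: float
    test_dose: float
    rbe: float
    endpoint_label: str = ""

    @property
    def rounded(self) -> float:
        """RBE rounded to 2 decimals, the conventional reporting precision."""
        return round(self.rbe, 2)


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------


def _check_params(d0: float, m: float) -> None:
    if not d0 > 0:
        raise ParameterDomainError(f"d0 must be > 0, got {d0}")
    if not m >= 1:
        raise ParameterDomainError(f"m must be >= 1, got {m}")


def shmt_rate(dose, d0: float, m: float):
    """Evaluate ``1 - (1 - exp(-dose/d0))**m``.

    Accepts a scalar or array dose; the result is in ``[0, 1]`` and
    non-increasing in dose.  ``dose=0`` gives exactly 1.
    """
    _check_params(d0, m)
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ParameterDomainError("dose must be >= 0")
    # 1 - e^{-D/d0} computed stably; t in [0, 1), so t**m is well behaved
    t = -np.expm1(-dose_arr / d0)
    out = 1.0 - t**m
    if np.isscalar(dose) or dose_arr.ndim == 0:
        return float(out)
    return out


def shoulder_dose(d0: float, m: float) -> float:
    """Quasi-threshold (shoulder) dose ``Dq = d0 * ln(m)`` in Gy."""
    _check_params(d0, m)
    return d0 * math.log(m)


def fertility_rate(total_pods: int, sterile_pods: int, single_seed_pods: int) -> float:
    """Fraction of pods that are not low-fertility.

    Sterile (seedless) and single-seed pods together count as low-fertility;
    the fertility rate is ``(total - low_fertility) / total``.
    """
    for name, value in (
        ("total_pods", total_pods),
        ("sterile_pods", sterile_pods),
        ("single_seed_pods", single_seed_pods),
    ):
        if value < 0:
            raise ParameterDomainError(f"{name} must be non-negative")
    if total_pods == 0:
        raise ParameterDomainError("total_pods must be positive")
    low = sterile_pods + single_seed_pods
    if low > total_pods:
        raise ParameterDomainError("low-fertility pods exceed total pods")
    return (total_pods - low) / total_pods


def rbe(reference_dose: float, test_dose: float, endpoint_label: str = "") -> RbeResult:
    """RBE = reference dose / test dose at one matched biological endpoint."""
    if reference_dose <= 0 or test_dose <= 0:
        raise ParameterDomainError("doses must be positive")
    return RbeResult(
        reference_dose=float(reference_dose),
        test_dose=float(test_dose),
        rbe=reference_dose / test_dose,
        endpoint_label=endpoint_label,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_dose_rate_arrays(observations) -> tuple[np.ndarray, np.ndarray]:
    """Normalize observation input to parallel (dose, rate) arrays."""
    if isinstance(observations, pd.DataFrame):
        return (
            observations["dose"].to_numpy(float),
            observations["rate"].to_numpy(float),
        )
    obs = list(observations)
    if obs and isinstance(obs[0], DoseResponseObservation):
        return (
            np.array([o.dose for o in obs], float),
            np.array([o.rate for o in obs], float),
        )
    arr = np.asarray(obs, dtype=float)
    return arr[:, 0], arr[:, 1]


def _average_replicates(dose: np.ndarray, rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average replicate rates sharing a dose; return sorted unique doses."""
    order = np.argsort(dose, kind="stable")
    dose, rate = dose[order], rate[order]
    uniq, inverse = np.unique(dose, return_inverse=True)
    mean_rate = np.bincount(inverse, weights=rate) / np.bincount(inverse)
    return uniq, mean_rate


class ShmtCurve(RegressorMixin, BaseEstimator):
    """Least-squares SHMT regressor on the rate scale.

    Parameters
    ----------
    n_starts_d0, m_starts :
        The optimizer is restarted from a coarse grid of initial values,
        ``n_starts_d0`` geometrically spaced D0 values in
        ``[max(dose)/10, max(dose)]`` crossed with the listed m values, and
        the best local optimum is kept.  Shoulder curves have flat ridges in
        (D0, m), so a single start is unreliable.
    max_nfev :
        Residual-evaluation budget per start.

    The constraint ``m >= 1`` (which keeps Dq non-negative) is enforced by
    the reparameterization ``m = 1 + exp(u)``, so the solver itself is
    unconstrained.

    Attributes
    ----------
    d0_, m_, dq_, r_squared_, converged_ :
        Fitted parameters, shoulder dose, coefficient of determination on
        the replicate-averaged rates, and solver status.
    """

    def __init__(self, n_starts_d0: int = 6, m_starts: tuple = (1.05, 2.0, 4.0, 8.0, 16.0), max_nfev: int = 400):
        self.n_starts_d0 = n_starts_d0
        self.m_starts = m_starts
        self.max_nfev = max_nfev

    def fit(self, X, y=None):
        """Fit to doses ``X`` (1-d or column vector, Gy) and rates ``y``.

        Replicate rows sharing a dose are averaged before fitting, so the
        objective is least squares on per-dose mean rates.
        """
        dose = np.asarray(X, dtype=float)
        if dose.ndim == 2 and dose.shape[1] == 1:
            dose = dose[:, 0]
        rate = np.asarray(y, dtype=float)
        if dose.shape != rate.shape:
            raise ParameterDomainError("dose and rate must have equal length")
        if np.any(dose < 0) or np.any(rate < 0) or np.any(rate > 1):
            raise ParameterDomainError("doses must be >= 0 and rates in [0, 1]")
        dose, rate = _average_replicates(dose, rate)
        if dose.size < 3:
            raise InsufficientDataError(
                f"need >= 3 distinct dose points, got {dose.size}"
            )
        if np.all(rate >= 1.0 - 1e-12):
            raise InsufficientDataError("all rates are 1; no decline to fit")
        dmax = dose.max()
        if dmax <= 0:
            raise InsufficientDataError("all doses are zero")

        def residuals(theta):
            d0 = math.exp(theta[0])
            m = 1.0 + math.exp(theta[1])
            return shmt_rate(dose, d0, m) - rate

        best = None
        d0_starts = np.geomspace(dmax / 10.0, dmax, self.n_starts_d0)
        for d0_0 in d0_starts:
            for m0 in self.m_starts:
                x0 = [math.log(d0_0), math.log(m0 - 1.0)]
                try:
                    res = least_squares(residuals, x0, method="lm", max_nfev=self.max_nfev)
                except (ValueError, OverflowError):
                    continue
                sse = float(np.sum(res.fun**2))
                if best is None or sse < best[0]:
                    best = (sse, res)
        if best is None:
            raise InsufficientDataError("optimizer failed from every start")
        sse, res = best
        self.d0_ = math.exp(res.x[0])
        self.m_ = 1.0 + math.exp(res.x[1])
        self.dq_ = shoulder_dose(self.d0_, self.m_)
        ss_tot = float(np.sum((rate - rate.mean()) ** 2))
        self.r_squared_ = 1.0 - sse / ss_tot if ss_tot >= 1e-15 else float("nan")
        self.converged_ = bool(res.success and np.isfinite(sse))
        self.n_points_ = int(dose.size)
        return self

    def predict(self, X):
        dose = np.asarray(X, dtype=float)
        if dose.ndim == 2 and dose.shape[1] == 1:
            dose = dose[:, 0]
        return shmt_rate(dose, self.d0_, self.m_)

    def dose_at_rate(self, target_rate: float, tol: float = 0.01) -> float:
        """Invert the fitted curve: dose (Gy) at which rate = target."""
        return dose_at_rate(self.to_fit(), target_rate, tol=tol)

    def to_fit(self) -> ShmtFit:
        return ShmtFit(
            d0=self.d0_,
            m=self.m_,
            dq=self.dq_,
            r_squared=self.r_squared_,
            converged=self.converged_,
        )


def fit_shmt(observations) -> ShmtFit:
    """Fit the SHMT model to observations and return an :class:`ShmtFit`.

    ``observations`` may be a list of :class:`DoseResponseObservation`, a
    DataFrame with ``dose`` / ``rate`` columns, or an iterable of
    ``(dose, rate)`` pairs.  Replicates at a dose are averaged first.
    """
    dose, rate = _as_dose_rate_arrays(observations)
    return ShmtCurve().fit(dose, rate).to_fit()


def _fit_params(fit) -> tuple[float, float]:
    if isinstance(fit, ShmtCurve):
        return fit.d0_, fit.m_
    return fit.d0, fit.m


def dose_at_rate(fit, target_rate: float, tol: float = 0.01) -> float:
    """Dose solving ``shmt_rate(D) = target_rate`` by bisection.

    The fitted curve is strictly decreasing for positive doses, so the root
    is unique; ``tol`` is the absolute dose tolerance in Gy.
    """
    if not 0.0 < target_rate < 1.0:
        raise ParameterDomainError("target_rate must lie strictly in (0, 1)")
    d0, m = _fit_params(fit)

    def f(d):
        return shmt_rate(d, d0, m) - target_rate

    hi = max(d0, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for valid parameters
            raise NoCrossingError("curve never reaches the target rate")
    return float(brentq(f, 0.0, hi, xtol=tol))


def r_squared(observations, fit) -> float:
    """Coefficient of determination on the rate scale.

    Computed against replicate-averaged rates; returns NaN (the flagged
    sentinel) when the observed rates have zero variance.
    """
    dose, rate = _as_dose_rate_arrays(observations)
    if dose.size < 3:
        raise InsufficientDataError("need >= 3 observations")
    dose, rate = _average_replicates(dose, rate)
    d0, m = _fit_params(fit)
    resid = rate - shmt_rate(dose, d0, m)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((rate - rate.mean()) ** 2))
    if ss_tot < 1e-15:  # constant observed rates: R^2 undefined
        return float("nan")
    return 1.0 - ss_res / ss_tot


def yield_half_dose(yield_table: Iterable[tuple[float, float]], threshold: float = 0.5) -> float:
    """Dose at which relative yield first falls through ``threshold``.

    The yield endpoint is read off by linear interpolation between the
    bracketing dose points (no SHMT fit: the yield decline is too shallow
    and shows low-dose stimulation).  Yields are relative to the unirradiated
    control (control = 1).
    """
    points = sorted((float(d), float(y)) for d, y in yield_table)
    if len(points) < 2:
        raise NoCrossingError("need at least two yield points")
    ys = [y for _, y in points]
    if min(ys) > threshold or max(ys) < threshold:
        raise NoCrossingError(f"yield never crosses {threshold}")
    for (d1, y1), (d2, y2) in zip(points, points[1:]):
        if y1 == threshold:
            return d1
        if y1 > threshold >= y2:
            return d1 + (y1 - threshold) / (y1 - y2) * (d2 - d1)
    if points[-1][1] == threshold:
        return points[-1][0]
    raise NoCrossingError(f"yield never crosses {threshold} downward")


# ---------------------------------------------------------------------------
# tabular ingestion
# ---------------------------------------------------------------------------


def read_dose_table(path, sep: str = "\t") -> list[DoseResponseObservation]:
    """Read a delimited dose-response table into observations.

    Accepted column layouts: ``dose, n_total, n_effect``; ``dose, rate``; or
    ``dose, total_pods, sterile_pods, single_seed_pods`` (converted via
    :func:`fertility_rate`).
    """
    df = pd.read_csv(path, sep=sep)
    cols = set(df.columns)
    out: list[DoseResponseObservation] = []
    if {"dose", "n_total", "n_effect"} <= cols:
        for row in df.itertuples(index=False):
            out.append(
                DoseResponseObservation(
                    dose=row.dose, n_total=int(row.n_total), n_effect=int(row.n_effect)
                )
            )
    elif {"dose", "total_pods", "sterile_pods", "single_seed_pods"} <= cols:
        for row in df.itertuples(index=False):
            out.append(
                DoseResponseObservation(
                    dose=row.dose,
                    rate=fertility_rate(
                        int(row.total_pods),
                        int(row.sterile_pods),
                        int(row.single_seed_pods),
                    ),
                )
            )
    elif {"dose", "rate"} <= cols:
        for row in df.itertuples(index=False):
            out.append(DoseResponseObservation(dose=row.dose, rate=row.rate))
    else:
        raise ParameterDomainError(
            f"unrecognized dose table columns: {sorted(cols)}"
        )
    return out
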