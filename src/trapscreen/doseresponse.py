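"""Four-parameter logistic (4PL) dose-response quantification.

Reporter titrations are fitted with the variable-slope agonist equation

    response(d) = Bottom + (Top - Bottom) / (1 + 10^(h * (logEC50 - log10 d)))

parameterized in log10-EC50 for numerical stability and a symmetric error
model on the log-dose axis. Parameter standard errors come from the
curvature of the least-squares fit at the optimum (Gauss-Newton covariance
``(J'J)^-1 * s^2`` with ``s^2 = RSS / (n - 4)``). EC50 and its standard
error are reported on the nM scale via the delta method.

A fit is reported as converged only when the optimizer succeeds, the fitted
dynamic range is positive (Top > Bottom), standard errors are finite, and
the fitted EC50 lies within 10x of the dosed range; otherwise no EC50 is
reported.

Potency comparisons between two fitted curves use a two-tailed unpaired
t-test on the EC50s with the fit standard errors and Welch-Satterthwaite
degrees of freedom from the residual degrees of freedom of each fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import t as t_dist

LN10 = math.log(10.0)

#: A converged fit's EC50 must lie within this factor of the dosed range.
EC50_RANGE_FACTOR = 10.0


@dataclass
class DoseResponseData:
    """Per-well median reporter responses for one sample's titration."""

    sample_id: str
    doses: np.ndarray  # nM, > 0
    responses: np.ndarray  # reporter fluorescence, arbitrary units

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive (zero-dose wells are excluded)")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if len(np.unique(self.doses)) < 4:
            raise ValueError("need >= 4 distinct positive doses to fit 4 parameters")

    @classmethod
    def from_frame(cls, table: pd.DataFrame, sample_id: str) -> "DoseResponseData":
        """Extract one sample's wells from a tidy (sample, dose_nM, replicate,
        response) table. Zero-dose wells are dropped."""
        rows = table[table["sample"] == sample_id]
        if rows.empty:
            raise ValueError(f"no rows for sample {sample_id!r}")
        rows = rows[rows["dose_nM"] > 0]
        return cls(
            sample_id=sample_id,
            doses=rows["dose_nM"].to_numpy(float),
            responses=rows["response"].to_numpy(float),
        )


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with standard errors."""

    sample_id: str
    bottom: float
    top: float
    log_ec50: float
    hill: float
    se_bottom: float
    se_top: float
    se_log_ec50: float
    se_hill: float
    residual_df: int
    rss: float
    converged: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FourPLFit":
        return cls(**json.loads(Path(path).read_text()))


def four_pl(dose, bottom, top, log_ec50, hill):
    """Variable-slope agonist equation on the nM dose scale."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - np.log10(dose))))


def _residuals_and_jac(params, log_dose, response):
    bottom, top, log_ec50, hill = params
    z = 10.0 ** (hill * (log_ec50 - log_dose))
    f = 1.0 / (1.0 + z)  # fractional occupancy
    resid = bottom + (top - bottom) * f - response
    # Analytic Jacobian of the residuals w.r.t. (bottom, top, log_ec50, hill)
    dfdz = -(f ** 2)
    span = top - bottom
    jac = np.column_stack(
        [
            1.0 - f,
            f,
            span * dfdz * z * LN10 * hill,
            span * dfdz * z * LN10 * (log_ec50 - log_dose),
        ]
    )
    return resid, jac


def fit_4pl(data: DoseResponseData) -> FourPLFit:
    """Least-squares 4PL fit of one titration.

    Initial values: Bottom = min response, Top = max response, logEC50 at
    the dose whose mean response is nearest half-maximal, Hill = 1. A fit
    that fails, has a non-positive dynamic range, non-finite standard
    errors, or an EC50 more than 10x outside the dosed range is returned
    with ``converged=False`` and must not be used to report an EC50.
    """
    log_dose = np.log10(data.doses)
    response = data.responses
    n = len(response)
    residual_df = n - 4

    rmin, rmax = float(response.min()), float(response.max())
    if rmax == rmin:
        # No dose dependence at all: nothing to fit.
        return FourPLFit(
            data.sample_id, rmin, rmax, float("nan"), float("nan"),
            *(float("nan"),) * 4, residual_df, 0.0, converged=False,
        )

    # Dose whose mean response is nearest to half-maximal.
    half = 0.5 * (rmin + rmax)
    means = pd.Series(response).groupby(log_dose).mean()
    x0_log_ec50 = float(means.index[np.argmin(np.abs(means.to_numpy() - half))])
    x0 = np.array([rmin, rmax, x0_log_ec50, 1.0])

    result = optimize.least_squares(
        lambda p: _residuals_and_jac(p, log_dose, response)[0],
        x0,
        jac=lambda p: _residuals_and_jac(p, log_dose, response)[1],
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10000,
    )
    bottom, top, log_ec50, hill = result.x
    # The equation is invariant under (Bottom, Top, h) -> (Top, Bottom, -h);
    # canonicalize to Top > Bottom so Hill's sign carries the direction.
    if top < bottom:
        result.x = np.array([top, bottom, log_ec50, -hill])
        bottom, top, log_ec50, hill = result.x
    rss = float(np.sum(result.fun ** 2))

    se = np.full(4, float("nan"))
    if result.success and residual_df >= 1:
        _, jac = _residuals_and_jac(result.x, log_dose, response)
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * (rss / residual_df)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            pass

    ec50_nm = 10.0 ** log_ec50
    dosed_lo, dosed_hi = float(data.doses.min()), float(data.doses.max())
    converged = bool(
        result.success
        and top > bottom
        and np.all(np.isfinite(se))
        and dosed_lo / EC50_RANGE_FACTOR <= ec50_nm <= dosed_hi * EC50_RANGE_FACTOR
    )
    return FourPLFit(
        sample_id=data.sample_id,
        bottom=float(bottom),
        top=float(top),
        log_ec50=float(log_ec50),
        hill=float(hill),
        se_bottom=float(se[0]),
        se_top=float(se[1]),
        se_log_ec50=float(se[2]),
        se_hill=float(se[3]),
        residual_df=residual_df,
        rss=rss,
        converged=converged,
    )


def ec50(fit: FourPLFit) -> tuple[float, float]:
    """EC50 on the nM scale with its delta-method standard error.

    ``value = 10^logEC50``; ``se = ln(10) * value * se(logEC50)``.
    """
    if not fit.converged:
        raise ValueError(f"fit for {fit.sample_id!r} did not converge; no EC50")
    value = 10.0 ** fit.log_ec50
    return value, LN10 * value * fit.se_log_ec50


def fold_change(fit_num: FourPLFit, fit_den: FourPLFit) -> float:
    """Ratio of EC50s (numerator over denominator); >1 means lower potency."""
    num, _ = ec50(fit_num)
    den, _ = ec50(fit_den)
    return num / den


def efficacy_ratio(fit_a: FourPLFit, fit_ref: FourPLFit) -> float:
    """Fitted dynamic range (Top - Bottom) of a, relative to the reference."""
    if not (fit_a.converged and fit_ref.converged):
        raise ValueError("both fits must be converged")
    ref_span = fit_ref.top - fit_ref.bottom
    if ref_span == 0:
        raise ValueError("reference fit has zero dynamic range")
    return (fit_a.top - fit_a.bottom) / ref_span


def compare_ec50(fit_a: FourPLFit, fit_b: FourPLFit) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test on two fitted EC50s.

    Uses each curve fit's EC50 standard error and Welch-Satterthwaite
    degrees of freedom computed from the fits' residual degrees of freedom.
    Returns ``(t, df, two_tailed_p)``.
    """
    for fit in (fit_a, fit_b):
        if not fit.converged:
            raise ValueError(f"fit for {fit.sample_id!r} did not converge")
        if fit.residual_df < 1:
            raise ValueError(f"fit for {fit.sample_id!r} has no residual df")
    ec_a, se_a = ec50(fit_a)
    ec_b, se_b = ec50(fit_b)
    pooled_var = se_a ** 2 + se_b ** 2
    if pooled_var == 0:
        raise ValueError("combined standard error is zero")
    t = (ec_a - ec_b) / math.sqrt(pooled_var)
    df = pooled_var ** 2 / (
        se_a ** 4 / fit_a.residual_df + se_b ** 4 / fit_b.residual_df
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return t, df, p
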