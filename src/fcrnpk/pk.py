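"""Noncompartmental and two-compartment pharmacokinetic estimation.

Implements the standard NCA toolchain for serum antibody curves after an
i.v. bolus: log-linear ("linear-up/log-down") trapezoidal AUC, terminal
log-linear regression over at least the last six measurable points,
extrapolation of AUC and AUMC to infinity, clearance CL = Dose / AUC_inf,
steady-state volume Vss = Dose * AUMC_inf / AUC_inf**2, biexponential
(two-phase) curve fitting, and fold-change tables between Fc variants.

Times are stored in hours (the half-life unit of the study tables);
areas, rates and clearances are per day.  ``HOURS_PER_DAY`` converts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

HOURS_PER_DAY = 24.0

__all__ = [
    "ConcentrationTimeSeries",
    "PKParameters",
    "BiexponentialFit",
    "auc_loglinear_trapezoid",
    "terminal_phase_fit",
    "auc_extrapolate_to_inf",
    "clearance",
    "vss",
    "fit_biexponential",
    "nca",
    "fold_changes",
    "HOURS_PER_DAY",
]


@dataclass(frozen=True)
class ConcentrationTimeSeries:
    """One subject's serum concentration curve.

    times are hours (strictly increasing); concentrations μg/mL; dose is
    μg per kg body weight; censored flags mark samples below the lower
    limit of quantification, which are excluded from all fits and areas.
    """

    subject_id: str
    variant: str
    dose: float
    times: np.ndarray
    concentrations: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        cen = (
            np.zeros(t.shape, dtype=bool)
            if self.censored is None
            else np.asarray(self.censored, dtype=bool)
        )
        if t.ndim != 1 or t.shape != c.shape or t.shape != cen.shape:
            raise ValueError("times, concentrations and censored must be 1-D and aligned")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c[~cen] < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "censored", cen)

    def measurable(self) -> tuple[np.ndarray, np.ndarray]:
        """(times_h, concentrations) of uncensored samples."""
        keep = ~self.censored
        return self.times[keep], self.concentrations[keep]


@dataclass(frozen=True)
class PKParameters:
    """NCA / biexponential summary for one subject or variant mean."""

    AUC_inf: float  # μg·day/mL
    AUMC_inf: float  # μg·day²/mL
    CL: float  # mL/day/kg
    T_half_beta: float  # hours
    V_ss: float  # mL/kg
    C_max: float  # μg/mL
    lambda_z: float  # per day
    n_terminal_points: int


def _interval_auc(t1, c1, t2, c2) -> tuple[float, float]:
    """(area, first-moment area) of one interval, linear-up/log-down."""
    dt = t2 - t1
    if c1 > c2 > 0.0:
        # log trapezoid; moment via exact integral of t*exp decay
        lam = np.log(c1 / c2) / dt
        auc = (c1 - c2) / lam
        aumc = (t1 * c1 - t2 * c2) / lam + (c1 - c2) / lam**2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def _auc_aumc_last(series: ConcentrationTimeSeries) -> tuple[float, float, float, float]:
    t_h, c = series.measurable()
    if len(t_h) < 2:
        raise ValueError("need at least 2 uncensored points for an AUC")
    t = t_h / HOURS_PER_DAY
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        a, m = _interval_auc(t[i], c[i], t[i + 1], c[i + 1])
        auc += a
        aumc += m
    return auc, aumc, t[-1], c[-1]


def auc_loglinear_trapezoid(series: ConcentrationTimeSeries) -> float:
    """Area to the last measurable time, μg·day/mL.

    Per interval: logarithmic trapezoid (C1 - C2)·Δt / ln(C1/C2) when the
    concentration is strictly decreasing with both endpoints positive,
    linear trapezoid otherwise (rising segments, zeros).
    """
    return _auc_aumc_last(series)[0]


def terminal_phase_fit(
    series: ConcentrationTimeSeries, min_points: int = 6
) -> tuple[float, float, int]:
    """Terminal log-linear regression: returns (lambda_z per day, intercept, n).

    Fits ln(C) on time over a terminal window of the last n measurable
    positive points, n >= min_points; among candidate window sizes the
    one maximizing adjusted R² wins, smallest window on ties.
    """
    t_h, c = series.measurable()
    pos = c > 0
    t_h, c = t_h[pos], c[pos]
    if len(t_h) < min_points:
        raise ValueError(
            f"need at least {min_points} measurable terminal points, have {len(t_h)}"
        )
    t = t_h / HOURS_PER_DAY
    logc = np.log(c)

    best = None  # (adj_r2, -n, slope, intercept, n); max() prefers small n on ties
    for n in range(min_points, len(t) + 1):
        tt, yy = t[-n:], logc[-n:]
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = (adj, -n, slope, intercept, n)
        if best is None or cand > best:
            best = cand
    _, _, slope, intercept, n = best
    if slope >= 0:
        raise ValueError("no terminal decay: terminal regression slope is non-negative")
    return -slope, intercept, n


def auc_extrapolate_to_inf(
    series: ConcentrationTimeSeries, lambda_z: float
) -> tuple[float, float]:
    """(AUC_inf, AUMC_inf): observed areas plus the exponential tail.

    AUC_inf  = AUC_last  + C_last/λz
    AUMC_inf = AUMC_last + t_last·C_last/λz + C_last/λz²
    """
    if lambda_z <= 0:
        raise ValueError(f"lambda_z must be positive, got {lambda_z}")
    auc_last, aumc_last, t_last, c_last = _auc_aumc_last(series)
    auc_inf = auc_last + c_last / lambda_z
    aumc_inf = aumc_last + t_last * c_last / lambda_z + c_last / lambda_z**2
    return auc_inf, aumc_inf


def clearance(dose: float, auc_inf: float) -> float:
    """CL = Dose / AUC_inf (mL/day/kg for dose in μg/kg, AUC in μg·day/mL)."""
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if auc_inf <= 0:
        raise ValueError(f"AUC_inf must be positive, got {auc_inf}")
    return dose / auc_inf


def vss(dose: float, aumc_inf: float, auc_inf: float) -> float:
    """Vss = Dose · AUMC_inf / AUC_inf² (mL/kg)."""
    if dose <= 0 or aumc_inf <= 0:
        raise ValueError("dose and AUMC_inf must be positive")
    if auc_inf <= 0:
        raise ValueError(f"AUC_inf must be positive, got {auc_inf}")
    return dose * aumc_inf / auc_inf**2


@dataclass(frozen=True)
class BiexponentialFit:
    A: float  # μg/mL
    alpha: float  # per day
    B: float  # μg/mL
    beta: float  # per day

    @property
    def t_half_beta_hours(self) -> float:
        return np.log(2.0) / self.beta * HOURS_PER_DAY

    def __call__(self, t_days):
        t = np.asarray(t_days, dtype=float)
        return self.A * np.exp(-self.alpha * t) + self.B * np.exp(-self.beta * t)


def fit_biexponential(
    series: ConcentrationTimeSeries, degeneracy_ratio: float = 1.2
) -> BiexponentialFit:
    """Two-phase clearance fit C(t) = A e^{-αt} + B e^{-βt}, α > β.

    Nonlinear least squares on log-concentration, initialized by curve
    stripping: the terminal phase is fit first and its back-extrapolated
    contribution subtracted to seed the fast phase.  Raises if α and β
    are not separated by at least ``degeneracy_ratio`` (mono-exponential
    data).
    """
    t_h, c = series.measurable()
    pos = c > 0
    t, c = t_h[pos] / HOURS_PER_DAY, c[pos]
    if len(t) < 5:
        raise ValueError("need at least 5 uncensored positive points")

    # strip: terminal line from the last half of points
    n_term = max(3, len(t) // 2)
    s, b0 = np.polyfit(t[-n_term:], np.log(c[-n_term:]), 1)
    beta0, B0 = max(-s, 1e-6), np.exp(b0)
    resid = c - B0 * np.exp(-beta0 * t)
    early = resid > 0
    if early.sum() >= 2:
        s2, a0 = np.polyfit(t[early][:max(2, early.sum() // 2)],
                            np.log(resid[early][:max(2, early.sum() // 2)]), 1)
        alpha0, A0 = max(-s2, 2 * beta0), np.exp(a0)
    else:
        alpha0, A0 = 10 * beta0, 0.5 * c[0]
    alpha0 = max(alpha0, 1.5 * beta0)

    def log_model(tt, logA, logalpha, logB, logbeta):
        A, alpha, B, beta = np.exp([logA, logalpha, logB, logbeta])
        return np.log(A * np.exp(-alpha * tt) + B * np.exp(-beta * tt))

    p0 = np.log([max(A0, 1e-8), alpha0, max(B0, 1e-8), beta0])
    try:
        popt, _ = curve_fit(log_model, t, np.log(c), p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"biexponential fit did not converge: {exc}") from exc
    A, alpha, B, beta = np.exp(popt)
    if alpha < beta:  # enforce α > β by swapping phases
        A, alpha, B, beta = B, beta, A, alpha
    # degenerate either when the two rates coincide or when one phase
    # has collapsed to negligible amplitude
    if alpha < degeneracy_ratio * beta or min(A, B) < 1e-6 * max(A, B):
        raise ValueError(
            f"alpha ({alpha:.4g}/day) and beta ({beta:.4g}/day) phases are not "
            "separable; data look mono-exponential — fit a single phase instead"
        )
    return BiexponentialFit(A=A, alpha=alpha, B=B, beta=beta)


def nca(series: ConcentrationTimeSeries, min_terminal_points: int = 6) -> PKParameters:
    """Full noncompartmental analysis of one subject's curve."""
    lambda_z, _, n_term = terminal_phase_fit(series, min_points=min_terminal_points)
    auc_inf, aumc_inf = auc_extrapolate_to_inf(series, lambda_z)
    _, c = series.measurable()
    return PKParameters(
        AUC_inf=auc_inf,
        AUMC_inf=aumc_inf,
        CL=clearance(series.dose, auc_inf),
        T_half_beta=np.log(2.0) / lambda_z * HOURS_PER_DAY,
        V_ss=vss(series.dose, aumc_inf, auc_inf),
        C_max=float(c.max()),
        lambda_z=lambda_z,
        n_terminal_points=n_term,
    )


def fold_changes(
    pk_table: pd.DataFrame | Mapping[str, PKParameters],
    pairs: Sequence[tuple[str, str]] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Pairwise parameter ratios between variants, rounded for comparison
    against printed fold-change statements.

    ``pk_table`` is a DataFrame indexed by variant (columns = PK
    parameters) or a mapping variant -> PKParameters.  ``pairs`` lists
    (numerator, denominator) variants; default is all ordered pairs.
    Returns a long table with columns numerator, denominator, parameter,
    ratio (rounded to ``decimals``).
    """
    if not isinstance(pk_table, pd.DataFrame):
        pk_table = pd.DataFrame({v: vars(p) for v, p in pk_table.items()}).T
    if len(pk_table) < 2:
        raise ValueError("need at least 2 variants for fold changes")
    if pairs is None:
        pairs = list(permutations(pk_table.index, 2))
    rows = []
    for num, den in pairs:
        for variant in (num, den):
            if variant not in pk_table.index:
                raise KeyError(f"variant {variant!r} missing from PK table")
        for param in pk_table.columns:
            a, b = pk_table.loc[num, param], pk_table.loc[den, param]
            if pd.isna(a) or pd.isna(b) or b == 0:
                continue
            rows.append(
                {
                    "numerator": num,
                    "denominator": den,
                    "parameter": param,
                    "ratio": round(float(a) / float(b), decimals),
                }
            )
    return pd.DataFrame(rows)
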