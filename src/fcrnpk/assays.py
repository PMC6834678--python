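"""Computational pieces of the binding and functional assays.

Steady-state and kinetic 1:1 Langmuir SPR fitting, pH-normalized
binding, percent target-cell lysis, and AC-SINS plasmon-wavelength
extraction by local quadratic fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "Isotherm",
    "Spectrum",
    "KdFit",
    "langmuir_equilibrium",
    "fit_kd_steady_state",
    "kinetic_1to1",
    "fit_kinetic_1to1",
    "normalized_ph_binding",
    "percent_lysis",
    "plasmon_wavelength",
    "plasmon_shift",
]


@dataclass(frozen=True)
class Isotherm:
    """Steady-state SPR responses (RU) at a series of analyte
    concentrations (nM), for one immobilization density and pH."""

    concentrations: np.ndarray
    responses: np.ndarray
    density: str = "low"  # low / medium / high ≈ 500 / 2000 / 4000 RU
    pH: float = 5.8

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be aligned 1-D arrays")
        if np.any(c <= 0):
            raise ValueError("analyte concentrations must be positive")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)


@dataclass(frozen=True)
class Spectrum:
    """Absorbance spectrum on an evenly spaced wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if w.shape != a.shape or w.ndim != 1 or len(w) < 3:
            raise ValueError("wavelengths and absorbances must be aligned 1-D arrays")
        dw = np.diff(w)
        if np.any(dw <= 0) or not np.allclose(dw, dw[0]):
            raise ValueError("wavelengths must be strictly increasing and evenly spaced")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbances", a)


def langmuir_equilibrium(C, Kd: float, Rmax: float):
    """1:1 equilibrium response Rmax·C/(Kd + C)."""
    if Kd <= 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be non-negative")
    out = Rmax * C / (Kd + C)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class KdFit:
    kd: float  # nM
    rmax: float  # RU
    kd_se: float
    rmax_se: float
    kd_ci: tuple[float, float]  # linearized 95% interval (t quantile, n-2 dof)
    flag: str | None = None  # "no_binding" / "kd_out_of_range" / None

    @property
    def detectable(self) -> bool:
        return self.flag != "no_binding"


def fit_kd_steady_state(iso: Isotherm) -> KdFit:
    """Least-squares 1:1 steady-state fit; CIs from the linearized
    covariance.

    All-zero (or negligible) responses are flagged ``no_binding``
    (reported as ND in affinity tables); a K_D more than 100× outside
    the concentration range is flagged ``kd_out_of_range``.
    """
    c, r = iso.concentrations, iso.responses
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    if c.max() / c.min() < 10:
        raise ValueError("concentration series must span at least 10-fold")
    if np.allclose(r, 0.0, atol=1e-9 * max(1.0, abs(r).max() if len(r) else 1.0)) or r.max() <= 0:
        return KdFit(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan), flag="no_binding")

    p0 = (np.median(c), r.max())
    popt, pcov = curve_fit(
        lambda x, kd, rmax: rmax * x / (kd + x), c, r, p0=p0,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    kd, rmax = popt
    se = np.sqrt(np.diag(pcov))
    tq = stats.t.ppf(0.975, len(c) - 2)  # small-sample quantile
    ci = (kd - tq * se[0], kd + tq * se[0])
    flag = None
    if not (c.min() / 100.0 <= kd <= c.max() * 100.0):
        flag = "kd_out_of_range"
    return KdFit(kd=kd, rmax=rmax, kd_se=se[0], rmax_se=se[1], kd_ci=ci, flag=flag)


def kinetic_1to1(
    ka: float, kd_off: float, C: float, times, Rmax: float, phase: str = "association"
):
    """1:1 Langmuir binding kinetics.

    Association: R(t) = Req·(1 − e^{−(ka·C + kd_off)·t}) with
    Req = Rmax·C/(Kd + C), Kd = kd_off/ka.  Dissociation from R0:
    R(t) = R0·e^{−kd_off·t}.  ka in 1/nM/s, kd_off in 1/s, C in nM.
    """
    if ka < 0 or kd_off < 0:
        raise ValueError("rates must be non-negative")
    t = np.asarray(times, dtype=float)
    if phase == "association":
        kobs = ka * C + kd_off
        req = Rmax * ka * C / kobs if kobs > 0 else 0.0
        return req * (1.0 - np.exp(-kobs * t))
    if phase == "dissociation":
        return np.exp(-kd_off * t)  # decay from unit R0
    raise ValueError(f"unknown phase {phase!r}")


def fit_kinetic_1to1(
    concentrations: Sequence[float], times, traces: np.ndarray, Rmax0: float | None = None
) -> tuple[float, float, float]:
    """Recover (ka, kd_off, Rmax) from association traces at several
    analyte concentrations by joint nonlinear least squares."""
    t = np.asarray(times, dtype=float)
    traces = np.asarray(traces, dtype=float)
    concs = np.asarray(concentrations, dtype=float)
    if traces.shape != (len(concs), len(t)):
        raise ValueError("traces must be (n_concentrations, n_times)")
    if Rmax0 is None:
        Rmax0 = traces.max() * 1.2

    def resid(logp):
        ka, kd_off, rmax = np.exp(logp)
        model = np.stack(
            [kinetic_1to1(ka, kd_off, c, t, rmax) for c in concs]
        )
        return (model - traces).ravel()

    p0 = np.log([1e-4, 1e-3, Rmax0])
    sol = least_squares(resid, p0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"kinetic fit did not converge: {sol.message}")
    ka, kd_off, rmax = np.exp(sol.x)
    return ka, kd_off, rmax


def normalized_ph_binding(ru_at_ph: float, ru_max_ph6: float) -> float:
    """Binding at a given pH normalized to the maximal response at pH
    6.0 (fraction, clipped below at 0)."""
    if ru_max_ph6 <= 0:
        raise ValueError("reference RU at pH 6.0 must be positive")
    return max(ru_at_ph / ru_max_ph6, 0.0)


def percent_lysis(E: float, S: float, M: float) -> float:
    """Percent target-cell lysis 100·(E − S)/(M − S).

    E: experimental fluorescence; S: spontaneous release (no antibody);
    M: maximal release (detergent lysis).
    """
    if M == S:
        raise ValueError("M equals S: assay has no dynamic range")
    return 100.0 * (E - S) / (M - S)


def plasmon_wavelength(spec: Spectrum, half_window: int = 20) -> float:
    """Plasmon peak wavelength (nm) via a quadratic fit around the
    absorbance maximum.

    A second-order polynomial is fit to the ``2·half_window`` + 1 points
    centered on the argmax (ties broken toward the lower wavelength;
    the window is truncated at a spectrum edge) and the vertex −b/2a is
    returned.  A non-concave fit raises.
    """
    w, a = spec.wavelengths, spec.absorbances
    if len(w) < 2 * half_window:
        raise ValueError(f"need at least {2 * half_window} points")
    i = int(np.argmax(a))  # argmax takes the first (lowest-wavelength) tie
    lo, hi = max(0, i - half_window), min(len(w), i + half_window + 1)
    coeff = np.polyfit(w[lo:hi], a[lo:hi], 2)
    if coeff[0] >= 0:
        raise ValueError("quadratic fit around the maximum is not concave")
    return float(-coeff[1] / (2.0 * coeff[0]))


def plasmon_shift(test: Spectrum, control: Spectrum) -> float:
    """Plasmon shift (nm): test peak minus control (no-antibody) peak."""
    return plasmon_wavelength(test) - plasmon_wavelength(control)
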