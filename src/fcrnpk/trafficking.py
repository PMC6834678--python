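"""Linear three-compartment model of exogenous IgG trafficking.

IgG distributes between a central extracellular space (relative volume
fixed at 1), a peripheral extracellular space (relative volume ``V_p``)
and an endosomal space (relative volume ``V_e``).  Antibody exchanges
between central and peripheral compartments at rate ``Q`` and is taken
up into cells from the peripheral space at rate ``Q_u`` (both in units
of central-compartment volumes per hour).  Inside the endosome a
fraction ``f_sort`` of the IgG is sorted to recycling (FcRn-bound at
endosomal pH); the remainder is degraded in the lysosome.  Of the
recycled IgG presented at the cell surface, a fraction ``f_release`` is
released back to the extracellular space; the rest (the surface
*recapture* fraction, ``1 - f_release``) is endocytosed again because it
remains FcRn-bound at extracellular pH.

The concentration vector ``c = (C_c, C_p, C_e)`` (μg/mL) obeys the
linear system ``dc/dt = M c``:

    dC_c/dt       = Q (C_p - C_c)
    V_p dC_p/dt   = Q C_c - Q C_p - Q_u C_p + Q_u C_e f_sort f_release
    V_e dC_e/dt   = Q_u [ C_p + C_e ((1 - f_release) f_sort - 1) ]

There is no clearance other than lysosomal degradation, so with
``f_sort = f_release = 1`` the system is closed and mass is conserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "TraffickingParameters",
    "CompartmentState",
    "build_rate_matrix",
    "propagate",
    "total_mass",
    "terminal_half_life",
    "time_to_half",
    "recapture_fraction",
]

#: eigenvalues with magnitude below RATE_FLOOR * scale(M) are treated as zero
#: (closed system -> infinite half-life)
_RATE_FLOOR = 1e-12


@dataclass(frozen=True)
class TraffickingParameters:
    """Volumes, flows and per-variant sorting/release fractions.

    Volumes are relative to the central compartment (V_c = 1); flows are
    in central-compartment volumes per hour.  ``f_sort`` and
    ``f_release`` map variant labels to fractions in [0, 1].
    """

    V_p: float
    V_e: float
    Q: float
    Q_u: float
    f_sort: dict[str, float] = field(default_factory=dict)
    f_release: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("V_p", "V_e", "Q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.Q_u < 0:
            raise ValueError(f"Q_u must be non-negative, got {self.Q_u}")
        for label, frac in list(self.f_sort.items()) + list(self.f_release.items()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for variant {label!r} outside [0, 1]: {frac}")

    @property
    def variants(self) -> list[str]:
        return sorted(set(self.f_sort) & set(self.f_release))

    def for_variant(self, variant: str) -> tuple[float, float]:
        """(f_sort, f_release) for one variant."""
        try:
            return self.f_sort[variant], self.f_release[variant]
        except KeyError as exc:
            raise KeyError(f"unknown variant {variant!r}; have {sorted(self.f_sort)}") from exc

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "V_p": self.V_p,
            "V_e": self.V_e,
            "Q": self.Q,
            "Q_u": self.Q_u,
            "variants": {
                v: {"f_sort": self.f_sort[v], "f_release": self.f_release[v]}
                for v in sorted(set(self.f_sort) | set(self.f_release))
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TraffickingParameters":
        variants = data.get("variants", {})
        return cls(
            V_p=float(data["V_p"]),
            V_e=float(data["V_e"]),
            Q=float(data["Q"]),
            Q_u=float(data["Q_u"]),
            f_sort={v: float(d["f_sort"]) for v, d in variants.items()},
            f_release={v: float(d["f_release"]) for v, d in variants.items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TraffickingParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_fractions(self, variant: str, f_sort: float, f_release: float):
        return replace(
            self,
            f_sort={**self.f_sort, variant: f_sort},
            f_release={**self.f_release, variant: f_release},
        )


@dataclass(frozen=True)
class CompartmentState:
    """Concentrations (μg/mL) in the three compartments at time t (hours)."""

    C_c: float
    C_p: float
    C_e: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.C_c, self.C_p, self.C_e) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.C_c, self.C_p, self.C_e], dtype=float)

    @classmethod
    def bolus(cls, dose_conc: float) -> "CompartmentState":
        """Initial state after an i.v. bolus: full dose in the central
        compartment (C_c(0) = dose / V_c with V_c = 1), nothing elsewhere."""
        return cls(C_c=dose_conc, C_p=0.0, C_e=0.0, t=0.0)


def build_rate_matrix(params: TraffickingParameters, variant: str) -> np.ndarray:
    """Rate matrix M with dc/dt = M c for one variant.

    The peripheral and endosomal rows of the stated balance equations
    are divided by V_p and V_e so that M acts on concentrations.
    """
    fs, fr = params.for_variant(variant)
    Q, Qu, Vp, Ve = params.Q, params.Q_u, params.V_p, params.V_e
    return np.array(
        [
            [-Q, Q, 0.0],
            [Q / Vp, -(Q + Qu) / Vp, Qu * fs * fr / Vp],
            [0.0, Qu / Ve, Qu * ((1.0 - fr) * fs - 1.0) / Ve],
        ]
    )


def propagate(
    state0: CompartmentState,
    params: TraffickingParameters,
    t: float,
    variant: str,
) -> CompartmentState:
    """State at time ``t`` (hours) via the matrix exponential exp(t M) c0."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if t == 0:
        return state0
    M = build_rate_matrix(params, variant)
    c = expm(t * M) @ state0.vector
    # exp(tM) has non-negative entries for a Metzler matrix; clip only
    # round-off noise
    c = np.where((c < 0) & (c > -1e-12 * max(1.0, abs(state0.C_c))), 0.0, c)
    return CompartmentState(C_c=c[0], C_p=c[1], C_e=c[2], t=state0.t + t)


def total_mass(state: CompartmentState, params: TraffickingParameters) -> float:
    """Total amount, μg per central-compartment volume.

    Along any trajectory d(total)/dt = Q_u * C_e * (f_sort - 1) <= 0, so
    this is constant exactly when f_sort = 1 (no lysosomal loss) or the
    endosome is empty.
    """
    return state.C_c + params.V_p * state.C_p + params.V_e * state.C_e


def _slow_eigenvalue(M: np.ndarray) -> float:
    """Real part of the eigenvalue closest to zero (the terminal rate)."""
    eig = np.linalg.eigvals(M)
    return float(np.max(eig.real))


def terminal_half_life(params: TraffickingParameters, variant: str) -> float:
    """Terminal (β-phase) half-life in hours: ln 2 / |λ_slow|.

    λ_slow is the rate-matrix eigenvalue of smallest magnitude.  A
    closed system (f_sort = f_release = 1) has a zero eigenvalue and the
    half-life is reported as ``math.inf`` rather than raising.
    """
    M = build_rate_matrix(params, variant)
    lam = _slow_eigenvalue(M)
    scale = np.abs(M).max()
    if scale == 0.0 or -lam < _RATE_FLOOR * scale:
        return math.inf
    return math.log(2.0) / (-lam)


def time_to_half(
    state0: CompartmentState,
    params: TraffickingParameters,
    variant: str,
    rtol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """Smallest t > 0 with C_c(t) = C_c(0) / 2, by Newton iteration.

    The derivative comes from d/dt [exp(tM) c0] = M exp(tM) c0.  If
    Newton leaves the bracket found by doubling, a bisection step is
    substituted.  This is the alternative half-life definition to
    :func:`terminal_half_life`; the two coincide for mono-exponential
    decay.
    """
    if state0.C_c <= 0:
        raise ValueError("C_c(0) must be positive")
    if terminal_half_life(params, variant) == math.inf:
        raise ValueError("closed system: central concentration never falls to half")
    M = build_rate_matrix(params, variant)
    c0 = state0.vector
    target = 0.5 * state0.C_c

    def f(t: float) -> tuple[float, float]:
        P = expm(t * M)
        c = P @ c0
        dc = M @ c
        return c[0] - target, dc[0]

    # bracket by doubling from a crude initial scale
    hi = 1.0 / max(np.abs(M).max(), 1e-12)
    f_hi, _ = f(hi)
    n_doublings = 0
    while f_hi > 0:
        hi *= 2.0
        f_hi, _ = f(hi)
        n_doublings += 1
        if n_doublings > 200:
            raise RuntimeError(f"could not bracket the half-time; last t={hi}")
    lo = 0.0

    t = 0.5 * hi
    for _ in range(max_iter):
        val, slope = f(t)
        if val > 0:
            lo = t
        else:
            hi = t
        if slope < 0:
            t_new = t - val / slope
        else:
            t_new = 0.5 * (lo + hi)
        if not (lo < t_new < hi):
            t_new = 0.5 * (lo + hi)
        if abs(t_new - t) <= rtol * max(t_new, 1e-300):
            return t_new
        t = t_new
    raise RuntimeError(
        f"Newton/bisection did not converge in {max_iter} iterations; bracket [{lo}, {hi}]"
    )


def recapture_fraction(params: TraffickingParameters, variant: str) -> float:
    """Surface recapture 1 - f_release: fraction of surface-presented IgG
    that is endocytosed again instead of being released."""
    _, fr = params.for_variant(variant)
    return 1.0 - fr
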