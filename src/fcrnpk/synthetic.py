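"""Synthetic study generator and packaged study fixtures.

Emulates the inputs of a mouse PK study of Fc-engineered IgG variants —
2 mg/kg i.v. bolus dosing, tail-vein sampling at fixed times,
multiplicative (log-normal) assay noise with lower-limit-of-
quantification censoring — plus 1:1 Langmuir SPR isotherms and
gold-nanoparticle absorbance spectra.  Printed study summaries
(half-life tables, FcRn affinity tables, PK summary tables) ship as
small CSV fixtures and are loaded here.

Real serum ELISA data differ from these simulations in ways the
generator deliberately ignores: between-animal parameter variability,
correlated within-animal errors, and standard-curve nonlinearity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import Isotherm, Spectrum
from .bayes import (
    AffinityTable,
    HalfLifeObservation,
    PosteriorFit,
    build_priors,
    run_mcmc,
)
from .pk import HOURS_PER_DAY, BiexponentialFit, ConcentrationTimeSeries
from .trafficking import CompartmentState, TraffickingParameters, propagate

__all__ = [
    "StudyDesign",
    "DEFAULT_SAMPLING_HOURS",
    "DEFAULT_CONC_LADDER_NM",
    "PLASMA_VOLUME_ML_PER_KG",
    "simulate_pk_study",
    "fit_packaged_study",
    "make_half_life_fixtures",
    "make_affinity_fixture",
    "make_pk_summary_fixture",
    "simulate_isotherm",
    "simulate_spectrum",
]

#: sampling schedule: 1 h, 6 h, then days 1, 2, 4, 7, 10, 14, 21, 28
DEFAULT_SAMPLING_HOURS = (1.0, 6.0, 24.0, 48.0, 96.0, 168.0, 240.0, 336.0, 504.0, 672.0)

#: serial two-fold dilution from 1000 nM with the last step clamped to 40 nM
DEFAULT_CONC_LADDER_NM = (1000.0, 500.0, 250.0, 125.0, 62.5, 40.0)

#: nominal mouse plasma volume used to convert a per-kg dose to an
#: initial serum concentration (dose 2 mg/kg -> C0 = 40 μg/mL)
PLASMA_VOLUME_ML_PER_KG = 50.0


@dataclass(frozen=True)
class StudyDesign:
    """Design of a simulated bolus PK study.

    ``truth`` maps variant labels to either a :class:`BiexponentialFit`
    (two-phase serum decay) or a :class:`TraffickingParameters` holding
    that variant's sorting/release fractions.
    """

    truth: Mapping[str, BiexponentialFit | TraffickingParameters]
    dose_mg_kg: float = 2.0
    sampling_hours: Sequence[float] = DEFAULT_SAMPLING_HOURS
    n_animals: int = 6
    noise_cv: float = 0.10
    lloq: float = 0.01  # μg/mL
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_hours, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.noise_cv < 0 or self.n_animals < 1 or self.dose_mg_kg <= 0:
            raise ValueError("require noise_cv >= 0, n_animals >= 1, dose > 0")

    @property
    def dose_ug_kg(self) -> float:
        return self.dose_mg_kg * 1000.0

    @property
    def c0(self) -> float:
        """Initial serum concentration after the bolus, μg/mL."""
        return self.dose_ug_kg / PLASMA_VOLUME_ML_PER_KG


def _predict_curve(truth, times_h: np.ndarray, c0: float) -> np.ndarray:
    if isinstance(truth, BiexponentialFit):
        return truth(times_h / HOURS_PER_DAY)
    if isinstance(truth, TraffickingParameters):
        (variant,) = truth.variants or list(truth.f_sort)
        state0 = CompartmentState.bolus(c0)
        return np.array(
            [propagate(state0, truth, t, variant).C_c for t in times_h]
        )
    raise TypeError(f"unsupported truth type {type(truth).__name__}")


def simulate_pk_study(design: StudyDesign) -> list[ConcentrationTimeSeries]:
    """Per-animal serum curves: model prediction × log-normal noise.

    The noise factor is exp(ε) with ε ~ Normal(0, σ), σ = ln(1 + CV²)^½,
    so the coefficient of variation of the simulated values equals the
    design CV.  Values below the LLOQ are kept in the table but flagged
    censored.  Identical designs (including seed) give identical data.
    """
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sampling_hours, dtype=float)
    sigma = np.sqrt(np.log1p(design.noise_cv**2))
    out = []
    for variant in design.truth:
        clean = _predict_curve(design.truth[variant], times, design.c0)
        for animal in range(design.n_animals):
            eps = rng.normal(0.0, sigma, size=times.shape) if sigma > 0 else 0.0
            conc = clean * np.exp(eps)
            out.append(
                ConcentrationTimeSeries(
                    subject_id=f"{variant}-{animal + 1:02d}",
                    variant=variant,
                    dose=design.dose_ug_kg,
                    times=times,
                    concentrations=conc,
                    censored=conc < design.lloq,
                )
            )
    return out


# ---------------------------------------------------------------------------
# packaged study fixtures


def _read_fixture(name: str) -> pd.DataFrame:
    with importlib.resources.files("fcrnpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def make_half_life_fixtures(strain: str) -> list[HalfLifeObservation]:
    """β-phase half-life observations (mean ± SD, n animals) for one
    FcRn-humanized strain: ``Tg276`` (n=11) or ``Scarlett`` (n=6)."""
    df = _read_fixture("half_lives.csv")
    sub = df[df["study"] == strain]
    if sub.empty:
        raise KeyError(f"unknown strain {strain!r}; have {sorted(df['study'].unique())}")
    return [
        HalfLifeObservation(variant=r.variant, mean=r.mean_h, sd=r.sd_h, n=int(r.n))
        for r in sub.itertuples()
    ]


def make_affinity_fixture() -> AffinityTable:
    """FcRn affinities: K_D at pH 5.8 per variant plus pH-7.4
    detectability per immobilization density and the high-density
    pH-7.4 K_D where measurable."""
    df = _read_fixture("affinities.csv").set_index("variant")
    return AffinityTable(
        kd_ph58={v: float(r["kd_ph58_nm"]) for v, r in df.iterrows()},
        ph74_detectable={
            v: {
                "low": bool(r["ph74_low_detectable"]),
                "medium": bool(r["ph74_medium_detectable"]),
                "high": bool(r["ph74_high_detectable"]),
            }
            for v, r in df.iterrows()
        },
        kd_ph74_high={
            v: float(r["kd_ph74_high_nm"])
            for v, r in df.iterrows()
            if pd.notna(r["kd_ph74_high_nm"])
        },
    )


def make_pk_summary_fixture(strain: str) -> pd.DataFrame:
    """Per-variant mean PK summary table (AUC_inf μg·day/mL, CL,
    β-phase T½ h, Vss mL/kg, C_max μg/mL) for one strain, indexed by
    variant; used for fold-change arithmetic."""
    df = _read_fixture("pk_summary.csv")
    sub = df[df["study"] == strain].drop(columns="study").set_index("variant")
    if sub.empty:
        raise KeyError(f"unknown strain {strain!r}")
    return sub.dropna(axis=1, how="all")


def fit_packaged_study(
    strain: str,
    seed: int,
    n_chains: int = 4,
    n_warmup: int = 8000,
    n_samples: int = 256000,
    n_walkers: int = 64,
    **kwargs,
) -> PosteriorFit:
    """Fit the trafficking model to one strain's packaged half-life
    observations with priors built from the packaged affinity table.

    The defaults are the study conditions used throughout: 4 chains of
    64 walkers, 8,000 discarded ensemble moves and 4,000 retained moves
    (256,000 post-warmup draws) per chain.
    """
    observations = make_half_life_fixtures(strain)
    priors = build_priors(
        make_affinity_fixture(), variants=[o.variant for o in observations]
    )
    return run_mcmc(
        observations, priors, seed=seed, n_chains=n_chains, n_warmup=n_warmup,
        n_samples=n_samples, n_walkers=n_walkers, **kwargs,
    )


# ---------------------------------------------------------------------------
# assay input simulators


def simulate_isotherm(
    kd: float,
    rmax: float,
    conc_series: Sequence[float] = DEFAULT_CONC_LADDER_NM,
    noise_cv: float = 0.0,
    seed: int = 0,
    density: str = "low",
    pH: float = 5.8,
) -> Isotherm:
    """Steady-state SPR isotherm: 1:1 Langmuir responses × log-normal noise."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    c = np.asarray(conc_series, dtype=float)
    r = rmax * c / (kd + c)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        r = r * np.exp(rng.normal(0.0, np.sqrt(np.log1p(noise_cv**2)), size=c.shape))
    return Isotherm(concentrations=c, responses=r, density=density, pH=pH)


def simulate_spectrum(
    center: float = 535.0,
    width: float = 30.0,
    amplitude: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    wavelengths: Sequence[float] | None = None,
) -> Spectrum:
    """Gaussian plasmon absorbance band on the 450–650 nm, 1 nm grid,
    with optional additive noise (fraction of the amplitude)."""
    if width <= 0 or amplitude <= 0:
        raise ValueError("width and amplitude must be positive")
    w = (
        np.arange(450.0, 651.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    a = amplitude * np.exp(-0.5 * ((w - center) / width) ** 2)
    if noise > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise * amplitude, size=w.shape)
    return Spectrum(wavelengths=w, absorbances=a)
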