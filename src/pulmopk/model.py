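"""Structural model for pulmonary drug distribution.

The plasma pharmacokinetic submodel is a transit-compartment absorption
chain feeding a one-compartment disposition model whose oral clearance is
multiplied by a slowly-turning-over enzyme pool: the plasma concentration
stimulates enzyme production through an Emax relationship, so the drug
induces its own elimination (autoinduction, the hallmark of rifampicin).
Lung exposure is described by two effect compartments driven by the plasma
concentration,

    dC_ELF/dt = k_ELF * (R_ELF/plasma * Cp - C_ELF)
    dC_AC/dt  = k_AC  * (R_AC/plasma  * Cp - C_AC)

where the rate constants set how fast epithelial lining fluid (ELF) and
alveolar cells (AC) equilibrate with plasma and the ratios set the extent
of distribution at pseudo steady state.  Typical clearance and central
volume scale allometrically with a body-size descriptor (bodyweight,
fat-free mass, or normal fat mass) standardised to 70 kg.

Units throughout: amounts mg, volumes L, times h, concentrations mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "SubjectCovariates",
    "SizeDescriptors",
    "PopulationParameters",
    "ModelState",
    "compute_ffm",
    "compute_nfm",
    "size_descriptors",
    "allometric_typical_values",
    "enzyme_production_multiplier",
    "ode_rhs",
    "unbound_ratio",
    "equilibration_half_life_minutes",
    "enzyme_time_to_steady_state_days",
]

#: Sex-specific constants of the fat-free-mass model: WHS_max (maximal
#: weight per height squared, kg/m^2) and WHS_50 (weight per height squared
#: at half WHS_max, kg/m^2).
FFM_CONSTANTS: dict[str, tuple[float, float]] = {
    "male": (42.92, 30.93),
    "female": (37.99, 35.98),
}

#: Standard mass (kg) to which allometric typical values are referenced.
STANDARD_MASS = 70.0

CL_ALLOMETRIC_EXPONENT = 0.75
VC_ALLOMETRIC_EXPONENT = 1.0

SCALING_MODES = ("none", "bodyweight", "ffm", "nfm")

Sex = Literal["male", "female"]

#: Parameters estimated (rather than fixed) in the reference analysis.
DEFAULT_ESTIMATED: tuple[str, ...] = (
    "cl_std",
    "vc_std",
    "r_elf_plasma",
    "r_ac_plasma",
    "omega_cl",
    "sigma_plasma",
    "sigma_elf",
    "sigma_ac",
)


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates of one subject driving the body-size descriptors."""

    subject_id: int | str
    sex: Sex
    weight: float  # kg
    height: float  # m

    def __post_init__(self) -> None:
        if self.sex not in FFM_CONSTANTS:
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.weight > 0:
            raise InvalidInputError(f"weight must be positive, got {self.weight}")
        if not self.height > 0:
            raise InvalidInputError(f"height must be positive, got {self.height}")


@dataclass(frozen=True)
class SizeDescriptors:
    """Body-size descriptors of one subject (all kg)."""

    ffm: float
    nfm_cl: float
    nfm_v: float
    bodyweight: float


def compute_ffm(sex: Sex, weight: float, height: float) -> float:
    """Fat-free mass (kg) from sex, weight (kg) and height (m).

    FFM = WHS_max * HT^2 * WT / (WHS_50 * HT^2 + WT), with sex-specific
    WHS_max and WHS_50.  The result is strictly below ``WHS_max * HT^2``
    and below total bodyweight for physiologic inputs.
    """
    if sex not in FFM_CONSTANTS:
        raise InvalidInputError(f"sex must be 'male' or 'female', got {sex!r}")
    if not weight > 0:
        raise InvalidInputError(f"weight must be positive, got {weight}")
    if not height > 0:
        raise InvalidInputError(f"height must be positive, got {height}")
    whs_max, whs_50 = FFM_CONSTANTS[sex]
    ht2 = height * height
    return whs_max * ht2 * weight / (whs_50 * ht2 + weight)


def compute_nfm(ffm: float, weight: float, ffat: float) -> float:
    """Normal fat mass (kg): FFM plus a fraction ``ffat`` of the fat mass.

    ``ffat`` is the estimated contribution of fat mass; 0 collapses NFM to
    FFM and 1 to total bodyweight.
    """
    if not 0 < ffm <= weight:
        raise InvalidInputError(f"require 0 < ffm <= weight, got ffm={ffm}, weight={weight}")
    return ffm + ffat * (weight - ffm)


@dataclass
class PopulationParameters:
    """Fixed effects, variability and constants of the population model.

    ``ka`` has no published value and therefore no default: it must be
    supplied explicitly (the reference configuration uses 2.0 h^-1, a
    package choice making absorption much faster than elimination).
    All other defaults are the final published estimates.

    ``omega_cl`` is the standard deviation of the lognormal between-subject
    variability on CL/F; ``sigma_*`` are proportional residual-error SDs
    per observation matrix.  ``estimated`` lists the parameters freed in
    the reference fit; everything else is fixed (``fixed_mask``).
    """

    ka: float  # 1/h, absorption rate constant (configuration-required)
    cl_std: float = 3.85  # L/h, typical pre-induced CL/F at 70 kg
    vc_std: float = 76.6  # L, typical Vc/F at 70 kg
    mtt: float = 0.71  # h, mean transit time (fixed)
    n_transit: int = 1  # number of transit compartments (fixed)
    emax: float = 1.04  # maximal autoinduction of CL/F (fixed)
    ec50: float = 0.0705  # mg/L, concentration at half-maximal induction (fixed)
    k_enz: float = 0.0036  # 1/h, enzyme-pool turnover rate (fixed)
    k_elf: float = 41.58  # 1/h, plasma->ELF distribution rate (fixed)
    k_ac: float = 41.58  # 1/h, plasma->AC distribution rate (fixed)
    r_elf_plasma: float = 0.26  # total ELF/plasma concentration ratio
    r_ac_plasma: float = 1.1  # total AC/plasma concentration ratio
    fu_plasma: float = 0.2  # unbound fraction of drug in plasma
    ffat_cl: float = 0.5  # fat-mass contribution to NFM for CL/F
    ffat_v: float = 0.5  # fat-mass contribution to NFM for V/F
    omega_cl: float = 0.888  # SD of lognormal IIV on CL/F
    sigma_plasma: float = 0.352  # proportional residual SD, plasma
    sigma_elf: float = 0.407  # proportional residual SD, ELF
    sigma_ac: float = 0.371  # proportional residual SD, AC
    scaling_mode: str = "ffm"
    estimated: tuple[str, ...] = DEFAULT_ESTIMATED

    def __post_init__(self) -> None:
        for name in ("ka", "cl_std", "vc_std", "mtt", "ec50", "k_enz", "k_elf",
                     "k_ac", "r_elf_plasma", "r_ac_plasma"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        # zero variability is a legitimate deterministic limit in simulation;
        # the estimator enforces positivity for freed variance parameters
        for name in ("emax", "omega_cl", "sigma_plasma", "sigma_elf", "sigma_ac"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")
        if not (isinstance(self.n_transit, (int, np.integer)) and self.n_transit >= 0):
            raise InvalidInputError("n_transit must be a nonnegative integer")
        if not 0 < self.fu_plasma <= 1:
            raise InvalidInputError("fu_plasma must lie in (0, 1]")
        for name in ("ffat_cl", "ffat_v"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        if self.scaling_mode not in SCALING_MODES:
            raise ConfigurationError(
                f"unknown scaling_mode {self.scaling_mode!r}; choose from {SCALING_MODES}"
            )

    @property
    def fixed_mask(self) -> dict[str, bool]:
        """Per-parameter flag: True where the parameter is fixed."""
        names = ("cl_std", "vc_std", "mtt", "n_transit", "ka", "emax", "ec50",
                 "k_enz", "k_elf", "k_ac", "r_elf_plasma", "r_ac_plasma",
                 "fu_plasma", "ffat_cl", "ffat_v", "omega_cl",
                 "sigma_plasma", "sigma_elf", "sigma_ac")
        return {n: n not in self.estimated for n in names}

    @property
    def ktr(self) -> float:
        """Transit rate constant (N + 1) / MTT, 1/h."""
        return (self.n_transit + 1) / self.mtt

    def sigma_for(self, matrix: str) -> float:
        try:
            return {"plasma": self.sigma_plasma, "elf": self.sigma_elf,
                    "ac": self.sigma_ac}[matrix]
        except KeyError:
            raise InvalidInputError(f"unknown matrix {matrix!r}") from None

    def replace(self, **changes) -> "PopulationParameters":
        return replace(self, **changes)

    def iiv_percent(self, convention: str = "sd") -> float:
        """Between-subject variability on CL/F as a percentage.

        ``sd``: 100 * omega (the convention used for comparison with the
        reference analysis); ``cv``: 100 * sqrt(exp(omega^2) - 1), the exact
        lognormal coefficient of variation.
        """
        if convention == "sd":
            return 100.0 * self.omega_cl
        if convention == "cv":
            return 100.0 * math.sqrt(math.expm1(self.omega_cl ** 2))
        raise InvalidInputError("convention must be 'sd' or 'cv'")


def size_descriptors(cov: SubjectCovariates, params: PopulationParameters) -> SizeDescriptors:
    """All body-size descriptors of one subject under ``params``."""
    ffm = compute_ffm(cov.sex, cov.weight, cov.height)
    return SizeDescriptors(
        ffm=ffm,
        nfm_cl=compute_nfm(ffm, cov.weight, params.ffat_cl),
        nfm_v=compute_nfm(ffm, cov.weight, params.ffat_v),
        bodyweight=cov.weight,
    )


def allometric_typical_values(
    params: PopulationParameters, cov: SubjectCovariates
) -> tuple[float, float]:
    """Typical (CL/F, Vc/F) of a subject under the configured scaling mode.

    CL scales with (MASS/70)^0.75 and Vc with (MASS/70)^1, where MASS is
    the size descriptor chosen by ``params.scaling_mode``; ``none`` returns
    the standardised values unchanged.
    """
    mode = params.scaling_mode
    if mode == "none":
        return params.cl_std, params.vc_std
    if mode == "bodyweight":
        mass_cl = mass_v = cov.weight
    elif mode == "ffm":
        mass_cl = mass_v = compute_ffm(cov.sex, cov.weight, cov.height)
    elif mode == "nfm":
        ffm = compute_ffm(cov.sex, cov.weight, cov.height)
        mass_cl = compute_nfm(ffm, cov.weight, params.ffat_cl)
        mass_v = compute_nfm(ffm, cov.weight, params.ffat_v)
    else:  # pragma: no cover - caught at construction
        raise ConfigurationError(f"unknown scaling_mode {mode!r}")
    cl_typ = params.cl_std * (mass_cl / STANDARD_MASS) ** CL_ALLOMETRIC_EXPONENT
    vc_typ = params.vc_std * (mass_v / STANDARD_MASS) ** VC_ALLOMETRIC_EXPONENT
    return cl_typ, vc_typ


def enzyme_production_multiplier(cp: float, emax: float, ec50: float) -> float:
    """Drug effect on enzyme production: 1 + Emax * Cp / (EC50 + Cp).

    Strictly increasing in the plasma concentration and bounded above by
    1 + Emax; equals 1 without drug on board.
    """
    cp = np.maximum(cp, 0.0)
    return 1.0 + emax * cp / (ec50 + cp)


@dataclass
class ModelState:
    """Instantaneous state of the structural system.

    ``enzyme_pool`` is normalised to 1 at the pre-induced baseline, where
    production and elimination balance.
    """

    transit_amounts: np.ndarray  # mg, length n_transit
    absorption_amount: float  # mg
    central_amount: float  # mg
    enzyme_pool: float = 1.0  # dimensionless
    c_elf: float = 0.0  # mg/L
    c_ac: float = 0.0  # mg/L

    @classmethod
    def initial(cls, n_transit: int) -> "ModelState":
        """Induction-naive state: no drug on board, enzyme pool at baseline."""
        return cls(np.zeros(n_transit), 0.0, 0.0, 1.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(self.transit_amounts, dtype=float),
            [self.absorption_amount, self.central_amount,
             self.enzyme_pool, self.c_elf, self.c_ac],
        ])

    @classmethod
    def from_array(cls, y: np.ndarray, n_transit: int) -> "ModelState":
        y = np.asarray(y, dtype=float)
        return cls(y[:n_transit].copy(), y[n_transit], y[n_transit + 1],
                   y[n_transit + 2], y[n_transit + 3], y[n_transit + 4])


def rhs_array(
    t: float,
    y: np.ndarray,
    params: PopulationParameters,
    cl_typ: float,
    vc_typ: float,
    individual_cl_multiplier: float,
) -> np.ndarray:
    """Right-hand side on the flat state vector (used by the solvers).

    Layout: [transit_1..transit_N, absorption, central, enzyme, C_ELF, C_AC].
    """
    n = params.n_transit
    ktr = params.ktr
    dy = np.zeros_like(y)
    if n > 0:
        dy[0] = -ktr * y[0]
        for k in range(1, n):
            dy[k] = ktr * (y[k - 1] - y[k])
        dy[n] = ktr * y[n - 1] - params.ka * y[n]
    else:
        dy[0] = -params.ka * y[0]
    i_abs, i_c, i_e = n, n + 1, n + 2
    cp = y[i_c] / vc_typ
    cl_t = cl_typ * individual_cl_multiplier * y[i_e]
    dy[i_c] = params.ka * y[i_abs] - cl_t * cp
    dy[i_e] = params.k_enz * enzyme_production_multiplier(cp, params.emax, params.ec50) \
        - params.k_enz * y[i_e]
    dy[i_c + 2] = params.k_elf * (params.r_elf_plasma * cp - y[i_c + 2])
    dy[i_c + 3] = params.k_ac * (params.r_ac_plasma * cp - y[i_c + 3])
    return dy


def ode_rhs(
    state: ModelState,
    t: float,
    params: PopulationParameters,
    individual_cl_multiplier: float,
    cov: SubjectCovariates | None = None,
) -> ModelState:
    """Time derivative of ``state`` (same fields, per hour).

    ``individual_cl_multiplier`` scales the typical clearance (exp(eta) for
    a lognormal random effect; 0 switches elimination off, which is useful
    for mass-balance checks).  Without covariates the 70-kg standard
    subject is assumed, so typical values equal the standardised ones.
    """
    if cov is None:
        cl_typ, vc_typ = params.cl_std, params.vc_std
    else:
        cl_typ, vc_typ = allometric_typical_values(params, cov)
    dy = rhs_array(t, state.as_array(), params, cl_typ, vc_typ,
                   individual_cl_multiplier)
    return ModelState.from_array(dy, params.n_transit)


def unbound_ratio(r_total: float, fu_plasma: float) -> float:
    """Tissue/unbound-plasma ratio from a total ratio and the plasma free
    fraction: ``r_total / fu_plasma``.

    Only unbound drug distributes from blood into tissue, so dividing the
    total ratio by fu references lung exposure to the pharmacologically
    active plasma concentration.
    """
    if not 0 < fu_plasma <= 1:
        raise InvalidInputError(f"fu_plasma must lie in (0, 1], got {fu_plasma}")
    return r_total / fu_plasma


def equilibration_half_life_minutes(k_per_h: float) -> float:
    """Half-life (minutes) of an effect compartment with rate ``k`` (1/h)."""
    if not k_per_h > 0:
        raise InvalidInputError("rate constant must be positive")
    return math.log(2.0) / k_per_h * 60.0


def enzyme_time_to_steady_state_days(k_enz: float, n_half_lives: float = 5.0) -> float:
    """Approximate time (days) for the enzyme pool to reach steady state,
    conventionally ``n_half_lives`` turnover half-lives."""
    if not k_enz > 0:
        raise InvalidInputError("k_enz must be positive")
    return n_half_lives * math.log(2.0) / k_enz / 24.0
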