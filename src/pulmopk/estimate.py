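"""Population-parameter estimation by approximate marginal maximum likelihood.

One lognormal random effect (on CL/F) is handled by an inner bounded Brent
search for its conditional mode per subject; the marginal -2
log-likelihood is the Laplace approximation at that mode with the residual
variance evaluated at the conditional prediction (the interaction term of
FOCE INTER).  The outer problem optimises the free population parameters
on a log scale (logit for the bounded fat-mass fractions) with
Nelder-Mead, which is robust for the small parameter counts involved.

The objective function value (OFV) is the sum over subjects of the
approximate -2 log marginal likelihood including all 2*pi constants;
nested models are compared by OFV differences against chi-squared
critical values (3.84 for one parameter at the 5 % level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.integrate import quad

from . import _kernel
from ._kernel import H_MAX_DEFAULT, MAT_CODE
from .errors import ConfigurationError, InvalidInputError
from .io import validate_event_table
from .model import (
    PopulationParameters,
    SubjectCovariates,
    allometric_typical_values,
    compute_ffm,
)

__all__ = [
    "PackedData",
    "FitResult",
    "pack_dataset",
    "foce_objective",
    "individual_neg2ll",
    "individual_laplace_neg2ll",
    "marginal_neg2ll_quadrature",
    "predict_observations",
    "fit",
    "lrt",
    "standard_errors",
    "numeric_hessian",
    "compare_scaling",
    "write_fit_report",
    "read_fit_report",
]

#: parameters the estimator knows how to free (continuous, kernel inputs)
ESTIMABLE = ("cl_std", "vc_std", "r_elf_plasma", "r_ac_plasma", "omega_cl",
             "sigma_plasma", "sigma_elf", "sigma_ac", "ka", "mtt", "emax",
             "ec50", "k_enz", "k_elf", "k_ac", "ffat_cl", "ffat_v")

_LOGIT_PARAMS = ("ffat_cl", "ffat_v")

_MODE_CODE = {"none": 0, "bodyweight": 1, "ffm": 2, "nfm": 3}


@dataclass
class PackedData:
    """Dataset flattened into the contiguous arrays the kernel consumes."""

    subject_ids: list
    covariates: list[SubjectCovariates]
    wt: np.ndarray
    ffm: np.ndarray
    seg_t: np.ndarray
    seg_bolus: np.ndarray
    seg_out: np.ndarray
    seg_ptr: np.ndarray
    obs_y: np.ndarray
    obs_mat: np.ndarray
    obs_ptr: np.ndarray
    obs_time: np.ndarray
    obs_row: np.ndarray  # positional index of each observation in the source table

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return self.obs_y.size


def pack_dataset(table: pd.DataFrame) -> PackedData:
    """Flatten a validated event table for the compiled kernel.

    Observations flagged missing (``mdv`` = 1) are excluded.  Events are
    merged into per-subject segment lists: at a shared time, observations
    are read before the bolus is applied (pre-dose samples).
    """
    validate_event_table(table)
    table = table.reset_index(drop=True)
    subject_ids, covs = [], []
    wt, ffm = [], []
    seg_t, seg_bolus, seg_out, seg_ptr = [], [], [], [0]
    obs_y, obs_mat, obs_ptr, obs_time, obs_row = [], [], [0], [], []

    for sid, sub in table.groupby("id", sort=False):
        first = sub.iloc[0]
        cov = SubjectCovariates(sid, str(first["sex"]), float(first["weight"]),
                                float(first["height"]))
        subject_ids.append(sid)
        covs.append(cov)
        wt.append(cov.weight)
        ffm.append(compute_ffm(cov.sex, cov.weight, cov.height))

        doses: dict[float, float] = {}
        for _, r in sub[sub["evid"] == 1].iterrows():
            doses[float(r["time"])] = doses.get(float(r["time"]), 0.0) + float(r["amt"])

        obs = sub[(sub["evid"] == 0) & (sub["mdv"] == 0)].sort_values(
            "time", kind="stable")
        obs_at: dict[float, list[int]] = {}
        for pos, (ridx, r) in enumerate(obs.iterrows()):
            g = len(obs_y)
            obs_y.append(float(r["dv"]))
            obs_mat.append(MAT_CODE[r["matrix"]])
            obs_time.append(float(r["time"]))
            obs_row.append(int(ridx))
            obs_at.setdefault(float(r["time"]), []).append(g)

        for t in sorted(set(doses) | set(obs_at)):
            for g in obs_at.get(t, []):
                seg_t.append(t)
                seg_bolus.append(0.0)
                seg_out.append(g)
            if t in doses:
                seg_t.append(t)
                seg_bolus.append(doses[t])
                seg_out.append(-1)
        seg_ptr.append(len(seg_t))
        obs_ptr.append(len(obs_y))

    return PackedData(
        subject_ids=subject_ids,
        covariates=covs,
        wt=np.asarray(wt, float),
        ffm=np.asarray(ffm, float),
        seg_t=np.asarray(seg_t, float),
        seg_bolus=np.asarray(seg_bolus, float),
        seg_out=np.asarray(seg_out, np.int64),
        seg_ptr=np.asarray(seg_ptr, np.int64),
        obs_y=np.asarray(obs_y, float),
        obs_mat=np.asarray(obs_mat, np.int64),
        obs_ptr=np.asarray(obs_ptr, np.int64),
        obs_time=np.asarray(obs_time, float),
        obs_row=np.asarray(obs_row, np.int64),
    )


def _kernel_scalars(p: PopulationParameters) -> tuple:
    return (float(p.ka), float(p.mtt), int(p.n_transit), float(p.emax),
            float(p.ec50), float(p.k_enz), float(p.k_elf), float(p.k_ac))


def foce_objective(
    params: PopulationParameters,
    packed: PackedData,
    h_max: float = H_MAX_DEFAULT,
) -> tuple[float, np.ndarray, np.ndarray]:
    """OFV under ``params`` plus conditional modes (empirical-Bayes etas)
    and per-subject curvature flags (1 = positive curvature at the mode)."""
    if not params.omega_cl > 0:
        raise InvalidInputError("omega_cl must be > 0 for marginal estimation")
    eta_out = np.zeros(packed.n_subjects)
    flag_out = np.zeros(packed.n_subjects, np.int64)
    total = _kernel.foce_neg2ll_kernel(
        float(params.cl_std), float(params.vc_std),
        float(params.r_elf_plasma), float(params.r_ac_plasma),
        float(params.omega_cl), float(params.sigma_plasma),
        float(params.sigma_elf), float(params.sigma_ac),
        float(params.ffat_cl), float(params.ffat_v),
        _MODE_CODE[params.scaling_mode],
        *_kernel_scalars(params),
        packed.wt, packed.ffm,
        packed.seg_t, packed.seg_bolus, packed.seg_out, packed.seg_ptr,
        packed.obs_y, packed.obs_mat, packed.obs_ptr,
        h_max, eta_out, flag_out)
    return float(total), eta_out, flag_out


def _single_subject(packed_or_table) -> PackedData:
    packed = packed_or_table if isinstance(packed_or_table, PackedData) \
        else pack_dataset(packed_or_table)
    if packed.n_subjects != 1:
        raise InvalidInputError("expected data from exactly one subject")
    return packed


def individual_neg2ll(
    subject_data: pd.DataFrame | PackedData,
    params: PopulationParameters,
    eta_cl: float,
    h_max: float = H_MAX_DEFAULT,
) -> float:
    """Joint -2 log-likelihood of one subject's observations and random
    effect at ``eta_cl``:

        sum_obs [log(2 pi v) + (y - f)^2 / v] + eta^2/omega^2 + log(2 pi omega^2)

    with v = f(eta)^2 * sigma_matrix^2 (eta-epsilon interaction), floored
    at (1e-10 mg/L)^2 where the conditional prediction vanishes.
    """
    packed = _single_subject(subject_data)
    if not params.omega_cl > 0:
        raise InvalidInputError("omega_cl must be > 0")
    cov = packed.covariates[0]
    cl_typ, vc_typ = allometric_typical_values(params, cov)
    n = packed.n_obs
    bufs = (np.empty(n), np.empty(n), np.empty(n))
    ka, mtt, n_tr, emax, ec50, kenz, kelf, kac = _kernel_scalars(params)
    absv = _kernel._absorption_grid(ka, (n_tr + 1) / mtt, n_tr,
                                    packed.seg_t, packed.seg_bolus, h_max)
    return float(_kernel._subject_joint(
        float(eta_cl), cl_typ, vc_typ,
        float(params.r_elf_plasma), float(params.r_ac_plasma),
        float(params.sigma_plasma), float(params.sigma_elf),
        float(params.sigma_ac), float(params.omega_cl),
        ka, emax, ec50, kenz, kelf, kac,
        packed.seg_t, packed.seg_out, absv,
        packed.obs_y, packed.obs_mat, 0, n, h_max, *bufs))


def individual_laplace_neg2ll(
    subject_data: pd.DataFrame | PackedData,
    params: PopulationParameters,
    h_max: float = H_MAX_DEFAULT,
) -> float:
    """Laplace-approximated -2 log marginal likelihood of one subject
    (the same quantity the fit objective sums over subjects)."""
    packed = _single_subject(subject_data)
    total, _, _ = foce_objective(params, packed, h_max)
    return total


def marginal_neg2ll_quadrature(
    subject_data: pd.DataFrame | PackedData,
    params: PopulationParameters,
    h_max: float = H_MAX_DEFAULT,
) -> float:
    """-2 log of the exact marginal likelihood of one subject, by adaptive
    quadrature over the random effect.  Slow; the independent check for the
    Laplace approximation on small instances."""
    packed = _single_subject(subject_data)

    def j_of(eta: float) -> float:
        return individual_neg2ll(packed, params, eta, h_max)

    half = 8.0 * params.omega_cl + 0.1
    res = optimize.minimize_scalar(j_of, bounds=(-half, half), method="bounded",
                                   options={"xatol": 1e-8})
    j0 = float(res.fun)
    span = 12.0 * params.omega_cl + 1.0
    val, _ = quad(lambda e: math.exp(-(j_of(e) - j0) / 2.0),
                  res.x - span, res.x + span, limit=200)
    return j0 - 2.0 * math.log(val)


def predict_observations(
    dataset: pd.DataFrame | PackedData,
    params: PopulationParameters,
    etas: np.ndarray | None = None,
    h_max: float = H_MAX_DEFAULT,
) -> np.ndarray:
    """Noise-free prediction per packed observation; ``etas`` defaults to
    zero (population predictions, PRED)."""
    packed = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset)
    if etas is None:
        etas = np.zeros(packed.n_subjects)
    etas = np.asarray(etas, float)
    if etas.shape != (packed.n_subjects,):
        raise InvalidInputError("etas must have one entry per subject")
    pred = np.empty(packed.n_obs)
    _kernel.predict_kernel(
        float(params.cl_std), float(params.vc_std),
        float(params.r_elf_plasma), float(params.r_ac_plasma),
        float(params.ffat_cl), float(params.ffat_v),
        _MODE_CODE[params.scaling_mode],
        *_kernel_scalars(params),
        packed.wt, packed.ffm,
        packed.seg_t, packed.seg_bolus, packed.seg_out, packed.seg_ptr,
        packed.obs_mat, packed.obs_ptr,
        etas, h_max, pred)
    return pred


# ---------------------------------------------------------------------------
# parameter transforms

def _to_internal(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        v = min(max(value, 1e-6), 1 - 1e-6)
        return math.log(v / (1 - v))
    if not value > 0:
        raise InvalidInputError(f"start value for {name} must be > 0, got {value}")
    return math.log(value)


def _from_internal(name: str, x: float) -> float:
    x = min(max(x, -300.0), 300.0)
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x)


def _dnatural_dinternal(name: str, value: float) -> float:
    """Jacobian d(natural)/d(internal) at the estimate, for the delta method."""
    if name in _LOGIT_PARAMS:
        return value * (1.0 - value)
    return value


@dataclass
class FitResult:
    """Outcome of a population fit."""

    estimates: PopulationParameters
    free: tuple[str, ...]
    ofv: float
    etas: dict
    converged: bool
    n_function_evals: int
    se: dict[str, float] | None = None
    rse_percent: dict[str, float] | None = None
    se_ok: bool = False
    curvature_ok: bool = True
    message: str = ""


def _check_bal_identifiability(table: pd.DataFrame, free: tuple[str, ...]) -> None:
    """Distribution rate constants need >= 2 distinct BAL sampling times
    (nominal where recorded); a single shared time only informs the extent
    of distribution, so freeing k_elf/k_ac there is refused."""
    for par, matrix in (("k_elf", "elf"), ("k_ac", "ac")):
        if par not in free:
            continue
        obs = table[(table["evid"] == 0) & (table["matrix"] == matrix)]
        if "nominal_time" in obs.columns and obs["nominal_time"].notna().any():
            times = obs["nominal_time"].dropna()
        else:
            times = obs["time"]
        if times.round(2).nunique() < 2:
            raise ConfigurationError(
                f"cannot free {par}: the design has fewer than two distinct "
                f"{matrix.upper()} sampling times, so the rate of distribution "
                "is not identifiable (only the extent is)")


def fit(
    dataset: pd.DataFrame,
    start: PopulationParameters,
    free: tuple[str, ...] | None = None,
    *,
    h_max: float = H_MAX_DEFAULT,
    compute_se: bool = True,
    optimizer: str = "lbfgsb",
    optimizer_options: dict | None = None,
    polish: bool = True,
) -> FitResult:
    """Maximise the approximate marginal likelihood over the free parameters.

    ``free`` defaults to ``start.estimated``.  Positive parameters are
    optimised on the log scale, fat-mass fractions on the logit scale.
    The default outer optimiser is bounded L-BFGS-B with finite-difference
    gradients followed by a short Nelder-Mead polish (guarding against
    finite-difference artefacts); ``optimizer='nelder-mead'`` selects a
    pure simplex search.  Non-convergence is reported through the result
    flags, not raised.
    """
    free = tuple(free if free is not None else start.estimated)
    for name in free:
        if name not in ESTIMABLE:
            raise ConfigurationError(f"parameter {name!r} cannot be estimated")
    _check_bal_identifiability(dataset, free)
    packed = pack_dataset(dataset)

    x0 = np.array([_to_internal(n, getattr(start, n)) for n in free])
    n_eval = 0

    def build(x: np.ndarray) -> PopulationParameters:
        return start.replace(**{n: _from_internal(n, xi) for n, xi in zip(free, x)})

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        if np.any(np.abs(x) > 40):
            return 1e12
        total, _, _ = foce_objective(build(x), packed, h_max)
        return total if np.isfinite(total) else 1e12

    if optimizer == "lbfgsb":
        opts = {"eps": 1e-5, "maxfun": 2000, "ftol": 1e-9, "gtol": 5e-5}
        opts.update(optimizer_options or {})
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=[(-12.0, 12.0)] * x0.size, options=opts)
        if polish:
            res_p = optimize.minimize(
                objective, res.x, method="Nelder-Mead",
                options={"maxfev": 300, "xatol": 1e-3, "fatol": 0.05,
                         "adaptive": True})
            if res_p.fun <= res.fun:
                res_p.success = res_p.success or res.success
                res = res_p
    elif optimizer == "nelder-mead":
        opts = {"maxfev": 3000, "xatol": 5e-4, "fatol": 0.02, "adaptive": True}
        opts.update(optimizer_options or {})
        res = optimize.minimize(objective, x0, method="Nelder-Mead", options=opts)
    else:
        raise ConfigurationError(f"unknown optimizer {optimizer!r}")

    estimates = build(res.x)
    ofv, etas, flags = foce_objective(estimates, packed, h_max)
    result = FitResult(
        estimates=estimates,
        free=free,
        ofv=ofv,
        etas={str(sid): float(e) for sid, e in zip(packed.subject_ids, etas)},
        converged=bool(res.success),
        n_function_evals=n_eval,
        curvature_ok=bool(np.all(flags == 1)),
        message=str(res.message),
    )
    if compute_se:
        se, rse, ok = standard_errors(result, packed, h_max=h_max)
        result.se, result.rse_percent, result.se_ok = se, rse, ok
    return result


def numeric_hessian(fun, x: np.ndarray, step: float = 5e-3) -> np.ndarray:
    """Central finite-difference Hessian of ``fun`` at ``x``."""
    x = np.asarray(x, float)
    p = x.size
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        hess[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess


def standard_errors(
    fit_result: FitResult,
    dataset: pd.DataFrame | PackedData,
    h_max: float = H_MAX_DEFAULT,
) -> tuple[dict[str, float] | None, dict[str, float] | None, bool]:
    """Asymptotic standard errors of the free parameters.

    The covariance is twice the inverse of the numeric Hessian of the OFV
    (-2 log-likelihood) on the internal scale, mapped to the natural scale
    by the delta method.  When the Hessian is not positive definite no SEs
    are reported and the flag is False.  Fixed parameters get no SE.
    RSE% = 100 * SE / |estimate|.
    """
    packed = dataset if isinstance(dataset, PackedData) else pack_dataset(dataset)
    est = fit_result.estimates
    free = fit_result.free
    x_opt = np.array([_to_internal(n, getattr(est, n)) for n in free])

    def objective(x: np.ndarray) -> float:
        p = est.replace(**{n: _from_internal(n, xi) for n, xi in zip(free, x)})
        total, _, _ = foce_objective(p, packed, h_max)
        return total

    hess = numeric_hessian(objective, x_opt)
    try:
        eigvals = np.linalg.eigvalsh(hess)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return None, None, False
    if np.min(eigvals) <= 0 or not np.all(np.isfinite(hess)):
        return None, None, False
    cov = 2.0 * np.linalg.inv(hess)
    se, rse = {}, {}
    for i, n in enumerate(free):
        value = getattr(est, n)
        se_nat = math.sqrt(max(cov[i, i], 0.0)) * abs(_dnatural_dinternal(n, value))
        se[n] = se_nat
        rse[n] = 100.0 * se_nat / abs(value)
    return se, rse, True


def lrt(ofv_full: float, ofv_reduced: float, d_params: int) -> tuple[float, bool]:
    """Likelihood-ratio test between nested fits.

    Returns (delta OFV, significant at the 5 % level), where the reduced
    model is rejected when the OFV drop exceeds the chi-squared 95th
    percentile with ``d_params`` degrees of freedom (3.84 for one).
    """
    if d_params < 1:
        raise InvalidInputError("d_params must be >= 1")
    delta = ofv_reduced - ofv_full
    return float(delta), bool(delta > stats.chi2.ppf(0.95, d_params))


def lrt_threshold(d_params: int = 1) -> float:
    """Chi-squared 5 % critical value used by :func:`lrt`."""
    if d_params < 1:
        raise InvalidInputError("d_params must be >= 1")
    return float(stats.chi2.ppf(0.95, d_params))


def compare_scaling(
    dataset: pd.DataFrame,
    start: PopulationParameters,
    modes: tuple[str, ...] = ("none", "bodyweight", "ffm", "nfm"),
    **fit_kwargs,
) -> tuple[pd.DataFrame, str, dict[str, FitResult]]:
    """Fit every allometric scaling mode and rank them.

    Selection rule: among the models whose OFV lies within 3.84 of the
    minimum, pick the one with the fewest free parameters (OFV as the tie
    break) — a model is only worth extra parameters when it buys a
    significant OFV drop.
    """
    results: dict[str, FitResult] = {}
    rows = []
    for mode in modes:
        free = tuple(start.estimated)
        if mode == "nfm":
            free = free + tuple(p for p in ("ffat_cl", "ffat_v") if p not in free)
        mode_start = start.replace(scaling_mode=mode)
        r = fit(dataset, mode_start, free=free, **fit_kwargs)
        results[mode] = r
        rows.append({"scaling_mode": mode, "ofv": r.ofv, "n_free": len(free),
                     "converged": r.converged})
    ranking = pd.DataFrame(rows).sort_values("ofv", ignore_index=True)
    best_ofv = ranking["ofv"].min()
    candidates = ranking[ranking["ofv"] <= best_ofv + 3.84]
    selected = candidates.sort_values(["n_free", "ofv"]).iloc[0]["scaling_mode"]
    ranking["selected"] = ranking["scaling_mode"] == selected
    return ranking, str(selected), results


# ---------------------------------------------------------------------------
# fit report serialisation

def write_fit_report(fit_result: FitResult, path) -> None:
    """Structured plain-text (YAML) fit report: estimates, uncertainty,
    objective value and convergence diagnostics."""
    est = fit_result.estimates
    import dataclasses as _dc
    payload = {
        "ofv": float(fit_result.ofv),
        "converged": bool(fit_result.converged),
        "curvature_ok": bool(fit_result.curvature_ok),
        "n_function_evals": int(fit_result.n_function_evals),
        "message": fit_result.message,
        "free_parameters": list(fit_result.free),
        "estimates": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in _dc.asdict(est).items()},
        "standard_errors": fit_result.se,
        "rse_percent": fit_result.rse_percent,
        "se_ok": bool(fit_result.se_ok),
        "etas": fit_result.etas,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_fit_report(path) -> FitResult:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    raw = dict(payload["estimates"])
    raw["estimated"] = tuple(raw.get("estimated", ()))
    est = PopulationParameters(**raw)
    return FitResult(
        estimates=est,
        free=tuple(payload["free_parameters"]),
        ofv=float(payload["ofv"]),
        etas=payload.get("etas", {}),
        converged=bool(payload["converged"]),
        n_function_evals=int(payload["n_function_evals"]),
        se=payload.get("standard_errors"),
        rse_percent=payload.get("rse_percent"),
        se_ok=bool(payload.get("se_ok", False)),
        curvature_ok=bool(payload.get("curvature_ok", True)),
        message=payload.get("message", ""),
    )
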