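"""Synthetic-study generation emulating the bronchoalveolar-lavage design.

The emulated study: 40 adults (10 women and 10 men each with and without
AIDS — the AIDS label is carried through but has no effect on any
parameter), 600 mg orally once daily for 5 days, plasma sampled at
approximately 2 and 4 h after the day-5 dose, and one BAL at
approximately 4 h after the day-5 dose yielding one ELF and one AC
concentration.  Of the nominal 80/40/40 samples, 76 plasma, 32 ELF and
36 AC concentrations were analysed; the generator reproduces those totals
by missing-completely-at-random censoring (the source gives no missingness
mechanism).

Covariate distributions are NOT taken from the source study (it reports
none): per-sex normal weight and height with plausible adult moments,
truncated at physiologic bounds.

Randomness contract: one master seed; each subject draws from a substream
keyed on (seed, subject id), so generated datasets are invariant to
subject ordering and bit-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .io import validate_event_table
from .model import PopulationParameters, SubjectCovariates
from .simulate import DosingRegimen, SamplingSchedule, apply_residual_error, simulate_individual

__all__ = ["CovariateModel", "StudyDesignSpec", "generate_study"]


@dataclass(frozen=True)
class CovariateModel:
    """Truncated-normal weight (kg) and height (m) generator for one sex.

    Defaults set in :data:`DEFAULT_COVARIATES`; plausible adult values, not
    derived from the emulated study.
    """

    weight_mean: float
    weight_sd: float
    height_mean: float
    height_sd: float
    weight_bounds: tuple[float, float] = (40.0, 120.0)
    height_bounds: tuple[float, float] = (1.40, 2.05)

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        def trunc(mean, sd, lo, hi):
            for _ in range(1000):
                x = rng.normal(mean, sd)
                if lo <= x <= hi:
                    return x
            return float(np.clip(mean, lo, hi))  # pragma: no cover

        wt = trunc(self.weight_mean, self.weight_sd, *self.weight_bounds)
        ht = trunc(self.height_mean, self.height_sd, *self.height_bounds)
        return wt, ht


DEFAULT_COVARIATES: dict[str, CovariateModel] = {
    "male": CovariateModel(77.0, 10.0, 1.76, 0.07),
    "female": CovariateModel(64.0, 9.0, 1.62, 0.06),
}

#: group composition mirroring the emulated study; the label is cosmetic.
DEFAULT_GROUPS: tuple[tuple[str, str, int], ...] = (
    ("female", "no-AIDS", 10),
    ("male", "no-AIDS", 10),
    ("female", "AIDS", 10),
    ("male", "AIDS", 10),
)

DEFAULT_TARGET_COUNTS: dict[str, int] = {"plasma": 76, "elf": 32, "ac": 36}


@dataclass
class StudyDesignSpec:
    """Design of one synthetic study.

    ``plasma_times`` and ``bal_times`` are hours after the final dose;
    every subject contributes all plasma times and one BAL (ELF + AC pair)
    at ``bal_times[i % len(bal_times)]``.  Nominal times are jittered
    uniformly within +-``time_jitter`` h.  ``target_counts`` maps matrix to
    the retained observation total (None keeps everything).
    """

    n_subjects: int = 40
    groups: tuple[tuple[str, str, int], ...] = DEFAULT_GROUPS
    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    plasma_times: tuple[float, ...] = (2.0, 4.0)
    bal_times: tuple[float, ...] = (4.0,)
    time_jitter: float = 0.25
    target_counts: dict[str, int] | None = field(
        default_factory=lambda: dict(DEFAULT_TARGET_COUNTS))
    covariates: dict[str, CovariateModel] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        if self.time_jitter < 0:
            raise InvalidInputError("time_jitter must be >= 0")
        if sum(n for _, _, n in self.groups) != self.n_subjects:
            raise InvalidInputError(
                "group sizes must sum to n_subjects "
                f"({sum(n for _, _, n in self.groups)} != {self.n_subjects})")
        nominal = self._nominal_counts()
        if self.target_counts is not None:
            for m, want in self.target_counts.items():
                if want > nominal[m]:
                    raise InvalidInputError(
                        f"target count {want} for {m!r} exceeds the nominal "
                        f"total {nominal[m]}")

    def _nominal_counts(self) -> dict[str, int]:
        return {
            "plasma": self.n_subjects * len(self.plasma_times),
            "elf": self.n_subjects,
            "ac": self.n_subjects,
        }

    def subject_rows(self) -> list[tuple[int, str, str]]:
        """(subject_id, sex, group label) in generation order."""
        rows = []
        sid = 1
        for sex, label, n in self.groups:
            for _ in range(n):
                rows.append((sid, sex, label))
                sid += 1
        return rows


def generate_study(
    spec: StudyDesignSpec, params: PopulationParameters
) -> tuple[pd.DataFrame, dict]:
    """Simulate one study; returns (event table, truth sidecar dict).

    The sidecar records the seed, the true parameters, the per-subject
    random effects and the fraction of negative simulated observations, so
    parameter-recovery experiments can compare against the truth.
    """
    last_dose = spec.regimen.dose_times[-1]
    rows = []
    truth_etas: dict[str, float] = {}
    n_neg = 0
    n_obs = 0

    for sid, sex, label in spec.subject_rows():
        rng = np.random.default_rng([spec.seed, sid])
        wt, ht = spec.covariates[sex].draw(rng)
        cov = SubjectCovariates(sid, sex, wt, ht)
        eta = rng.normal(0.0, params.omega_cl) if params.omega_cl > 0 else 0.0
        truth_etas[str(sid)] = float(eta)

        bal_nominal = spec.bal_times[(sid - 1) % len(spec.bal_times)]
        nominal = [(t, "plasma") for t in spec.plasma_times]
        nominal += [(bal_nominal, "elf"), (bal_nominal, "ac")]
        jitters = rng.uniform(-spec.time_jitter, spec.time_jitter, len(nominal)) \
            if spec.time_jitter > 0 else np.zeros(len(nominal))
        # ELF and AC come from the same lavage: share one jitter
        jitters[-1] = jitters[-2]
        samples = sorted(
            ((last_dose + tn + dt, tn, m) for (tn, m), dt in zip(nominal, jitters)),
            key=lambda x: (x[0], x[2]))

        schedule = SamplingSchedule(tuple((t, m) for t, _, m in samples))
        preds = simulate_individual(cov, params, eta, spec.regimen, schedule)

        for t_dose in spec.regimen.dose_times:
            rows.append(dict(id=sid, time=float(t_dose), evid=1,
                             amt=spec.regimen.dose_amount, dv=np.nan,
                             matrix=np.nan, mdv=1, sex=sex, weight=wt,
                             height=ht, nominal_time=np.nan, group=label))
        for (t, tn, m), pred in zip(samples, preds["pred"]):
            dv = float(apply_residual_error(pred, m, params, rng))
            n_obs += 1
            n_neg += dv < 0
            rows.append(dict(id=sid, time=float(t), evid=0, amt=np.nan,
                             dv=dv, matrix=m, mdv=0, sex=sex, weight=wt,
                             height=ht, nominal_time=last_dose + tn, group=label))

    table = pd.DataFrame(rows).sort_values(
        ["id", "time", "evid"], kind="stable", ignore_index=True)

    if spec.target_counts is not None:
        censor_rng = np.random.default_rng([spec.seed, 0])
        drop: list[int] = []
        for m, want in spec.target_counts.items():
            idx = table.index[(table["evid"] == 0) & (table["matrix"] == m)]
            n_drop = len(idx) - want
            if n_drop > 0:
                drop.extend(censor_rng.choice(idx, size=n_drop, replace=False))
        table = table.drop(index=drop).reset_index(drop=True)

    validate_event_table(table)
    truth = {
        "seed": spec.seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(params).items()},
        "etas": truth_etas,
        "negative_observation_fraction": (n_neg / n_obs) if n_obs else 0.0,
    }
    return table, truth
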