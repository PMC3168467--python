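"""Synthetic measurement generators with the study's statistical structure.

These generators produce every input the estimation cascade and cohort
analyses consume: saturating CD33 time courses (flow-cytometry style, at
0/1/3/6 h and 5 µg/mL), 15-minute sub-saturating dose–responses, one- and
two-infusion blood PK curves, dye-efflux ratios, and a virtual AML cohort
whose per-parameter means and inter-patient coefficients of variation match
the reported clinical estimates.

Measurement noise is multiplicative log-normal with unit mean; inter-patient
variability is independent log-normal per parameter (only marginal
means/CVs are available — no covariance structure is imposed).  Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import MeasurementSet
from .model import one_compartment_concentration, simulate_in_vitro, simulate_patient
from .params import (
    BlastDynamics,
    CellKineticParams,
    CLINICAL_CV_PERCENT,
    CLINICAL_MEAN_PARAMS,
    DoseSchedule,
    EffluxAssay,
    InVitroConfig,
    NONSATURATING_DOSES_UG_ML,
    NONSATURATING_TIME_H,
    SATURATING_CONC_UG_ML,
    SystemicParams,
    ug_per_ml_to_molar,
)

__all__ = [
    "CohortSpec",
    "NoiseSpec",
    "generate_cohort",
    "cohort_to_frame",
    "generate_saturating_experiment",
    "generate_nonsaturating_experiment",
    "generate_blood_pk",
    "generate_dye_efflux",
    "default_pk_sampling_times",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal measurement noise with unit mean.

    ``cv`` is the coefficient of variation in percent (default 10, a
    flow-cytometry-scale error).  ``cv = 0`` reproduces the model output
    exactly.
    """

    cv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv!r}")

    def apply(self, values: np.ndarray, rng: Optional[np.random.Generator] = None):
        values = np.asarray(values, dtype=float)
        if self.cv == 0:
            return values.copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        sigma2 = np.log1p((self.cv / 100.0) ** 2)
        draws = rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=values.shape)
        return values * np.exp(draws)


@dataclass(frozen=True)
class CohortSpec:
    """A virtual AML cohort: per-parameter log-normal inter-patient spread.

    Defaults reproduce the clinical parameter estimates: means from the
    patient column (binding constants k_b/k_u from the cell-line column,
    mirroring how they were obtained) and CVs of 109.6% (R_p), 65.7%
    (k_e), 50% (k_i) and 64.7% (k_d).  Parameters without a reported CV are
    held fixed across patients.
    """

    n: int
    means: CellKineticParams = CLINICAL_MEAN_PARAMS
    cvs: Dict[str, float] = field(
        default_factory=lambda: dict(CLINICAL_CV_PERCENT)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n!r}")
        if any(v < 0 for v in self.cvs.values()):
            raise ValueError("CVs must be >= 0")


def _lognormal_with_mean_cv(
    rng: np.random.Generator, mean: float, cv_percent: float, size: int
) -> np.ndarray:
    """Log-normal draws with a given arithmetic mean and CV (percent)."""
    if cv_percent == 0 or mean == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((cv_percent / 100.0) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_cohort(spec: CohortSpec) -> list:
    """Draw ``spec.n`` patients' cell-kinetic parameter sets."""
    rng = np.random.default_rng(spec.seed)
    names = ("R_p", "k_e", "k_i", "k_b", "k_u", "k_d")
    draws = {}
    for name in names:  # fixed draw order keeps cohorts seed-stable
        mean = getattr(spec.means, name)
        cv = spec.cvs.get(name, 0.0)
        draws[name] = _lognormal_with_mean_cv(rng, mean, cv, spec.n)
    return [
        CellKineticParams(**{name: float(draws[name][i]) for name in names})
        for i in range(spec.n)
    ]


def cohort_to_frame(cohort: Sequence[CellKineticParams]) -> pd.DataFrame:
    """One patient per row, one column per rate constant."""
    return pd.DataFrame(
        [
            {n: getattr(p, n) for n in ("R_p", "k_e", "k_i", "k_b", "k_u", "k_d")}
            for p in cohort
        ]
    )


def generate_saturating_experiment(
    p: CellKineticParams,
    cfg: Optional[InVitroConfig] = None,
    noise: NoiseSpec = NoiseSpec(),
) -> MeasurementSet:
    """Noisy total and bound CD33 from a saturating incubation.

    Default protocol: 5 µg/mL drug, samples at 0, 1, 3 and 6 hours.
    """
    if cfg is None:
        cfg = InVitroConfig.from_ug_per_ml(SATURATING_CONC_UG_ML)
    traj = simulate_in_vitro(p, cfg)
    times = np.asarray(cfg.sample_times, dtype=float)
    total = np.interp(times, traj.t, traj.T)
    bound = np.interp(times, traj.t, traj.B)
    rng = np.random.default_rng(noise.seed)
    records = pd.DataFrame(
        {
            "time_h": np.concatenate([times, times]),
            "dose_ug_ml": np.nan,
            "observable": ["T"] * len(times) + ["B"] * len(times),
            "value": noise.apply(np.concatenate([total, bound]), rng),
        }
    )
    return MeasurementSet(kind="saturating_timecourse", records=records)


def generate_nonsaturating_experiment(
    p: CellKineticParams,
    doses: Sequence[float] = NONSATURATING_DOSES_UG_ML,
    noise: NoiseSpec = NoiseSpec(),
    cfg: Optional[InVitroConfig] = None,
    t_obs: float = NONSATURATING_TIME_H,
) -> MeasurementSet:
    """Noisy bound and total CD33 after a 15-minute sub-saturating exposure."""
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("need at least one dose")
    base = cfg if cfg is not None else InVitroConfig(A_0=0.0)
    bound = np.empty_like(doses)
    total = np.empty_like(doses)
    for j, dose in enumerate(doses):
        c = base.replace(
            A_0=ug_per_ml_to_molar(float(dose)), duration=t_obs,
            sample_times=(t_obs,),
        )
        traj = simulate_in_vitro(p, c)
        bound[j] = traj.B[-1]
        total[j] = traj.T[-1]
    rng = np.random.default_rng(noise.seed)
    records = pd.DataFrame(
        {
            "time_h": t_obs,
            "dose_ug_ml": np.concatenate([doses, doses]),
            "observable": ["B"] * len(doses) + ["T"] * len(doses),
            "value": noise.apply(np.concatenate([bound, total]), rng),
        }
    )
    return MeasurementSet(kind="nonsaturating_doseresponse", records=records)


def default_pk_sampling_times(sched: DoseSchedule, n_per_infusion: int = 25) -> np.ndarray:
    """Dense sampling over 0–120 h after each infusion start."""
    times = []
    for e in sched.events:
        times.append(e.start + np.linspace(0.25, 120.0, n_per_infusion))
    return np.unique(np.concatenate(times))


def generate_blood_pk(
    cell: CellKineticParams,
    sys: SystemicParams,
    blasts: BlastDynamics,
    sched: DoseSchedule,
    times: Optional[np.ndarray] = None,
    noise: NoiseSpec = NoiseSpec(),
) -> MeasurementSet:
    """Noisy blood concentrations (ng/mL) for an arbitrary schedule.

    With ``blasts.N_0 = 0`` this emulates second-infusion conditions where
    only nonspecific clearance operates and the profile collapses onto the
    one-compartment closed form.
    """
    if times is None:
        times = default_pk_sampling_times(sched)
    times = np.asarray(times, dtype=float)
    horizon = max(float(times.max()), sched.last_stop)
    traj = simulate_patient(
        cell, sys, blasts, sched, horizon=horizon, extra_times=times
    )
    conc = np.interp(times, traj.t, traj.A_ng_ml)
    records = pd.DataFrame(
        {
            "time_h": times,
            "dose_ug_ml": np.nan,
            "observable": "A_blood",
            "value": noise.apply(conc),
        }
    )
    return MeasurementSet(kind="blood_pk", records=records)


def generate_dye_efflux(
    k_d: float, noise: NoiseSpec = NoiseSpec(), interval: float = 1.5
) -> EffluxAssay:
    """A dye-retention assay consistent with efflux rate ``k_d``.

    The noise-free ratio is exp(k_d · interval); noisy draws are clipped to
    the valid range (ratio >= 1).
    """
    if k_d < 0:
        raise ValueError(f"k_d must be >= 0, got {k_d!r}")
    ratio = float(np.exp(k_d * interval))
    ratio = float(np.maximum(noise.apply(np.array([ratio]))[0], 1.0))
    return EffluxAssay(ratio=ratio, interval=interval)
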