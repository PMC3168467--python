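"""Parameter and state containers for the GO–CD33 kinetic model.

Gemtuzumab ozogamicin (GO) is an anti-CD33 IgG4 antibody conjugated to a
calicheamicin derivative.  Its pharmacokinetics in acute myeloid leukemia
are target-mediated: binding to cell-surface CD33, internalization of the
drug–antigen complex and P-glycoprotein efflux of internalized drug all
shape both the blood concentration and the intracellular exposure.  The
containers here carry the per-cell rate constants, the systemic (whole
body or well) constants, the leukemic blast-burden dynamics and dosing
schedules consumed by the simulators in :mod:`gopk.model`.

Units are fixed throughout the package: time in hours, free drug as a molar
concentration, receptor quantities in molecules per cell, volumes in liters
and doses in mg/m² of body surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.constants import Avogadro

AVOGADRO: float = Avogadro
#: Molar mass of the antibody-drug conjugate (IgG4 + calicheamicin), g/mol.
GO_MOLAR_MASS: float = 1.515e5
#: Default adult body surface area used for mg/m² → mole conversion, m².
DEFAULT_BSA: float = 1.8
#: Default intravenous infusion duration, hours.
DEFAULT_INFUSION_HOURS: float = 2.0


def ug_per_ml_to_molar(conc_ug_ml: float, molar_mass: float = GO_MOLAR_MASS) -> float:
    """Convert a mass concentration in µg/mL to molar units.

    1 µg/mL = 1e-3 g/L, so C[M] = 1e-3 * C[µg/mL] / MW[g/mol].
    """
    return 1e-3 * conc_ug_ml / molar_mass


def molar_to_ng_per_ml(conc_molar, molar_mass: float = GO_MOLAR_MASS):
    """Convert a molar concentration to ng/mL (1 g/L = 1e6 ng/mL)."""
    return np.asarray(conc_molar) * molar_mass * 1e6


@dataclass(frozen=True)
class CellKineticParams:
    """Per-cell rate constants of GO–CD33 interaction.

    Attributes
    ----------
    R_p : float
        CD33 production rate, molecules·cell⁻¹·hour⁻¹.
    k_e : float
        Free-CD33 internalization rate, hour⁻¹.
    k_i : float
        Drug–CD33 complex internalization rate, hour⁻¹.
    k_b : float
        GO–CD33 association rate, M⁻¹·hour⁻¹.
    k_u : float
        GO–CD33 dissociation rate, hour⁻¹.
    k_d : float
        Intracellular drug efflux (elimination) rate, hour⁻¹.
    """

    R_p: float
    k_e: float
    k_i: float
    k_b: float
    k_u: float
    k_d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R_p", "k_e", "k_i", "k_b", "k_u", "k_d"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def baseline_cd33(self) -> float:
        """Pre-treatment surface CD33 per cell, R_p/k_e (steady state)."""
        if self.k_e <= 0:
            raise ValueError("baseline CD33 requires k_e > 0")
        return self.R_p / self.k_e

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant k_u/k_b, molar."""
        if self.k_b <= 0:
            raise ValueError("K_D requires k_b > 0")
        return self.k_u / self.k_b

    def replace(self, **changes) -> "CellKineticParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class SystemicParams:
    """Whole-body constants of the in vivo model.

    ``k`` is the nonspecific first-order elimination rate of free drug from
    blood (hour⁻¹) and ``V`` the volume of distribution (L); both were
    estimated from second-infusion blood PK where blast-mediated clearance
    is negligible.  ``BSA`` and ``MW`` convert mg/m² doses into moles.
    """

    k: float
    V: float
    tau: float = DEFAULT_INFUSION_HOURS
    BSA: float = DEFAULT_BSA
    MW: float = GO_MOLAR_MASS
    n_A: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k!r}")
        for name in ("V", "tau", "BSA", "MW", "n_A"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")

    def dose_to_moles(self, dose_mg_m2: float) -> float:
        """Total moles of conjugate delivered by a mg/m² dose."""
        return dose_mg_m2 * self.BSA * 1e-3 / self.MW

    def replace(self, **changes) -> "SystemicParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class BlastDynamics:
    """Leukemic blast count over time.

    The blast population is held at ``N_0`` until ``onset`` hours after the
    first infusion starts, then decays exponentially at rate ``alpha``:
    N(t) = N_0 for t <= onset, N_0·exp(-alpha·(t-onset)) afterwards.
    """

    N_0: float
    alpha: float
    onset: float = 6.0

    def __post_init__(self) -> None:
        if self.N_0 < 0:
            raise ValueError(f"N_0 must be >= 0, got {self.N_0!r}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha!r}")
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset!r}")

    def count(self, t):
        """Blast count at time(s) ``t`` (hours since first infusion start)."""
        t = np.asarray(t, dtype=float)
        decayed = self.N_0 * np.exp(-self.alpha * np.maximum(t - self.onset, 0.0))
        return decayed if decayed.ndim else float(decayed)

    def replace(self, **changes) -> "BlastDynamics":
        return replace(self, **changes)


@dataclass(frozen=True)
class InVitroConfig:
    """Configuration of an in vitro incubation experiment.

    ``A_0`` is the initial free drug concentration in the well (molar),
    ``N`` the number of cells and ``v`` the well volume in liters.  The
    defaults emulate 10⁶ cells in 1 mL.  ``R_0`` overrides the initial
    free-receptor count per cell; by default cells start at their
    drug-free steady state R_p/k_e.
    """

    A_0: float
    N: float = 1e6
    v: float = 1e-3
    duration: float = 6.0
    sample_times: tuple = (0.0, 1.0, 3.0, 6.0)
    R_0: "float | None" = None

    def __post_init__(self) -> None:
        if self.A_0 < 0:
            raise ValueError(f"A_0 must be >= 0, got {self.A_0!r}")
        if not self.N > 0:
            raise ValueError(f"N must be > 0, got {self.N!r}")
        if not self.v > 0:
            raise ValueError(f"v must be > 0, got {self.v!r}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")

    @classmethod
    def from_ug_per_ml(
        cls, conc_ug_ml: float, molar_mass: float = GO_MOLAR_MASS, **kwargs
    ) -> "InVitroConfig":
        return cls(A_0=ug_per_ml_to_molar(conc_ug_ml, molar_mass), **kwargs)

    def replace(self, **changes) -> "InVitroConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class InfusionEvent:
    """One intravenous infusion: start time (h), dose (mg/m²), duration (h)."""

    start: float
    dose: float
    duration: float = DEFAULT_INFUSION_HOURS

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")

    @property
    def stop(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered sequence of non-overlapping infusion events."""

    events: tuple

    def __post_init__(self) -> None:
        events = tuple(
            e if isinstance(e, InfusionEvent) else InfusionEvent(*e)
            for e in self.events
        )
        object.__setattr__(self, "events", events)
        for prev, nxt in zip(events, events[1:]):
            if nxt.start < prev.start:
                raise ValueError("infusion events must be time-ordered")
            if nxt.start < prev.stop:
                raise ValueError(
                    f"overlapping infusions: one ends at t={prev.stop} h, "
                    f"next starts at t={nxt.start} h"
                )

    @classmethod
    def single(
        cls,
        dose: float,
        start: float = 0.0,
        duration: float = DEFAULT_INFUSION_HOURS,
    ) -> "DoseSchedule":
        return cls(events=((start, dose, duration),))

    @classmethod
    def from_day_doses(
        cls,
        day_doses: Iterable[tuple],
        duration: float = DEFAULT_INFUSION_HOURS,
    ) -> "DoseSchedule":
        """Build a schedule from (day, dose mg/m²) pairs; day 1 starts at t=0."""
        return cls(
            events=tuple(
                (24.0 * (day - 1), dose, duration) for day, dose in day_doses
            )
        )

    @classmethod
    def aml19_nonfractionated(cls) -> "DoseSchedule":
        """AML19 arm: 6 mg/m² on day 1 plus 3 mg/m² on day 8."""
        return cls.from_day_doses([(1, 6.0), (8, 3.0)])

    @classmethod
    def aml19_fractionated(cls) -> "DoseSchedule":
        """AML19 arm: 3 mg/m² on each of days 1, 3 and 5."""
        return cls.from_day_doses([(1, 3.0), (3, 3.0), (5, 3.0)])

    @classmethod
    def standard_two_infusion(cls, dose: float = 9.0) -> "DoseSchedule":
        """Historical schedule: two infusions 14 days apart."""
        return cls.from_day_doses([(1, dose), (15, dose)])

    def scaled(self, factor: float) -> "DoseSchedule":
        """Multiply every dose by ``factor`` (used by dose sweeps)."""
        if factor < 0:
            raise ValueError("dose scale factor must be >= 0")
        return DoseSchedule(
            events=tuple((e.start, e.dose * factor, e.duration) for e in self.events)
        )

    @property
    def total_dose(self) -> float:
        return sum(e.dose for e in self.events)

    @property
    def last_stop(self) -> float:
        return max((e.stop for e in self.events), default=0.0)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class EffluxAssay:
    """Dye-retention efflux assay readout.

    ``ratio`` is the intracellular dye content immediately after loading
    divided by the content after the efflux interval (90 minutes by
    default); values below 1 would imply dye gain and are invalid.
    """

    ratio: float
    interval: float = 1.5

    def __post_init__(self) -> None:
        if not self.interval > 0:
            raise ValueError(f"interval must be > 0, got {self.interval!r}")
        if not np.isfinite(self.ratio):
            raise ValueError(f"ratio must be finite, got {self.ratio!r}")


# --- Reported parameter estimates ------------------------------------------
# In vitro column: AML193 cell-line experiments.  Clinical column: means over
# 47 AML patients (inter-patient CVs in CLINICAL_CV_PERCENT); the binding
# constants k_b/k_u were measured only in vitro and are reused clinically.

IN_VITRO_PARAMS = CellKineticParams(
    R_p=2047.0, k_e=0.12, k_i=0.4, k_b=1.1e12, k_u=397.1, k_d=0.0
)
CLINICAL_MEAN_PARAMS = CellKineticParams(
    R_p=279.0, k_e=0.213, k_i=0.66, k_b=1.1e12, k_u=397.1, k_d=0.34
)
CLINICAL_CV_PERCENT = {"R_p": 109.6, "k_e": 65.7, "k_i": 50.0, "k_d": 64.7}
CLINICAL_SYSTEMIC = SystemicParams(k=0.01919, V=6.2)
CLINICAL_BLASTS = BlastDynamics(N_0=2.47e12, alpha=0.104, onset=6.0)
#: Saturating in vitro incubation: 5 µg/mL GO, sampled at 0, 1, 3, 6 h.
SATURATING_CONC_UG_ML = 5.0
#: Non-saturating incubation: 15 minutes at 0.1–0.5 µg/mL.
NONSATURATING_DOSES_UG_ML = (0.1, 0.2, 0.3, 0.4, 0.5)
NONSATURATING_TIME_H = 0.25
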