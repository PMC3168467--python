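import numpy as np
import pytest

from gopk import (
    Baseline,
    BlastDynamics,
    CLINICAL_BLASTS,
    CLINICAL_MEAN_PARAMS,
    CLINICAL_SYSTEMIC,
    DoseSchedule,
    InVitroConfig,
    IN_VITRO_PARAMS,
    simulate_patient,
)


@pytest.fixture(scope="session")
def saturating_cfg():
    """The saturating in vitro protocol: 5 µg/mL, sampled at 0/1/3/6 h."""
    return InVitroConfig.from_ug_per_ml(5.0)


@pytest.fixture(scope="session")
def mean_baseline():
    """Population-mean in vivo baseline: single 9 mg/m² 2-h infusion."""
    return Baseline()


@pytest.fixture(scope="session")
def mean_trajectory(mean_baseline):
    """One cached 28-day simulation at population means."""
    return mean_baseline.simulate()


@pytest.fixture(scope="session")
def aml19_iaucs(mean_baseline):
    """Cached I-AUC values for the two AML19 arms at population means."""
    from gopk import intracellular_auc

    return {
        "nonfractionated": intracellular_auc(
            mean_baseline.simulate(schedule=DoseSchedule.aml19_nonfractionated())
        ),
        "fractionated": intracellular_auc(
            mean_baseline.simulate(schedule=DoseSchedule.aml19_fractionated())
        ),
    }
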