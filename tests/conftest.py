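import numpy as np
import pytest

from envsig.io import ExpressionMatrix, Scale
from envsig.synthetic import CohortConfig, generate_cohort


def tiny_config(**overrides) -> CohortConfig:
    """A 12-patient, 120-miRNA cohort that runs the full pipeline fast."""
    cfg = CohortConfig(
        n_patients=12,
        n_mirnas=120,
        n_cancer_related=30,
        signature_sizes={
            "passive_smoke_home": 3,
            "passive_smoke_work": 1,
            "vehicle_traffic_home": 6,
            "distance_etna_km": 4,
            "radon_risk": 3,
        },
        prevalences={
            "passive_smoke_home": 0.33,
            "passive_smoke_work": 0.25,
            "vehicle_traffic_home": 0.5,
            "radon_risk": 0.33,
        },
        n_histotype_linked=4,
        sclc_fraction=0.25,
        complete_fraction=1.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale cohort (2549 miRNAs x 50 paired patients), seed 7."""
    return generate_cohort(CohortConfig(), seed=7)


@pytest.fixture()
def tiny_cohort():
    return generate_cohort(tiny_config(), seed=5)


def random_matrix(rng, n_mirnas, sample_ids, loc=8.0, scale=1.0, prefix="miR"):
    return ExpressionMatrix(
        [f"{prefix}-{i}" for i in range(n_mirnas)],
        list(sample_ids),
        rng.normal(loc, scale, size=(n_mirnas, len(sample_ids))),
        Scale.LOG2,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
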