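import numpy as np
import pytest

from lensage import (
    OCA_IBERIAN,
    OCC_IBERIAN,
    FitSpec,
    GeneratorConfig,
    ObservationRecord,
    ObservationSet,
    generate_dataset,
    predict_ldw,
)


@pytest.fixture
def oca():
    return OCA_IBERIAN


@pytest.fixture
def occ():
    return OCC_IBERIAN


@pytest.fixture
def model4_spec():
    return FitSpec(share_a=False, share_b=True)


@pytest.fixture
def study_dataset():
    """One synthetic dataset under the study-design defaults."""
    return generate_dataset(GeneratorConfig(seed=1))


def make_noiseless(params_by_group, ages, c=32.0):
    """Deterministic observations lying exactly on each group's curve."""
    records = []
    for g, params in params_by_group.items():
        for i, age in enumerate(ages):
            records.append(
                ObservationRecord(
                    id=f"{g}-{i}",
                    group=g,
                    age_days=float(age),
                    ldw_mg=float(predict_ldw(params, age)),
                )
            )
    return ObservationSet(records=tuple(records), groups=tuple(params_by_group))


def make_noisy(params_by_group, ages, sd, seed, c=32.0):
    """Noiseless design plus seeded additive Gaussian lens-weight noise."""
    rng = np.random.default_rng(seed)
    records = []
    for g, params in params_by_group.items():
        mu = predict_ldw(params, np.asarray(ages, dtype=float))
        y = mu + rng.normal(0, sd, len(mu))
        y = np.where(y <= 0.1, mu, y)  # keep tiny designs valid
        for i, (age, w) in enumerate(zip(ages, y)):
            records.append(
                ObservationRecord(
                    id=f"{g}-{i}", group=g, age_days=float(age), ldw_mg=float(w)
                )
            )
    return ObservationSet(records=tuple(records), groups=tuple(params_by_group))
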