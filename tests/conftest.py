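import numpy as np
import pytest

from dtmeta.datatypes import PrimaryDataset, TreatmentRecord


def make_dataset(
    female,
    male,
    female_se=None,
    male_se=None,
    dataset_id="d1",
    study_id="s1",
    species="Aus bus",
    order_name="Diptera",
    trait="total",
    factor="temperature",
    treatments=None,
):
    """Build a PrimaryDataset from plain sequences."""
    female = list(female)
    male = list(male)
    k = len(female)
    if treatments is None:
        treatments = [10.0 + 5.0 * i for i in range(k)]
    female_se = [None] * k if female_se is None else list(female_se)
    male_se = [None] * k if male_se is None else list(male_se)
    records = tuple(
        TreatmentRecord(
            treatment_value=treatments[i],
            male_mean_dt=male[i],
            female_mean_dt=female[i],
            male_se=male_se[i],
            female_se=female_se[i],
        )
        for i in range(k)
    )
    return PrimaryDataset(
        dataset_id=dataset_id,
        study_id=study_id,
        species=species,
        order_name=order_name,
        trait=trait,
        factor=factor,
        records=records,
    )


@pytest.fixture
def three_treatment_ds():
    """k=3 dataset with SEs; development time declines with temperature."""
    return make_dataset(
        female=[30.0, 20.0, 10.0],
        male=[26.0, 17.0, 8.0],
        female_se=[0.6, 0.4, 0.2],
        male_se=[0.5, 0.35, 0.15],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
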