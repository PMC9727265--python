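import numpy as np
import pytest

from mesfmon import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized default cohort (26 HC / 65 stable / 50 infection)."""
    return synthetic.generate_cohort(synthetic.default_cohort_spec(seed=7))


@pytest.fixture(scope="session")
def four_protocols():
    return synthetic.default_protocols(noise_cv=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def small_cohort(n_per_group: int = 5, seed: int = 3):
    """A tiny cohort for fast end-to-end tests."""
    spec = synthetic.default_cohort_spec(seed=seed)
    subgroups = tuple(
        synthetic.SubgroupSpec(
            group=sg.group,
            n=n_per_group,
            sepsis=sg.sepsis,
            markers=sg.markers,
            tbnk=sg.tbnk,
            creatinine=sg.creatinine,
            sofa=sg.sofa,
        )
        for sg in spec.subgroups
    )
    small = synthetic.CohortSpec(
        subgroups=subgroups,
        pathogen_counts={"bacterial": 4, "viral": 3, "fungal": 3},
        n_second_timepoint=4,
        n_second_sepsis=2,
        n_exacerbation=1,
        seed=seed,
    )
    return synthetic.generate_cohort(small)
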