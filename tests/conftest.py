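import pytest
from hypothesis import settings

from hpglyco import CohortConfig, PeakModel, build_target_list, generate_cohort, render_chromatograms

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def targets():
    return build_target_list()


@pytest.fixture(scope="session")
def default_cohort(targets):
    """Full-size default cohort with rendered (noisy) chromatograms."""
    config = CohortConfig(seed=11)
    dataset = generate_cohort(config, targets)
    render_chromatograms(dataset, config)
    return config, dataset


@pytest.fixture(scope="session")
def noisefree_cohort(targets):
    """Small cohort rendered without baseline or multiplicative noise."""
    peaks = PeakModel(baseline=0.0, multiplicative_noise_sd=0.0)
    config = CohortConfig(
        seed=7,
        peaks=peaks,
        n_per_group=(4, 4),
        gender_counts={"cirrhosis": (2, 2), "HCC": (2, 2)},
    )
    dataset = generate_cohort(config, targets)
    render_chromatograms(dataset, config)
    return config, dataset
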