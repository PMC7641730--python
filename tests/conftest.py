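import pytest

from nmrbind.synthetic import StudyConfig, generate_fixture_study


@pytest.fixture(scope="session")
def default_cfg() -> StudyConfig:
    return StudyConfig(seed=1)


@pytest.fixture(scope="session")
def low_noise_cfg() -> StudyConfig:
    """Study with shift noise far below the perturbation scale."""
    return StudyConfig(seed=11, shift_noise_sd_H=1e-4, shift_noise_sd_N=5e-4)


@pytest.fixture(scope="session")
def noiseless_cfg() -> StudyConfig:
    return StudyConfig(seed=3, shift_noise_sd_H=0.0, shift_noise_sd_N=0.0,
                       intensity_noise_frac=0.0)


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """A complete synthetic study tree written once per session."""
    out = tmp_path_factory.mktemp("study")
    study_yaml = generate_fixture_study(out, StudyConfig(seed=1))
    return study_yaml
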