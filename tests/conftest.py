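import pytest

from shsexposure import StudyConfig, load_area_survey, load_nicotine_survey, qc_exclude
from shsexposure.nicotine import prison_values


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def area_survey():
    """Published per-prison area-monitoring summary (15 prisons)."""
    return load_area_survey()


@pytest.fixture(scope="session")
def nicotine_qc():
    """Published nicotine monitors after QC partitioning."""
    return qc_exclude(load_nicotine_survey())


@pytest.fixture(scope="session")
def nicotine_by_prison(nicotine_qc, config):
    """Processed per-prison nicotine values (duplicates merged, ½-LOD imputed)."""
    return prison_values(nicotine_qc.analysis, config.nicotine_half_lod)
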