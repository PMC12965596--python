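import datetime as dt

import pytest

from faersignal.pipeline import AnalysisConfig, Dataset
from faersignal.synth import SynthConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_reports=6000, n_drugs=8, n_events=40, seed=101,
        background_rate=0.01, duplicate_rate=0.06,
        partial_date_rate=0.05, missing_demo_rate=0.1,
        planted_signals=[("MIRTAZAPINE", "EVENT 0001", 10.0),
                         ("MIRTAZAPINE", "EVENT 0002", 8.0)],
        date_window=(dt.date(2015, 1, 1), dt.date(2023, 12, 31)))


@pytest.fixture(scope="session")
def small_synth(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_synth) -> Dataset:
    return Dataset.from_synthetic(small_synth)


@pytest.fixture()
def basic_analysis_config() -> AnalysisConfig:
    return AnalysisConfig(target_synonyms=["MIRTAZAPINE"])
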