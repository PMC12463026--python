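import numpy as np
import pytest

from funnelbias.simulate import (
    MetaAnalysisDataset,
    ScenarioConfig,
    Selection,
    StudyRecord,
    generate_dataset,
)


def make_records(effects, ses):
    return [StudyRecord(float(y), float(s)) for y, s in zip(effects, ses)]


def make_dataset(effects, ses, n_published=None, severity=0.0, tau2=0.0,
                 selection=Selection.NONE, seed=0):
    """Wrap explicit study values in a MetaAnalysisDataset (no simulation)."""
    records = tuple(make_records(effects, ses))
    config = ScenarioConfig(
        n_published=len(records), severity=severity, tau2=tau2,
        selection=selection, seed=seed,
    )
    return MetaAnalysisDataset(
        published=records, unpublished=(), config=config, replicate_id=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def biased_dataset():
    """A 15-study meta-analysis with severe p-value-driven suppression."""
    config = ScenarioConfig(
        n_published=15, severity=1 / 3, tau2=0.0,
        selection=Selection.P_VALUE, seed=42,
    )
    return generate_dataset(config, replicate_id=0)


@pytest.fixture
def null_dataset():
    """A 15-study meta-analysis with no suppression."""
    config = ScenarioConfig(n_published=15, severity=0.0, tau2=0.0, seed=42)
    return generate_dataset(config, replicate_id=0)
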