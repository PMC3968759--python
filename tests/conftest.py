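import warnings

import pytest

import fefrac as ff


@pytest.fixture(scope="session")
def fixture_records() -> dict:
    """The five shipped reference samples, keyed by sample id."""
    return {meta.sample_id: (meta, m) for meta, m in ff.load_fixture()}


@pytest.fixture(scope="session")
def fixture_speciation(fixture_records) -> dict:
    """Point speciation of all five reference samples (paper-mode ratios)."""
    out = {}
    for sid, (meta, m) in fixture_records.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[sid] = ff.speciate(meta, m)
    return out


@pytest.fixture(scope="session")
def paper_ratios() -> ff.RatioSet:
    return ff.RatioSet(mode="paper")


@pytest.fixture(scope="session")
def exact_ratios() -> ff.RatioSet:
    return ff.RatioSet(mode="exact")


@pytest.fixture
def clampfree_sample() -> tuple:
    """A measurement set whose chain sits many sds away from every clamp.

    Margins are all > 5 sd, so Monte-Carlo draws essentially never clamp and
    linear propagation is an exact oracle for the ensemble sds.
    """
    meta = ff.SampleMetadata(sample_id="clampfree")
    m = ff.ExtractionMeasurements(
        fe_total=ff.Measurement(3.0, 0.05, 3),
        fe2_ferrozine=ff.Measurement(0.30, 0.04, 3),
        fe_dcb=ff.Measurement(1.53, 0.05, 2),
        fe_aod=ff.Measurement(1.00, 0.04, 2),
        fe_fes=ff.Measurement(0.10, 0.01, 2),
        fe_pyrite=ff.Measurement(0.30, 0.02, 3),
        fe_siderite=ff.Measurement(0.20, 0.02, 3),
        fe_vivianite=ff.Measurement(0.05, 0.005, 3),
    )
    return meta, m
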