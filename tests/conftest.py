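import pytest

import luminolpmi as lp


@pytest.fixture(scope="session")
def fixture_ds():
    return lp.load_fixture()


@pytest.fixture(scope="session")
def working23(fixture_ds):
    """The bundled dataset with the approximate ~500-year sample removed."""
    return lp.exclude_samples(fixture_ds, sorted(fixture_ds.approximate_ids))


@pytest.fixture(scope="session")
def default_model(fixture_ds):
    """Segmented model at the scan-derived breakpoint with default rules."""
    return lp.fit_segmented(fixture_ds, breakpoint_years=30.5)


@pytest.fixture(scope="session")
def default_loocv(default_model):
    return lp.loocv_model(default_model)
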