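import pytest
from hypothesis import HealthCheck, settings as hyp_settings

hyp_settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("suite")


@pytest.fixture()
def clo_bundle():
    from ontoforge.fixtures import make_clo_fixture

    return make_clo_fixture()


@pytest.fixture()
def clo_run(clo_bundle):
    """Parsed settings + full new-classes run of the cell-line bundle."""
    from ontoforge import engine, parse_settings

    settings = parse_settings(clo_bundle.settings_text)
    doc, mdoc, report = engine.run(settings, clo_bundle.table)
    return settings, doc, mdoc, report
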