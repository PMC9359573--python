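import pytest
from hypothesis import HealthCheck, settings

from culexkdr import assay, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def oligos():
    return assay.default_oligos()


@pytest.fixture(scope="session")
def templates():
    """Synthetic Vgsc cDNA stand-ins with the published assay geometry."""
    return synthetic.synthetic_vgsc_templates()


@pytest.fixture(scope="session")
def tarsalis_amplicon(oligos, templates):
    out = assay.in_silico_pcr(
        templates["tarsalis_syn"], oligos["RTSeq_Fwd"], oligos["RTkdr_Rev"]
    )
    assert out.status == "ok"
    return out.amplicon
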