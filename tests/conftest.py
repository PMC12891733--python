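from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


AIRR_FIXTURE = """\
v_call\tjunction_aa\tduplicate_count\tproductive
TCRBV28.01.01\tCASRLGNTGELFF\t10\tT
TCRBV05.01.01\tCASSLAPGATNEKLFF\t5\tT
TCRBV28.01.01\tCASRRGNTGELFF\t1\tT
"""

AIRR_FIXTURE_NONPROD = """\
v_call\tjunction_aa\tduplicate_count\tproductive
TCRBV28.01.01\tCASRLGNTGELFF\t10\tT
TCRBV05.01.01\tCASSL*GELFF\t4\tF
TCRBV28.01.01\tCASRRGNTGELFF\t1\tT
"""

# Same rearrangements as AIRR_FIXTURE in the Adaptive export dialect
# (dash/star separators, frame_type, templates).
ADAPTIVE_FIXTURE = """\
v_resolved\tamino_acid\ttemplates\tframe_type
TCRBV28-01*01\tCASRLGNTGELFF\t10\tIn
TCRBV05-01*01\tCASSLAPGATNEKLFF\t5\tIn
TCRBV28-01*01\tCASRRGNTGELFF\t1\tIn
"""


@pytest.fixture
def airr_path(tmp_path):
    p = tmp_path / "sample.airr.tsv"
    p.write_text(AIRR_FIXTURE)
    return p


@pytest.fixture
def airr_nonprod_path(tmp_path):
    p = tmp_path / "nonprod.airr.tsv"
    p.write_text(AIRR_FIXTURE_NONPROD)
    return p


@pytest.fixture
def adaptive_path(tmp_path):
    p = tmp_path / "sample.adaptive.tsv"
    p.write_text(ADAPTIVE_FIXTURE)
    return p


@pytest.fixture(scope="session")
def toy_cohort():
    """Small deterministic cohort with ground truth, shared across tests."""
    from tcrvax.synthetic import simulate_cohort, toy_study_config

    return simulate_cohort(toy_study_config())
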