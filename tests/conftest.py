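import pytest

from crmscreen.ontology import DomainOntology, StageAxis
from crmscreen.pattern_matrix import AnnotationRecord, PatternMatrix


@pytest.fixture(scope="session")
def ontology():
    return DomainOntology()


@pytest.fixture(scope="session")
def axis():
    return StageAxis()


@pytest.fixture
def make_matrix(ontology, axis):
    """Build a PatternMatrix from (stage, domain) 1-bit cells."""

    def _make(subject_id, cells):
        pm = PatternMatrix.zeros(subject_id, ontology, axis)
        for stage, domain in cells:
            pm.set_bit(stage, domain)
        return pm

    return _make


@pytest.fixture
def make_records():
    def _make(rows):
        return [
            AnnotationRecord(sid, stage, frozenset(domains))
            for sid, stage, domains in rows
        ]

    return _make
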