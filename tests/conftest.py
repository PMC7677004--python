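import pytest

from ampliscan import builtin_pools
from ampliscan.reference import Lineage, ReferenceRecord, parse_lineage


@pytest.fixture(scope="session")
def pools():
    return builtin_pools()


@pytest.fixture
def record_factory():
    """Build a ReferenceRecord from a raw sequence with minimal ceremony."""

    def _make(sequence, rec_id="rec1", lineage="Bacteria", five_prime="unknown"):
        return ReferenceRecord(
            id=rec_id,
            sequence=sequence,
            lineage=parse_lineage(lineage) if isinstance(lineage, str) else lineage,
            five_prime_complete=five_prime,
        )

    return _make


FULL_LINEAGE = parse_lineage(
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;crispatus"
)


@pytest.fixture
def full_lineage() -> Lineage:
    return FULL_LINEAGE
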