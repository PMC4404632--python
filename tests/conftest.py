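import pytest

from multihla.drb_haplotype import load_linkage_fixture
from multihla.evaluation import score_roundtrip
from multihla.fixtures import panel_config, toy_reference
from multihla.genotyping import TypingParams
from multihla.pipeline import QCParams

#: QC settings matched to the 1:10-scale read profile
FAST_QC = QCParams(qv_threshold=10, min_length=30, barcode_mismatches=1)


@pytest.fixture(scope="session")
def fast_ref():
    """Synthetic reference at the 1:10 test scale: (database, primers)."""
    return toy_reference(0.1)


@pytest.fixture(scope="session")
def full_ref():
    """Synthetic reference at full product sizes."""
    return toy_reference(1.0)


@pytest.fixture(scope="session")
def small_panel(fast_ref):
    """A typed six-sample panel shared by structural tests:
    (sim config, n matching sample-locus genotypes, n total, result)."""
    db, primers = fast_ref
    config = panel_config(db, n_samples=6, seed=11, reads_per_sample=12000)
    n_match, n_total, result = score_roundtrip(
        config, db, primers, TypingParams(), FAST_QC
    )
    return config, n_match, n_total, result


@pytest.fixture(scope="session")
def linkage():
    return load_linkage_fixture()
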