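import pytest

from fastqplex import TrimConfig, parse_sample_sheet

# the combinatorial sheet dialect's canonical worked example:
# four samples, two 5'-only and two sharing the 5' core GCGG
WORKED_CSV = "NNNATGCNN\nNNNATTANNN:sample_2\nNNNGCGGN,NNAA:sample_3,NNNTT\n"


@pytest.fixture(scope="session")
def worked_sheet():
    return parse_sample_sheet(WORKED_CSV)


@pytest.fixture
def cfg():
    """Permissive defaults for unit tests: no quality trim, no length filter."""
    return TrimConfig(min_length=0, quality_threshold=0)
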