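import pytest

from aflpsim.digestion import BUILTIN_ENZYMES, double_digest
from aflpsim.amplification import amplify
from aflpsim.genome_io import GenomeSequence
from aflpsim.profiling import AdaptorModel, build_profile


@pytest.fixture
def ecori():
    return BUILTIN_ENZYMES["EcoRI"]


@pytest.fixture
def msei():
    return BUILTIN_ENZYMES["MseI"]


@pytest.fixture
def toy_genome():
    """18 bp toy: EcoRI site at [2,8) (cut 3), MseI site at [12,16) (cut 13)."""
    return GenomeSequence("toy", "AAGAATTCGGGGTTAACC")


@pytest.fixture
def run_pipeline(ecori, msei):
    """Digest -> amplify -> profile on one genome with one combination."""

    def _run(genome, combo, policy="rare-freq", adaptor=AdaptorModel(),
             window=(50, 500), window_on="peak"):
        frags = double_digest(genome, ecori, msei)
        amps = amplify(frags, genome, combo, policy=policy)
        return build_profile(amps, combo, adaptor, window, window_on)

    return _run
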