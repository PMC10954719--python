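import numpy as np
import pytest

from droshascan import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    """5 + 5 planted loci on a 20 kb genome with its truth table."""
    fasta, truth = synthetic.build_genome(5, 5, 20_000, np.random.default_rng(2))
    seqs = {}
    name = None
    for line in fasta.splitlines():
        if line.startswith(">"):
            name = line[1:]
            seqs[name] = []
        else:
            seqs[name].append(line)
    genome = {k: "".join(v) for k, v in seqs.items()}
    return genome, truth


@pytest.fixture(scope="session")
def designed_hairpin():
    """A canonical hairpin cassette with verified cleavage geometry."""
    rng = np.random.default_rng(11)
    return synthetic.design_hairpin(synthetic.HairpinSpec(), rng)
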