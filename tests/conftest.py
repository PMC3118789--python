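import pytest

from mitocomp.synthetic_data import RepeatSpec, SyntheticSpec, simulate_genome

# a reduced gene complement keeps per-test genome builds fast while
# preserving the structural features (classes, strands, repeat host)
SMALL_GENES = [
    ("cox1", 300, "known", "CDS"),
    ("cob", 200, "known", "CDS"),
    ("nad1", 150, "known", "CDS"),
    ("rps3", 120, "known", "CDS"),
    ("ymf64", 400, "orf", "CDS"),
    ("ymf80", 90, "orf", "CDS"),
    ("rns", 600, "rna", "rRNA"),
    ("trnF", 72, "rna", "tRNA"),
]


@pytest.fixture
def small_spec():
    return SyntheticSpec(genes=list(SMALL_GENES), repeat=RepeatSpec(host_gene="ymf64"))


@pytest.fixture
def small_genome(small_spec):
    return simulate_genome(small_spec, seed=101)


@pytest.fixture
def full_genome():
    """Default study-scale genome (~43 kb); built once per session."""
    return simulate_genome(seed=7)
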