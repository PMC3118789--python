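import math

import numpy as np
import pytest

from mitocomp import refdata
from mitocomp.codes import get_code
from mitocomp.codon_usage import count_codons, relative_frequencies
from mitocomp.seq_io import extract_cds
from mitocomp.synthetic_data import (
    RepeatSpec,
    SyntheticSpec,
    evolve_pair,
    simulate_alignment,
    simulate_genome,
    simulate_repeat_strains,
)


def test_generators_byte_reproducible_under_fixed_seed(small_spec):
    r1, t1 = simulate_genome(small_spec, seed=5)
    r2, t2 = simulate_genome(small_spec, seed=5)
    assert r1.sequence == r2.sequence
    assert t1 == t2
    a1 = simulate_alignment("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2,(E:0.1,F:0.1):0.1);",
                            n_codons=50, seed=3)
    a2 = simulate_alignment("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2,(E:0.1,F:0.1):0.1);",
                            n_codons=50, seed=3)
    assert a1 == a2
    p1 = evolve_pair("ATGGGTAAA" * 20, 0.1, 0.5, seed=2)
    p2 = evolve_pair("ATGGGTAAA" * 20, 0.1, 0.5, seed=2)
    assert p1 == p2
    s1 = simulate_repeat_strains(seed=4)
    s2 = simulate_repeat_strains(seed=4)
    assert s1 == s2


def test_different_seeds_differ(small_spec):
    r1, _ = simulate_genome(small_spec, seed=1)
    r2, _ = simulate_genome(small_spec, seed=2)
    assert r1.sequence != r2.sequence


def test_genome_is_linear_and_ledger_layout_consistent(small_genome):
    rec, truth = small_genome
    assert rec.topology == "linear"
    for g, f in zip(truth["genes"], sorted(rec.genes(), key=lambda f: f.start)):
        assert (g["name"], g["start"], g["end"], g["strand"]) == (
            f.name, f.start, f.end, f.strand,
        )
    assert truth["total_bp"] == rec.length


def test_cds_features_are_stop_free_and_in_frame(small_genome):
    rec, _ = small_genome
    for f in rec.genes():
        if f.ftype == "CDS":
            cds = extract_cds(rec, f, 4)  # raises on internal stops
            assert cds.trailing_stop


def test_codon_profile_recovered_at_large_n():
    """Sampling from the published codon-frequency column reproduces it."""
    profile = refdata.codon_frequencies("P_caudatum")
    genes = [("g1", 5000, "known", "CDS"), ("g2", 5000, "known", "CDS")]
    spec = SyntheticSpec(genes=genes, repeat=None, long_spacers=())
    rec, truth = simulate_genome(spec, seed=13)
    cds_set = [extract_cds(rec, f, 4) for f in rec.genes() if f.ftype == "CDS"]
    table = count_codons(cds_set, code_id=4)
    got = relative_frequencies(table)
    code = get_code(4)
    for aa in code.amino_acids:
        fam = code.family(aa)
        n = got.family_totals.get(aa, 0)
        if n < 200:
            continue
        for codon in fam:
            p = profile[codon]
            se = math.sqrt(max(p * (1 - p), 1e-6) / n)
            assert abs(got.frequencies[codon] - p) < 4 * se + 0.01


def test_infeasible_genome_length_rejected(small_spec):
    small_spec.genome_length = 100
    with pytest.raises(ValueError, match="genome_length"):
        simulate_genome(small_spec, seed=0)


def test_genome_padding_to_explicit_length(small_spec):
    small_spec.genome_length = 20_000
    rec, truth = simulate_genome(small_spec, seed=3)
    assert rec.length == 20_000


def test_evolve_pair_rejects_negative_omega():
    with pytest.raises(ValueError):
        evolve_pair("ATGGGT", 0.1, -0.5)


def test_evolve_pair_keeps_frame_and_avoids_stops():
    code = get_code(4)
    a, b, ledger = evolve_pair("ATGGGTAAACTTTGA"[:12] * 30, t_syn=0.5, omega=0.3,
                               seed=8)
    for seq in (a, b):
        assert len(seq) % 3 == 0
        assert "*" not in code.translate(seq)
    assert ledger["syn"] > 0


def test_alignment_zero_branch_lengths_give_identical_sequences():
    aln, _ = simulate_alignment("((A:0,B:0):0,(C:0,D:0):0);", n_codons=40, seed=1)
    seqs = {s for _, s in aln}
    assert len(seqs) == 1


def test_alignment_clade_gc3_targets_reached():
    nwk = "((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1,(E:0.05,F:0.05):0.1);"
    aln, truth = simulate_alignment(
        nwk, n_codons=500, seed=2, high_clade=("A", "B"),
        clade_gc3=48.0, background_gc3=10.0,
    )
    from mitocomp.phylogeny import gc3_by_taxon

    gc3 = gc3_by_taxon(aln)
    for t in ("A", "B"):
        assert abs(gc3[t].gc3 - 48.0) < 8
    for t in ("C", "D", "E", "F"):
        assert gc3[t].gc3 < 25


def test_alignment_rejects_unknown_clade_taxa_and_bad_targets():
    nwk = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);"
    with pytest.raises(ValueError):
        simulate_alignment(nwk, high_clade=("Z",))
    with pytest.raises(ValueError):
        simulate_alignment(nwk, clade_gc3=120.0)
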