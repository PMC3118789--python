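import itertools
import math

import numpy as np
import pytest
import scipy.stats as ss

from mitocomp.divergence import (
    KaKsRecord,
    SaturationError,
    class_summary,
    codon_align,
    kaks_record,
    mann_whitney,
    ng86_kaks,
    pairwise_identity,
)
from mitocomp.seq_io import CodingSequence
from mitocomp.synthetic_data import evolve_pair


def test_identity_examples():
    assert pairwise_identity("MKLY", "MKLY", aligned=True) == 1.0
    assert pairwise_identity("AAAA", "AAAT", aligned=True) == 0.75


def test_identity_excludes_gap_columns():
    assert pairwise_identity("MK-Y", "MKLY", aligned=True) == 1.0


def test_identity_matches_bruteforce_column_count():
    rng = np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(20):
        n = int(rng.integers(5, 40))
        a = "".join(rng.choice(aas, size=n))
        b = "".join(rng.choice(aas, size=n))
        expected = sum(x == y for x, y in zip(a, b)) / n
        assert math.isclose(pairwise_identity(a, b, aligned=True), expected)


def test_empty_identity_rejected():
    with pytest.raises(ValueError):
        pairwise_identity("", "A")


def test_ng86_hand_worked_example():
    res = ng86_kaks("GGTGGTGGT", "GGCGGTGGT", code_id=4)
    assert math.isclose(res.s_sites, 3.0)
    assert math.isclose(res.sd, 1.0)
    assert math.isclose(res.ks, 0.4408, abs_tol=5e-5)
    assert res.ka == 0.0
    assert res.ratio == 0.0


def test_ng86_identical_sequences_flag_undefined_ratio():
    res = ng86_kaks("ATGGGT", "ATGGGT", code_id=4)
    assert res.ka == res.ks == 0.0
    assert res.ratio is None


def test_ng86_symmetric_and_sites_conserved():
    rng = np.random.default_rng(3)
    from mitocomp.codes import get_code

    sense = sorted(get_code(4).forward)
    for _ in range(10):
        n = int(rng.integers(10, 60))
        a = "".join(rng.choice(sense, size=n))
        # moderately diverged partner: swap a few codons, keep below saturation
        b_codons = list(a[i : i + 3] for i in range(0, 3 * n, 3))
        for pos in rng.choice(n, size=max(1, n // 5), replace=False):
            b_codons[pos] = str(rng.choice(sense))
        b = "".join(b_codons)
        r1 = ng86_kaks(a, b)
        r2 = ng86_kaks(b, a)
        assert math.isclose(r1.ka, r2.ka) and math.isclose(r1.ks, r2.ks)
        assert math.isclose(r1.s_sites + r1.n_sites, 3.0 * n)


def test_ng86_saturation_error():
    a = "GGT" * 30
    b = "CCA" * 30  # every position differs
    with pytest.raises(SaturationError):
        ng86_kaks(a, b)


def test_codon_align_drops_gap_codons_pairwise():
    a = CodingSequence(name="a", nucleotides="ATGAAAGGT", protein="MKG", code_id=4)
    b = CodingSequence(name="b", nucleotides="ATGGGT", protein="MG", code_id=4)
    nt_a, nt_b = codon_align(a, b)
    assert len(nt_a) == len(nt_b)
    assert len(nt_a) % 3 == 0
    assert nt_a.count("ATG") >= 1 and nt_b.count("ATG") >= 1


def test_evolved_pair_with_omega_zero_has_ka_zero():
    cds = "ATGGGTAAACTT" * 50
    a, b, _ = evolve_pair(cds, t_syn=0.2, omega=0.0, seed=5)
    res = ng86_kaks(a, b)
    assert res.ka == 0.0 and res.ks > 0


def test_evolved_pair_with_zero_time_is_identical():
    cds = "ATGGGTAAACTT" * 10
    a, b, _ = evolve_pair(cds, t_syn=0.0, omega=1.0, seed=5)
    assert a == b == cds


def test_mann_whitney_identical_groups_give_z_zero():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.z == pytest.approx(0.0, abs=1e-12)


def test_mann_whitney_matches_scipy_tie_corrected():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = list(rng.integers(0, 8, size=9).astype(float))
        b = list(rng.integers(0, 8, size=13).astype(float))
        res = mann_whitney(a, b)
        sp = ss.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        # scipy reports U and a two-sided p from the same normal approximation
        assert res.u_statistic == pytest.approx(float(sp.statistic))
        assert res.p_two_sided == pytest.approx(float(sp.pvalue), rel=1e-9)


def test_normal_approximation_brackets_exact_permutation_p():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=4))
        res = mann_whitney(a, b)
        assert res.p_exact is not None
        # both are valid two-sided p-values of the same U; they agree in order
        assert abs(res.p_two_sided - res.p_exact) < 0.25


def test_mann_whitney_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def _rec(gene, cls, ka, ks):
    return KaKsRecord(gene=gene, gene_class=cls, identity=0.9, ka=ka, ks=ks,
                      aligned_codons=100)


def test_class_summary_means_and_exclusions():
    recs = [
        _rec("a", "known", 0.01, 0.1),
        _rec("b", "known", 0.02, 0.1),
        _rec("c", "orf", 0.09, 0.3),
        _rec("d", "orf", 0.0, 0.0),  # undefined ratio -> excluded
    ]
    summary = class_summary(recs)
    assert summary.n_excluded == 1
    assert summary.mean_by_class["known"] == pytest.approx(0.15)
    assert summary.mean_by_class["orf"] == pytest.approx(0.3)


def test_single_record_classes_mean_equals_record():
    recs = [_rec("a", "known", 0.01, 0.1), _rec("b", "orf", 0.3, 0.5)]
    summary = class_summary(recs)
    assert summary.mean_by_class["known"] == pytest.approx(0.1)
    assert summary.mean_by_class["orf"] == pytest.approx(0.6)
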