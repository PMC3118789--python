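import numpy as np
import pytest

from mitocomp import refdata
from mitocomp.minisatellite import (
    RepeatCall,
    compare_strain_repeats,
    find_tandem_repeats,
    frame_preserving,
)
from mitocomp.synthetic_data import simulate_repeat_strains

from .oracles import tandem_calls_bruteforce


def _random_seq(rng, n, gc=0.22):
    p = np.array([gc / 2, (1 - gc) / 2, (1 - gc) / 2, gc / 2])
    return "".join(np.array(list("GATC"))[rng.choice(4, size=n, p=p)])


def test_perfect_repeat_detected():
    calls = find_tandem_repeats("ACGACGACGACG", min_unit=3, max_unit=6, min_copies=3)
    assert len(calls) == 1
    c = calls[0]
    assert (c.start, c.end, c.unit_length) == (0, 12, 3)
    assert c.copy_number == 4.0
    assert c.mean_identity == 1.0


def test_primitive_period_reporting():
    # a 12-mer lag match is also present, but the true period is 2
    calls = find_tandem_repeats("ACACACACACACACAC", min_unit=2, max_unit=8,
                                min_copies=3)
    assert all(c.unit_length == 2 for c in calls)


def test_contradictory_thresholds_rejected():
    with pytest.raises(ValueError):
        find_tandem_repeats("ACGT", min_unit=10, max_unit=5)


def test_frame_preservation_rule():
    def call(u):
        return RepeatCall(start=0, end=3 * u, unit_length=u, copy_number=3,
                          consensus="A" * u, mean_identity=1.0)

    assert frame_preserving(call(18))
    assert frame_preserving(call(3))
    assert not frame_preserving(call(17))


def test_detector_matches_bruteforce_scanner_on_random_sequences():
    rng = np.random.default_rng(12)
    for _ in range(10):
        seq = _random_seq(rng, 2000)
        got = [
            (c.start, c.end, c.unit_length, round(c.copy_number, 6))
            for c in find_tandem_repeats(seq)
        ]
        expected = [
            (s, e, u, round(cp, 6)) for s, e, u, cp in tandem_calls_bruteforce(seq)
        ]
        assert got == expected


def test_detector_exhaustive_on_planted_perfect_repeats():
    rng = np.random.default_rng(3)
    for unit_len, copies in ((6, 3), (11, 4), (24, 5)):
        unit = _random_seq(rng, unit_len)
        seq = _random_seq(rng, 400) + unit * copies + _random_seq(rng, 400)
        calls = find_tandem_repeats(seq, min_identity=1.0)
        spans = [(c.unit_length, int(round(c.copy_number))) for c in calls]
        assert any(
            u == unit_len and cp >= copies for u, cp in spans
        ) or any(  # unit itself may have internal structure -> smaller period
            unit_len % u == 0 and cp >= copies * (unit_len // u) for u, cp in spans
        )


def test_extra_unit_increments_copy_number_by_one():
    rng = np.random.default_rng(9)
    unit = _random_seq(rng, 18)
    flanks = (_random_seq(rng, 300), _random_seq(rng, 300))
    for copies in (5, 9):
        seq = flanks[0] + unit * copies + flanks[1]
        seq_plus = flanks[0] + unit * (copies + 1) + flanks[1]
        c = max(find_tandem_repeats(seq), key=lambda x: x.span)
        c_plus = max(find_tandem_repeats(seq_plus), key=lambda x: x.span)
        assert c_plus.copy_number == pytest.approx(c.copy_number + 1, abs=1e-9)


def test_planted_imperfect_array_found_and_random_noise_stays_small(small_genome):
    rec, truth = small_genome
    calls = find_tandem_repeats(rec.sequence)
    planted = [c for c in calls if c.unit_length == truth["repeat"]["unit_length"]]
    assert len(planted) == 1
    c = planted[0]
    assert abs(c.copy_number - truth["repeat"]["copies"]) <= 0.5
    assert c.start == pytest.approx(truth["repeat"]["start"], abs=c.unit_length)
    assert frame_preserving(c)
    # chance calls in random AT-rich sequence stay near the detection floor
    rng = np.random.default_rng(77)
    for _ in range(15):
        noise_calls = find_tandem_repeats(_random_seq(rng, 2000))
        assert all(
            c.unit_length < 15 and c.copy_number < 5 for c in noise_calls
        )


def test_strain_panel_copy_numbers_recovered():
    """The published strain panel (copies 18/11/11/9/9/14/10) is recovered
    per strain up to the array-boundary ambiguity of a tail unit."""
    strains, truth = simulate_repeat_strains(seed=21)
    calls = {
        name: find_tandem_repeats(seq) for name, seq in strains.items()
    }
    table = compare_strain_repeats(calls, unit_length=truth["unit_length"])
    got = {s: v for s, v in table.rows if v is not None}
    assert set(got) == set(refdata.STRAIN_REPEAT_COPIES)
    for strain, expected in refdata.STRAIN_REPEAT_COPIES.items():
        assert abs(got[strain] - expected) <= 0.75, (strain, got[strain])
    lo, hi = table.copy_range
    assert abs(lo - 9) <= 0.75 and abs(hi - 18) <= 0.75
    # rows are sorted ascending by copy number
    vals = [v for _, v in table.rows]
    assert vals == sorted(vals)


def test_strain_table_single_and_absent():
    call = RepeatCall(start=0, end=54, unit_length=18, copy_number=3,
                      consensus="A" * 18, mean_identity=1.0)
    table = compare_strain_repeats({"s1": [call], "s2": []})
    assert table.rows == [("s1", 3), ("s2", None)]
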