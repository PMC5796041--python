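"""Sequence assembly: rounding, insertion, gating, trimming, batches."""

import dataclasses
from collections import Counter

import numpy as np
import pytest

from idpdesign import (
    DesignFailure,
    DesignParams,
    DisorderProfile,
    accept_sequence,
    benchmark_generation,
    central_insert,
    compare_init_strategies,
    design_batch,
    design_sequence,
    init_sequence,
    quadrant_table,
    replay_design,
    round_length,
    summarize_benchmark,
    trim_to_length,
)


class CountingStub:
    """Adapter scorer that always fails the mean criterion and counts calls."""

    def __init__(self):
        self.calls = 0

    def __call__(self, seq):
        self.calls += 1
        return np.zeros(len(seq))


# -- length rounding --------------------------------------------------------

@pytest.mark.parametrize("l, expected", [(100, 100), (101, 110), (50, 50), (195, 200)])
def test_round_length_examples(l, expected):
    assert round_length(l) == expected


def test_round_length_exhaustive_invariant():
    for l in range(50, 201):
        l_r = round_length(l)
        assert l <= l_r < l + 10 and l_r % 10 == 0


@pytest.mark.parametrize("l", [49, 201, 0])
def test_round_length_enforces_bounds(l):
    with pytest.raises(ValueError, match="50|200"):
        round_length(l)


# -- initial sequence -------------------------------------------------------

def test_init_sequence_is_a_tandem_repeat(library):
    seq, block, shuffled = init_sequence(0.70, 50, library, rng=4)
    assert len(seq) == 50
    assert seq == shuffled * 5
    assert Counter(shuffled) == Counter(block)
    assert block in [bb.sequence for bb in library.families[0.70]]


def test_init_sequence_is_seed_deterministic(library):
    assert init_sequence(0.60, 80, library, rng=9) == init_sequence(0.60, 80, library, rng=9)


# -- central insertion ------------------------------------------------------

def test_central_insert_hand_example():
    out = central_insert("A" * 20, "D" * 10, rng=None)
    assert out == "AAAAA" + "D" * 10 + "AAAAA"


def test_central_insert_preserves_length_and_books_composition():
    rng = np.random.default_rng(2)
    for L in (20, 50, 100, 200):
        seq = "".join(rng.choice(list("ADEG"), L))
        block = "PEGSKDNQRA"
        out = central_insert(seq, block, rng)
        assert len(out) == L
        expected = Counter(seq) - Counter(seq[:5]) - Counter(seq[-5:]) + Counter(block)
        assert Counter(out) == expected


@pytest.mark.parametrize("seq, block", [("A" * 25, "D" * 10), ("A" * 20, "D" * 9), ("A" * 10, "D" * 10)])
def test_central_insert_rejects_bad_lengths(seq, block):
    with pytest.raises(ValueError):
        central_insert(seq, block)


# -- acceptance gate --------------------------------------------------------

@pytest.mark.parametrize(
    "scores, dt, expected",
    [
        ([0.0, 0.15], 0.075, True),    # delta exactly at the 0.15 threshold
        ([0.0, 0.0], 0.025, True),     # mean residual exactly at the 0.025 threshold
        ([0.0, 0.151], 0.0755, False),  # smoothness violated alone
        ([0.5, 0.5], 0.527, False),    # mean residual 0.027 violated alone
    ],
)
def test_acceptance_gate_is_boundary_inclusive(scores, dt, expected):
    profile = DisorderProfile(np.array(scores))
    assert accept_sequence(profile, dt) is expected


# -- final trimming ---------------------------------------------------------

def test_trim_identity_when_length_matches():
    profile = DisorderProfile(np.full(50, 0.7))
    assert trim_to_length("A" * 50, profile, 50, 0.7) == "A" * 50


def test_trim_removes_the_most_deviant_extremity():
    scores = np.full(20, 0.60)
    scores[0], scores[-1] = 0.58, 0.70
    seq = "N" + "A" * 18 + "Q"
    out = trim_to_length(seq, DisorderProfile(scores), 19, 0.60)
    assert out == "N" + "A" * 18  # C-terminal residue deviates more


def test_trim_tie_break_removes_n_terminus():
    scores = np.full(20, 0.60)
    scores[0] = scores[-1] = 0.65
    seq = "N" + "A" * 18 + "Q"
    out = trim_to_length(seq, DisorderProfile(scores), 19, 0.60)
    assert out == "A" * 18 + "Q"


def test_trim_rejects_inconsistent_lengths():
    profile = DisorderProfile(np.full(50, 0.7))
    with pytest.raises(ValueError):
        trim_to_length("A" * 50, profile, 39, 0.7)


# -- full design ------------------------------------------------------------

def test_design_records_j_insertions_for_l50(library, model, params):
    d = design_sequence(50, 0.75, library, model, params, rng=3)
    assert len(d.provenance.insertions) == 4  # j = 50/10 - 1
    assert len(d.sequence) == 50


def test_design_is_byte_identical_under_a_fixed_seed(library, model, params):
    a = design_sequence(73, 0.65, library, model, params, rng=21)
    b = design_sequence(73, 0.65, library, model, params, rng=21)
    assert a.sequence == b.sequence
    assert a.provenance == b.provenance


def test_forced_failure_aborts_after_exactly_200_rejections(library, params):
    stub = CountingStub()
    strict = dataclasses.replace(params, max_restarts=1)
    with pytest.raises(DesignFailure):
        design_sequence(50, 0.70, library, stub, strict, rng=0)
    # one scored candidate per rejected insertion attempt, nothing else
    assert stub.calls == 200


def test_design_satisfies_the_gate_at_rounded_length(library, model, params):
    d = design_sequence(94, 0.80, library, model, params, rng=12)
    assert d.provenance.delta_at_lr <= params.delta_threshold
    assert abs(0.80 - d.provenance.mean_at_lr) <= params.mean_threshold
    assert len(d.sequence) == 94
    assert "W" not in d.sequence and "C" not in d.sequence


def test_provenance_replay_reproduces_the_sequence(library, model, params):
    d = design_sequence(87, 0.70, library, model, params, rng=5)
    assert replay_design(d.provenance, model, params) == d.sequence


def test_designs_of_length_100_use_several_distinct_blocks(library, model, params):
    d = design_sequence(100, 0.75, library, model, params, rng=8)
    distinct = {rec.block for rec in d.provenance.insertions}
    assert len(distinct) >= 3


def test_design_batch_ranks_and_bounds(library, model, params):
    batch = design_batch(10, 50, 0.85, library, model, params, seed=2)
    assert [d.rank for d in batch] == list(range(1, 11))
    for d in batch:
        assert abs(0.85 - d.provenance.mean_at_lr) <= params.mean_threshold
        assert d.provenance.delta_at_lr <= params.delta_threshold
    for bad in (0, 11):
        with pytest.raises(ValueError):
            design_batch(bad, 50, 0.85, library, model, params, seed=2)


def test_design_rejects_off_grid_dt(library, model, params):
    with pytest.raises(ValueError, match="grid"):
        design_sequence(50, 0.57, library, model, params, rng=0)


# -- benchmark harness ------------------------------------------------------

def test_benchmark_counts_are_recountable(library, model, params):
    table = benchmark_generation([52], [0.75, 0.85], [200], 4, library, model,
                                 params, seed=6)
    assert (table["discarded"] >= 0).all()
    assert table["discarded"].dtype.kind == "i"
    summary = summarize_benchmark(table)
    for _, row in summary.iterrows():
        raw = table[(table["length"] == row["length"]) & (table["dt"] == row["dt"])
                    & (table["cap"] == row["cap"])]
        assert row["mean_discarded"] == pytest.approx(raw["discarded"].mean())
        assert row["failure_rate"] == pytest.approx(raw["failed"].mean())


def test_init_strategy_quadrants_partition(library, model, params):
    comp = compare_init_strategies([0.70], [50], 20, library, model, params, seed=4)
    table = quadrant_table(comp)
    np.testing.assert_allclose(table.sum(axis=1), 1.0)
    assert set(table.index) == {"concat", "repeat"}
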