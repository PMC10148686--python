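import math
import random

import pytest

from ehmmalign import (ModelError, NullModel, SubAlignment, bit_score,
                       build_profile_hmm, determine_match_columns,
                       forward_log, viterbi)
from ehmmalign.alphabet import DNA
from ehmmalign.hmm import END

from conftest import assert_dist_sums, random_profile_hmm, random_query
from oracles import (brute_forward_log, brute_viterbi_log,
                     enumerate_path_probs, path_log_prob)


def sub(rows):
    return SubAlignment(rows, list(range(len(next(iter(rows.values()))))))


# ---------------------------------------------------------------------------
# Match-column calling


def test_all_gap_column_excluded():
    s = sub({"a": "A-G", "b": "C-T"})
    assert determine_match_columns(s, 0.5) == [0, 2]


def test_half_occupied_column_included_at_symfrac_half():
    s = sub({"a": "A", "b": "-"})
    assert determine_match_columns(s, 0.5) == [0]
    assert determine_match_columns(s, 0.6) == []


def test_full_column_included_for_any_symfrac():
    s = sub({"a": "A", "b": "C"})
    assert determine_match_columns(s, 1.0) == [0]


# ---------------------------------------------------------------------------
# Model building


def test_single_ungapped_sequence_model():
    hmm = build_profile_hmm(sub({"a": "ACG"}), alphabet=DNA)
    assert hmm.S_local == 3
    assert hmm.column_map == [0, 1, 2]


def test_match_emission_pseudocount_formula():
    # two A's in a DNA match column with pseudocount 1: (2+1)/(2+4) = 0.5
    hmm = build_profile_hmm(sub({"a": "A", "b": "A"}), pseudocount=1.0,
                            alphabet=DNA)
    assert math.isclose(hmm.match_emissions[0]["A"], 0.5)


def test_all_outgoing_distributions_normalized(rng):
    for _ in range(25):
        hmm = random_profile_hmm(rng)
        if hmm is None:
            continue
        outgoing = {}
        for (u, _v), p in hmm.transitions.items():
            outgoing.setdefault(u, []).append(p)
        for u, ps in outgoing.items():
            assert math.isclose(sum(ps), 1.0, abs_tol=1e-9), u
        for dist in hmm.match_emissions:
            assert_dist_sums(dist)
        for dist in hmm.insert_emissions.values():
            assert_dist_sums(dist)


def test_zero_match_columns_is_model_error():
    with pytest.raises(ModelError):
        build_profile_hmm(sub({"a": "A---", "b": "-C--", "c": "--G-",
                               "d": "---T"}), symfrac=0.5)


def test_column_map_points_at_backbone_columns():
    s = SubAlignment({"a": "A-G", "b": "A-G"}, [2, 5, 9])
    hmm = build_profile_hmm(s, alphabet=DNA)
    assert hmm.column_map == [2, 9]


# ---------------------------------------------------------------------------
# Forward / Viterbi against exhaustive path enumeration


def test_forward_and_viterbi_match_enumeration(rng):
    checked = 0
    while checked < 60:
        hmm = random_profile_hmm(rng)
        if hmm is None:
            continue
        emissions = hmm.emissions()
        q = random_query(rng)
        f = forward_log(hmm, q)
        assert math.isclose(f, brute_forward_log(hmm.transitions,
                                                 emissions, q),
                            abs_tol=1e-9)
        path, v = viterbi(hmm, q)
        assert math.isclose(v, brute_viterbi_log(hmm.transitions,
                                                 emissions, q),
                            abs_tol=1e-9)
        # the returned path must itself have the claimed score
        assert math.isclose(path_log_prob(hmm.transitions, emissions,
                                          path, q), v, abs_tol=1e-9)
        assert f >= v - 1e-12  # sum over paths >= best path
        checked += 1


def test_viterbi_deterministic(rng):
    hmm = None
    while hmm is None:
        hmm = random_profile_hmm(rng)
    q = "ACG"
    assert viterbi(hmm, q) == viterbi(hmm, q)


def test_self_sequence_has_finite_probability():
    hmm = build_profile_hmm(sub({"a": "ACGT"}), alphabet=DNA)
    assert forward_log(hmm, "ACGT") > float("-inf")


def test_all_match_path_for_point_mass_model():
    # a model built from one ungapped sequence, queried with that
    # sequence under small pseudocounts, follows the all-match path
    hmm = build_profile_hmm(sub({"a": "ACGT"}), pseudocount=0.05,
                            transition_pseudocount=0.01, alphabet=DNA)
    path, _ = viterbi(hmm, "ACGT")
    assert path == [("M", 1), ("M", 2), ("M", 3), ("M", 4), END]


def test_empty_query_takes_pure_deletion_path():
    hmm = build_profile_hmm(sub({"a": "ACG", "b": "ACG"}), alphabet=DNA)
    path, score = viterbi(hmm, "")
    assert score > float("-inf")
    assert path == [("D", 1), ("D", 2), ("D", 3), END]


def test_probability_mass_conservation_small_model(rng):
    # sum of P(seq) over all sequences of length <= 3 never exceeds 1
    hmm = None
    while hmm is None or hmm.S_local > 2:
        hmm = random_profile_hmm(rng, max_match=2, backbone_len=3)
    emissions = hmm.emissions()
    total = 0.0
    seqs = [""]
    for _ in range(3):
        seqs += [s + a for s in seqs for a in "ACGT" if len(s) == _]
    for q in {s for s in seqs if len(s) <= 3}:
        paths = enumerate_path_probs(hmm.transitions, emissions, q)
        total += sum(p for _, p in paths)
    assert total <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# Bit scores


def test_null_model_closed_form():
    null = NullModel()
    n = 5
    expected = n * math.log(0.25) + n * math.log(n / (n + 1)) \
        + math.log(1 - n / (n + 1))
    assert math.isclose(null.null_log("ACGTA", DNA), expected)


def test_identical_models_identical_bit_scores():
    h1 = build_profile_hmm(sub({"a": "ACGT", "b": "AC-T"}), alphabet=DNA)
    h2 = build_profile_hmm(sub({"x": "ACGT", "y": "AC-T"}), alphabet=DNA)
    for q in ("ACGT", "AC", "GGG"):
        assert bit_score(h1, q) == bit_score(h2, q)


def test_bit_score_matches_brute_force(rng):
    hmm = None
    while hmm is None:
        hmm = random_profile_hmm(rng)
    q = "ACG"
    brute = brute_forward_log(hmm.transitions, hmm.emissions(), q)
    expected = (brute - NullModel().null_log(q, DNA)) / math.log(2)
    assert math.isclose(bit_score(hmm, q), expected, abs_tol=1e-9)
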