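import math
import random

import numpy as np
import pytest

from ehmmalign import (Alignment, ProfileHMM, SubAlignment, add_glocal,
                       align_query, build_merged_topology,
                       build_profile_hmm, build_query_hmm,
                       compute_adjusted_weights, induce_subalignment,
                       parameterize, viterbi)
from ehmmalign.alphabet import DNA
from ehmmalign.hmm import END, START

from conftest import random_profile_hmm, random_query
from oracles import brute_forward_log, brute_viterbi_log

UNIFORM = {a: 0.25 for a in "ACGT"}


def manual_hmm(m1_out=(0.8, 0.1, 0.1)):
    """Two-match-state HMM over backbone columns 0,1 with hand-set
    M1 outgoing probabilities (M->M, M->I, M->D)."""
    mm, mi, md = m1_out
    trans = {
        (START, ("M", 1)): 1.0,
        (("M", 1), ("M", 2)): mm, (("M", 1), ("I", 1)): mi,
        (("M", 1), ("D", 2)): md,
        (("I", 1), ("M", 2)): 0.9, (("I", 1), ("I", 1)): 0.1,
        (("M", 2), END): 1.0,
        (("D", 2), END): 1.0,
    }
    return ProfileHMM(column_map=[0, 1], transitions=trans,
                      match_emissions=[dict(UNIFORM), dict(UNIFORM)],
                      insert_emissions={k: dict(UNIFORM) for k in range(3)},
                      alphabet=DNA, subset_size=2)


# ---------------------------------------------------------------------------
# Adjusted-bitscore weights


def test_equal_scores_equal_sizes_uniform_weights():
    w = compute_adjusted_weights([3.0, 3.0, 3.0], [5, 5, 5])
    assert np.allclose(w.weights, 1 / 3)
    assert math.isclose(w.weights.sum(), 1.0, abs_tol=1e-9)


def test_one_bit_advantage_doubles_weight():
    w = compute_adjusted_weights([4.0, 3.0], [7, 7])
    assert np.allclose(w.weights, [2 / 3, 1 / 3])


def test_size_prior_scales_weight():
    w = compute_adjusted_weights([2.5, 2.5], [10, 5])
    assert np.allclose(w.weights, [2 / 3, 1 / 3])


def test_extreme_scores_stay_normalized():
    w = compute_adjusted_weights([-100000.0, 100000.0], [1, 1])
    assert math.isclose(w.weights.sum(), 1.0, abs_tol=1e-9)
    assert w.weights[1] > 0.999999


def test_all_neg_inf_falls_back_to_uniform():
    with pytest.warns(UserWarning):
        w = compute_adjusted_weights([float("-inf")] * 4, [1, 2, 3, 4])
    assert np.allclose(w.weights, 0.25)


# ---------------------------------------------------------------------------
# Union topology


def independent_union(hmms):
    """Edge union recomputed directly from the definition."""
    edges = set()
    for h in hmms:
        def m(s, h=h):
            if s in (START, END):
                return s
            kind, k = s
            if kind == "I":
                return ("I", -1 if k == 0 else h.column_map[k - 1])
            return (kind, h.column_map[k - 1])
        for (u, v) in h.transitions:
            edges.add((m(u), m(v)))
    return edges


def map_edge(h, edge):
    def m(s):
        if s in (START, END):
            return s
        kind, k = s
        if kind == "I":
            return ("I", -1 if k == 0 else h.column_map[k - 1])
        return (kind, h.column_map[k - 1])
    return (m(edge[0]), m(edge[1]))


def test_singleton_union_is_isomorphic():
    h = manual_hmm()
    topo = build_merged_topology([h])
    assert topo.edges == {map_edge(h, e) for e in h.transitions}
    assert topo.S == 2


def test_skip_edge_from_interior_all_gap_subset():
    # a subset entirely gapped at an interior backbone column yields a
    # match-to-match transition that skips that column in the merged model
    bb = Alignment({
        "a": "ACGTA",
        "b": "ACGTA",
        "c": "AC-TA",
        "d": "AC-TA",
    })
    full = build_profile_hmm(induce_subalignment(bb, bb.ids), alphabet=DNA)
    gapped = build_profile_hmm(induce_subalignment(bb, ["c", "d"]),
                               alphabet=DNA)
    assert gapped.column_map == [0, 1, 3, 4]  # no match state for column 2
    topo = build_merged_topology([full, gapped], bb.length)
    assert (("M", 1), ("M", 3)) in topo.edges  # the skip edge
    # and it is supported only by the gapped subset's HMM
    assert [i for i, _ in topo.edge_support[(("M", 1), ("M", 3))]] == [1]


def test_union_matches_independent_set_union(rng):
    for _ in range(25):
        hmms = []
        while len(hmms) < rng.randint(2, 3):
            h = random_profile_hmm(rng, max_match=5, backbone_len=6)
            if h is not None:
                hmms.append(h)
        topo = build_merged_topology(hmms)
        assert topo.edges == independent_union(hmms)
        assert topo.match_columns == \
            sorted({c for h in hmms for c in h.column_map})


# ---------------------------------------------------------------------------
# Query-specific parameters


def test_singleton_ensemble_reproduces_source_parameters():
    h = manual_hmm()
    topo = build_merged_topology([h])
    mhmm = parameterize(topo, [h], compute_adjusted_weights([1.0], [2]))
    for edge, p in h.transitions.items():
        assert math.isclose(mhmm.transitions[map_edge(h, edge)], p,
                            abs_tol=1e-12)


def test_identical_hmms_any_weights_reproduce_shared_parameters():
    h1, h2 = manual_hmm(), manual_hmm()
    topo = build_merged_topology([h1, h2])
    w = compute_adjusted_weights([10.0, 2.0], [3, 9])  # arbitrary skew
    mhmm = parameterize(topo, [h1, h2], w)
    for edge, p in h1.transitions.items():
        assert math.isclose(mhmm.transitions[map_edge(h1, edge)], p,
                            abs_tol=1e-12)


def test_weighted_average_of_shared_edge():
    # edges 0.8 and 0.6 under weights (1/2, 1/2): raw 0.7; the state's raw
    # outgoing mass sums to 1, so the normalized value is exactly 0.7
    h1, h2 = manual_hmm((0.8, 0.1, 0.1)), manual_hmm((0.6, 0.2, 0.2))
    topo = build_merged_topology([h1, h2])
    w = compute_adjusted_weights([5.0, 5.0], [4, 4])
    mhmm = parameterize(topo, [h1, h2], w)
    assert math.isclose(mhmm.transitions[(("M", 0), ("M", 1))], 0.7)


def test_weight_sensitivity_converges_to_dominant_hmm():
    # when one HMM's weight -> 1, merged parameters on its edges match it
    h1, h2 = manual_hmm((0.8, 0.1, 0.1)), manual_hmm((0.6, 0.2, 0.2))
    topo = build_merged_topology([h1, h2])
    w = compute_adjusted_weights([100.0, 0.0], [4, 4])
    assert w.weights[0] >= 1 - 1e-6
    mhmm = parameterize(topo, [h1, h2], w)
    for edge, p in h1.transitions.items():
        assert math.isclose(mhmm.transitions[map_edge(h1, edge)], p,
                            abs_tol=1e-6)


# ---------------------------------------------------------------------------
# Glocal edges


@pytest.mark.parametrize("S", [1, 5, 17])
def test_glocal_constants_pre_normalization(S):
    rows = {"a": "ACGT" * 5, "b": "ACGT" * 5}
    sub = SubAlignment({i: r[:S] for i, r in rows.items()}, list(range(S)))
    h = build_profile_hmm(sub, alphabet=DNA)
    topo = build_merged_topology([h])
    mhmm = parameterize(topo, [h], compute_adjusted_weights([1.0], [2]))
    pre = add_glocal(mhmm, renormalize=False)
    entries = {v: p for (u, v), p in pre.transitions.items() if u == START
               and v[0] == "M"}
    assert len(entries) == S
    assert all(math.isclose(p, 0.1 / S) for p in entries.values())
    assert math.isclose(sum(entries.values()), 0.1, abs_tol=1e-9)
    for c in range(1, S + 1):
        assert math.isclose(pre.transitions[(("M", c - 1), END)], 0.1)
    dstates = {s for e in pre.transitions for s in e
               if s not in (START, END) and s[0] == "D"}
    for d in dstates:
        assert math.isclose(pre.transitions[(d, END)], 0.1)
    # after renormalization every outgoing distribution sums to 1
    post = add_glocal(mhmm)
    outgoing = {}
    for (u, _v), p in post.transitions.items():
        outgoing[u] = outgoing.get(u, 0.0) + p
    for u, total in outgoing.items():
        assert math.isclose(total, 1.0, abs_tol=1e-9), u


def test_glocal_beats_global_for_interior_fragment(toy_backbone):
    h = build_profile_hmm(induce_subalignment(toy_backbone,
                                              toy_backbone.ids),
                          pseudocount=0.1, transition_pseudocount=0.05,
                          alphabet=DNA)
    topo = build_merged_topology([h])
    w = compute_adjusted_weights([1.0], [3])
    mhmm = parameterize(topo, [h], w)
    frag = toy_backbone.ungapped("a")[3:5]  # 25% of length 8
    _, global_score = viterbi(mhmm, frag)
    _, glocal_score = viterbi(add_glocal(mhmm), frag)
    assert glocal_score >= global_score


# ---------------------------------------------------------------------------
# Query alignment


def ensemble_for(backbone, **kwargs):
    h = build_profile_hmm(induce_subalignment(backbone, backbone.ids),
                          alphabet=DNA, **kwargs)
    topo = build_merged_topology([h])
    w = compute_adjusted_weights([1.0], [len(backbone)])
    return topo, [h], w


def test_full_length_query_gets_all_match_row(toy_backbone):
    topo, hmms, w = ensemble_for(toy_backbone, pseudocount=0.1,
                                 transition_pseudocount=0.01)
    mhmm = build_query_hmm(topo, hmms, w)
    row = align_query(mhmm, type("Q", (), {"id": "q", "letters":
                                           toy_backbone.ungapped("a")})())
    assert row.placements == [("match", c) for c in range(8)]


def test_interior_fragment_matches_its_window(toy_backbone):
    topo, hmms, w = ensemble_for(toy_backbone, pseudocount=0.1,
                                 transition_pseudocount=0.01)
    mhmm = build_query_hmm(topo, hmms, w)
    frag = toy_backbone.ungapped("a")[2:6]
    row = align_query(mhmm, type("Q", (), {"id": "q", "letters": frag})())
    assert row.placements == [("match", c) for c in range(2, 6)]


def test_single_letter_query_single_placement(toy_backbone):
    topo, hmms, w = ensemble_for(toy_backbone)
    mhmm = build_query_hmm(topo, hmms, w)
    row = align_query(mhmm, type("Q", (), {"id": "q", "letters": "A"})())
    assert len(row.placements) == 1


def test_reduction_to_plain_profile_viterbi(toy_backbone):
    # singleton ensemble with glocal disabled: the merged model's path is
    # the profile HMM's path, state for state (mapped through column_map)
    topo, hmms, w = ensemble_for(toy_backbone)
    h = hmms[0]
    mhmm = build_query_hmm(topo, hmms, w, glocal=False)
    for q in ("ACGTACGT", "ACGT", "C", "GGTT"):
        ppath, pscore = viterbi(h, q)
        mpath, mscore = viterbi(mhmm, q)
        assert math.isclose(pscore, mscore, abs_tol=1e-9)
        mapped = []
        for s in ppath:
            if s == END:
                mapped.append(s)
            elif s[0] == "I":
                mapped.append(("I", -1 if s[1] == 0
                               else h.column_map[s[1] - 1]))
            else:
                mapped.append((s[0], h.column_map[s[1] - 1]))
        assert mapped == mpath


def test_merged_dp_matches_enumeration_glocal_on_and_off(rng):
    checked = 0
    while checked < 20:
        hmms = []
        while len(hmms) < 2:
            h = random_profile_hmm(rng, max_match=3, backbone_len=4)
            if h is not None:
                hmms.append(h)
        topo = build_merged_topology(hmms)
        w = compute_adjusted_weights(
            [rng.uniform(-2, 2) for _ in hmms],
            [h.subset_size for h in hmms])
        for glocal in (False, True):
            mhmm = build_query_hmm(topo, hmms, w, glocal=glocal)
            q = random_query(rng, max_len=4)
            bf = brute_forward_log(mhmm.transitions, mhmm.emissions, q)
            bv = brute_viterbi_log(mhmm.transitions, mhmm.emissions, q)
            from ehmmalign import forward_log
            if bv == float("-inf"):
                continue
            assert math.isclose(forward_log(mhmm, q), bf, abs_tol=1e-9)
            assert math.isclose(viterbi(mhmm, q)[1], bv, abs_tol=1e-9)
        checked += 1
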