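"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and set-union
code paths: path probabilities come from exhaustive enumeration over the
raw transition/emission dictionaries, homologies from a naive column scan,
and centroid edges from dendropy's own bipartition machinery.
"""

from __future__ import annotations

import math
from itertools import combinations

import dendropy

START = ("S",)
END = ("E",)


def _adjacency(transitions):
    adj = {}
    for (u, v), p in transitions.items():
        if p > 0:
            adj.setdefault(u, []).append((v, p))
    return adj


def enumerate_path_probs(transitions, emissions, seq):
    """Probability of every complete START→END path emitting ``seq``.

    Returns a list of (path, probability).  Terminates because delete
    chains strictly advance and every insert self-loop consumes a letter.
    """
    adj = _adjacency(transitions)
    n = len(seq)
    results = []

    def walk(state, pos, prob, path):
        for nxt, t in adj.get(state, []):
            p2 = prob * t
            if nxt == END:
                if pos == n:
                    results.append((path + [nxt], p2))
                continue
            if nxt in emissions:
                if pos < n:
                    e = emissions[nxt].get(seq[pos], 0.0)
                    if e > 0:
                        walk(nxt, pos + 1, p2 * e, path + [nxt])
            else:
                walk(nxt, pos, p2, path + [nxt])

    walk(START, 0, 1.0, [START])
    return results


def brute_forward_log(transitions, emissions, seq):
    paths = enumerate_path_probs(transitions, emissions, seq)
    total = sum(p for _, p in paths)
    return math.log(total) if total > 0 else float("-inf")


def brute_viterbi_log(transitions, emissions, seq):
    paths = enumerate_path_probs(transitions, emissions, seq)
    best = max((p for _, p in paths), default=0.0)
    return math.log(best) if best > 0 else float("-inf")


def path_log_prob(transitions, emissions, path, seq):
    """Replay a path (without START/END affixes handled by caller)."""
    logp = 0.0
    pos = 0
    prev = START
    for state in path:
        logp += math.log(transitions[(prev, state)])
        if state in emissions:
            logp += math.log(emissions[state][seq[pos]])
            pos += 1
        prev = state
    assert pos == len(seq)
    return logp


def brute_homologies(rows, restrict_to=None):
    """Naive homology enumeration: per column, per pair of uppercase
    letters; residue indices count all non-gap letters."""
    ids = list(rows)
    length = len(next(iter(rows.values())))
    ridx = {}
    for i in ids:
        c = 0
        cells = []
        for ch in rows[i]:
            if ch in "-.":
                cells.append(None)
            else:
                cells.append((c, ch.isupper()))
                c += 1
        ridx[i] = cells
    pairs = set()
    for j in range(length):
        present = []
        for i in ids:
            cell = ridx[i][j]
            if cell is not None and cell[1]:
                present.append((i, cell[0]))
        for a, b in combinations(present, 2):
            if restrict_to is not None and a[0] not in restrict_to \
                    and b[0] not in restrict_to:
                continue
            pairs.add((a, b) if a[0] < b[0] else (b, a))
    return pairs


def all_balances(newick):
    """max(|A|,|B|) for every edge bipartition, via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.encode_bipartitions()
    n = len(tree.taxon_namespace)
    balances = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        bits = bin(edge.bipartition.leafset_bitmask).count("1")
        if bits == 0 or bits == n:
            continue
        balances.append(max(bits, n - bits))
    return balances
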