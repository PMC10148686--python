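"""Query-specific merged HMM over the union topology of an ensemble.

Every profile HMM in the ensemble is built on a sub-alignment of the same
backbone, so each of its match states corresponds to a backbone column.
Mapping every state to backbone coordinates and taking the union of the
mapped edge sets yields one shared topology: where a subset alignment is
entirely gapped over a run of columns, its HMM contributes a transition
that *skips* those columns, so the merged model is richer than any single
profile HMM.

The topology is computed once; the numeric parameters are recomputed per
query: each HMM receives a weight from its adjusted bit score (a softmax
over ``b_i + log2 s_i``, i.e. w_i ∝ 2^{b_i}·s_i with the subset size s_i
acting as a prior), transition/emission values are weight-averaged over
the HMMs supporting each edge/state, and every state's outgoing
distribution is renormalised.

Glocal entry/exit edges (start → every match state, every match/delete
state → end) let a short query align to an interior window of the
backbone without paying for flanking deletions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence as TSequence

import numpy as np
from scipy.special import logsumexp

from .alignment import BEFORE_FIRST, ExtendedRow
from .errors import InputError, ModelError
from .hmm import (END, LogHMM, ProfileHMM, START, State, viterbi)

DEFAULT_ENTRY_TOTAL = 0.1
DEFAULT_PEXIT = 0.1


# ---------------------------------------------------------------------------
# Adjusted-bitscore weights


@dataclass
class QueryWeights:
    """Normalised per-HMM weights for one query."""

    weights: np.ndarray
    bitscores: np.ndarray
    sizes: np.ndarray

    def __len__(self) -> int:
        return len(self.weights)


def compute_adjusted_weights(bitscores: TSequence[float],
                             sizes: TSequence[int]) -> QueryWeights:
    """w_i ∝ 2^{b_i}·s_i, normalised stably in the log domain.

    The weight estimates the probability that HMM i generated the query,
    with the subset size as the prior.  If every bit score is -inf the
    weights fall back to uniform (with a warning).
    """
    b = np.asarray(bitscores, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if len(b) == 0 or len(b) != len(s):
        raise InputError("need matching, non-empty bitscore and size lists")
    if np.any(s < 1):
        raise InputError("subset sizes must be >= 1")
    log2w = b + np.log2(s)
    if np.all(np.isneginf(log2w)):
        warnings.warn("all bit scores are -inf; falling back to uniform "
                      "HMM weights")
        w = np.full(len(b), 1.0 / len(b))
    else:
        ln = log2w * math.log(2)
        w = np.exp(ln - logsumexp(ln))
        w /= w.sum()
    return QueryWeights(weights=w, bitscores=b, sizes=np.asarray(sizes))


# ---------------------------------------------------------------------------
# Topology


def map_state(hmm: ProfileHMM, s: State) -> State:
    """A profile-HMM state in backbone coordinates.

    M_k / D_k map to the match/delete state at their backbone column;
    I_k maps to the insert state anchored after column_map(k), with I_0
    mapping to the before-first insert state.
    """
    if s in (START, END):
        return s
    kind, k = s
    if kind == "I":
        return ("I", BEFORE_FIRST if k == 0 else hmm.column_map[k - 1])
    return (kind, hmm.column_map[k - 1])


@dataclass
class MergedTopology:
    """Union topology over backbone columns with supporter bookkeeping."""

    match_columns: list[int]                     # sorted union
    # edge (u, v) -> [(hmm index, transition prob), ...]
    edge_support: dict[tuple[State, State], list[tuple[int, float]]]
    # emitting state -> [(hmm index, emission distribution), ...]
    emit_support: dict[State, list[tuple[int, dict[str, float]]]]
    n_hmms: int

    @property
    def S(self) -> int:
        """Number of merged match states."""
        return len(self.match_columns)

    @property
    def edges(self) -> set[tuple[State, State]]:
        return set(self.edge_support)


def build_merged_topology(hmms: TSequence[ProfileHMM],
                          backbone_length: int | None = None
                          ) -> MergedTopology:
    """Union of the mapped per-HMM edge sets (and emitting states)."""
    if not hmms:
        raise InputError("ensemble is empty")
    if backbone_length is not None:
        for h in hmms:
            if h.column_map and h.column_map[-1] >= backbone_length:
                raise InputError(
                    f"subset {h.subset_id!r} maps match states beyond the "
                    f"backbone (column {h.column_map[-1]} >= "
                    f"{backbone_length})")
    match_cols: set[int] = set()
    edge_support: dict[tuple[State, State], list[tuple[int, float]]] = {}
    emit_support: dict[State, list[tuple[int, dict[str, float]]]] = {}
    for i, h in enumerate(hmms):
        match_cols.update(h.column_map)
        for (u, v), p in h.transitions.items():
            mu, mv = map_state(h, u), map_state(h, v)
            edge_support.setdefault((mu, mv), []).append((i, p))
        for s, dist in h.emissions().items():
            emit_support.setdefault(map_state(h, s), []).append((i, dist))
    return MergedTopology(sorted(match_cols), edge_support, emit_support,
                          len(hmms))


# ---------------------------------------------------------------------------
# Query-specific parameters


@dataclass
class MergedHMM:
    """A merged model with one query's parameters filled in."""

    topology: MergedTopology
    transitions: dict[tuple[State, State], float]
    emissions: dict[State, dict[str, float]]
    alphabet: object
    glocal: bool = False
    entry_total: float = DEFAULT_ENTRY_TOTAL
    pexit: float = DEFAULT_PEXIT
    _log: LogHMM | None = field(default=None, repr=False, compare=False)

    @property
    def S(self) -> int:
        return self.topology.S

    def to_log(self) -> LogHMM:
        if self._log is None:
            self._log = LogHMM(self.transitions, self.emissions,
                               self.alphabet)
        return self._log


def _normalize_outgoing(transitions: dict[tuple[State, State], float]
                        ) -> dict[tuple[State, State], float]:
    totals: dict[State, float] = {}
    for (u, _v), p in transitions.items():
        totals[u] = totals.get(u, 0.0) + p
    out = {}
    for (u, v), p in transitions.items():
        if totals[u] <= 0.0:
            raise ModelError(f"state {u} has zero total outgoing mass")
        out[(u, v)] = p / totals[u]
    return out


def parameterize(topology: MergedTopology, hmms: TSequence[ProfileHMM],
                 weights: QueryWeights) -> MergedHMM:
    """Weight-average the supporters of every edge and emitting state.

    Raw edge value = Σ_i w_i·t_i(edge) over the HMMs that have the edge
    (weights are used as-is, not renormalised over supporters); the
    per-state outgoing renormalisation then absorbs any missing mass.
    Emissions are averaged the same way and renormalised per state.
    """
    if len(weights) != len(hmms):
        raise InputError("one weight per ensemble HMM required")
    w = weights.weights
    raw_trans = {edge: sum(w[i] * p for i, p in sup)
                 for edge, sup in topology.edge_support.items()}
    transitions = _normalize_outgoing(raw_trans)
    emissions: dict[State, dict[str, float]] = {}
    for s, sup in topology.emit_support.items():
        acc: dict[str, float] = {}
        for i, dist in sup:
            for a, p in dist.items():
                acc[a] = acc.get(a, 0.0) + w[i] * p
        total = sum(acc.values())
        if total <= 0.0:
            raise ModelError(f"state {s} has zero total emission mass")
        emissions[s] = {a: p / total for a, p in acc.items()}
    return MergedHMM(topology=topology, transitions=transitions,
                     emissions=emissions, alphabet=hmms[0].alphabet)


def add_glocal(mhmm: MergedHMM,
               entry_total: float = DEFAULT_ENTRY_TOTAL,
               pexit: float = DEFAULT_PEXIT,
               renormalize: bool = True) -> MergedHMM:
    """Add entry/exit edges so a query may span any column window.

    Start→M_c is set to entry_total/S for every merged match state (total
    entry mass entry_total, split equally), and M_c→End, D_c→End are set
    to ``pexit``; existing edges of the same name are overwritten so the
    pre-normalisation constants are exact.  Each state's outgoing
    distribution is then renormalised.
    """
    if mhmm.S < 1:
        raise ModelError("merged model has no match states")
    trans = dict(mhmm.transitions)
    pentry = entry_total / mhmm.S
    for c in mhmm.topology.match_columns:
        trans[(START, ("M", c))] = pentry
        trans[(("M", c), END)] = pexit
    # exit edges from every delete state present in the topology
    dstates = {s for edge in mhmm.transitions for s in edge
               if s not in (START, END) and s[0] == "D"}
    for d in dstates:
        trans[(d, END)] = pexit
    if renormalize:
        trans = _normalize_outgoing(trans)
    return MergedHMM(topology=mhmm.topology, transitions=trans,
                     emissions=mhmm.emissions, alphabet=mhmm.alphabet,
                     glocal=True, entry_total=entry_total, pexit=pexit)


def build_query_hmm(topology: MergedTopology, hmms: TSequence[ProfileHMM],
                    weights: QueryWeights, glocal: bool = True,
                    entry_total: float = DEFAULT_ENTRY_TOTAL,
                    pexit: float = DEFAULT_PEXIT) -> MergedHMM:
    """Parameterise the merged model for one query, optionally glocal."""
    mhmm = parameterize(topology, hmms, weights)
    if glocal:
        mhmm = add_glocal(mhmm, entry_total=entry_total, pexit=pexit)
    return mhmm


def align_query(mhmm: MergedHMM, query) -> ExtendedRow:
    """Glocal Viterbi placement of a query into backbone coordinates.

    Match states in the optimal path place letters into their backbone
    columns; insert states place letters after their anchor column
    (before-first for the leading insert state).
    """
    letters = getattr(query, "letters", query)
    qid = getattr(query, "id", "query")
    if not letters:
        raise InputError(f"query {qid!r} is empty")
    path, _score = viterbi(mhmm, letters)
    placements = []
    for s in path:
        if s == END or s[0] == "D":
            continue
        if s[0] == "M":
            placements.append(("match", s[1]))
        elif s[0] == "I":
            placements.append(("insert", s[1]))
    return ExtendedRow(query_id=qid, letters=letters, placements=placements)
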