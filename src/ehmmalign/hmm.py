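"""Profile HMMs built from sub-alignments, with log-space forward/Viterbi.

This replaces an external ``hmmbuild``/``hmmsearch`` with a transparent,
fully documented model.  Bit-exact HMMER parity is a non-goal; what matters
downstream is that every model exposes match states tied to backbone
columns, proper probability distributions, and comparable bit scores.

States are tuples: ``("S",)`` start, ``("E",)`` end, ``("M", k)`` match,
``("I", k)`` insert anchored after match ``k`` (``("I", 0)`` before the
first match), ``("D", k)`` delete.  Matches and inserts emit; start, end
and deletes are silent.  The transition set is the full 9-transition
profile topology (including I→D and D→I), so any gapped row of the source
sub-alignment traces a path of nonzero probability.

The same machinery (:class:`LogHMM`, :func:`forward_log`, :func:`viterbi`)
runs the merged, glocal model as well: it accepts an arbitrary edge set as
long as silent-state edges always advance the column index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from .alignment import SubAlignment
from .alphabet import Alphabet, GAP_CHARS, detect_alphabet
from .errors import ModelError

State = tuple
START: State = ("S",)
END: State = ("E",)

NEG_INF = float("-inf")

# predecessor preference for Viterbi tie-breaking: M over D over I,
# then lower index
_KIND_RANK = {"S": 0, "M": 1, "D": 2, "I": 3, "E": 4}


def _state_sort_key(s: State):
    if s == START:
        return (-2, -1)
    if s == END:
        return (float("inf"), 5)
    kind, k = s
    # within a column: D (silent) before M before I, so that silent
    # propagation at a fixed sequence position only ever looks backwards
    return (k + (0.5 if kind == "I" else 0.0), {"D": 0, "M": 1, "I": 2}[kind])


def _pref_key(s: State):
    if s == START:
        return (0, -1)
    if s == END:
        return (4, -1)
    return (_KIND_RANK[s[0]], s[1])


class LogHMM:
    """An HMM frozen into log space and indexed for dynamic programming."""

    def __init__(self, transitions: dict[tuple[State, State], float],
                 emissions: dict[State, dict[str, float]],
                 alphabet: Alphabet):
        self.alphabet = alphabet
        self.background_log = -math.log(alphabet.size)
        states = {START, END}
        for u, v in transitions:
            states.add(u)
            states.add(v)
        self.states = sorted(states, key=_state_sort_key)
        self.in_edges: dict[State, list[tuple[State, float]]] = \
            {s: [] for s in self.states}
        for (u, v), p in transitions.items():
            if p > 0.0:
                self.in_edges[v].append((u, math.log(p)))
        for v in self.states:
            self.in_edges[v].sort(key=lambda e: _pref_key(e[0]))
        self.emit_log: dict[State, dict[str, float]] = {
            s: {a: (math.log(p) if p > 0 else NEG_INF)
                for a, p in dist.items()}
            for s, dist in emissions.items()}

    def is_emitting(self, s: State) -> bool:
        return s in self.emit_log

    def emission_log(self, s: State, ch: str) -> float:
        """Log emission probability; ambiguity codes emit at background."""
        c = self.alphabet.canonical(ch)
        if c is None:
            return self.background_log
        return self.emit_log[s].get(c, NEG_INF)


def forward_log(model, seq) -> float:
    """log P(seq | model), summed over all start→end paths.

    ``model`` is anything with a ``to_log()`` method (ProfileHMM,
    MergedHMM) or a LogHMM; ``seq`` is a letter string or Sequence.
    """
    lh = model if isinstance(model, LogHMM) else model.to_log()
    x = getattr(seq, "letters", seq)
    n = len(x)
    F: dict[State, list[float]] = {s: [NEG_INF] * (n + 1) for s in lh.states}
    F[START][0] = 0.0
    for i in range(n + 1):
        for s in lh.states:
            if s == START:
                continue
            if lh.is_emitting(s):
                if i == 0:
                    continue
                e = lh.emission_log(s, x[i - 1])
                if e == NEG_INF:
                    continue
                terms = [F[u][i - 1] + lt for u, lt in lh.in_edges[s]
                         if F[u][i - 1] > NEG_INF]
                if terms:
                    F[s][i] = _logsumexp(terms) + e
            else:
                terms = [F[u][i] + lt for u, lt in lh.in_edges[s]
                         if F[u][i] > NEG_INF]
                if terms:
                    F[s][i] = _logsumexp(terms)
    return F[END][n]


def viterbi(model, seq) -> tuple[list[State], float]:
    """Highest-log-probability start→end path and its score.

    Deterministic: on ties the predecessor earliest in the preference
    order (M over D over I, then lower index) wins, because candidate
    edges are scanned in that order and only a strict improvement
    replaces the incumbent.
    """
    lh = model if isinstance(model, LogHMM) else model.to_log()
    x = getattr(seq, "letters", seq)
    n = len(x)
    V: dict[State, list[float]] = {s: [NEG_INF] * (n + 1) for s in lh.states}
    bp: dict[State, list[State | None]] = \
        {s: [None] * (n + 1) for s in lh.states}
    V[START][0] = 0.0
    for i in range(n + 1):
        for s in lh.states:
            if s == START:
                continue
            emitting = lh.is_emitting(s)
            if emitting:
                if i == 0:
                    continue
                e = lh.emission_log(s, x[i - 1])
                if e == NEG_INF:
                    continue
                j = i - 1
            else:
                e = 0.0
                j = i
            best, arg = NEG_INF, None
            for u, lt in lh.in_edges[s]:
                cand = V[u][j] + lt
                if cand > best:
                    best, arg = cand, u
            if arg is not None:
                V[s][i] = best + e
                bp[s][i] = arg
    if V[END][n] == NEG_INF:
        raise ModelError("no finite-probability path through the model")
    path: list[State] = []
    s, i = END, n
    while s != START:
        u = bp[s][i]
        if lh.is_emitting(s):
            i -= 1
        path.append(s)
        s = u
    path.reverse()
    return path, V[END][n]  # START omitted, END included


def _logsumexp(vals: list[float]) -> float:
    m = max(vals)
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(sum(math.exp(v - m) for v in vals))


# ---------------------------------------------------------------------------
# Profile HMM construction


def allowed_transitions(S_local: int) -> list[tuple[State, State]]:
    """The full profile-HMM edge set for ``S_local`` match states."""
    edges: list[tuple[State, State]] = []

    def targets(k: int) -> list[State]:
        if k < S_local:
            return [("M", k + 1), ("I", k), ("D", k + 1)]
        return [END, ("I", S_local)]

    edges += [(START, t) for t in targets(0)]
    for k in range(1, S_local + 1):
        edges += [(("M", k), t) for t in targets(k)]
        edges += [(("D", k), t) for t in targets(k)]
    for k in range(0, S_local + 1):
        # I_k shares M_k's forward targets but may also self-loop
        nxt = [("M", k + 1), ("D", k + 1)] if k < S_local else [END]
        edges += [(("I", k), t) for t in nxt]
        edges.append((("I", k), ("I", k)))
    return edges


@dataclass
class NullModel:
    """Background model for bit scores.

    ``background`` of None means uniform over the alphabet; ``extension``
    of None uses the length-adaptive geometric n/(n+1) at scoring time
    (so the null assigns most mass near the observed length, in the
    spirit of HMMER's R-type null).
    """

    background: dict[str, float] | None = None
    extension: float | None = None

    def null_log(self, seq, alphabet: Alphabet) -> float:
        x = getattr(seq, "letters", seq)
        n = len(x)
        uniform = -math.log(alphabet.size)
        total = 0.0
        for ch in x:
            c = alphabet.canonical(ch)
            if c is None or self.background is None:
                total += uniform
            else:
                total += math.log(self.background[c])
        p = self.extension if self.extension is not None else n / (n + 1)
        total += n * math.log(p) + math.log1p(-p)
        return total


@dataclass
class ProfileHMM:
    """A profile HMM over a sub-alignment, tied to backbone columns.

    ``column_map[k-1]`` is the backbone column of match state ``("M", k)``.
    """

    column_map: list[int]
    transitions: dict[tuple[State, State], float]
    match_emissions: list[dict[str, float]]
    insert_emissions: dict[int, dict[str, float]]
    alphabet: Alphabet
    subset_id: str | int | None = None
    subset_size: int = 1
    _log: LogHMM | None = field(default=None, repr=False, compare=False)

    @property
    def S_local(self) -> int:
        return len(self.column_map)

    def emissions(self) -> dict[State, dict[str, float]]:
        out: dict[State, dict[str, float]] = {}
        for k, dist in enumerate(self.match_emissions, start=1):
            out[("M", k)] = dist
        for k, dist in self.insert_emissions.items():
            out[("I", k)] = dist
        return out

    def to_log(self) -> LogHMM:
        if self._log is None:
            self._log = LogHMM(self.transitions, self.emissions(),
                               self.alphabet)
        return self._log

    def dump(self) -> str:
        """Human-readable tabular dump for debugging."""
        lines = [f"# profile HMM: S={self.S_local} subset={self.subset_id} "
                 f"size={self.subset_size}"]
        lines.append("# match_state\tbackbone_column")
        for k, c in enumerate(self.column_map, start=1):
            lines.append(f"M{k}\t{c}")
        lines.append("# transition\tprobability")
        for (u, v), p in sorted(self.transitions.items(),
                                key=lambda kv: (_state_sort_key(kv[0][0]),
                                                _state_sort_key(kv[0][1]))):
            lines.append(f"{_fmt(u)}->{_fmt(v)}\t{p:.6g}")
        return "\n".join(lines)


def _fmt(s: State) -> str:
    return s[0] if len(s) == 1 else f"{s[0]}{s[1]}"


def determine_match_columns(sub: SubAlignment, symfrac: float = 0.5
                            ) -> list[int]:
    """Backbone columns that receive a match state.

    A column qualifies when its non-gap occupancy fraction in the
    sub-alignment is at least ``symfrac``.  Columns entirely gapped in the
    subset never qualify — that is what creates column-skipping edges when
    the models are merged.
    """
    if not 0 < symfrac <= 1:
        raise ValueError("symfrac must be in (0, 1]")
    nrows = len(sub.rows)
    cols = []
    for j in range(sub.length):
        occ = sum(1 for c in sub.column(j) if c not in GAP_CHARS)
        if occ / nrows >= symfrac:
            cols.append(sub.backbone_columns[j])
    return cols


def build_profile_hmm(sub: SubAlignment, symfrac: float = 0.5,
                      pseudocount: float = 1.0,
                      transition_pseudocount: float = 0.1,
                      alphabet: Alphabet | None = None,
                      subset_id: str | int | None = None) -> ProfileHMM:
    """Estimate a profile HMM from a sub-alignment by path counting.

    Each row induces a unique state path (letter in a match column → M,
    letter elsewhere → I at the preceding match index, gap in a match
    column → D); transitions and match emissions are Laplace-smoothed
    counts.  Insert states emit the background distribution.
    """
    if alphabet is None:
        alphabet = detect_alphabet(sub.rows.values())
    match_cols = determine_match_columns(sub, symfrac)
    if not match_cols:
        raise ModelError(
            f"subset {subset_id!r}: no column meets symfrac={symfrac}; "
            "the model would have zero match states")
    S = len(match_cols)
    col_is_match = set(match_cols)
    col_to_k = {c: k for k, c in enumerate(match_cols, start=1)}

    tcount: dict[tuple[State, State], float] = {}
    ecount: list[dict[str, float]] = [dict() for _ in range(S)]
    for row in sub.rows.values():
        prev: State = START
        for j in range(sub.length):
            col = sub.backbone_columns[j]
            ch = row[j]
            is_gap = ch in GAP_CHARS
            if col in col_is_match:
                k = col_to_k[col]
                cur: State = ("D", k) if is_gap else ("M", k)
            elif is_gap:
                continue
            else:
                # insert anchored at the last match column passed
                anchor = 0
                if prev != START:
                    anchor = prev[1]
                cur = ("I", anchor)
            tcount[(prev, cur)] = tcount.get((prev, cur), 0.0) + 1.0
            if cur[0] == "M" and not is_gap:
                c = alphabet.canonical(ch)
                if c is not None:
                    ecount[cur[1] - 1][c] = ecount[cur[1] - 1].get(c, 0) + 1.0
            prev = cur
        tcount[(prev, END)] = tcount.get((prev, END), 0.0) + 1.0

    transitions: dict[tuple[State, State], float] = {}
    by_source: dict[State, list[State]] = {}
    for u, v in allowed_transitions(S):
        by_source.setdefault(u, []).append(v)
    for u, targets in by_source.items():
        total = sum(tcount.get((u, v), 0.0) for v in targets)
        denom = total + transition_pseudocount * len(targets)
        for v in targets:
            transitions[(u, v)] = \
                (tcount.get((u, v), 0.0) + transition_pseudocount) / denom

    K = alphabet.size
    match_emissions = []
    for counts in ecount:
        total = sum(counts.values())
        match_emissions.append(
            {a: (counts.get(a, 0.0) + pseudocount) / (total + pseudocount * K)
             for a in alphabet.letters})
    background = {a: 1.0 / K for a in alphabet.letters}
    insert_emissions = {k: dict(background) for k in range(S + 1)}

    return ProfileHMM(column_map=match_cols, transitions=transitions,
                      match_emissions=match_emissions,
                      insert_emissions=insert_emissions, alphabet=alphabet,
                      subset_id=subset_id, subset_size=len(sub.rows))


def bit_score(model, seq, null: NullModel | None = None) -> float:
    """(log2) odds of the model against the null for ``seq``."""
    if null is None:
        null = NullModel()
    lh = model if isinstance(model, LogHMM) else model.to_log()
    return (forward_log(lh, seq) - null.null_log(seq, lh.alphabet)) \
        / math.log(2)
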