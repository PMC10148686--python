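"""Sum-of-pairs alignment error (SPFN/SPFP).

A *homology* is an unordered pair of residues — identified by (sequence id,
ungapped residue index) — that share a column.  Lowercase letters were
emitted by insertion states and are never homologous, so they contribute no
pairs.  SPFN is the fraction of reference homologies missing from the
estimate; SPFP the fraction of estimated homologies absent from the
reference.  In *query-only* mode, only pairs touching at least one query
sequence are counted, which isolates placement error when every method
shares the same backbone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .alignment import Alignment
from .alphabet import GAP_CHARS
from .errors import InputError

Residue = tuple[str, int]
Homology = tuple[Residue, Residue]


@dataclass
class SPScore:
    spfn: float
    spfp: float
    shared: int
    ref_only: int
    est_only: int

    @property
    def average(self) -> float:
        """(SPFN + SPFP) / 2 — the conventional single-number summary."""
        return (self.spfn + self.spfp) / 2.0


def homology_pairs(aln: Alignment,
                   restrict_to: Iterable[str] | None = None
                   ) -> set[Homology]:
    """All homologous residue pairs of an alignment.

    With ``restrict_to``, only pairs with at least one member in the given
    id set are returned (query-only mode).
    """
    restrict = None if restrict_to is None else set(restrict_to)
    # per-row cumulative residue index at each column (uppercase only count)
    ids = aln.ids
    residue_idx: dict[str, list[int | None]] = {}
    for i in ids:
        row = aln.rows[i]
        counter = 0
        cells: list[int | None] = []
        for ch in row:
            if ch in GAP_CHARS:
                cells.append(None)
            else:
                cells.append(counter if ch.isupper() else None)
                counter += 1
        residue_idx[i] = cells
    pairs: set[Homology] = set()
    for j in range(aln.length):
        col = [(i, residue_idx[i][j]) for i in ids
               if residue_idx[i][j] is not None]
        for (ia, ra), (ib, rb) in combinations(col, 2):
            if restrict is not None and ia not in restrict \
                    and ib not in restrict:
                continue
            pair = ((ia, ra), (ib, rb)) if ia < ib else ((ib, rb), (ia, ra))
            pairs.add(pair)
    return pairs


def sp_error(est: Alignment, ref: Alignment,
             restrict_to: Iterable[str] | None = None) -> SPScore:
    """SPFN/SPFP of an estimated alignment against a reference.

    Both alignments must contain the same sequences (same ids, identical
    letters once gaps and case are stripped).  A side with no homologies
    contributes an error of 0 by convention.
    """
    if set(est.ids) != set(ref.ids):
        raise InputError("estimated and reference alignments have "
                         "different sequence id sets")
    for i in est.ids:
        if est.ungapped(i).upper() != ref.ungapped(i).upper():
            raise InputError(
                f"sequence {i!r} differs between estimated and reference "
                "alignments once gaps are removed")
    if restrict_to is not None:
        unknown = set(restrict_to) - set(ref.ids)
        if unknown:
            raise InputError(f"restrict_to ids not in alignments: "
                             f"{sorted(unknown)}")
    est_pairs = homology_pairs(est, restrict_to)
    ref_pairs = homology_pairs(ref, restrict_to)
    shared = len(est_pairs & ref_pairs)
    ref_only = len(ref_pairs) - shared
    est_only = len(est_pairs) - shared
    spfn = ref_only / (shared + ref_only) if (shared + ref_only) else 0.0
    spfp = est_only / (shared + est_only) if (shared + est_only) else 0.0
    return SPScore(spfn=spfn, spfp=spfp, shared=shared,
                   ref_only=ref_only, est_only=est_only)
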