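"""Self-contained desk-scale placement-recovery experiment.

Simulates a backbone with known true alignment, trims some held-in
sequences to fragments following the high-fragmentary protocol (target
mean 25% of the median length; the sd is scaled to the fixture lengths),
re-places the fragments with the merged-HMM pipeline, and scores
query-only SPFN/SPFP against the truth.  Because each fragment descends
from a backbone row, the true placement is the source row restricted to
the fragment's window — no external reference data is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import Alignment, Sequence
from .errors import InputError
from .pipeline import RunConfig, run_align
from .scoring import SPScore, sp_error
from .simulate import FragmentConfig, SimConfig, make_fragments, \
    simulate_true_msa


@dataclass
class RecoveryResult:
    score: SPScore
    n_backbone: int
    n_queries: int
    fragment_lengths: list[int]
    estimated: Alignment
    reference: Alignment


def _window_row(row: str, fragment: str) -> str:
    """True reference row for a fragment: the source row with residues
    outside the fragment's window gapped out."""
    ungapped = row.replace("-", "")
    start = ungapped.find(fragment)
    if start < 0:
        raise InputError("fragment is not a substring of its source")
    end = start + len(fragment)
    cells = []
    seen = 0
    for ch in row:
        if ch == "-":
            cells.append("-")
        else:
            cells.append(ch if start <= seen < end else "-")
            seen += 1
    return "".join(cells)


def placement_recovery(seed: int, n_taxa: int = 20, root_length: int = 300,
                       n_fragments: int = 10, fragment_sd: float = 12.0,
                       cfg: RunConfig | None = None) -> RecoveryResult:
    """Run the simulate → fragment → re-place → score loop once.

    ``seed`` drives the simulation and the fragmenter.  ``cfg`` tunes the
    aligner (ensemble mode, glocal on/off, ...); the default uses the
    disjoint ensemble with glocal edges.
    """
    cfg = cfg or RunConfig(max_subset_size=10)
    true_aln, tree = simulate_true_msa(SimConfig(
        n_taxa=n_taxa, root_length=root_length, seed=seed))
    sources = sorted(true_aln.ids)[:n_fragments]
    full = [Sequence(i, true_aln.ungapped(i)) for i in sources]
    frags = make_fragments(full, FragmentConfig(
        mean_fraction=0.25, sd=fragment_sd, fraction=1.0, seed=seed + 1))
    queries = [Sequence(f"q_{s.id}", s.letters) for s in frags]

    est = run_align(true_aln, tree, queries, cfg)

    ref_rows = dict(true_aln.rows)
    for frag in frags:
        ref_rows[f"q_{frag.id}"] = _window_row(true_aln.rows[frag.id],
                                               frag.letters)
    ref = Alignment(ref_rows)
    # pad the reference to the estimate's sequence set (ids must agree)
    score = sp_error(est, ref, restrict_to=[q.id for q in queries])
    return RecoveryResult(score=score, n_backbone=len(true_aln),
                          n_queries=len(queries),
                          fragment_lengths=[len(q.letters) for q in queries],
                          estimated=est, reference=ref)
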