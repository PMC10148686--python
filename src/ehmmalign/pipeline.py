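"""End-to-end orchestration: backbone → ensemble → merged HMM → final MSA.

The pipeline has three stages.  First the backbone is fixed (given, or
carved out of a single unaligned input by a length policy).  Second the
backbone tree is decomposed at centroid edges and a profile HMM is built
on the sub-alignment of every ensemble subset.  Third, per query: bit
scores against every ensemble HMM → adjusted weights → query-specific
merged HMM with glocal edges → Viterbi placement.  The placements are
assembled into the final alignment by transitivity.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence as TSequence

import dendropy

from .alignment import (Alignment, ExtendedRow, Sequence,
                        induce_subalignment, merge_extended)
from .alphabet import detect_alphabet
from .decomposition import (Decomposition, EnsembleSpec, decompose,
                            leaf_labels, select_ensemble)
from .errors import InputError
from .hmm import NullModel, ProfileHMM, bit_score, build_profile_hmm
from .merged import (DEFAULT_ENTRY_TOTAL, DEFAULT_PEXIT, MergedTopology,
                     align_query, build_merged_topology, build_query_hmm,
                     compute_adjusted_weights)
from .scoring import SPScore, sp_error

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of the alignment pipeline (defaults match the method)."""

    ensemble: str = "disjoint"
    max_subset_size: int = 50
    symfrac: float = 0.5
    pseudocount: float = 1.0
    transition_pseudocount: float = 0.1
    glocal: bool = True
    entry_total: float = DEFAULT_ENTRY_TOTAL
    pexit: float = DEFAULT_PEXIT
    top_k: int | None = None      # keep only the k best-scoring HMMs
    threads: int = 1
    max_merged_edges: int | None = 2_000_000  # memory guardrail


@dataclass
class EnsembleModel:
    """The query-independent part: subsets, HMMs and merged topology."""

    spec: EnsembleSpec
    hmms: list[ProfileHMM]
    topology: MergedTopology
    backbone: Alignment


def build_ensemble(backbone: Alignment, tree: dendropy.Tree,
                   cfg: RunConfig | None = None) -> EnsembleModel:
    """Decompose the tree and build one profile HMM per ensemble subset."""
    cfg = cfg or RunConfig()
    leaves = set(leaf_labels(tree))
    if leaves != set(backbone.ids):
        raise InputError(
            "tree leaves do not match backbone ids "
            f"(only in tree: {sorted(leaves - set(backbone.ids))[:5]}, "
            f"only in backbone: {sorted(set(backbone.ids) - leaves)[:5]})")
    dec: Decomposition = decompose(tree, cfg.max_subset_size)
    spec = select_ensemble(dec, cfg.ensemble)
    alphabet = detect_alphabet(backbone.rows.values())
    hmms = []
    for idx, subset in enumerate(spec.subsets):
        sub = induce_subalignment(backbone, sorted(subset))
        hmms.append(build_profile_hmm(
            sub, symfrac=cfg.symfrac, pseudocount=cfg.pseudocount,
            transition_pseudocount=cfg.transition_pseudocount,
            alphabet=alphabet, subset_id=idx))
    topology = build_merged_topology(hmms, backbone.length)
    n_edges = len(topology.edge_support)
    logger.info("ensemble mode=%s subsets=%d sizes=%s merged_edges=%d",
                cfg.ensemble, len(spec.subsets), spec.subset_sizes, n_edges)
    if cfg.max_merged_edges is not None and n_edges > cfg.max_merged_edges:
        raise InputError(
            f"merged topology has {n_edges} edges, above the configured "
            f"cap {cfg.max_merged_edges}; raise max_merged_edges or use a "
            "smaller ensemble")
    return EnsembleModel(spec=spec, hmms=hmms, topology=topology,
                         backbone=backbone)


def place_query(model: EnsembleModel, query: Sequence,
                cfg: RunConfig | None = None) -> ExtendedRow:
    """Score, weight, parameterise and align a single query."""
    cfg = cfg or RunConfig()
    null = NullModel()
    scores = [bit_score(h, query, null) for h in model.hmms]
    sizes = [h.subset_size for h in model.hmms]
    weights = compute_adjusted_weights(scores, sizes)
    if cfg.top_k is not None and cfg.top_k < len(model.hmms):
        order = sorted(range(len(model.hmms)),
                       key=lambda i: weights.weights[i], reverse=True)
        keep = set(order[:cfg.top_k])
        scores = [s if i in keep else float("-inf")
                  for i, s in enumerate(scores)]
        weights = compute_adjusted_weights(scores, sizes)
    top = int(max(range(len(model.hmms)), key=lambda i: weights.weights[i]))
    entropy = -sum(w * math.log(w) for w in weights.weights if w > 0)
    logger.debug("query %s: top HMM=%s w=%.4f weight entropy=%.4f",
                 query.id, model.hmms[top].subset_id,
                 weights.weights[top], entropy)
    mhmm = build_query_hmm(model.topology, model.hmms, weights,
                           glocal=cfg.glocal, entry_total=cfg.entry_total,
                           pexit=cfg.pexit)
    return align_query(mhmm, query)


def run_align(backbone: Alignment, tree: dendropy.Tree,
              queries: TSequence[Sequence],
              cfg: RunConfig | None = None) -> Alignment:
    """Align all queries into the backbone; returns the final MSA.

    Per-query work is independent; with ``cfg.threads > 1`` queries are
    placed concurrently and results are identical to serial execution
    (placements are collected in input order).
    """
    cfg = cfg or RunConfig()
    dup = set(backbone.rows) & {q.id for q in queries}
    if dup:
        raise InputError(f"query ids duplicate backbone ids: {sorted(dup)}")
    model = build_ensemble(backbone, tree, cfg)
    if not queries:
        logger.warning("no query sequences; output equals the backbone")
        return Alignment(dict(backbone.rows))
    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            rows = list(pool.map(lambda q: place_query(model, q, cfg),
                                 queries))
    else:
        rows = [place_query(model, q, cfg) for q in queries]
    return merge_extended(backbone, rows)


def run_eval(est: Alignment, ref: Alignment,
             query_ids: TSequence[str] | None = None) -> SPScore:
    """SPFN/SPFP report (query-only when ``query_ids`` is given)."""
    return sp_error(est, ref, restrict_to=query_ids)
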