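"""Backbone/query split, newick parsing and centroid-edge decomposition.

The guide tree over the backbone sequences is recursively cut at *centroid
edges* — edges whose removal splits the leaf set as evenly as possible —
until every part holds at most ``max_size`` leaves.  Every subset touched on
the way down (the full set included) is recorded; the recursion's leaves are
the *minimal* subsets, which are pairwise disjoint and partition the
backbone.  Three ensemble variants are drawn from one decomposition:

``disjoint``
    the minimal subsets only (the default),
``disjoint+bb``
    the minimal subsets plus the full backbone set,
``upp``
    every recorded subset (a hierarchical, laminar family).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Sequence as TSequence

import dendropy

from .alignment import Sequence
from .errors import ConfigurationError, DecompositionError, InputError

logger = logging.getLogger(__name__)

ENSEMBLE_MODES = ("disjoint", "disjoint+bb", "upp")


# ---------------------------------------------------------------------------
# Backbone / query split


def split_by_length(seqs: TSequence[Sequence], *,
                    fraction: float | None = None,
                    threshold: int | None = None,
                    ) -> tuple[list[str], list[str]]:
    """Split sequences into (backbone ids, query ids) by ungapped length.

    Exactly one policy applies: with ``threshold`` t, backbone sequences are
    those of length >= t; with ``fraction`` f (default 0.25), those whose
    length is within f·median of the median length.  Order is preserved.
    """
    if len(seqs) < 2:
        raise InputError("need at least 2 sequences to split")
    if fraction is not None and threshold is not None:
        raise ConfigurationError("give either fraction or threshold, not both")
    lengths = {s.id: sum(c != "-" for c in s.letters) for s in seqs}
    if threshold is not None:
        keep = {i for i, n in lengths.items() if n >= threshold}
    else:
        f = 0.25 if fraction is None else fraction
        med = statistics.median(lengths.values())
        keep = {i for i, n in lengths.items() if abs(n - med) <= f * med}
    backbone = [s.id for s in seqs if s.id in keep]
    queries = [s.id for s in seqs if s.id not in keep]
    if not backbone:
        raise ConfigurationError(
            "length split left no backbone sequences; loosen the policy "
            "(larger fraction or lower threshold)")
    return backbone, queries


# ---------------------------------------------------------------------------
# Trees


def read_tree(path) -> dendropy.Tree:
    """Read a newick tree; branch lengths/support are tolerated and ignored."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises various parse errors
        raise InputError(f"cannot parse newick tree {path}: {exc}") from exc
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


@dataclass(frozen=True)
class CentroidSplit:
    """The two leaf-label sets either side of a chosen (centroid) edge."""

    small: frozenset[str]
    large: frozenset[str]

    @property
    def balance(self) -> int:
        return max(len(self.small), len(self.large))


def _splits(tree: dendropy.Tree) -> list[tuple[frozenset[str], frozenset[str]]]:
    """All leaf bipartitions induced by edges, deduplicated.

    Newick forces an arbitrary rooting; the two root-adjacent edges of a
    bifurcating root describe the same unrooted edge, hence the dedup by
    canonical side.
    """
    all_leaves = frozenset(leaf_labels(tree))
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = frozenset(acc)
    seen: set[frozenset[str]] = set()
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a = below[id(node)]
        b = all_leaves - a
        if not a or not b:
            continue
        key = min(a, b, key=lambda s: (len(s), sorted(s)))
        if key in seen:
            continue
        seen.add(key)
        out.append((a, b))
    return out


def find_centroid_edge(tree: dendropy.Tree) -> CentroidSplit:
    """Edge minimising max(|A|, |B|) over its two leaf sides.

    Ties are broken deterministically by the lexicographically smallest
    sorted label list of the smaller side.
    """
    splits = _splits(tree)
    if not splits:
        raise DecompositionError("tree has fewer than 2 leaves; cannot split")
    best = None
    best_key = None
    for a, b in splits:
        small, large = (a, b) if (len(a), sorted(a)) <= (len(b), sorted(b)) \
            else (b, a)
        key = (max(len(a), len(b)), sorted(small))
        if best_key is None or key < best_key:
            best_key = key
            best = CentroidSplit(small, large)
    return best


# ---------------------------------------------------------------------------
# Decomposition


@dataclass(frozen=True)
class Subset:
    labels: frozenset[str]
    level: int
    parent: int | None  # index into Decomposition.subsets


@dataclass
class Decomposition:
    subsets: list[Subset] = field(default_factory=list)
    max_size: int = 50

    @property
    def full_set(self) -> frozenset[str]:
        return self.subsets[0].labels

    @property
    def minimal_subsets(self) -> list[frozenset[str]]:
        parents = {s.parent for s in self.subsets if s.parent is not None}
        return [s.labels for i, s in enumerate(self.subsets)
                if i not in parents]


def decompose(tree: dendropy.Tree, max_size: int = 50) -> Decomposition:
    """Recursive centroid-edge decomposition down to ``max_size`` leaves.

    Every subset encountered is recorded (full set first); a subset larger
    than ``max_size`` is cut at its centroid edge and both sides recursed,
    smaller side first.  Deterministic for a given tree.
    """
    if max_size < 2:
        raise ConfigurationError("max_size must be >= 2")
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        raise InputError("tree leaf labels are not unique")
    dec = Decomposition(max_size=max_size)

    def recurse(subtree: dendropy.Tree, level: int, parent: int | None) -> None:
        labs = frozenset(leaf_labels(subtree))
        idx = len(dec.subsets)
        dec.subsets.append(Subset(labs, level, parent))
        if len(labs) <= max_size:
            if len(labs) == 1:
                logger.warning(
                    "decomposition produced a single-sequence subset %s; "
                    "its profile HMM is degenerate but well-defined",
                    sorted(labs))
            return
        split = find_centroid_edge(subtree)
        for side in (split.small, split.large):
            sub = subtree.extract_tree_with_taxa_labels(side)
            recurse(sub, level + 1, idx)

    recurse(tree, 0, None)
    return dec


# ---------------------------------------------------------------------------
# Ensemble selection


@dataclass
class EnsembleSpec:
    """The id subsets whose profile HMMs make up the ensemble."""

    mode: str
    subsets: list[frozenset[str]]

    @property
    def subset_sizes(self) -> list[int]:
        return [len(s) for s in self.subsets]


def select_ensemble(dec: Decomposition, mode: str = "disjoint") -> EnsembleSpec:
    if mode not in ENSEMBLE_MODES:
        raise ConfigurationError(
            f"unknown ensemble mode {mode!r}; choose from {ENSEMBLE_MODES}")
    minimal = dec.minimal_subsets
    if mode == "disjoint":
        subsets = list(minimal)
    elif mode == "disjoint+bb":
        subsets = list(minimal)
        if dec.full_set not in subsets:
            subsets.append(dec.full_set)
    else:  # upp
        subsets = [s.labels for s in dec.subsets]
    return EnsembleSpec(mode, subsets)
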