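"""Desk-scale synthetic data: a true-alignment simulator and a fragmenter.

The simulator evolves a root sequence down a random binary tree with
per-branch substitutions and indels while tracking which residues descend
from which ancestral site, so the returned alignment is the *true*
homology-faithful alignment.  It is deliberately simple — uniform
substitutions, geometric indel lengths, unit branch lengths — which is
enough signal for placement-recovery experiments but does not emulate
rate heterogeneity, selection or realistic gap-length mixtures.

The fragmenter reproduces the high-fragmentary protocol used in
fragmentation benchmarks: a seeded subset of sequences is trimmed to a
substring whose target length is drawn from Normal(mean, sd), where the
mean is 25% of the median sequence length in the high-fragmentary (HF)
condition and half of that in the ultra-high-fragmentary (UHF) condition,
with sd 60 at benchmark scale.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence as TSequence

import dendropy
import numpy as np

from .alignment import Alignment, Sequence
from .errors import InputError

_DNA = "ACGT"


@dataclass
class SimConfig:
    """Parameters of the toy evolution model (all per branch)."""

    n_taxa: int = 20
    root_length: int = 300
    sub_prob: float = 0.05        # per-site substitution probability
    indel_prob: float = 0.01      # per-site deletion / per-gap insertion rate
    mean_indel_length: float = 2.0
    seed: int = 0


@dataclass
class FragmentConfig:
    """Fragmentation protocol parameters.

    ``mean_length`` (absolute), when given, takes precedence over
    ``mean_fraction`` (of the median ungapped input length).
    """

    mean_length: float | None = None
    mean_fraction: float | None = 0.25
    sd: float = 60.0
    fraction: float = 0.5   # fraction of sequences to fragment
    seed: int = 0

    @classmethod
    def hf(cls, seed: int = 0, sd: float = 60.0) -> "FragmentConfig":
        """High-fragmentary: target mean 25% of the median length."""
        return cls(mean_fraction=0.25, sd=sd, fraction=0.5, seed=seed)

    @classmethod
    def uhf(cls, seed: int = 0, sd: float = 60.0) -> "FragmentConfig":
        """Ultra-high-fragmentary: exactly half the HF target mean."""
        hf = cls.hf(seed=seed, sd=sd)
        return cls(mean_fraction=hf.mean_fraction / 2.0, sd=sd,
                   fraction=0.5, seed=seed)


def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random binary tree as nested tuples, by repeated random joins."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def _to_newick(node) -> str:
    if isinstance(node, str):
        return f"{node}:1.0"
    left, right = node
    return f"({_to_newick(left)},{_to_newick(right)}):1.0"


def simulate_true_msa(cfg: SimConfig) -> tuple[Alignment, dendropy.Tree]:
    """Simulate a true alignment and its generating tree.

    Residues are tracked by globally ordered site ids: substitutions keep
    a site's id, insertions mint new ids spliced into the global order,
    deletions drop the residue but not the site.  Leaf rows written over
    the surviving site order therefore reproduce true homologies exactly.
    """
    if cfg.n_taxa < 2:
        raise InputError("need at least 2 taxa")
    if not 0 <= cfg.sub_prob <= 1 or not 0 <= cfg.indel_prob <= 1:
        raise InputError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    labels = [f"s{i:03d}" for i in range(cfg.n_taxa)]
    topo = _random_topology(labels, rng)

    order: list[int] = list(range(cfg.root_length))  # global site order
    next_id = cfg.root_length
    root_seq = [(i, _DNA[rng.integers(4)]) for i in range(cfg.root_length)]
    leaf_seqs: dict[str, list[tuple[int, str]]] = {}

    def insert_after(site: int | None, count: int) -> list[int]:
        """Mint ``count`` new site ids after ``site`` in the global order."""
        nonlocal next_id
        ids = list(range(next_id, next_id + count))
        next_id += count
        pos = 0 if site is None else order.index(site) + 1
        order[pos:pos] = ids
        return ids

    def evolve(seq: list[tuple[int, str]]) -> list[tuple[int, str]]:
        out: list[tuple[int, str]] = []
        # substitutions + deletions in one left-to-right pass
        skip = 0
        for site, letter in seq:
            if skip > 0:
                skip -= 1
                continue
            if rng.random() < cfg.indel_prob / 2.0:
                skip = rng.geometric(1.0 / cfg.mean_indel_length) - 1
                continue
            if rng.random() < cfg.sub_prob:
                letter = _DNA[(rng.integers(1, 4) + _DNA.index(letter)) % 4]
            out.append((site, letter))
        # insertions between residues (and at the front)
        result: list[tuple[int, str]] = []
        prev_site: int | None = None
        for idx in range(len(out) + 1):
            if rng.random() < cfg.indel_prob / 2.0:
                n_ins = int(rng.geometric(1.0 / cfg.mean_indel_length))
                for sid in insert_after(prev_site, n_ins):
                    result.append((sid, _DNA[rng.integers(4)]))
                    prev_site = sid
            if idx < len(out):
                result.append(out[idx])
                prev_site = out[idx][0]
        return result

    def walk(node, seq: list[tuple[int, str]]) -> None:
        if isinstance(node, str):
            leaf_seqs[node] = seq
            return
        for child in node:
            walk(child, evolve(seq))

    walk(topo, root_seq)

    present = set()
    for seq in leaf_seqs.values():
        present.update(site for site, _ in seq)
    columns = [site for site in order if site in present]
    col_of = {site: j for j, site in enumerate(columns)}
    rows = {}
    for label in labels:
        cells = ["-"] * len(columns)
        for site, letter in leaf_seqs[label]:
            cells[col_of[site]] = letter
        rows[label] = "".join(cells)
    tree = dendropy.Tree.get(data=_to_newick(topo) + ";", schema="newick",
                             preserve_underscores=True)
    return Alignment(rows), tree


def make_fragments(seqs: TSequence[Sequence], cfg: FragmentConfig
                   ) -> list[Sequence]:
    """Trim a seeded subset of sequences to substrings (prefix and suffix
    deleted).

    Target lengths are drawn from Normal(mean, sd), rounded and clamped to
    [1, source length]; the start offset is uniform over valid positions.
    Unselected sequences are returned unchanged; order is preserved.
    """
    if any("-" in s.letters for s in seqs):
        raise InputError("fragmentation expects ungapped sequences")
    if cfg.mean_length is not None:
        mean = float(cfg.mean_length)
    else:
        frac = cfg.mean_fraction if cfg.mean_fraction is not None else 0.25
        mean = frac * statistics.median(len(s) for s in seqs)
    if mean <= 0:
        raise InputError("target mean length must be positive")
    if cfg.sd < 0:
        raise InputError("sd must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    n_frag = int(round(cfg.fraction * len(seqs)))
    chosen = set(rng.choice(len(seqs), size=n_frag, replace=False).tolist())
    out: list[Sequence] = []
    for idx, s in enumerate(seqs):
        if idx not in chosen:
            out.append(s)
            continue
        target = int(round(rng.normal(mean, cfg.sd)))
        target = max(1, min(len(s.letters), target))
        start = int(rng.integers(0, len(s.letters) - target + 1))
        out.append(Sequence(s.id, s.letters[start:start + target]))
    return out
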