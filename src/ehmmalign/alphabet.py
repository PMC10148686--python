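"""Alphabet handling for the numeric core.

The emission machinery works over a small canonical alphabet: DNA ``ACGT``
(RNA ``U`` is mapped to ``T`` internally and sequences are never mutated, so
the original letters reappear on output) or the 20 amino acids.  Ambiguity
codes (``N``, ``R``, ``X``, ...) are parsed but contribute no emission counts;
during scoring they emit with the background probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAP_CHARS = frozenset("-.")

_DNA_CANONICAL = "ACGT"
_DNA_AMBIGUOUS = set("NRYSWKMBDHV")
_PROTEIN_CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_AMBIGUOUS = set("XBZJUO")


@dataclass(frozen=True)
class Alphabet:
    """A canonical residue alphabet plus its tolerated ambiguity codes."""

    name: str
    letters: tuple[str, ...]
    ambiguous: frozenset[str]
    # input letter -> canonical letter (identity for canonical letters,
    # U->T for nucleotides); ambiguity codes are absent and map to None.
    _canon: dict[str, str] = field(repr=False, default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.letters)

    def canonical(self, ch: str) -> str | None:
        """Canonical letter for ``ch``, or None for an ambiguity code.

        Raises KeyError for characters outside the alphabet entirely.
        """
        c = self._canon.get(ch.upper())
        if c is None and ch.upper() not in self.ambiguous:
            raise KeyError(f"letter {ch!r} not in {self.name} alphabet")
        return c

    def is_valid(self, ch: str) -> bool:
        up = ch.upper()
        return up in self._canon or up in self.ambiguous


def _make(name: str, canonical: str, ambiguous: set[str],
          extra_map: dict[str, str] | None = None) -> Alphabet:
    canon = {c: c for c in canonical}
    if extra_map:
        canon.update(extra_map)
    return Alphabet(name, tuple(canonical), frozenset(ambiguous), canon)


DNA = _make("dna", _DNA_CANONICAL, _DNA_AMBIGUOUS, {"U": "T"})
PROTEIN = _make("protein", _PROTEIN_CANONICAL, _PROTEIN_AMBIGUOUS)


def detect_alphabet(strings) -> Alphabet:
    """Guess DNA vs protein from residue content.

    A sequence set is called nucleotide when >= 90% of its non-gap letters
    are in ``ACGTUN`` — the heuristic most alignment tools apply.
    """
    total = 0
    nuc = 0
    for s in strings:
        for ch in s:
            if ch in GAP_CHARS:
                continue
            total += 1
            if ch.upper() in "ACGTUN":
                nuc += 1
    if total == 0 or nuc / total >= 0.9:
        return DNA
    return PROTEIN
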