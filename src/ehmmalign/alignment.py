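"""Alignment data model, FASTA I/O and transitivity-based assembly.

Conventions
-----------
* ``-`` is the gap character; ``.`` is accepted on read and normalised.
* Uppercase letters carry homology information (they sit in backbone
  columns); lowercase letters were emitted by insertion states and are never
  homologous to anything.  Backbone rows keep whatever case they came with
  and are trusted as all-match content.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence as TSequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP_CHARS
from .errors import AlignmentShapeError, InputError

GAP = "-"


@dataclass
class Sequence:
    """A named, unaligned sequence (case preserved)."""

    id: str
    letters: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.letters)


class Alignment:
    """A rectangular set of gapped rows keyed by sequence id.

    Rows preserve input order and case.  All rows must share one length.
    """

    def __init__(self, rows: dict[str, str] | Iterable[tuple[str, str]]):
        self.rows: dict[str, str] = dict(rows)
        if not self.rows:
            raise InputError("alignment needs at least one row")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"rows have differing lengths: {sorted(lengths)}")
        self._length = lengths.pop()

    @property
    def length(self) -> int:
        """Number of columns."""
        return self._length

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self.rows == other.rows

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows.values()]

    def ungapped(self, seq_id: str) -> str:
        """Row with gaps removed (case preserved)."""
        return "".join(c for c in self.rows[seq_id] if c not in GAP_CHARS)

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [j for j in range(self._length)
                if any(c not in GAP_CHARS for c in self.column(j))]
        return Alignment({i: "".join(r[j] for j in keep)
                          for i, r in self.rows.items()})


@dataclass
class SubAlignment:
    """Rows of a parent alignment restricted to an id subset.

    ``backbone_columns[j]`` is the parent-alignment column index of local
    column ``j``.  Induction keeps every parent column (all-gap columns
    included — match-column calling removes them later), so the map starts
    as the identity.
    """

    rows: dict[str, str]
    backbone_columns: list[int]

    def __post_init__(self) -> None:
        ncol = len(next(iter(self.rows.values())))
        if len(self.backbone_columns) != ncol:
            raise InputError("column map length does not match column count")
        if any(b >= a for a, b in zip(self.backbone_columns[1:],
                                      self.backbone_columns[:-1])):
            raise InputError("backbone_columns must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.backbone_columns)

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows.values()]


Placement = tuple[Literal["match", "insert"], int]
BEFORE_FIRST = -1


@dataclass
class ExtendedRow:
    """One query's placement against the backbone coordinate system.

    ``placements`` holds one entry per query letter, in letter order:
    ``("match", column)`` puts the letter in that backbone column;
    ``("insert", anchor)`` emits it after backbone column ``anchor``
    (``BEFORE_FIRST`` = before the first column).
    """

    query_id: str
    letters: str
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.placements) != len(self.letters):
            raise InputError(
                f"query {self.query_id}: {len(self.letters)} letters but "
                f"{len(self.placements)} placements")
        cols = [c for kind, c in self.placements if kind == "match"]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise InputError(
                f"query {self.query_id}: match columns must strictly increase")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, as_alignment: bool = False):
    """Read FASTA records, preserving case; ``.`` is normalised to ``-``.

    Returns an :class:`Alignment` when ``as_alignment`` is set (all records
    must then share one length), else a list of :class:`Sequence`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq).replace(".", GAP)))
    if as_alignment:
        return Alignment(pairs)
    return [Sequence(i, s) for i, s in pairs]


def write_fasta(obj, path) -> None:
    """Write an Alignment or Sequence list as FASTA (case preserved).

    Insertion letters are already lowercase in rows produced by
    :func:`merge_extended`, so a plain case-preserving write implements the
    lowercase-insertion output convention.
    """
    if isinstance(obj, Alignment):
        items = obj.rows.items()
    else:
        items = ((s.id, s.letters) for s in obj)
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    try:
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def fasta_string(aln: Alignment) -> str:
    buf = io.StringIO()
    SeqIO.write([SeqRecord(Seq(s), id=i, description="")
                 for i, s in aln.rows.items()], buf, "fasta-2line")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Sub-alignment induction and transitivity merge


def induce_subalignment(aln: Alignment, ids: Iterable[str]) -> SubAlignment:
    """Restrict ``aln`` to ``ids``, keeping all columns.

    All-gap columns are intentionally retained; they are excluded later by
    match-column calling, which is what gives subset HMMs their
    column-skipping structure.
    """
    ids = list(ids)
    if not ids:
        raise InputError("cannot induce a sub-alignment on an empty id set")
    unknown = [i for i in ids if i not in aln.rows]
    if unknown:
        raise InputError(f"ids not in alignment: {unknown}")
    return SubAlignment({i: aln.rows[i] for i in ids},
                        list(range(aln.length)))


def merge_extended(backbone: Alignment,
                   rows: TSequence[ExtendedRow]) -> Alignment:
    """Assemble the final MSA from the backbone and per-query placements.

    Backbone columns are preserved in order.  Each query letter placed by a
    match state goes (uppercase) into its backbone column; each insertion
    segment opens fresh columns directly after its anchor, lowercase, and
    private to that query — insertion letters are never placed in a shared
    column, so they participate in no homologies.  Blocks from different
    queries at the same anchor are laid out in query input order.
    """
    L = backbone.length
    for er in rows:
        if er.query_id in backbone.rows:
            raise InputError(
                f"query id {er.query_id!r} duplicates a backbone id")
        for kind, c in er.placements:
            if kind == "match" and not 0 <= c < L:
                raise InputError(
                    f"query {er.query_id}: match column {c} outside backbone")
    ids = [er.query_id for er in rows]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate query ids in extended rows")

    # insertion block widths: anchor -> per-query letter count
    ins_count: dict[int, dict[str, int]] = {}
    for er in rows:
        for kind, a in er.placements:
            if kind == "insert":
                ins_count.setdefault(a, {}).setdefault(er.query_id, 0)
                ins_count[a][er.query_id] += 1

    # global column layout: [ins blocks @ -1] col0 [ins blocks @0] col1 ...
    # ins_offset[(anchor, qid)] = start column of that query's block
    ins_offset: dict[tuple[int, str], int] = {}
    bb_col_at: list[int] = [0] * L  # output position of each backbone column
    pos = 0
    for anchor in range(BEFORE_FIRST, L):
        if anchor >= 0:
            bb_col_at[anchor] = pos
            pos += 1
        blocks = ins_count.get(anchor)
        if blocks:
            for er in rows:  # query input order
                n = blocks.get(er.query_id)
                if n:
                    ins_offset[(anchor, er.query_id)] = pos
                    pos += n
    total = pos

    out: dict[str, str] = {}
    for bid, row in backbone.rows.items():
        cells = [GAP] * total
        for c in range(L):
            cells[bb_col_at[c]] = row[c]
        out[bid] = "".join(cells)
    for er in rows:
        cells = [GAP] * total
        seen_at_anchor: dict[int, int] = {}
        for letter, (kind, c) in zip(er.letters, er.placements):
            if kind == "match":
                cells[bb_col_at[c]] = letter.upper()
            else:
                k = seen_at_anchor.get(c, 0)
                cells[ins_offset[(c, er.query_id)] + k] = letter.lower()
                seen_at_anchor[c] = k + 1
        out[er.query_id] = "".join(cells)
    return Alignment(out)
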