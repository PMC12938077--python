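"""Dot-bracket parsing, stem detection, and junction decomposition.

An RNA secondary structure in dot-bracket notation is decomposed into its
helical *stems* (maximal runs of consecutively stacked base pairs) and the
*n-way junctions* they border: loops closed on all sides by two or more
stems.  Each junction is further decomposed into *pseudo two-way junctions*
-- cyclically adjacent stem pairs together with the unpaired nucleotides
that connect them -- the unit sample on which stacking propensity is
scored.

Coordinates are 0-based internally; user-facing serializations emit
1-based inclusive ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

__all__ = [
    "DbnRecord",
    "Stem",
    "Junction",
    "PseudoTwoWayJunction",
    "StructureError",
    "parse_dbn",
    "read_dbn_file",
    "to_dbn",
    "find_stems",
    "extract_junctions",
    "decompose_junction",
    "junction_to_dict",
]

_SEQ_ALPHABET = frozenset("ACGU")
_PSEUDOKNOT_CHARS = frozenset("[]{}<>") | frozenset("abcdefghijklmnopqrstuvwxyz") \
    | frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


class StructureError(ValueError):
    """Raised for malformed sequence/structure input."""


@dataclass(frozen=True)
class DbnRecord:
    """One sequence + dot-bracket record (Vienna ``.dbn`` style)."""

    id: str
    sequence: str
    structure: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise StructureError(
                f"{self.id or '<record>'}: sequence length {len(self.sequence)} "
                f"!= structure length {len(self.structure)}"
            )
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise StructureError(f"illegal sequence characters: {sorted(bad)}")
        knots = set(self.structure) & _PSEUDOKNOT_CHARS
        if knots:
            raise StructureError(
                f"pseudoknot/extra bracket types not supported: {sorted(knots)}; "
                "only nested '(', ')', '.' structures are accepted"
            )
        bad = set(self.structure) - set(".()")
        if bad:
            raise StructureError(f"illegal structure characters: {sorted(bad)}")
        _pair_table(self.structure)  # balanced-bracket check

    @property
    def pair_table(self) -> list[int]:
        """Partner index per position (-1 when unpaired)."""
        return _pair_table(self.structure)


def _pair_table(structure: str) -> list[int]:
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[0] + 1}")
    return partner


def _normalize_sequence(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def parse_dbn(record_text: str, default_id: str = "") -> DbnRecord:
    """Parse a single dot-bracket record.

    Accepts an optional ``>id`` header line followed by one sequence line and
    one structure line.
    """
    lines = [ln.strip() for ln in record_text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty record")
    rec_id = default_id
    if lines[0].startswith(">"):
        rec_id = lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) != 2:
        raise StructureError(
            f"expected sequence and structure lines, got {len(lines)} line(s)"
        )
    return DbnRecord(id=rec_id, sequence=_normalize_sequence(lines[0]), structure=lines[1])


def read_dbn_file(path) -> list[DbnRecord]:
    """Read a multi-record ``.dbn`` file (``>id`` / sequence / structure)."""
    records: list[DbnRecord] = []
    chunk: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">") and chunk:
                records.append(parse_dbn("\n".join(chunk), default_id=f"record{len(records)}"))
                chunk = []
            chunk.append(line)
    if chunk:
        records.append(parse_dbn("\n".join(chunk), default_id=f"record{len(records)}"))
    return records


def to_dbn(record: DbnRecord) -> str:
    """Serialize a record back to ``.dbn`` text (round-trips ``parse_dbn``)."""
    header = f">{record.id}\n" if record.id else ""
    return f"{header}{record.sequence}\n{record.structure}\n"


@dataclass(frozen=True)
class Stem:
    """A maximal run of consecutively stacked base pairs.

    ``pairs`` are (i, j) with i < j, ordered outermost-first so that
    pair k+1 is (i_k + 1, j_k - 1).  ``bases`` holds the corresponding
    (5'-strand base, 3'-strand base) tuples.
    """

    pairs: tuple[tuple[int, int], ...]
    bases: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise StructureError("stem with no base pairs")
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if (i1, j1) != (i0 + 1, j0 - 1):
                raise StructureError("stem pairs are not a stacked run")

    @property
    def length_bp(self) -> int:
        return len(self.pairs)

    @property
    def five_prime_range(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def three_prime_range(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1])

    @property
    def outer_pair(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner_pair(self) -> tuple[int, int]:
        return self.pairs[-1]

    def reversed(self) -> "Stem":
        """The same duplex with strand roles swapped (H1<->H2 relabeling)."""
        pairs = tuple((i, j) for i, j in self.pairs)  # indices meaningless after swap
        bases = tuple((b3, b5) for b5, b3 in reversed(self.bases))
        return replace(self, pairs=pairs, bases=bases)


def find_stems(record: DbnRecord) -> list[Stem]:
    """All maximal stacked-pair runs, ordered by 5'-most residue."""
    partner = record.pair_table
    seq = record.sequence
    stems: list[Stem] = []
    n = len(seq)
    for i in range(n):
        j = partner[i]
        if j <= i:
            continue
        # start of a run unless (i-1, j+1) is also a pair
        if i > 0 and j + 1 < n and partner[i - 1] == j + 1:
            continue
        pairs = [(i, j)]
        while True:
            i2, j2 = pairs[-1][0] + 1, pairs[-1][1] - 1
            if i2 < j2 and partner[i2] == j2:
                pairs.append((i2, j2))
            else:
                break
        bases = tuple((seq[a], seq[b]) for a, b in pairs)
        stems.append(Stem(pairs=tuple(pairs), bases=bases))
    return stems


@dataclass(frozen=True)
class Junction:
    """An n-way junction: a loop closed by ``order_n`` >= 2 stems.

    Stems are in cyclic 5'->3' order around the loop, the closing (outer)
    stem first.  ``loop_segments[k]`` is the unpaired nucleotide string
    between stem k and stem k+1 (cyclic).  ``entries[k]``/``exits[k]`` are
    the junction-proximal paired residue indices where the loop traversal
    enters/leaves stem k.
    """

    source_id: str
    sequence: str
    stems: tuple[Stem, ...]
    loop_segments: tuple[str, ...]
    entries: tuple[int, ...]
    exits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stems) < 2:
            raise StructureError("junction needs at least two stems")
        if len(self.loop_segments) != len(self.stems):
            raise StructureError("loop segment count must equal stem count")

    @property
    def order_n(self) -> int:
        return len(self.stems)


def extract_junctions(record: DbnRecord) -> list[Junction]:
    """All n-way junctions (n >= 2) of a record.

    A junction is a loop bounded on every side by a stem: the closing stem's
    innermost pair plus the outermost pairs of the stems directly nested
    within it.  Hairpin loops (no inner stem) and the exterior loop (no
    closing stem) are not junctions.
    """
    stems = find_stems(record)
    partner = record.pair_table
    seq = record.sequence
    by_outer_start = {s.outer_pair[0]: s for s in stems}
    junctions: list[Junction] = []
    for closing in stems:
        i, j = closing.inner_pair
        children: list[Stem] = []
        segments: list[str] = []
        cur: list[str] = []
        k = i + 1
        while k < j:
            p = partner[k]
            if p == -1:
                cur.append(seq[k])
                k += 1
            else:
                children.append(by_outer_start[k])
                segments.append("".join(cur))
                cur = []
                k = p + 1
        segments.append("".join(cur))
        if not children:
            continue  # hairpin loop
        juncs_stems = (closing, *children)
        entries = (j, *(c.outer_pair[0] for c in children))
        exits = (i, *(c.outer_pair[1] for c in children))
        junctions.append(
            Junction(
                source_id=record.id,
                sequence=seq,
                stems=juncs_stems,
                loop_segments=tuple(segments),
                entries=entries,
                exits=exits,
            )
        )
    return junctions


@dataclass(frozen=True)
class PseudoTwoWayJunction:
    """An adjacent stem pair within a junction: the classifier's sample unit.

    ``loop0_seq`` is the unpaired segment directly connecting H1 to H2 along
    the junction loop; ``loop1_seq``/``loop2_seq`` are the segments flanking
    H1's far side and H2's far side (for a true two-way junction both equal
    the 3'-side loop).  ``interface_top``/``interface_bottom`` give the
    nearest-neighbor step formed by the two junction-proximal closing pairs,
    read 5'->3' on the continuous strand (top) and 3'->5' aligned (bottom).
    """

    pair_id: str
    h1: Stem
    h2: Stem
    loop0_seq: str
    loop1_seq: str
    loop2_seq: str
    intervening_stem_count: int
    parent_order: int
    interface_top: str
    interface_bottom: str
    stem_indices: tuple[int, int] = (0, 1)
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.intervening_stem_count != self.parent_order - 2:
            raise ValueError("intervening_stem_count must equal parent_order - 2")


def decompose_junction(junction: Junction) -> list[PseudoTwoWayJunction]:
    """Decompose a junction into its cyclically adjacent pseudo two-way pairs.

    An order-n junction (n >= 3) yields exactly n pairs (H1-H2, H2-H3, ...,
    Hn-H1); a two-way junction yields the single pair H1-H2 with
    ``loop1_seq == loop2_seq`` (its 3'-side loop).
    """
    n = junction.order_n
    seq = junction.sequence
    segs = junction.loop_segments
    pairs: list[PseudoTwoWayJunction] = []
    indices = [(0, 1)] if n == 2 else [(i, (i + 1) % n) for i in range(n)]
    for a, b in indices:
        loop0 = segs[a]
        loop1 = segs[(a - 1) % n]
        loop2 = segs[b]
        a_exit, b_entry = junction.exits[a], junction.entries[b]
        a_entry, b_exit = junction.entries[a], junction.exits[b]
        pairs.append(
            PseudoTwoWayJunction(
                pair_id=f"{junction.source_id}:H{a + 1}-H{b + 1}",
                h1=junction.stems[a],
                h2=junction.stems[b],
                loop0_seq=loop0,
                loop1_seq=loop1,
                loop2_seq=loop2,
                intervening_stem_count=n - 2,
                parent_order=n,
                interface_top=seq[a_exit] + seq[b_entry],
                interface_bottom=seq[a_entry] + seq[b_exit],
                stem_indices=(a, b),
            )
        )
    return pairs


def junction_to_dict(junction: Junction) -> dict:
    """JSON-serializable junction description (1-based inclusive ranges)."""
    return {
        "id": junction.source_id,
        "order": junction.order_n,
        "stems": [
            {
                "length_bp": s.length_bp,
                "five_prime_range": [s.five_prime_range[0] + 1, s.five_prime_range[1] + 1],
                "three_prime_range": [s.three_prime_range[0] + 1, s.three_prime_range[1] + 1],
            }
            for s in junction.stems
        ],
        "loop_segments": list(junction.loop_segments),
    }
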