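"""SuperGenome coordinate system over an XMFA whole-genome alignment.

A multiple genome alignment (progressiveMauve XMFA dialect) is a sequence of
alignment blocks; concatenating the blocks' columns in file order yields a
single shared axis, the *SuperGenome*.  Every aligned base of every genome maps
to exactly one column of that axis, and every column maps back to at most one
position per genome, giving a bidirectional lift-over between each genome's
own coordinates and the shared coordinate system.

Conventions
-----------
* All coordinates are 1-based and inclusive, as in Mauve XMFA.
* A super position returned by :func:`to_super` is *signed*: negative means
  the genome is reverse-complemented at that column (its block entry is on
  the ``-`` strand).
* Genome positions not covered by any block map to :data:`UNALIGNED`;
  columns where a genome has a gap (or is absent from the block) map back to
  :data:`GAP`.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UNALIGNED",
    "GAP",
    "BlockEntry",
    "AlignmentBlock",
    "SuperGenome",
    "XmfaParseError",
    "BlockConsistencyError",
    "SuperGenomeError",
    "parse_xmfa",
    "build_supergenome",
    "to_super",
    "to_genome",
]


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._name


#: A genome position not covered by any alignment block.
UNALIGNED = _Sentinel("UNALIGNED")
#: A super column at which the genome has a gap or no block entry.
GAP = _Sentinel("GAP")


class XmfaParseError(ValueError):
    """Malformed XMFA input; message names the offending line."""


class BlockConsistencyError(ValueError):
    """An alignment block violates its structural invariants."""


class SuperGenomeError(ValueError):
    """Blocks are mutually inconsistent (overlapping genome intervals)."""


_HEADER_RE = re.compile(r"^>\s*([^\s:]+):(\d+)-(\d+)\s+([+-])(?:\s+(.*))?$")


@dataclass(frozen=True)
class BlockEntry:
    """One genome's row in an alignment block."""

    genome_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    strand: str  # '+' or '-'
    gapped_sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def _n_non_gap(self) -> int:
        return len(self.gapped_sequence) - self.gapped_sequence.count("-")


@dataclass(frozen=True)
class AlignmentBlock:
    """A block of mutually aligned genome segments (equal gapped length)."""

    block_index: int
    entries: tuple[BlockEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise BlockConsistencyError(
                f"block {self.block_index}: no non-absent entries"
            )
        widths = {len(e.gapped_sequence) for e in self.entries}
        if len(widths) != 1:
            raise BlockConsistencyError(
                f"block {self.block_index}: unequal gapped sequence lengths {sorted(widths)}"
            )
        if next(iter(widths)) < 1:
            raise BlockConsistencyError(f"block {self.block_index}: empty block")
        seen: set[str] = set()
        for e in self.entries:
            if e.genome_id in seen:
                raise BlockConsistencyError(
                    f"block {self.block_index}: genome {e.genome_id!r} appears twice"
                )
            seen.add(e.genome_id)
            if e.strand not in "+-":
                raise BlockConsistencyError(
                    f"block {self.block_index}: bad strand {e.strand!r}"
                )
            if e._n_non_gap() != e.length:
                raise BlockConsistencyError(
                    f"block {self.block_index}, genome {e.genome_id!r}: "
                    f"{e._n_non_gap()} non-gap characters but interval length {e.length}"
                )

    @property
    def width(self) -> int:
        return len(self.entries[0].gapped_sequence)

    def entry_for(self, genome_id: str) -> BlockEntry | None:
        for e in self.entries:
            if e.genome_id == genome_id:
                return e
        return None


def parse_xmfa(path) -> list[AlignmentBlock]:
    """Parse a progressiveMauve-style XMFA file into alignment blocks.

    Entry headers follow ``> seqId:start-end strand [comment]``; blocks are
    separated by lines starting with ``=``.  An entry with coordinates
    ``0-0`` (Mauve's convention for a genome absent from the block) is
    dropped from the block.  Genome ids are taken in order of first
    appearance.
    """
    blocks: list[AlignmentBlock] = []
    cur: list[tuple[str, int, int, str]] = []  # headers of current block
    seqs: list[list[str]] = []
    n_absent = 0

    def flush() -> None:
        nonlocal cur, seqs, n_absent
        entries = tuple(
            BlockEntry(g, s, e, st, "".join(chunks))
            for (g, s, e, st), chunks in zip(cur, seqs)
            if not (s == 0 and e == 0)  # Mauve 0-0 = genome absent from block
        )
        if entries:
            blocks.append(AlignmentBlock(len(blocks), entries))
        elif n_absent:
            raise BlockConsistencyError(
                f"block {len(blocks)}: all entries absent (0-0)"
            )
        cur, seqs, n_absent = [], [], 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("="):
                flush()
                continue
            if line.startswith(">"):
                m = _HEADER_RE.match(line)
                if m is None:
                    raise XmfaParseError(f"line {lineno}: malformed XMFA header {line!r}")
                gid, s, e, strand = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
                if s == 0 and e == 0:
                    cur.append((gid, 0, 0, strand))  # marked absent, dropped at flush
                    seqs.append([])
                    n_absent += 1
                    continue
                if s < 1 or e < s:
                    raise XmfaParseError(
                        f"line {lineno}: bad coordinates {s}-{e} (1-based inclusive expected)"
                    )
                cur.append((gid, s, e, strand))
                seqs.append([])
            else:
                if not cur:
                    raise XmfaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                seqs[-1].append(line.strip())
    if cur:
        flush()
    return blocks


@dataclass(frozen=True)
class _Segment:
    """Per-genome view of one block: genome interval -> absolute columns."""

    block_index: int
    gstart: int
    gend: int
    strand: str
    cols: np.ndarray  # cols[p - gstart] = 1-based super column of genome pos p


@dataclass
class SuperGenome:
    """Bidirectional maps between genome coordinates and the shared axis."""

    genome_roster: tuple[str, ...]
    total_length: int
    blocks: tuple[AlignmentBlock, ...]
    block_offsets: tuple[int, ...]  # column offset preceding each block
    genome_lengths: dict[str, int] | None = None
    _segments: dict[str, list[_Segment]] = field(default_factory=dict, repr=False)
    _seg_starts: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _backward: list[dict[str, np.ndarray]] = field(default_factory=list, repr=False)

    def segments(self, genome_id: str) -> Sequence[_Segment]:
        self._check_genome(genome_id)
        return tuple(self._segments[genome_id])

    def _check_genome(self, genome_id: str) -> None:
        if genome_id not in self._segments:
            raise KeyError(f"genome {genome_id!r} not in roster {self.genome_roster}")

    def to_super(self, genome_id: str, position: int):
        """Signed super position of a genome position, or UNALIGNED."""
        self._check_genome(genome_id)
        if position < 1:
            raise IndexError(f"position {position} out of range (1-based)")
        gl = (self.genome_lengths or {}).get(genome_id)
        if gl is not None and position > gl:
            raise IndexError(
                f"position {position} beyond genome {genome_id!r} length {gl}"
            )
        starts = self._seg_starts[genome_id]
        i = bisect_right(starts, position) - 1
        if i < 0:
            return UNALIGNED
        seg = self._segments[genome_id][i]
        if position > seg.gend:
            return UNALIGNED
        col = int(seg.cols[position - seg.gstart])
        return -col if seg.strand == "-" else col

    def to_genome(self, genome_id: str, super_position: int):
        """Genome position at a super column, or GAP."""
        self._check_genome(genome_id)
        if not 1 <= super_position <= self.total_length:
            raise IndexError(
                f"super position {super_position} outside [1, {self.total_length}]"
            )
        bi = bisect_right(self.block_offsets, super_position - 1) - 1
        arr = self._backward[bi].get(genome_id)
        if arr is None:
            return GAP
        v = int(arr[super_position - self.block_offsets[bi] - 1])
        return GAP if v == 0 else v


def build_supergenome(
    blocks: Iterable[AlignmentBlock],
    genome_lengths: dict[str, int] | None = None,
) -> SuperGenome:
    """Number alignment columns 1..total across blocks in file order and
    build the per-genome bidirectional maps.

    Raises :class:`SuperGenomeError` when two blocks claim overlapping
    intervals of the same genome.
    """
    blocks = tuple(blocks)
    if not blocks:
        raise SuperGenomeError("no alignment blocks")
    roster: list[str] = []
    offsets: list[int] = []
    segments: dict[str, list[_Segment]] = {}
    backward: list[dict[str, np.ndarray]] = []
    off = 0
    for b in blocks:
        offsets.append(off)
        width = b.width
        bmap: dict[str, np.ndarray] = {}
        for e in b.entries:
            if e.genome_id not in segments:
                segments[e.genome_id] = []
                roster.append(e.genome_id)
            cols = np.zeros(e.length, dtype=np.int64)
            back = np.zeros(width, dtype=np.int64)
            if e.strand == "+":
                p = e.start
                step = 1
            else:
                p = e.end
                step = -1
            for ci, ch in enumerate(e.gapped_sequence):
                if ch != "-":
                    cols[p - e.start] = off + ci + 1
                    back[ci] = p
                    p += step
            segments[e.genome_id].append(
                _Segment(b.block_index, e.start, e.end, e.strand, cols)
            )
            bmap[e.genome_id] = back
        backward.append(bmap)
        off += width

    for gid, segs in segments.items():
        segs.sort(key=lambda s: s.gstart)
        for a, bseg in zip(segs, segs[1:]):
            if bseg.gstart <= a.gend:
                raise SuperGenomeError(
                    f"genome {gid!r}: blocks cover overlapping intervals "
                    f"[{a.gstart},{a.gend}] and [{bseg.gstart},{bseg.gend}]"
                )
        if genome_lengths is not None and gid in genome_lengths:
            if segs and segs[-1].gend > genome_lengths[gid]:
                raise SuperGenomeError(
                    f"genome {gid!r}: block interval exceeds genome length"
                )

    sg = SuperGenome(
        genome_roster=tuple(roster),
        total_length=off,
        blocks=blocks,
        block_offsets=tuple(offsets),
        genome_lengths=dict(genome_lengths) if genome_lengths else None,
    )
    sg._segments.update(segments)
    sg._seg_starts.update({g: [s.gstart for s in segs] for g, segs in segments.items()})
    sg._backward.extend(backward)
    return sg


def to_super(sg: SuperGenome, genome_id: str, position: int):
    return sg.to_super(genome_id, position)


def to_genome(sg: SuperGenome, genome_id: str, super_position: int):
    return sg.to_genome(genome_id, super_position)
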