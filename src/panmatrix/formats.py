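"""Readers and writers for the tabular formats the tool touches.

* GFF3 gene annotations (one file per genome),
* two tab-delimited pan-genome map dialects:

  - ``pangee``: ``pan_id``, ``super_start``, ``super_stop``,
    ``consensus_description``, then per genome a triplet of columns
    ``<genome>:gene_id``, ``<genome>:strand``, ``<genome>:description``
    (empty triplet = gene absent),
  - ``generic``: ``pan_id`` followed by one column per genome; cells are
    empty (absent) or hold ``gene_id`` / ``gene_id:-`` tokens (strand
    suffix optional, ``+`` by default),

* TIGRFAM assignment tables (``gene_id<TAB>tigrfam_id<TAB>description``).

All writers emit UTF-8, tab-separated, newline-terminated rows, no quoting.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.iterators import DataIterator

from .matrix import Member, PanGene, PanGenomeMatrix

__all__ = [
    "GeneAnnotation",
    "TigrfamAssignment",
    "FormatError",
    "PanGeneDefinitionError",
    "read_gff",
    "read_panmap",
    "write_panmap",
    "read_tigrfam",
    "write_tigrfam",
]

logger = logging.getLogger(__name__)

DIALECTS = ("pangee", "generic")


class FormatError(ValueError):
    pass


class PanGeneDefinitionError(FormatError):
    """A pan-map row holds two or more genes from the same genome."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene on one genome, 1-based inclusive coordinates."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end}]"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TigrfamAssignment:
    gene_id: str
    tigrfam_id: str
    description: str = ""


_DESC_ATTRS = ("product", "description", "Name", "gene")


def read_gff(
    path,
    genome_id: str | None = None,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneAnnotation]:
    """Read gene (or CDS) records from a GFF3 file.

    ``genome_id`` defaults to the file stem.  Records without an ``ID``
    attribute or without a definite strand are skipped with a warning —
    strand is required for glyph orientation.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in DataIterator(str(path)):
        if feat.featuretype not in feature_types:
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            logger.warning("%s: %s record without ID attribute skipped", path, feat.featuretype)
            continue
        if feat.strand not in "+-":
            logger.warning("%s: record %s has no strand, skipped", path, ids[0])
            continue
        if ids[0] in seen:
            logger.warning("%s: duplicate gene id %s skipped", path, ids[0])
            continue
        seen.add(ids[0])
        desc = ""
        for a in _DESC_ATTRS:
            vals = feat.attributes.get(a)
            if vals:
                desc = vals[0]
                break
        out.append(GeneAnnotation(gid, ids[0], feat.start, feat.end, feat.strand, desc))
    return out


# -- pan-map dialects --------------------------------------------------------

_TOKEN_SPLIT = re.compile(r"[,;\s]+")


def _parse_generic_cell(cell: str, pan_id: str, genome: str) -> Member | None:
    cell = cell.strip()
    if not cell:
        return None
    tokens = [t for t in _TOKEN_SPLIT.split(cell) if t]
    if len(tokens) > 1:
        raise PanGeneDefinitionError(
            f"pan gene {pan_id!r}: cell for genome {genome!r} holds "
            f"{len(tokens)} gene tokens; a pan gene cannot contain two or "
            f"more genes from the same genome"
        )
    token = tokens[0]
    if token.endswith(":-"):
        return Member(token[:-2], "-")
    if token.endswith(":+"):
        return Member(token[:-2], "+")
    return Member(token, "+")


def read_panmap(path, dialect: str = "pangee") -> PanGenomeMatrix:
    """Load a pan-genome map file; genome roster comes from the header."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file, header row required")
    header = rows[0]
    if dialect == "generic":
        roster = header[1:]
        genes: list[PanGene] = []
        seen: set[str] = set()
        for r in rows[1:]:
            if not any(c.strip() for c in r):
                continue
            pan_id = r[0].strip()
            if pan_id in seen:
                raise FormatError(f"{path}: duplicate pan gene identifier {pan_id!r}")
            seen.add(pan_id)
            members = {}
            for g, cell in zip(roster, r[1:]):
                m = _parse_generic_cell(cell, pan_id, g)
                if m is not None:
                    members[g] = m
            genes.append(PanGene(pan_id=pan_id, members=members))
        return PanGenomeMatrix(roster, genes, dialect="generic")

    # pangee dialect
    fixed = ["pan_id", "super_start", "super_stop", "consensus_description"]
    if header[: len(fixed)] != fixed or (len(header) - len(fixed)) % 3 != 0:
        raise FormatError(f"{path}: malformed pangee header")
    roster = [header[len(fixed) + 3 * i].split(":", 1)[0]
              for i in range((len(header) - len(fixed)) // 3)]
    genes = []
    seen = set()
    for r in rows[1:]:
        if not any(c.strip() for c in r):
            continue
        pan_id = r[0].strip()
        if pan_id in seen:
            raise FormatError(f"{path}: duplicate pan gene identifier {pan_id!r}")
        seen.add(pan_id)
        sstart = int(r[1]) if r[1].strip() else None
        sstop = int(r[2]) if r[2].strip() else None
        members = {}
        for i, g in enumerate(roster):
            gene_id, strand, desc = (r[4 + 3 * i : 7 + 3 * i] + ["", "", ""])[:3]
            if not gene_id.strip():
                continue
            if _TOKEN_SPLIT.search(gene_id.strip()):
                raise PanGeneDefinitionError(
                    f"pan gene {pan_id!r}: multiple gene tokens for genome {g!r}"
                )
            members[g] = Member(gene_id.strip(), strand.strip() or "+", desc)
        genes.append(
            PanGene(
                pan_id=pan_id,
                members=members,
                super_start=sstart,
                super_stop=sstop,
                consensus_description=r[3],
            )
        )
    return PanGenomeMatrix(roster, genes, dialect="pangee")


def write_panmap(matrix: PanGenomeMatrix, path, dialect: str | None = None) -> None:
    """Write the matrix back out; the dialect defaults to the one it was
    loaded from, so modified matrices round-trip through the same format."""
    dialect = dialect or matrix.dialect
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "generic":
            w.writerow(["pan_id", *matrix.genome_roster])
            for pg in matrix:
                cells = []
                for g in matrix.genome_roster:
                    m = pg.members.get(g)
                    if m is None:
                        cells.append("")
                    else:
                        cells.append(m.gene_id if m.strand == "+" else f"{m.gene_id}:-")
                w.writerow([pg.pan_id, *cells])
            return
        header = ["pan_id", "super_start", "super_stop", "consensus_description"]
        for g in matrix.genome_roster:
            header += [f"{g}:gene_id", f"{g}:strand", f"{g}:description"]
        w.writerow(header)
        for pg in matrix:
            row = [
                pg.pan_id,
                "" if pg.super_start is None else pg.super_start,
                "" if pg.super_stop is None else pg.super_stop,
                pg.consensus_description,
            ]
            for g in matrix.genome_roster:
                m = pg.members.get(g)
                row += ["", "", ""] if m is None else [m.gene_id, m.strand, m.description]
            w.writerow(row)


# -- TIGRFAM -----------------------------------------------------------------


def read_tigrfam(path) -> dict[str, TigrfamAssignment]:
    """Read ``gene_id<TAB>tigrfam_id[<TAB>description]`` rows.

    Genes absent from the file simply have no assignment; duplicate gene
    rows keep the first assignment (one family per gene).
    """
    out: dict[str, TigrfamAssignment] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
            gene_id, fam = row[0].strip(), row[1].strip()
            if gene_id in out:
                logger.warning("%s: duplicate TIGRFAM row for %s, keeping first", path, gene_id)
                continue
            out[gene_id] = TigrfamAssignment(gene_id, fam, row[2] if len(row) > 2 else "")
    return out


def write_tigrfam(assignments: Iterable[TigrfamAssignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a in assignments:
            w.writerow([a.gene_id, a.tigrfam_id, a.description])
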