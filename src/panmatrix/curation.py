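"""Automatic detection of aggregation candidates, and matrix search.

Disrupted pan genes — one ortholog group erroneously split in two — show a
characteristic signature: rows in direct or very close neighbourhood on the
SuperGenome axis whose genome compositions are complementary and whose
functional annotation agrees.  ``find_candidates`` scans for that signature;
every emitted pair is guaranteed to pass the aggregation precondition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .matrix import CORE, PanGenomeMatrix, classify

__all__ = ["Candidate", "SearchMatch", "find_candidates", "search", "write_candidates"]

DEFAULT_WINDOW = 2
REQUIRE_MODES = ("tigrfam", "description", "either")
SEARCH_FIELDS = ("pan_id", "gene_id", "description", "tigrfam_id")


@dataclass(frozen=True)
class Candidate:
    """A pair of rows proposed for aggregation."""

    rank_i: int  # 0-based row ranks, rank_i < rank_j
    rank_j: int
    pan_id_i: str
    pan_id_j: str
    reason: str
    flanking_core_count: int  # informational: core rows directly around the pair
    combined_size: int


class SearchMatch(NamedTuple):
    pan_id: str
    genome_id: str | None
    field: str
    text: str


def _annotation_match(a, b, require: str) -> str | None:
    """Return the matching reason, or None if annotations disagree."""
    tig = bool(a.tigrfam_id) and a.tigrfam_id == b.tigrfam_id
    desc = (
        bool(a.consensus_description)
        and a.consensus_description.lower() == b.consensus_description.lower()
    )
    if require == "tigrfam":
        return f"tigrfam:{a.tigrfam_id}" if tig else None
    if require == "description":
        return "description" if desc else None
    if tig:
        return f"tigrfam:{a.tigrfam_id}"
    if desc:
        return "description"
    return None


def find_candidates(
    matrix: PanGenomeMatrix,
    window: int = DEFAULT_WINDOW,
    require: str = "either",
) -> list[Candidate]:
    """Rank pairs of nearby, complementary, annotation-matching rows.

    ``window`` is the maximum row-rank distance counting as "very close
    neighbourhood"; ``require`` selects which annotation must agree
    (equal non-empty TIGRFAM id, case-insensitively equal consensus
    description, or either).  Pairs are ordered by (row distance ascending,
    combined member count descending, rank).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if require not in REQUIRE_MODES:
        raise ValueError(f"require must be one of {REQUIRE_MODES}")
    rows = matrix.pan_genes
    n = len(matrix.genome_roster)
    out: list[Candidate] = []
    for i in range(len(rows)):
        for j in range(i + 1, min(i + window + 1, len(rows))):
            a, b = rows[i], rows[j]
            reason = _annotation_match(a, b, require)
            if reason is None:
                continue
            ok, _ = matrix.can_aggregate([a.pan_id, b.pan_id])
            if not ok:
                continue
            flank = 0
            if i > 0 and classify(rows[i - 1], n) == CORE:
                flank += 1
            if j + 1 < len(rows) and classify(rows[j + 1], n) == CORE:
                flank += 1
            out.append(
                Candidate(i, j, a.pan_id, b.pan_id, reason, flank, a.size + b.size)
            )
    out.sort(key=lambda c: (c.rank_j - c.rank_i, -c.combined_size, c.rank_i))
    return out


def write_candidates(candidates: Sequence[Candidate], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["rank_i", "rank_j", "pan_id_i", "pan_id_j", "reason", "flanking_core_count"]
        )
        for c in candidates:
            w.writerow(
                [c.rank_i, c.rank_j, c.pan_id_i, c.pan_id_j, c.reason, c.flanking_core_count]
            )


def search(
    matrix: PanGenomeMatrix,
    query: str,
    fields: Sequence[str] = SEARCH_FIELDS,
) -> list[SearchMatch]:
    """Case-insensitive substring search over selected fields, in row order."""
    if not query:
        raise ValueError("query must be non-empty")
    bad = set(fields) - set(SEARCH_FIELDS)
    if bad:
        raise ValueError(f"unknown search fields {sorted(bad)}")
    q = query.lower()
    out: list[SearchMatch] = []
    for pg in matrix:
        if "pan_id" in fields and q in pg.pan_id.lower():
            out.append(SearchMatch(pg.pan_id, None, "pan_id", pg.pan_id))
        if "description" in fields and q in pg.consensus_description.lower():
            out.append(
                SearchMatch(pg.pan_id, None, "description", pg.consensus_description)
            )
        if "tigrfam_id" in fields and pg.tigrfam_id and q in pg.tigrfam_id.lower():
            out.append(SearchMatch(pg.pan_id, None, "tigrfam_id", pg.tigrfam_id))
        if "gene_id" in fields:
            for g in matrix.genome_roster:
                m = pg.members.get(g)
                if m is not None and q in m.gene_id.lower():
                    out.append(SearchMatch(pg.pan_id, g, "gene_id", m.gene_id))
    return out
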