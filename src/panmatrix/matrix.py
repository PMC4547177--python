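"""Pan-genome matrix: classification, summary statistics, curation algebra.

The matrix is an ordered list of pan genes (ortholog groups, at most one
member gene per genome) over a fixed genome roster.  Curation operations —
aggregation of complementary groups into an ``AGN`` row, its inverse
deaggregation, and undo — are validated, logged to an append-only history,
and exactly reversible.
"""

from __future__ import annotations

import csv
import datetime as _dt
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, NamedTuple, Sequence

__all__ = [
    "Member",
    "PanGene",
    "SummaryStats",
    "InteractionEvent",
    "PanGenomeMatrix",
    "AggregationError",
    "NotAggregatedError",
    "NothingToUndoError",
    "classify",
    "summary",
    "can_aggregate",
    "aggregate",
    "deaggregate",
    "undo",
    "export_history",
    "read_history",
    "apply_history",
]

CORE = "core"
ORPHAN = "orphan"
DISPENSABLE = "dispensable"


class AggregationError(ValueError):
    """Requested aggregation violates the complementarity precondition."""


class NotAggregatedError(ValueError):
    pass


class NothingToUndoError(ValueError):
    pass


class Member(NamedTuple):
    """One genome's gene in a pan gene."""

    gene_id: str
    strand: str  # '+' or '-' (strand in SuperGenome context / annotation)
    description: str = ""


@dataclass(frozen=True)
class PanGene:
    """An orthologous gene group: at most one member gene per genome."""

    pan_id: str
    members: dict[str, Member]  # genome_id -> Member, treated as immutable
    super_start: int | None = None
    super_stop: int | None = None
    consensus_description: str = ""
    tigrfam_id: str | None = None
    aggregated_from: tuple[str, ...] = ()
    # retained so deaggregation restores constituents byte-identically;
    # not serialised by the pan-map writers
    constituents: tuple["PanGene", ...] = field(default=(), compare=False)
    pos_key: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pan gene {self.pan_id!r}: must contain at least one gene")
        if self.super_start is not None and self.super_stop is not None:
            if self.super_start > self.super_stop:
                raise ValueError(f"pan gene {self.pan_id!r}: empty super interval")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_aggregated(self) -> bool:
        return bool(self.aggregated_from)

    @property
    def n_leaves(self) -> int:
        """Number of original (non-aggregated) pan genes this row stands for."""
        if not self.constituents:
            return 1
        return sum(c.n_leaves for c in self.constituents)

    @property
    def display_label(self) -> str:
        """Row label; aggregated rows show the constituent count in brackets."""
        if self.is_aggregated:
            return f"{self.pan_id} ({self.n_leaves})"
        return self.pan_id


@dataclass(frozen=True)
class SummaryStats:
    n_genomes: int
    n_pan_genes: int
    n_core: int
    n_orphan: int
    n_dispensable: int

    def __post_init__(self) -> None:
        assert self.n_core + self.n_orphan + self.n_dispensable == self.n_pan_genes


@dataclass(frozen=True)
class InteractionEvent:
    timestamp: str
    kind: str  # 'aggregate' | 'deaggregate'
    pan_ids: tuple[str, ...]  # inputs
    result: tuple[str, ...]  # resulting pan id(s)


def classify(pg: PanGene, n: int) -> str:
    """Core (all genomes), orphan (exactly one) or dispensable (in between)."""
    k = pg.size
    if not 1 <= k <= n:
        raise ValueError(f"pan gene {pg.pan_id!r}: {k} members outside [1, {n}]")
    if k == n:
        return CORE
    if k == 1:
        return ORPHAN
    return DISPENSABLE


class PanGenomeMatrix:
    """Ordered pan genes x fixed genome roster, with interaction history.

    Rows keep a stable integer ``pos_key`` assigned at load; aggregation
    places the merged row at the smallest constituent key, so ordering and
    deaggregation are exact without re-sorting.
    """

    def __init__(
        self,
        genome_roster: Sequence[str],
        pan_genes: Iterable[PanGene] = (),
        dialect: str = "pangee",
        clock: Callable[[], str] | None = None,
    ) -> None:
        self.genome_roster: tuple[str, ...] = tuple(genome_roster)
        if len(set(self.genome_roster)) != len(self.genome_roster):
            raise ValueError("duplicate genome in roster")
        self.dialect = dialect
        self.history: list[InteractionEvent] = []
        self._undo_stack: list[tuple[list[PanGene], int]] = []
        self._agn_serial = 0
        self._clock = clock or (lambda: _dt.datetime.now().isoformat(timespec="seconds"))
        self._rows: list[PanGene] = []
        roster = set(self.genome_roster)
        ids: set[str] = set()
        for i, pg in enumerate(pan_genes):
            if pg.pan_id in ids:
                raise ValueError(f"duplicate pan gene id {pg.pan_id!r}")
            ids.add(pg.pan_id)
            unknown = set(pg.members) - roster
            if unknown:
                raise ValueError(
                    f"pan gene {pg.pan_id!r}: member genomes {sorted(unknown)} not in roster"
                )
            self._rows.append(replace(pg, pos_key=i) if pg.pos_key == 0 else pg)

    # -- container protocol -------------------------------------------------

    @property
    def pan_genes(self) -> tuple[PanGene, ...]:
        return tuple(self._rows)

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    def __getitem__(self, rank: int) -> PanGene:
        return self._rows[rank]

    def get(self, pan_id: str) -> PanGene:
        for pg in self._rows:
            if pg.pan_id == pan_id:
                return pg
        raise KeyError(f"unknown pan gene id {pan_id!r}")

    def rank(self, pan_id: str) -> int:
        for i, pg in enumerate(self._rows):
            if pg.pan_id == pan_id:
                return i
        raise KeyError(f"unknown pan gene id {pan_id!r}")

    def n_genes(self) -> int:
        """Total member-gene (filled cell) count."""
        return sum(pg.size for pg in self._rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanGenomeMatrix):
            return NotImplemented
        return (
            self.genome_roster == other.genome_roster
            and self.dialect == other.dialect
            and [self._obs(pg) for pg in self._rows]
            == [self._obs(pg) for pg in other._rows]
        )

    @staticmethod
    def _obs(pg: PanGene):
        return (
            pg.pan_id,
            dict(pg.members),
            pg.super_start,
            pg.super_stop,
            pg.consensus_description,
            pg.tigrfam_id,
            pg.aggregated_from,
        )

    # -- statistics ---------------------------------------------------------

    def summary(self) -> SummaryStats:
        n = len(self.genome_roster)
        counts = Counter(classify(pg, n) for pg in self._rows)
        return SummaryStats(
            n_genomes=n,
            n_pan_genes=len(self._rows),
            n_core=counts.get(CORE, 0),
            n_orphan=counts.get(ORPHAN, 0),
            n_dispensable=counts.get(DISPENSABLE, 0),
        )

    # -- annotation ---------------------------------------------------------

    def apply_tigrfam(self, assignments: dict[str, "object"]) -> int:
        """Label rows with the TIGRFAM of their member genes.

        A row gets the most frequent family among its members' assignments
        (ties: lexicographically first id).  Returns the number of rows
        labelled.
        """
        labelled = 0
        for i, pg in enumerate(self._rows):
            fams = Counter()
            for m in pg.members.values():
                a = assignments.get(m.gene_id)
                if a is not None:
                    fams[a.tigrfam_id] += 1
            if fams:
                best = max(fams, key=lambda f: (fams[f], [-ord(c) for c in f]))
                self._rows[i] = replace(pg, tigrfam_id=best)
                labelled += 1
        return labelled

    # -- curation algebra ---------------------------------------------------

    def can_aggregate(self, pan_ids: Sequence[str]) -> tuple[bool, str]:
        """Complementarity check: member genome sets pairwise disjoint.

        Strand differences never block aggregation.
        """
        if len(pan_ids) < 2:
            return False, "need at least two pan genes"
        if len(set(pan_ids)) != len(pan_ids):
            return False, "pan gene ids must be distinct"
        rows = [self.get(p) for p in pan_ids]
        seen: dict[str, str] = {}
        for pg in rows:
            for g in pg.members:
                if g in seen:
                    return False, (
                        f"genome {g!r} has a gene in both {seen[g]} and {pg.pan_id}"
                    )
                seen[g] = pg.pan_id
        return True, "ok"

    def _snapshot(self) -> None:
        self._undo_stack.append((list(self._rows), self._agn_serial))

    def _log(self, kind: str, inputs: Sequence[str], result: Sequence[str]) -> None:
        self.history.append(
            InteractionEvent(self._clock(), kind, tuple(inputs), tuple(result))
        )

    def aggregate(self, pan_ids: Sequence[str], agn_id: str | None = None) -> str:
        """Merge complementary pan genes into one ``AGN`` row.

        The merged row is placed at the position of the constituent with the
        smallest position key (hence smallest super start in built matrices)
        and records its constituents for exact deaggregation.  Returns the
        new identifier.
        """
        ok, reason = self.can_aggregate(pan_ids)
        if not ok:
            raise AggregationError(f"aggregation is not feasible: {reason}")
        rows = sorted((self.get(p) for p in pan_ids), key=lambda pg: pg.pos_key)
        self._snapshot()
        if agn_id is None:
            self._agn_serial += 1
            agn_id = f"AGN{self._agn_serial}"
        else:
            # replayed event: keep the serial counter ahead of forced ids
            try:
                self._agn_serial = max(self._agn_serial, int(agn_id[3:]))
            except ValueError:
                pass
        members: dict[str, Member] = {}
        for pg in rows:
            members.update(pg.members)
        members = {g: members[g] for g in self.genome_roster if g in members}
        starts = [pg.super_start for pg in rows if pg.super_start is not None]
        stops = [pg.super_stop for pg in rows if pg.super_stop is not None]
        merged = PanGene(
            pan_id=agn_id,
            members=members,
            super_start=min(starts) if starts else None,
            super_stop=max(stops) if stops else None,
            consensus_description=consensus_description(
                [m.description for m in members.values()],
                fallback=[pg.consensus_description for pg in rows],
            ),
            tigrfam_id=_consensus_tigrfam(rows),
            aggregated_from=tuple(pg.pan_id for pg in rows),
            constituents=tuple(rows),
            pos_key=rows[0].pos_key,
        )
        for pg in rows:
            self._rows.remove(pg)
        self._insert(merged)
        self._log("aggregate", [pg.pan_id for pg in rows], [agn_id])
        return agn_id

    def deaggregate(self, agn_id: str) -> tuple[str, ...]:
        """Restore the constituents of an aggregated row, byte-identical."""
        pg = self.get(agn_id)
        if not pg.is_aggregated or not pg.constituents:
            raise NotAggregatedError(f"{agn_id!r} is not an aggregated pan gene")
        self._snapshot()
        self._rows.remove(pg)
        for c in pg.constituents:
            self._insert(c)
        restored = tuple(c.pan_id for c in pg.constituents)
        self._log("deaggregate", [agn_id], restored)
        return restored

    def _insert(self, pg: PanGene) -> None:
        keys = [r.pos_key for r in self._rows]
        self._rows.insert(bisect_left(keys, pg.pos_key), pg)

    def undo(self) -> None:
        """Revert the most recent event; the reversal itself is logged."""
        if not self._undo_stack:
            raise NothingToUndoError("no interaction to undo")
        last = self.history[-1]
        rows, serial = self._undo_stack.pop()
        self._rows = rows
        self._agn_serial = serial
        kind = "deaggregate" if last.kind == "aggregate" else "aggregate"
        self._log(kind, last.result, last.pan_ids)

    def undo_all(self) -> None:
        while self._undo_stack:
            self.undo()

    # -- history ------------------------------------------------------------

    def export_history(self, path) -> None:
        """Write the interaction history as a replayable TSV audit log."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["timestamp", "kind", "pan_ids", "result"])
            for ev in self.history:
                w.writerow([ev.timestamp, ev.kind, ",".join(ev.pan_ids), ",".join(ev.result)])


def consensus_description(descriptions: Iterable[str], fallback: Iterable[str] = ()) -> str:
    """Most frequent non-empty description; ties broken lexicographically."""
    for pool in (descriptions, fallback):
        c = Counter(d for d in pool if d)
        if c:
            top = max(c.values())
            return min(d for d, k in c.items() if k == top)
    return ""


def _consensus_tigrfam(rows: Sequence[PanGene]) -> str | None:
    c = Counter(pg.tigrfam_id for pg in rows if pg.tigrfam_id)
    if not c:
        return None
    top = max(c.values())
    return min(t for t, k in c.items() if k == top)


# -- module-level wrappers ---------------------------------------------------


def summary(matrix: PanGenomeMatrix) -> SummaryStats:
    return matrix.summary()


def can_aggregate(matrix: PanGenomeMatrix, pan_ids: Sequence[str]) -> tuple[bool, str]:
    return matrix.can_aggregate(pan_ids)


def aggregate(matrix: PanGenomeMatrix, pan_ids: Sequence[str]) -> str:
    return matrix.aggregate(pan_ids)


def deaggregate(matrix: PanGenomeMatrix, agn_id: str) -> tuple[str, ...]:
    return matrix.deaggregate(agn_id)


def undo(matrix: PanGenomeMatrix) -> None:
    matrix.undo()


def export_history(matrix: PanGenomeMatrix, path) -> None:
    matrix.export_history(path)


def read_history(path) -> list[InteractionEvent]:
    events: list[InteractionEvent] = []
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is not None and header[:2] != ["timestamp", "kind"]:
            raise ValueError("not a history file (bad header)")
        for row in r:
            ts, kind, inputs, result = row
            events.append(
                InteractionEvent(
                    ts,
                    kind,
                    tuple(inputs.split(",")) if inputs else (),
                    tuple(result.split(",")) if result else (),
                )
            )
    return events


def apply_history(matrix: PanGenomeMatrix, events: Iterable[InteractionEvent]) -> None:
    """Replay an exported history on a freshly loaded matrix."""
    for ev in events:
        if ev.kind == "aggregate":
            matrix.aggregate(list(ev.pan_ids), agn_id=ev.result[0])
        elif ev.kind == "deaggregate":
            matrix.deaggregate(ev.pan_ids[0])
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
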