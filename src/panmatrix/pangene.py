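"""Pan gene construction from lifted annotations.

Gene annotations are transferred into SuperGenome coordinates through the
bidirectional maps, grouped by interval overlap on the shared axis, and each
overlap component is resolved into ortholog groups by greedy average-linkage
merging under two constraints: a pan gene holds at most one gene per genome,
and merges require the average pairwise sequence identity of the joined
groups to reach a threshold.  The resulting pan genes are ordered by their
appearance on the SuperGenome axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from Bio import Align

from .formats import GeneAnnotation
from .matrix import Member, PanGene, PanGenomeMatrix, consensus_description
from .supergenome import SuperGenome

__all__ = [
    "LiftedGene",
    "lift_annotations",
    "overlap_components",
    "pairwise_identity",
    "resolve_component",
    "build_pangenome",
    "sense_sequence",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 1
DEFAULT_IDENTITY_THRESHOLD = 0.5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalise(seq: str) -> str:
    """Uppercase; IUPAC ambiguity codes other than ACGT collapse to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class LiftedGene:
    """A gene annotation expressed in SuperGenome coordinates.

    ``lifted_strand`` is the annotation strand flipped when the carrying
    block entry is reverse, i.e. the gene's orientation along the shared
    axis.
    """

    annotation: GeneAnnotation
    super_start: int
    super_stop: int
    lifted_strand: str

    def __post_init__(self) -> None:
        if self.super_start > self.super_stop:
            raise ValueError("empty super interval")

    @property
    def genome_id(self) -> str:
        return self.annotation.genome_id

    @property
    def gene_id(self) -> str:
        return self.annotation.gene_id


def lift_annotations(
    sg: SuperGenome, annotations: Iterable[GeneAnnotation]
) -> list[LiftedGene]:
    """Transfer annotations onto the SuperGenome axis.

    A gene contained in one alignment block is lifted exactly.  A gene
    spanning several blocks is lifted to the interval of the block holding
    the majority of its bases (one gene, one interval).  Genes with no
    aligned base are dropped with a warning.
    """
    out: list[LiftedGene] = []
    for ann in annotations:
        best = None  # (covered, block_index, segment)
        for seg in sg.segments(ann.genome_id):
            lo, hi = max(ann.start, seg.gstart), min(ann.end, seg.gend)
            if lo > hi:
                continue
            cand = (hi - lo + 1, -seg.block_index)
            if best is None or cand > best[0]:
                best = (cand, seg, lo, hi)
        if best is None:
            logger.warning(
                "gene %s (%s) has no aligned base; dropped", ann.gene_id, ann.genome_id
            )
            continue
        _, seg, lo, hi = best
        c1 = abs(int(seg.cols[lo - seg.gstart]))
        c2 = abs(int(seg.cols[hi - seg.gstart]))
        strand = ann.strand
        if seg.strand == "-":
            strand = "+" if strand == "-" else "-"
        out.append(LiftedGene(ann, min(c1, c2), max(c1, c2), strand))
    return out


def overlap_components(
    lifted: Sequence[LiftedGene],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    roster: Sequence[str] | None = None,
) -> list[list[LiftedGene]]:
    """Connected components of the interval-overlap graph on the super axis.

    Two genes are linked when their super intervals share at least
    ``min_overlap`` columns.  Because the intervals live on a line, a single
    sweep over genes sorted by start position yields exactly the connected
    components; order is deterministic by (min super start, roster index).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    idx = {g: i for i, g in enumerate(roster)} if roster is not None else {}

    def key(lg: LiftedGene):
        return (lg.super_start, lg.super_stop, idx.get(lg.genome_id, 0), lg.gene_id)

    ordered = sorted(lifted, key=key)
    # intervals shorter than min_overlap can never share enough columns:
    # isolate them so they do not interrupt the sweep
    short = [lg for lg in ordered if lg.super_stop - lg.super_start + 1 < min_overlap]
    components: list[list[LiftedGene]] = [[lg] for lg in short]
    reach = None  # rightmost stop of current component
    for lg in ordered:
        if lg.super_stop - lg.super_start + 1 < min_overlap:
            continue
        # overlap with the current component is maximised against its
        # rightmost stop; exact on a line by transitivity
        if reach is not None and reach - lg.super_start + 1 >= min_overlap:
            components[-1].append(lg)
            reach = max(reach, lg.super_stop)
        else:
            components.append([lg])
            reach = lg.super_stop
    components.sort(key=lambda c: key(c[0]))
    return components


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment nucleotide identity in [0, 1].

    Needleman-Wunsch with match +1, mismatch -1, gap -2; identity is the
    fraction of alignment columns at which both sequences carry the same
    base.  The pair is ordered internally so the value is symmetric.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    a, b = sorted((_normalise(seq_a), _normalise(seq_b)))
    aln = _ALIGNER.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / aln.length


def sense_sequence(ann: GeneAnnotation, genome_seq: str) -> str:
    """The gene's coding-orientation sequence extracted from its genome."""
    sub = genome_seq[ann.start - 1 : ann.end]
    return reverse_complement(sub) if ann.strand == "-" else sub


def resolve_component(
    component: Sequence[LiftedGene],
    similarity: Callable[[LiftedGene, LiftedGene], float] | None = None,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    roster: Sequence[str] | None = None,
) -> list[list[LiftedGene]]:
    """Split an overlap component into ortholog groups.

    Greedy agglomerative merging: starting from singletons, repeatedly merge
    the pair of groups with the highest average inter-group similarity,
    allowed only when their genome sets are disjoint and that similarity
    reaches ``threshold``.  Ties break on (smaller super start, roster
    index, gene id).  With no similarity function every pair scores 1.0 and
    overlap plus the per-genome uniqueness constraint alone drive grouping.
    """
    idx = {g: i for i, g in enumerate(roster)} if roster is not None else {}
    genes = list(component)
    n = len(genes)
    if n == 0:
        return []
    sim = [[1.0] * n for _ in range(n)]
    if similarity is not None:
        for i in range(n):
            for j in range(i + 1, n):
                sim[i][j] = sim[j][i] = similarity(genes[i], genes[j])

    groups: list[list[int]] = [[i] for i in range(n)]

    def gkey(g: list[int]):
        return min(
            (genes[i].super_start, idx.get(genes[i].genome_id, 0), genes[i].gene_id)
            for i in g
        )

    def genomes(g: list[int]) -> set[str]:
        return {genes[i].genome_id for i in g}

    while len(groups) > 1:
        best = None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if genomes(groups[a]) & genomes(groups[b]):
                    continue
                pairs = [(i, j) for i in groups[a] for j in groups[b]]
                avg = sum(sim[i][j] for i, j in pairs) / len(pairs)
                if avg < threshold:
                    continue
                ka, kb = sorted((gkey(groups[a]), gkey(groups[b])))
                cand = (-avg, ka, kb)
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        if best is None:
            break
        _, a, b = best
        merged = sorted(groups[a] + groups[b])
        groups = [g for k, g in enumerate(groups) if k not in (a, b)]
        groups.append(merged)

    groups.sort(key=gkey)
    return [[genes[i] for i in g] for g in groups]


def build_pangenome(
    sg: SuperGenome,
    annotations: Mapping[str, Sequence[GeneAnnotation]] | Sequence[GeneAnnotation],
    sequences: Mapping[str, str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    dialect: str = "pangee",
) -> PanGenomeMatrix:
    """Full pipeline: lift, group by overlap, resolve, order, label.

    ``sequences`` (genome id -> genome sequence) enables similarity
    refinement on annotation-oriented gene sequences; without it, grouping
    relies on overlap and the per-genome uniqueness constraint only.  Pan
    genes are sorted ascending by super interval and numbered ``PG000001``
    onward.
    """
    if hasattr(annotations, "values"):
        flat = [a for anns in annotations.values() for a in anns]
    else:
        flat = list(annotations)
    lifted = lift_annotations(sg, flat)
    roster = sg.genome_roster

    similarity = None
    if sequences is not None:
        cache: dict[str, str] = {}

        def _seq(lg: LiftedGene) -> str:
            key = f"{lg.genome_id}\t{lg.gene_id}"
            if key not in cache:
                cache[key] = sense_sequence(lg.annotation, sequences[lg.genome_id])
            return cache[key]

        def similarity(a: LiftedGene, b: LiftedGene) -> float:
            return pairwise_identity(_seq(a), _seq(b))

    groups: list[list[LiftedGene]] = []
    for comp in overlap_components(lifted, min_overlap, roster):
        if len(comp) == 1:
            groups.append(comp)
        else:
            groups.extend(
                resolve_component(comp, similarity, identity_threshold, roster)
            )

    idx = {g: i for i, g in enumerate(roster)}
    drafts = []
    for g in groups:
        members = {
            lg.genome_id: Member(
                lg.gene_id, lg.lifted_strand, lg.annotation.description
            )
            for lg in sorted(g, key=lambda x: idx[x.genome_id])
        }
        if len(members) != len(g):
            raise AssertionError("per-genome uniqueness violated in resolved group")
        sstart = min(lg.super_start for lg in g)
        sstop = max(lg.super_stop for lg in g)
        drafts.append((sstart, sstop, min(idx[lg.genome_id] for lg in g), members))
    drafts.sort(key=lambda d: d[:3])

    genes = [
        PanGene(
            pan_id=f"PG{k:06d}",
            members=members,
            super_start=sstart,
            super_stop=sstop,
            consensus_description=consensus_description(
                m.description for m in members.values()
            ),
        )
        for k, (sstart, sstop, _, members) in enumerate(drafts, start=1)
    ]
    matrix = PanGenomeMatrix(roster, genes, dialect=dialect)
    assert matrix.n_genes() == len(lifted), "gene conservation violated"
    return matrix
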