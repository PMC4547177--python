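"""Shared independent oracles and random-instance generators for the tests.

Everything here is deliberately naive (column scans, exhaustive DP and
partition enumeration) and independent of the implementation paths it
checks.
"""

from __future__ import annotations

import random
from itertools import combinations

from panmatrix.formats import GeneAnnotation
from panmatrix.pangene import LiftedGene
from panmatrix.supergenome import UNALIGNED


# -- column-scan oracle for the SuperGenome maps -----------------------------


def forward_map_by_column_scan(blocks):
    """Expand every block column by column: genome pos -> signed column."""
    fwd: dict[str, dict[int, int]] = {}
    off = 0
    for b in blocks:
        for e in b.entries:
            d = fwd.setdefault(e.genome_id, {})
            p = e.start if e.strand == "+" else e.end
            step = 1 if e.strand == "+" else -1
            for ci, ch in enumerate(e.gapped_sequence):
                if ch != "-":
                    col = off + ci + 1
                    d[p] = -col if e.strand == "-" else col
                    p += step
        off += b.width
    return fwd


def check_roundtrip(sg, seqs) -> int:
    """Assert to_genome(to_super(p)) == p everywhere; returns positions checked."""
    fwd = forward_map_by_column_scan(sg.blocks)
    checked = 0
    for g in sg.genome_roster:
        for p in range(1, len(seqs[g]) + 1):
            want = fwd.get(g, {}).get(p, UNALIGNED)
            got = sg.to_super(g, p)
            assert got == want, (g, p, got, want)
            if got is not UNALIGNED:
                assert sg.to_genome(g, abs(got)) == p
                checked += 1
    return checked


# -- exhaustive alignment oracle ---------------------------------------------


def nw_optimal_identities(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """All (matches/length) values over *all* optimal global alignments.

    Exhaustive DP with full traceback enumeration; only for short strings.
    Returns (optimal score, set of identity fractions).
    """
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = i * gap
    for j in range(1, m + 1):
        S[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i][j] = max(
                S[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch),
                S[i - 1][j] + gap,
                S[i][j - 1] + gap,
            )
    idents = set()

    def walk(i, j, matches, length):
        if i == 0 and j == 0:
            idents.add(matches / length)
            return
        if i > 0 and j > 0:
            sc = match if a[i - 1] == b[j - 1] else mismatch
            if S[i][j] == S[i - 1][j - 1] + sc:
                walk(i - 1, j - 1, matches + (a[i - 1] == b[j - 1]), length + 1)
        if i > 0 and S[i][j] == S[i - 1][j] + gap:
            walk(i - 1, j, matches, length + 1)
        if j > 0 and S[i][j] == S[i][j - 1] + gap:
            walk(i, j - 1, matches, length + 1)

    walk(n, m, 0, 0)
    return S[n][m], idents


# -- exhaustive partition oracle for component resolution --------------------


def set_partitions(items):
    """All set partitions (exhaustive, order-free)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def partition_score(partition, sim, threshold):
    """Sum over intra-group pairs of (similarity - threshold)."""
    total = 0.0
    for group in partition:
        for x, y in combinations(group, 2):
            total += sim[x][y] - threshold
    return total


def best_feasible_partition_score(genes_genomes, sim, threshold):
    """Oracle optimum over all per-genome-unique partitions."""
    best = None
    for part in set_partitions(range(len(genes_genomes))):
        if any(
            len({genes_genomes[i] for i in g}) != len(g) for g in part
        ):
            continue
        s = partition_score(part, sim, threshold)
        if best is None or s > best:
            best = s
    return best


def planted_component(rng: random.Random, max_genes: int = 8):
    """A random overlap component with a planted ortholog partition.

    Within-group identities 0.75-1.0, between-group 0.0-0.40 — the
    separation that alignment of true orthologs vs unrelated overlapping
    genes produces.  Returns (lifted genes, sim matrix, true partition as
    index sets).
    """
    n_genomes = rng.randint(2, 5)
    genomes = [f"genome{i + 1}" for i in range(n_genomes)]
    n_groups = rng.randint(1, 3)
    assignment = []  # (group, genome)
    for grp in range(n_groups):
        size = rng.randint(1, n_genomes)
        for g in rng.sample(genomes, size):
            assignment.append((grp, g))
    rng.shuffle(assignment)
    assignment = assignment[: max_genes]
    genes = []
    for k, (grp, g) in enumerate(assignment):
        start = 1000 + rng.randint(0, 30)
        ann = GeneAnnotation(g, f"{g}_x{k}", 1, 10, "+", f"grp{grp}")
        genes.append(LiftedGene(ann, start, start + 300, "+"))
    n = len(genes)
    sim = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            same = assignment[i][0] == assignment[j][0]
            v = rng.uniform(0.75, 1.0) if same else rng.uniform(0.0, 0.40)
            sim[i][j] = sim[j][i] = v
    truth = {}
    for k, (grp, _) in enumerate(assignment):
        truth.setdefault(grp, set()).add(k)
    return genes, sim, sorted(map(frozenset, truth.values()), key=min)


def resolve_with_matrix(genes, sim, threshold=0.5):
    """Run resolve_component against an index-keyed similarity matrix."""
    from panmatrix.pangene import resolve_component

    index = {id(g): i for i, g in enumerate(genes)}

    def similarity(a, b):
        return sim[index[id(a)]][index[id(b)]]

    groups = resolve_component(genes, similarity, threshold)
    return sorted(
        (frozenset(index[id(g)] for g in grp) for grp in groups), key=min
    )


# -- random curation event sequences -----------------------------------------


def random_events(matrix, rng: random.Random, n_events: int = 6) -> int:
    """Apply a random valid aggregate/deaggregate sequence; returns count."""
    applied = 0
    for _ in range(n_events):
        agns = [pg.pan_id for pg in matrix if pg.is_aggregated]
        if agns and rng.random() < 0.3:
            matrix.deaggregate(rng.choice(agns))
            applied += 1
            continue
        ids = [pg.pan_id for pg in matrix]
        if len(ids) < 2:
            break
        for _attempt in range(10):
            k = rng.randint(2, min(3, len(ids)))
            pick = rng.sample(ids, k)
            ok, _ = matrix.can_aggregate(pick)
            if ok:
                matrix.aggregate(pick)
                applied += 1
                break
    return applied
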