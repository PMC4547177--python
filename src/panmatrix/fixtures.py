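"""Deterministic synthetic data with known ground truth.

Everything the pipeline consumes — genome FASTAs, per-genome GFF3 gene
annotations, an XMFA whole-genome alignment, TIGRFAM assignment tables and
pan-genome map files — can be generated here with a seed, so the full tool
chain is testable without any external download or aligner run.

``make_toy_dataset`` builds toy bacterial genomes from gene families laid
out on a shared axis: core families in all genomes, private orphans,
dispensable families on random proper subsets.  Optional perturbations
emulate the situations the curation workflow targets:

* *inversions* — a copy sits on the opposite strand, either as an in-place
  gene inversion inside a forward block (the lifted strand flips) or as a
  whole-segment inversion carried by a reverse-strand block entry,
* *truncations* — a copy's annotation is cut to 40% of the gene (premature
  stop after a simulated homopolymer insertion), so it falls below the
  identity threshold and splits off as an orphan next to its complementary
  group,
* *block splits* — one genome's segment is torn out of its family block
  into a private block, mimicking an erroneously aligned region.

The generator knows the homology, so it writes the true alignment and the
true pan-genome matrix; the block-split and truncation perturbations are
recorded as planted disrupted pairs for the candidate detector to find.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .formats import (
    GeneAnnotation,
    TigrfamAssignment,
    write_panmap,
    write_tigrfam,
)
from .matrix import Member, PanGene, PanGenomeMatrix, consensus_description
from .supergenome import AlignmentBlock, BlockEntry

__all__ = [
    "ToyDataset",
    "make_toy_dataset",
    "make_random_alignment",
    "make_synthetic_matrix",
    "write_xmfa",
    "SAUREUS_LIKE",
]

#: Category composition of the published 32-genome S. aureus study.
SAUREUS_LIKE = dict(n_genomes=32, n_core=1846, n_orphan=3848, n_dispensable=2953)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRUNCATED_FRACTION = 0.4  # annotation kept after the simulated premature stop
SUBSTITUTION_RATE = 0.02  # per-base substitutions per gene copy


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float = SUBSTITUTION_RATE) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


def write_xmfa(blocks, path) -> None:
    """Emit alignment blocks in the Mauve XMFA dialect (80-column wrap)."""
    with open(path, "w") as fh:
        for b in blocks:
            for e in b.entries:
                fh.write(f"> {e.genome_id}:{e.start}-{e.end} {e.strand}\n")
                for i in range(0, len(e.gapped_sequence), 80):
                    fh.write(e.gapped_sequence[i : i + 80] + "\n")
            fh.write("=\n")


def _write_gff(annotations, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.genome_id}\tpanmatrix\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t"
                f"ID={a.gene_id};product={a.description}\n"
            )


def _write_fasta(seqs: dict[str, str], out_dir: Path) -> dict[str, Path]:
    paths = {}
    for gid, seq in seqs.items():
        p = out_dir / f"{gid}.fna"
        with open(p, "w") as fh:
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        paths[gid] = p
    return paths


@dataclass
class ToyDataset:
    """A generated data set plus its ground truth."""

    genomes: dict[str, str]
    annotations: dict[str, list[GeneAnnotation]]
    blocks: list[AlignmentBlock]
    tigrfam: dict[str, TigrfamAssignment]
    truth: PanGenomeMatrix
    disrupted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def write(self, out_dir) -> dict[str, Path]:
        """Materialise FASTA/GFF3/XMFA/TIGRFAM/truth files; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for gid, p in _write_fasta(self.genomes, out).items():
            paths[f"fasta:{gid}"] = p
        for gid, anns in self.annotations.items():
            p = out / f"{gid}.gff3"
            _write_gff(anns, p)
            paths[f"gff:{gid}"] = p
        paths["xmfa"] = out / "alignment.xmfa"
        write_xmfa(self.blocks, paths["xmfa"])
        paths["tigrfam"] = out / "tigrfam.tsv"
        write_tigrfam(self.tigrfam.values(), paths["tigrfam"])
        paths["truth"] = out / "truth.panmap.tsv"
        write_panmap(self.truth, paths["truth"])
        return paths


@dataclass
class _Copy:
    genome: str
    gene_id: str
    ann_strand: str
    lifted_strand: str
    style: str  # normal | inplace | block | truncated | split


def make_toy_dataset(
    seed: int = 0,
    n_genomes: int = 3,
    n_core: int = 5,
    n_orphan_per_genome: int = 1,
    n_dispensable: int = 0,
    inversion_rate: float = 0.0,
    truncation_rate: float = 0.0,
    block_split_rate: float = 0.0,
    tigrfam_prob: float = 0.7,
) -> ToyDataset:
    """Generate toy genomes sharing gene families, with known truth.

    Core families occur in all genomes (substitution-mutated copies), each
    genome carries private orphans, dispensable families go to random proper
    subsets (needs >= 3 genomes).  ``inversion_rate``, ``truncation_rate``
    and ``block_split_rate`` apply per multi-genome family (one affected
    copy each); truncations and block splits are recorded as planted
    disrupted pairs.
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if min(n_core, n_orphan_per_genome, n_dispensable) < 0:
        raise ValueError("family counts must be >= 0")
    if n_dispensable > 0 and n_genomes < 3:
        raise ValueError("dispensable families need >= 3 genomes (proper subset of size >= 2)")
    for name, rate in (
        ("inversion_rate", inversion_rate),
        ("truncation_rate", truncation_rate),
        ("block_split_rate", block_split_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    rng = random.Random(seed)
    roster = [f"genome{i + 1}" for i in range(n_genomes)]
    ridx = {g: i for i, g in enumerate(roster)}

    # family plan: (kind, subset)
    plan: list[tuple[str, list[str]]] = [
        ("core", list(roster)) for _ in range(n_core)
    ]
    for g in roster:
        plan += [("orphan", [g]) for _ in range(n_orphan_per_genome)]
    for _ in range(n_dispensable):
        k = rng.randint(2, n_genomes - 1)
        plan.append(("dispensable", sorted(rng.sample(roster, k), key=ridx.get)))
    rng.shuffle(plan)

    genomes: dict[str, list[str]] = {g: [] for g in roster}
    cursor = {g: 0 for g in roster}
    annotations: dict[str, list[GeneAnnotation]] = {g: [] for g in roster}
    blocks: list[AlignmentBlock] = []
    tigrfam: dict[str, TigrfamAssignment] = {}
    col = 0  # running SuperGenome column offset
    gene_serial = {g: 0 for g in roster}
    truth_rows: list[tuple[tuple[int, int, int], PanGene]] = []
    disrupted: list[tuple[PanGene, PanGene]] = []

    def emit_block(entries: list[BlockEntry]) -> int:
        nonlocal col
        start_col = col
        blocks.append(AlignmentBlock(len(blocks), tuple(entries)))
        col += len(entries[0].gapped_sequence)
        return start_col

    def append_seq(g: str, seq: str) -> tuple[int, int]:
        genomes[g].append(seq)
        s = cursor[g] + 1
        cursor[g] += len(seq)
        return s, cursor[g]

    def private_block(g: str, seq: str) -> tuple[int, int, int]:
        s, e = append_seq(g, seq)
        off = emit_block([BlockEntry(g, s, e, "+", seq)])
        return s, e, off

    def new_gene_id(g: str) -> str:
        gene_serial[g] += 1
        return f"{g}_{gene_serial[g]:04d}"

    def draft_row(
        key: tuple[int, int, int], members: dict[str, Member], tig: str | None
    ) -> PanGene:
        pg = PanGene(
            pan_id=f"T{len(truth_rows):05d}",  # renumbered after the global sort
            members=members,
            super_start=key[0],
            super_stop=key[1],
            consensus_description=consensus_description(
                m.description for m in members.values()
            ),
            tigrfam_id=tig,
        )
        truth_rows.append((key, pg))
        return pg

    # shared anchor region (think: origin neighbourhood) opens the alignment,
    # fixing the genome roster order to the order of the generated genomes
    anchor = _random_seq(rng, 60)
    anchor_entries = []
    for g in roster:
        seq = _mutate(rng, anchor)
        s, e = append_seq(g, seq)
        anchor_entries.append(BlockEntry(g, s, e, "+", seq))
    emit_block(anchor_entries)

    for fam_idx, (kind, subset) in enumerate(plan):
        length = rng.randrange(300, 601, 3)
        ancestor = _random_seq(rng, length)
        desc = f"hypothetical protein fam{fam_idx:03d}"
        tig = f"TIGR{fam_idx % 40 + 1:05d}" if rng.random() < tigrfam_prob else None

        # private spacers keep genomes realistic without touching the truth
        for g in subset:
            private_block(g, _random_seq(rng, rng.randint(40, 80)))

        # pick at most one perturbation for multi-genome families
        perturb = None
        target = None
        if len(subset) >= 2:
            if rng.random() < truncation_rate:
                perturb, target = "truncated", rng.choice(subset)
            elif rng.random() < block_split_rate:
                perturb, target = "split", rng.choice(subset)

        copies: list[_Copy] = []
        entries: list[BlockEntry] = []
        split_copy: tuple[str, str] | None = None  # (genome, seq)
        for g in subset:
            copy = _mutate(rng, ancestor)
            style = "normal"
            if perturb and g == target:
                style = perturb
            elif len(subset) >= 2 and g != subset[0] and rng.random() < inversion_rate:
                style = rng.choice(["inplace", "block"])
            if style == "split":
                split_copy = (g, copy)
                copies.append(_Copy(g, new_gene_id(g), "+", "+", style))
                continue
            if style == "inplace":
                # gene inverted within a forward-aligned block
                s, e = append_seq(g, _revcomp(copy))
                entries.append(BlockEntry(g, s, e, "+", _revcomp(copy)))
                copies.append(_Copy(g, new_gene_id(g), "-", "-", style))
            elif style == "block":
                # whole segment inverted; the block entry is reverse-strand
                s, e = append_seq(g, _revcomp(copy))
                entries.append(BlockEntry(g, s, e, "-", copy))
                copies.append(_Copy(g, new_gene_id(g), "-", "+", style))
            else:
                s, e = append_seq(g, copy)
                entries.append(BlockEntry(g, s, e, "+", copy))
                copies.append(_Copy(g, new_gene_id(g), "+", "+", style))

        fam_off = emit_block(entries)

        # annotations + truth membership
        main_members: dict[str, Member] = {}
        main_span = [fam_off + 1, fam_off + length]
        orphan_rows: list[PanGene] = []
        for cp in copies:
            g = cp.genome
            if cp.style == "split":
                continue
            ann_start = cursor[g] - length + 1
            ann_end = cursor[g]
            if cp.style == "truncated":
                ann_end = ann_start + int(length * TRUNCATED_FRACTION) - 1
            annotations[g].append(
                GeneAnnotation(g, cp.gene_id, ann_start, ann_end, cp.ann_strand, desc)
            )
            if tig:
                tigrfam[cp.gene_id] = TigrfamAssignment(cp.gene_id, tig, desc)
            member = Member(cp.gene_id, cp.lifted_strand, desc)
            if cp.style == "truncated":
                span = (fam_off + 1, fam_off + int(length * TRUNCATED_FRACTION))
                orphan_rows.append(
                    draft_row((span[0], span[1], ridx[g]), {g: member}, tig)
                )
            else:
                main_members[g] = member

        if split_copy is not None:
            # the torn-out copy follows its family in its own block
            g, seq = split_copy
            s, e = append_seq(g, seq)
            off = emit_block([BlockEntry(g, s, e, "+", seq)])
            cp = next(c for c in copies if c.style == "split")
            annotations[g].append(GeneAnnotation(g, cp.gene_id, s, e, "+", desc))
            if tig:
                tigrfam[cp.gene_id] = TigrfamAssignment(cp.gene_id, tig, desc)
            orphan_rows.append(
                draft_row(
                    (off + 1, off + length, ridx[g]),
                    {g: Member(cp.gene_id, "+", desc)},
                    tig,
                )
            )

        if main_members:
            main_row = draft_row(
                (main_span[0], main_span[1], min(ridx[g] for g in main_members)),
                main_members,
                tig,
            )
            for orow in orphan_rows:
                disrupted.append((orow, main_row))

    # uncovered tails exercise UNALIGNED positions
    for g in roster:
        append_seq(g, _random_seq(rng, rng.randint(10, 30)))

    truth_rows.sort(key=lambda kv: kv[0])
    final = []
    renamed: dict[str, str] = {}
    from dataclasses import replace

    for k, (_, pg) in enumerate(truth_rows, start=1):
        new_id = f"PG{k:06d}"
        renamed[pg.pan_id] = new_id
        final.append(replace(pg, pan_id=new_id))
    truth = PanGenomeMatrix(roster, final, dialect="pangee")
    pairs = [(renamed[a.pan_id], renamed[b.pan_id]) for a, b in disrupted]

    return ToyDataset(
        genomes={g: "".join(parts) for g, parts in genomes.items()},
        annotations=annotations,
        blocks=blocks,
        tigrfam=tigrfam,
        truth=truth,
        disrupted_pairs=pairs,
    )


def make_random_alignment(
    seed: int = 0,
    n_genomes: int = 3,
    n_blocks: int | None = None,
    max_width: int = 400,
    gap_prob: float = 0.15,
    presence_prob: float = 0.85,
    reverse_prob: float = 0.3,
) -> tuple[list[AlignmentBlock], dict[str, str]]:
    """Random blockwise alignment plus the genome sequences it implies.

    Used for coordinate-map property testing: gapped rows, absent genomes,
    reverse-strand entries and uncovered genome tails all occur.  Returns
    (blocks, genome sequences).
    """
    rng = random.Random(seed)
    roster = [f"genome{i + 1}" for i in range(n_genomes)]
    nb = n_blocks if n_blocks is not None else rng.randint(1, 6)
    cursor = {g: 0 for g in roster}
    parts: dict[str, list[str]] = {g: [] for g in roster}
    blocks: list[AlignmentBlock] = []
    for bi in range(nb):
        width = rng.randint(20, max_width)
        present = [g for g in roster if rng.random() < presence_prob]
        if not present:
            present = [rng.choice(roster)]
        entries = []
        for g in present:
            row = [
                "-" if rng.random() < gap_prob else rng.choice(_BASES)
                for _ in range(width)
            ]
            if all(c == "-" for c in row):
                row[rng.randrange(width)] = rng.choice(_BASES)
            gapped = "".join(row)
            ungapped = gapped.replace("-", "")
            strand = "-" if rng.random() < reverse_prob else "+"
            s = cursor[g] + 1
            e = cursor[g] + len(ungapped)
            cursor[g] = e
            parts[g].append(_revcomp(ungapped) if strand == "-" else ungapped)
            entries.append(BlockEntry(g, s, e, strand, gapped))
        blocks.append(AlignmentBlock(bi, entries))
    for g in roster:  # uncovered tail
        parts[g].append(_random_seq(rng, rng.randint(0, 25)))
    return blocks, {g: "".join(p) for g, p in parts.items()}


def make_synthetic_matrix(
    seed: int = 0,
    n_genomes: int = 3,
    n_core: int = 2,
    n_orphan: int = 1,
    n_dispensable: int = 1,
    preset: str | None = None,
) -> PanGenomeMatrix:
    """A matrix with exactly the requested category composition.

    ``preset='saureus_like'`` uses the published 32-genome composition
    (1846 core + 3848 orphan + 2953 dispensable pan genes).  Dispensable
    group sizes are uniform on [2, n_genomes - 1].
    """
    if preset is not None:
        if preset != "saureus_like":
            raise ValueError(f"unknown preset {preset!r}")
        n_genomes = SAUREUS_LIKE["n_genomes"]
        n_core = SAUREUS_LIKE["n_core"]
        n_orphan = SAUREUS_LIKE["n_orphan"]
        n_dispensable = SAUREUS_LIKE["n_dispensable"]
    if min(n_core, n_orphan, n_dispensable) < 0:
        raise ValueError("row counts must be >= 0")
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if n_dispensable > 0 and n_genomes < 3:
        raise ValueError("dispensable rows need >= 3 genomes")

    rng = random.Random(seed)
    roster = [f"genome{i + 1}" for i in range(n_genomes)]
    ridx = {g: i for i, g in enumerate(roster)}
    labels = ["core"] * n_core + ["orphan"] * n_orphan + ["dispensable"] * n_dispensable
    rng.shuffle(labels)
    serial = {g: 0 for g in roster}
    rows = []
    cursor = 0
    for k, lab in enumerate(labels, start=1):
        if lab == "core":
            subset = roster
        elif lab == "orphan":
            subset = [rng.choice(roster)]
        else:
            subset = sorted(rng.sample(roster, rng.randint(2, n_genomes - 1)), key=ridx.get)
        length = rng.randrange(300, 601, 3)
        desc = f"hypothetical protein fam{k:05d}"
        members = {}
        for g in subset:
            serial[g] += 1
            members[g] = Member(
                f"{g}_{serial[g]:05d}", rng.choice("++-"), desc
            )
        rows.append(
            PanGene(
                pan_id=f"PG{k:06d}",
                members=members,
                super_start=cursor + 1,
                super_stop=cursor + length,
                consensus_description=desc,
            )
        )
        cursor += length + rng.randint(20, 120)
    return PanGenomeMatrix(roster, rows, dialect="pangee")
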