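# panmatrix

Construction, curation and visualisation of bacterial pan-genomes from
whole-genome alignments.

A pan-genome is the union of all genes across the strains of a species,
organised into *pan genes* — ortholog groups with at most one member per
genome.  With `n` genomes, a pan gene present in all `n` is **core**, in
exactly one an **orphan**, otherwise **dispensable**, so for any matrix

```
n_core + n_orphan + n_dispensable = n_pan_genes .
```

Instead of reciprocal-BLAST clustering, `panmatrix` exploits a multiple
genome alignment: the alignment blocks of an XMFA file (progressiveMauve
dialect) are concatenated into a single *SuperGenome* axis with an exact
bidirectional map between alignment columns and each genome's own
coordinates.  Gene annotations lift onto that axis; genes whose lifted
intervals overlap are candidate orthologs, refined by Needleman–Wunsch
identity (match +1, mismatch −1, gap −2; identity = matches / alignment
length) under the constraint that a group never holds two genes of the
same genome.  The resulting presence–absence matrix is ordered along the
SuperGenome and can be *curated*: complementary rows (sharing no genome)
merge into an `AGN` row, merges are reversible, every interaction is
logged, and candidates for merging — nearby complementary rows with the
same TIGRFAM family or consensus description, the signature of one
ortholog group erroneously split in two — are detected automatically.
Matrices render as glyph matrices (strand-oriented arrows, presence /
strand / TIGRFAM colouring, core–orphan group-size column) to SVG, PDF,
PNG, JPEG or TIFF.

For scientists working on microbial comparative genomics who have an
alignment and per-genome GFF3 annotations — or who want a fully synthetic,
ground-truthed sandbox, which the `fixtures` module generates from a seed.

## Worked example

Generate a toy data set (3 genomes, 4 shared gene families, one private
gene each), build its pan-genome, and inspect it:

```sh
$ panmatrix simulate --seed 5 --out-dir sim --genomes 3 --core 4 --orphans-per-genome 1
wrote 9 files to sim (7 truth pan genes, 0 planted pairs)

$ panmatrix build sim/alignment.xmfa sim -o pan.tsv --fasta-dir sim
wrote pan.tsv: 7 pan genes over 3 genomes

$ panmatrix stats pan.tsv
genomes      3
pan_genes    7
core         4
orphan       3
dispensable  0

$ panmatrix render pan.tsv -o pan.svg --scheme strand
wrote pan.svg: 15 glyphs
```

The 7 pan genes are the 4 core families plus the 3 private orphans; the 15
glyphs are the 15 gene occurrences (4 × 3 core members + 3 orphans), drawn
as up/down arrows by strand.  The built matrix is identical to the
generator's ground-truth matrix (`sim/truth.panmap.tsv`).

The same from Python:

```python
import panmatrix as pm

ds = pm.make_toy_dataset(seed=5, n_genomes=3, n_core=4, n_orphan_per_genome=1)
sg = pm.build_supergenome(ds.blocks)
m = pm.build_pangenome(sg, ds.annotations, ds.genomes)
print(m.summary())        # SummaryStats(n_genomes=3, n_pan_genes=7, n_core=4, ...)
assert m == ds.truth
```

Curation, on rows that share no genome:

```python
agn = m.aggregate(["PG000002", "PG000003"])   # raises if not complementary
print(m.get(agn).display_label)               # e.g. 'AGN1 (2)'
m.undo()                                      # exact restoration, logged
```

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

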