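# tcskit

Genome-wide annotation of **two-component-system (TCS) phosphorelay gene
families** — the His→Asp→His→Asp signaling cascade that transduces
cytokinin in plants.  The toolkit is aimed at comparative genomicists
cataloguing cytokinin-signaling repertoires (receptors, phosphotransfer
proteins, response regulators) across plant genomes, with particular
attention to *non-canonical* family members whose phosphoacceptor residue
has been substituted.

## What it does

Given candidate protein sets (FASTA), domain tables (HMMER3
`--domtblout`), gene-locus tables, genome/promoter sequences and
expression matrices, `tcskit`:

1. **Classifies** each protein into a TCS family from its domain
   architecture via a priority-ordered rule table: CHASE → CHK (cytokinin
   receptor), EBD → ETR (ethylene receptor), HisKA/HATPase → HK,
   Hpt → HPT, Rec+CCT → clock-RR, Rec+Myb → RRB, Rec → RRA/RRC.
2. **Identifies the phosphoacceptor residue** of every protein by global
   affine-gap alignment (Gotoh, BLOSUM62, open 11 / extend 1) to a family
   reference and projection of the reference coordinate — e.g. H77 of the
   HPT reference, D64 of the Type-B RR reference — and calls the variant
   class (HPT-H / HPT-N / HPT-X; D / D-to-E / D-to-N / other; truncated).
3. **Computes substitution-rate tables** comparing the phosphoacceptor
   column with every other H (or D) position of the reference, the
   signature of purifying selection on relay function.
4. Builds **neighbor-joining trees** on Poisson-corrected distances
   (d = −ln(1−p)) with outgroup rooting, as a distance-based stand-in for
   ML inference.
5. Counts the degenerate cytokinin-response **cis-element AGATHY**
   (H = A/C/T, Y = C/T) in 2.5-kb promoters, both strands, overlaps
   included.
6. Detects **tandem-duplicated arrays** (same-family genes with ≤ 10
   intervening genes on one chromosome).
7. Normalizes and **clusters expression profiles** (per-dataset
   (min, median, max) → (0, 0.5, 1) rescaling; Euclidean average-linkage)
   and extracts the **core signaling module**: the most highly expressed
   gene per family (highest median across samples).

A deterministic synthetic-data module generates all of these inputs with
known ground truth (planted substitutions, tandem arrays, motif counts,
co-expression clusters), so every stage is testable offline.  A packaged
census fixture transcribes the published *Medicago truncatula* TCS
catalogue (77 proteins in five sections).

## Worked example

Simulate a Type-B response-regulator family with 25% planted
phosphoacceptor substitutions, then run the census:

```bash
tcs simulate --kind family --family RRB --n 20 --q 0.25 --seed 7 --out demo
tcs census --proteins demo/proteins.fasta --domains demo/domains.domtblout --out demo_out
```

prints

```json
{
  "families": {
    "RRB": { "canonical": 16, "non_canonical": 4, "total": 20 }
  },
  "variants": {
    "RRB": { "D-to-E": 3, "D-to-N": 1, "canonical": 16 }
  }
}
```

— 4 of 20 simulated proteins carry a substituted phosphoacceptor (the
planted rate was q = 0.25; the draw gave 3 D→E and 1 D→N), and the
classifier flags exactly those as non-canonical.  The substitution table
for the same family:

```bash
tcs phosphosite --proteins demo/proteins.fasta --family RRB --out demo_out/subs.tsv
```

```
position  kind        D   E   N   other  gaps
30        comparison  20  0   0   0      0
64        site        16  3   1   0      0
...
%site     percent     80  15  5   0
```

The site column (D64) reads 80% D / 15% E / 5% N, matching the planted
truth; comparison D positions are fully conserved here because the demo
family was generated at low background divergence.

Running the classifier on the packaged census fixture
(`tcs census --fixture`) reproduces the published family sections:
5 CHK, 7 HK, 6 ETR, 10 HPT (6 HPT-H, 2 HPT-N, 2 HPT-X), 10 RRA (all
canonical), 32 RRB-group (17 canonical, 15 non-canonical) and 7 clock-RRs.

## Layout

```
src/tcskit/
  seqio.py        FASTA / domtblout / TSV / Newick I/O, census fixture
  align.py        Gotoh affine-gap alignment, projection, progressive MSA
  families.py     rule-based family classification, nomenclature
  phosphosite.py  phosphoacceptor mapping, variant classes, rate tables
  phylogeny.py    distances, neighbor joining, UPGMA, outgroup rooting
  genome.py       promoters, IUPAC motif scanning, tandem arrays
  expression.py   heat-map normalization, clustering, core module
  synthetic.py    ground-truth data generators
  references.py   packaged synthetic stand-in reference proteins
  pipeline.py     orchestration, config, reports
  cli.py          the `tcs` command-line interface
```

See `docs/methods.md` for the scientific assumptions, parameter choices
and known limitations.
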