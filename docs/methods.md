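# Methods

## Overview

`tcskit` annotates two-component-system (TCS) phosphorelay gene families —
the signaling backbone of cytokinin response in plants.  The relay passes a
phosphate along a His → Asp → His → Asp chain: a CHASE-domain histidine
kinase receptor (CHK) autophosphorylates a conserved histidine, transfers
the phosphate to the aspartate of its receiver domain, then to the
conserved histidine of a histidine phosphotransfer protein (HPT), and
finally to the conserved aspartate of a Type-B response regulator (RRB),
a Myb-domain transcription factor.  Type-A regulators (RRA,
receiver-only) provide negative feedback; clock-related regulators
(receiver-E + CCT) and Type-C regulators sit outside the cytokinin relay.
Annotation therefore hinges on two things: the *domain composition* of
each protein, and the identity of the *phosphoacceptor residue* inside
its Hpt or receiver domain.

## Family classification

Family membership is decided by a priority-ordered rule table over domain
names (`data/family_rules.yaml`): CHASE → CHK; ethylene-binding domain →
ETR; HisKA/HATPase without either → HK; sole Hpt → HPT; receiver + CCT →
clock-RR; receiver + Myb → RRB; receiver + transactivation without Myb →
Myb-less RRB-like; receiver alone → RRA (refined by nearest-reference
assignment when sequences are available).  Exactly one rule (or none)
fires per protein; an empty architecture is `unclassified`.

Canonicity then requires the family's functional motifs: an intact H-box
histidine and all four ATPase boxes (N, G1, F, G2) for kinases, plus a
receiver aspartate; H for HPTs; D for receiver families.  A Type-B
regulator is canonical when it carries the conserved D, a Myb domain and
a transactivation (C-terminal) domain; a transactivation domain shorter
than 100 aa is recorded as a separate `short_cter` flag but does not by
itself make the protein non-canonical — this matches how the family
census counts canonical Type-B regulators.  Missing required domains set
`truncated`; `canonical` and `truncated` are mutually exclusive by
construction.

Motif states come from two sources.  The packaged census fixture
(`data/mtruncatula_census.tsv`, a transcription of the published *M. truncatula*
census table) carries them directly in its domain strings.  For sequence
input, motif states are resolved by projection (below): kinase boxes are
five-residue consensus windows on the HK reference judged present when at
least 60% of the projected window matches — the literature states the
motifs exist but no detection criterion, so the 60% window rule is this
package's operationalization.

## Alignment and phosphoacceptor projection

Pairwise alignment is a three-state Gotoh global dynamic program with
affine gaps (a gap of length *k* costs `gap_open + (k-1)·gap_extend`;
terminal gaps penalized).  Defaults are BLOSUM62, gap open 11, gap extend
1 — community defaults; the source analysis does not state its alignment
scoring.  `X` scores 0 against everything and never counts as a motif
match.  Ties are broken deterministically (match over a gap in the
second sequence over a gap in the first), so outputs are platform- and
order-stable.  The implementation is checked in tests against exhaustive
alignment enumeration (lengths ≤ 6) and against an independent
affine-gap aligner on longer pairs.

The phosphoacceptor of a candidate protein is identified by aligning it
to a family reference with a documented phosphoacceptor coordinate and
reading the residue in the projected column.  Identification references
are the functionally documented exemplars (AHK4/CRE1 for kinases, AHP1
for HPTs, ARR1 for Type-B, ARR6 for Type-A); substitution-rate tables use
the in-genome references (the HPT reference with its H at position 77,
the Type-B reference with its D at position 64).  A projection landing in
a gap (e.g. a truncated protein) returns a gap result, not an error.
Pairwise projection to the reference is the default; a family-wide MSA
route exists through `progressive_msa` for sensitivity checks.

The progressive MSA aligns profiles along a UPGMA guide tree built on
alignment-score distances and then applies two leave-one-out refinement
rounds.  MSA accuracy on synthetic families is measured as sum-of-pairs
recovery of planted homologous residue pairs (the standard MSA accuracy
score); under the default synthetic conditions (divergence 0.1, indel
rate 0.02) recovery is ≥ 95%.  Columns exceeding a 50% gap fraction can
be removed before tree building; the 0.5 default is a declared
approximation of the published alignment-trimming step, whose settings
are not stated.

## Substitution-rate tables

For a family and its reference, every other occurrence of the expected
residue in the reference (e.g. every other H of the HPT reference; every
other D of the Type-B reference, such as D192) defines a comparison
position.  Each protein is aligned once; the site and all comparison
positions are projected and the projected residues binned (H/N/other for
HPTs; D/E/N/other for receivers).  Percentages are whole-percent values
over non-gap projections; gap projections are reported separately and
excluded from denominators.  Two pooling conventions are emitted, since
"x% of proteins substituted" is ambiguous: pooled protein×position cells,
and per-protein-any-position.  The relay signature — the phosphoacceptor
column more conserved than pooled comparison columns — is asserted on
synthetic families generated at study-like conditions.  The published
sequence sets behind the printed percentages are external supplementary
FASTA files; when supplied, `tcs phosphosite --proteins <fasta>` computes
the same tables on them.

## Trees

Distance trees stand in for full maximum-likelihood inference, which is
out of scope: pairwise p-distances over shared ungapped columns, Poisson
corrected (d = −ln(1−p), capped at 10), then canonical Saitou–Nei
neighbor joining with deterministic tie-breaking (lowest leaf-label pair)
and negative branch lengths clamped to zero with a warning.  NJ recovers
additive matrices exactly (tested against generated random additive trees
and an exhaustive least-squares topology search at six taxa).  Trees are
rooted on a designated outgroup at the midpoint of its pendant edge —
mirroring the published practice of rooting the HPT tree on an
*Ostreococcus tauri* HPT and the RR tree on ARR22.  Because the stand-in
is distance-based, only clade memberships are asserted (e.g. that two
HPT-X variants descended from a shared ancestor form one clade), never
branch supports.

## Promoters, motifs, tandem arrays

Promoters are the 2.5 kb immediately 5′ of the start codon (strand-aware,
reverse-complemented on the minus strand, truncated with a flag at contig
edges).  The cytokinin-response cis-element AGATHY (IUPAC: H = A/C/T,
Y = C/T) is counted with overlapping matches on both strands by default —
the published scan does not state strandedness, so the per-strand
breakdown is also available.  `N` in a sequence never matches.  The
scanner is checked against a naive O(nm) oracle.

Tandem duplicates are pairs of same-family genes on one chromosome with
at most `max_intervening` genes between them (default 10, a
synteny-tool-style convention; the publication used an online tool whose
threshold is not stated), chained into maximal arrays.  Block/WGD
duplication detection requires whole-genome collinearity and is out of
scope; block pairs can be supplied as annotations.

## Expression

Expression matrices carry log2 values with NaN for missing probes (never
zero-filled).  Heat-map normalization is per dataset block — independent
platforms are not comparable — with a piecewise-linear map sending the
block's (min, median, max) to (0, 0.5, 1); constant blocks map to 0.5.
Gene clustering is average-linkage agglomeration on Euclidean row
distances (the same engine as UPGMA), with block-median imputation (and
a warning) for missing values.  The "core" signaling module is, per
family in {CHK, HPT, RRB}, the gene with the highest median expression
over all supplied samples, ties broken by mean; median was chosen because
the published claim states the outcome ("most highly expressed") but not
the statistic, and median is robust to single-sample spikes.  The union
of all supplied datasets is the default sample set; per-dataset results
can be obtained by subsetting columns.

## Synthetic data and references

Real curated reference proteins are not shipped; the packaged references
(`data/synthetic_references.fasta`, built deterministically by
`references.build_reference_set`) are constructed stand-ins that carry
the documented coordinates — H77 and four comparison histidines in the
HPT reference, D64 plus comparison aspartates including D192 in the
Type-B reference, and fixed H-box/N/G1/F/G2 windows in the HK reference.
Their background alphabet excludes H, N and D so the placed residues are
the only occurrences.  Analyses of real proteomes should substitute
curated references through the same `ReferenceSet` interface.

The generators emulate: protein families as point-mutated descendants of
a reference consensus (per-site divergence, motif windows frozen), with
the phosphoacceptor substituted at probability *q* from a family-typical
spectrum (H→N 0.55 / R 0.25 / other 0.20 for HPTs; D→E 0.70 / N 0.17 /
other 0.13 for receivers — the variant spectra the relay literature
reports, with E and N dominating); optional short indels (1–3 aa) for
alignment stress-tests; toy genomes with planted consecutive tandem
arrays and promoters carrying exact planted motif counts on a background
screened free of accidental matches (both strands); and block-structured
expression with cluster-specific "on" sample blocks (gap 8 log2 units,
noise SD 0.5) and one dominant gene per family raised 3 log2 units.
Identical seeds give byte-identical output.

What synthetic tests do *not* show: real families have rate heterogeneity
across sites, realistic indel processes, paralog-specific domain decay
and annotation noise, none of which the generators model.  Passing
recovery tests therefore demonstrates correctness of the statistical
machinery, not performance guarantees on real proteomes.

## Problem sizes and numerical choices

Tests run at the scales the analyses describe: families of 78 (HPT-like)
and 138 (RRB-like) members for substitution tables, n = 400 for
binomial-recovery checks, 200 enumeration-oracle alignment trials, 1000
random sequences for the motif-scanner oracle, and 100 random additive
trees (≤ 8 taxa) for NJ recovery.  Floating-point ties in the alignment
traceback are resolved with a 1e-9 tolerance; distance matrices must be
symmetric to 1e-8; saturated Poisson distances cap at 10.

## Known limitations

- Maximum-likelihood trees, branch supports and model selection are not
  implemented; distance trees are a documented stand-in.
- Type-C assignment uses nearest-reference similarity to the ARR22
  exemplar, an approximation of the published phylogenetic criterion.
- The nomenclature numbering for genes without published aliases follows
  chromosomal order and is provisional.
- BLAST-based candidate discovery and HMMER itself are out of scope:
  candidate sets and domain tables are inputs.
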