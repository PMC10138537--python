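# ctmarker

Analysis toolkit for a single-locus natural-transgene (cT-DNA) marker in a
polyploid plant genus: phasing marker alleles from heterozygous Sanger
consensus sequences, summarizing allele diversity and zygosity, building
per-species consensus sequences with optional hybrid-allele exclusion,
reconstructing distance and maximum-likelihood phylogenies, and predicting
PCR products and open reading frames on the marker reference.

## The scientific problem

Some plant lineages carry agrobacterial T-DNA fixed in their nuclear
genome (cellular T-DNA, cT-DNA). Such an insert marks a founder event, does
not multiply into paralogs, and accumulates substitutions and indels over
time — which makes a *rolB/C*-like cT-DNA gene an attractive single-copy
nuclear marker for a genus such as *Vaccinium* (blueberries, cranberries,
lingonberries), where hybridization and polyploidy confound the classical
ITS/matK barcodes.

The practical obstacle is that Sanger sequencing of a heterozygote yields a
single consensus in which every heterozygous position appears as an IUPAC
ambiguity code (R, Y, S, W, K, M, ...). Before any phylogenetics, the
individual alleles must be reconstructed from these ambiguous consensus
sequences — the *phasing* problem this package solves combinatorially.

## The core procedure

Within a species, each biallelic polymorphic alignment column is ranked by
base frequency: writing **1** for the species-major base and **0** for the
minor base, a sample becomes a string over {1, 0, H}, where **H** marks an
ambiguous (heterozygous) position covering both states. Phasing is
Clark-style parsimony:

1. **Seeding.** A sample with no H site *is* an allele; a sample with
   exactly one H site yields both of its resolutions. These form the
   primary allele pool.
2. **Complementary pairs (diploids).** A pool allele *a* consistent with a
   sample implies the partner `comp(a)` carrying the alternative value at
   every H site; the pair is assigned and `comp(a)` joins the pool. Passes
   repeat to a fixpoint.
3. **Minimal explanations (tetra-/hexaploids).** The smallest subsets of
   the pool that cover every H site with both values; dosage is not
   inferred (a Sanger trace carries none).

Samples with no explanation, or several equally parsimonious ones, keep an
explicit `unresolved`/`ambiguous` status — the genotypes that would be
cloned and re-sequenced in the wet lab. Downstream, allele frequencies and
zygosity are tabulated per species, intra- vs interspecific variability is
compared (the marker is phylogenetically useful only if the former is
smaller), and trees are built with NJ/BioNJ starting trees, TN93 distances,
and a GTR maximum-likelihood search (site-coverage filtering at 95%,
branch-length optimization, NNI hill-climbing).

A ground-truthed synthetic-data generator (Yule species tree, GTR
substitutions, frame-preserving indels, star-shaped within-species allele
pools, polyploid genotypes, Sanger-style consensus rendering including
unreadable heterozygous-indel traces) emulates the study design so every
stage is testable end to end. Because the real reference contig cannot be
bundled, in-silico PCR and ORF checks run against a *synthetic* reference
fragment that reproduces the published geometry: three primer pairs with
product sizes 1503, 1002 and 838 nt around an 876-nt (292-codon) CDS.

## Worked example

```bash
python examples/01_phase_a_species.py
```

prints (abridged):

```
13 polymorphic sites at columns [85, 124, 215, 259, 319, 376, 416, 427, 433, 455, 571, 777, 784]

sample      pattern            alleles
spX_h01     1011111010101      A/A
spX_h05     1111100111011      B/B
spX_r01     1HH1111HHH1HH      A/C
spX_r03     11H11HH1H1H1H      C/B
...
20/20 genotypes match the simulated truth
```

Each pattern row is one genotype over the 13 polymorphic sites (1 =
species-major base, 0 = minor, H = heterozygous IUPAC position); the
alleles column is the reconstructed pair, named A, B, C... by decreasing
frequency. On this panel every genotype is resolved and matches the
generator's ground truth. The other examples cover the population summary
and variability comparison (`02`), ML tree recovery (`03`), and in-silico
PCR / ORF / deletion-span calls (`04`).

The same stages are scriptable from the shell:

```bash
ctmarker simulate --n-species 6 --seed 1 --outdir sim/
ctmarker run --alignment sim/samples.fasta --metadata sim/samples.tsv --outdir sim/run
ctmarker pcr --template reference.fasta
```

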