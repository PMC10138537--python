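# Methods

This note documents the models, conventions and design choices behind
`ctmarker`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic experiments do and do not show.

## Coordinates and alphabets

All coordinates are 1-based and inclusive ("nucleotides 198 to 800" means
exactly those bases). The only gap character is `-` (`.` is rejected with a
message); `U` is converted to `T` on input; residues are upper-cased and
restricted to the IUPAC nucleotide alphabet. An ambiguity code is read as
the set of bases it denotes; `N` is treated as *missing* wherever bases are
counted (site discovery, coverage filtering, consensus voting), because a
four-way observation carries no allele information and would otherwise
manufacture spurious polymorphism.

## Polymorphic sites and the binary representation

Site discovery is per species by default (variability is defined relative
to a species' own allele pool); a joint scan over all samples is available
by omitting the sample subset. Base counting expands IUPAC codes — a
heterozygote contributes one observation to each covered base. Columns
containing alignment gaps are excluded from SNP discovery (length variation
is the indel catalogue's job), as are columns with more than two observed
bases: the 1/0/H representation is biallelic by construction, so
multi-allelic columns are counted and reported but not encoded. A
major/minor frequency tie is broken alphabetically, with a warning, so
output is deterministic. In a sample, a base covering neither major nor
minor (a third allele, a gap, or N at the site) masks that site for that
sample (`X`); masked sites impose no constraint during phasing.

## Phasing

The diploid resolver is Clark parsimony with the complementary-pair rule: a
pool allele consistent with a pattern implies the partner with flipped
values at every H site. Clark's procedure is order-dependent, so the
processing order is fixed: fewest H sites first, ties by sample id.
Homozygous patterns always resolve to a self-pair (they are the seeding
material). In each pass only samples whose explanations against the current
pool reduce to exactly one distinct pair are resolved; the pool only grows
and alleles are never mutated. Samples explainable by several pairs end
`ambiguous` with all candidate pairs listed; samples with none end
`unresolved`. Ambiguity is reported, never silently broken — these statuses
are the in-silico counterpart of the wet-lab cloning fallback.

For tetra- and hexaploids the resolver searches subsets of the pool of
increasing cardinality (bounded by ploidy) whose value sets match the
pattern at every site; all minimal explanations are retained. Dosage within
a genotype is not inferred: a Sanger consensus shows which bases are
present, not how many chromosome sets carry each, so polyploid genotypes
are reported as distinct-allele sets. The polyploid search is validated
against plain subset enumeration in the test suite.

Allele naming is per species, letters A, B, C... by decreasing frequency
(diploids contribute their full multiset, a homozygote counting twice;
polyploids one presence per carrier — a documented bias, since dosage is
unknowable). Full allele sequences are realized by substituting each site's
major/minor base into the species backbone (the column-majority consensus
of that species' readable samples).

## Population summaries

* **Frequencies** use the counting rule above, only over resolved samples.
* **Variability**: mean pairwise p-distance among alleles within species
  (species with one allele contribute nothing) versus between species;
  sites where either sequence has a gap or ambiguity are excluded pairwise.
  The marker is fit for phylogenetics when intra < inter.
* **Hybrid flags** (advisory, never auto-applied): an allele is flagged iff
  every nearest neighbor belongs to a different species *and* that distance
  is strictly below its own species' mean intra-allele distance. Species
  with a single allele define no threshold and are never flagged. Note that
  when a foreign copy is identical to a native allele, both members of the
  pair sit closer to each other than to their own kin, so the donor copy
  can be flagged too — the flag marks the pair for inspection, it does not
  decide directionality.
* **Consensus**: column-majority over included alleles; base ties give the
  IUPAC code of the tied set; a strict majority of gaps gives a gap (bases
  win a base/gap tie).

## Phylogenetics

Columns with less than 95% site coverage are removed first; coverage counts
unambiguous A/C/G/T only, i.e. gaps *and* ambiguity codes are missing data
(the "partial deletion" convention of the standard desktop tools).

Starting distances are TN93 by its closed form (pairwise deletion;
frequencies pooled from the pair). TN93 stands in for composite-likelihood
distances whose exact definition varies between tools; at the small
divergences this marker shows the difference is negligible. Saturated pairs
(non-positive logarithm argument) are reported at a flagged large value
(10 substitutions/site) rather than raising.

NJ follows the Saitou–Nei Q-criterion; BioNJ additionally propagates
variance estimates and picks the variance-minimizing reduction weight. Ties
in the Q matrix are broken by the lexicographically lowest cluster-label
pair, so both builders are deterministic; on an additive matrix both
recover the generating topology and branch lengths exactly (this is
asserted to 1e-9 in the tests). Negative branch-length estimates are
clamped to zero on output (the raw values still drive the reduction).

The GTR model is parameterized by six exchangeabilities and four
stationary frequencies, with the rate matrix rescaled to mean rate one so
branch lengths are expected substitutions per site. Transition matrices
come from one symmetric eigendecomposition per parameter set (cached).
Likelihoods use Felsenstein pruning with per-node rescaling; ambiguous tip
bases enter as partial likelihoods over their IUPAC set, gaps as fully
missing. Time-reversibility makes the likelihood invariant to root
placement (tested to 1e-8). No rate heterogeneity across sites is modeled.

The ML search estimates base frequencies empirically and the five free
exchangeabilities (one fixed at 1) by L-BFGS-B on a log scale on the NJ
starting tree, then for each start (NJ and BioNJ) optimizes branch lengths
by bounded per-branch Brent iteration (tolerance 1e-6, lengths in
[1e-9, 5]) and hill-climbs through nearest-neighbor interchanges, accepting
the first move that improves the likelihood and terminating at a local
optimum; the higher-scoring start wins, so the final likelihood is never
below either starting tree's. With fewer than four taxa the topology is
forced and the NJ tree is returned with optimized branch lengths.

## The synthetic-data generator

The generator emulates the study's structure, not any particular dataset:

* **Species tree**: pure-birth (Yule), ultrametric, waiting time Exp(kλ)
  with k lineages; expected root height Σ_{k=2..n} 1/(kλ) (used as the
  Monte-Carlo oracle in tests). Default 8 species, λ = 1.
* **Marker**: 876 nt (the CDS length of the real marker), evolved under
  GTR (uniform defaults; no rates are published for the locus). The tree
  is rescaled so root-to-tip divergence is `subst_rate` (default 0.02
  substitutions/site), putting typical interspecific p-distances at a few
  percent — the regime the marker shows in real data.
* **Indels**: Poisson(0.3) events per branch, deletion or insertion with
  equal probability, lengths 3×Geometric(0.5) so every indel is
  frame-preserving, mirroring the observed "multiples of three" pattern
  that argues for a functional product. Indels are tracked in
  root-anchored master coordinates, so all ground-truth alleles stay
  co-aligned and every downstream stage can be checked by column scans.
* **Within-species alleles**: each of the (default 4) alleles adds
  max(1, Poisson(1.5)) private substitutions at columns not previously
  mutated within that species — a star-shaped, infinite-sites-style model.
  This is an assumption, not an observation: the real generative process
  of within-species variation is unknown. A useful consequence is that
  each heterozygote's pattern is explainable by exactly one allele pair,
  which makes the phasing-recovery experiments exact rather than
  probabilistic.
* **Genotypes**: per species, allele frequencies drawn from a flat
  Dirichlet; each sample draws `ploidy` alleles, and with probability
  `selfing` (default 0.3) one draw fills the whole genotype, raising
  homozygosity. Ploidies cycle through 2/2/4/2/6/... across species unless
  given explicitly, mirroring a genus that is mostly diploid with tetra-
  and hexaploid members.
* **Deletion alleles**: with probability 0.1 per species, one full-span
  allele receives a configured large CDS deletion (default 198–800,
  603 nt), mimicking the mutated marker copies seen in swamp cranberry.
* **Sanger rendering**: agreeing columns give the base, substitution
  heterozygosity the IUPAC code; a column where some alleles have a base
  and others a gap marks a heterozygous indel, after which the
  electropherogram is uninterpretable — everything downstream is rendered
  `N` and the sample flagged unreadable (the pipeline sets such samples
  aside as cloning-needed).

What passing tests on this generator do **not** show: performance under
recombination within the marker, gene conversion, sequencing error,
alignment error (inputs are assumed correctly aligned), non-star
within-species genealogies, or paralogy — none of which the generator
produces.

## Experiment sizes and numerical conventions

The recovery experiments are sized for a desktop run: phasing recovery
uses 20 samples over 5 alleles; NJ exactness 100 random 4–8-taxon trees;
the likelihood oracle 4-taxon/2-site toys (exhaustive sums over 4^2 to 4^3
internal states); ML recovery one 6-taxon tree with 2000 sites, rescaled
to root-to-tip height 0.3 with internal branches floored at 0.02
substitutions/site so the topology is identifiable from that many sites
under any seed; the variability comparison 20 replicate simulations at the
default configuration. Pairwise alignment for indel calling uses affine
scores (match +1, mismatch −1, gap open −10, extend −0.5) chosen so one
biological indel appears as one gap run; the largest deletion of a sample
is additionally slid rightward through repeat-equivalent placements so a
terminal truncation is reported as reaching the end of the gene.

The published product sizes checked by the PCR stage (1503 / 1002 /
838 nt) and the CDS geometry (876 coding nt = 292 codons; the stated CDS
length excludes the stop codon, and both conventions are exposed as
`OrfRecord.length` vs `OrfRecord.coding_length`) are embedded in a
*synthetic* reference fragment constructed from the published primer
sequences, because the real genome contig cannot be bundled. Checks
against it validate the machinery on the published geometry; they are not
a re-measurement of the real accession.

## Known limitations

* The pipeline consumes pre-aligned consensus sequences; no multiple
  alignment is performed.
* Polyploid dosage is never inferred; frequency tables for polyploids are
  presence counts.
* The hybrid-allele flag is a heuristic operationalization of a judgment
  the original analyses made narratively; it is advisory only.
* No bootstrap support, Bayesian inference, model selection, or rate
  heterogeneity in the ML stage.
* Short-read (NGS) phasing is out of scope; the package covers the
  combinatorial Sanger route only.
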