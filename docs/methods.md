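# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Genomic-context classification

Each assembled transcript is compared against the reference annotation
(assumed to contain protein-coding genes only) and assigned exactly one
code with this precedence:

1. any same-strand exonic overlap with a reference transcript →
   *sense overlap* (excluded from lncRNA candidacy; this collapses the
   full-match and partial-match codes of transcript-comparison tools, since
   the cascade only ever discards them);
2. otherwise, any opposite-strand exonic overlap → `x` (antisense);
3. otherwise, span fully contained within a single reference intron, on
   either strand → `i` (intronic);
4. otherwise → `u` (intergenic).

Intron containment is tested against references on *either* strand: `x` is
defined by exonic overlap only, so after step 2 no strand collision is
possible and the three retained codes partition the candidates.  Whether
same-strand-only intron containment is wanted instead is a known ambiguity
of the upstream tools; the either-strand choice is explicit here and
recorded per transcript.  Transcripts with strand "." are accepted at parse
time but excluded from classification (the codes are strand-defined) and
logged.

Coordinates are 1-based inclusive throughout (GTF convention); the BED-like
TE track is converted from 0-based half-open exactly once, at the parser
boundary.  A transcript's span is [min exon start, max exon end].

## Filter cascade

Candidates with codes u/i/x pass six criteria in order: (a) exonic length
≥ 200 nt and ≥ 2 exons; (b) no coding call from *either* CPC or CNCI — the
conjunctive reading of "no or weak protein-coding potential based on both
tools"; (c) longest ORF < 300 nt; (d) no BLASTX hit (SwissProt, E ≤ 1e-3);
(e) no Pfam hit (E ≤ 1e-3); (f) RPKM_max ≥ 1.0 across all samples
(per-sample RPKM first, then the maximum).  Criteria b–e are independent
predicates, so their order affects only the per-stage survivor counts, not
the final set; the stage report records both.

ORF convention: an ORF opens at ATG in any of the three forward frames;
its length includes the stop codon, and a stop-less ORF extends to the last
complete codon and still counts.  This is the conservative choice — a
3'-truncated coding fragment is still discarded — and it makes the length
exactly testable.  External-tool verdicts (CPC/CNCI/BLASTX/Pfam) are
consumed as boolean tables; a transcript absent from the table carries no
evidence of coding.

Survivors map u → lincRNA, i → ilncRNA, x → lncNAT.  Report percentages are
rounded half-up to two decimals.  (One published percentage of the kind
this reproduces, 461/9875 printed as 4.66, is truncated rather than
rounded; the formatter here rounds, and the one-cent discrepancy is noted
rather than replicated.)

## Expression and tissue specificity

RPKM = 10⁹ · C / (N · L) with C the read count, N the library size (total
mapped reads) and L the exon-model length.  Replicates are averaged within
their group; specificity is scored on the gene × group matrix of mean RPKM.

* **JS score**: normalise the profile to a probability vector p; for each
  group t compute the Jensen-Shannon divergence against the one-hot
  indicator δ_t with base-2 entropies, JSD(p, δ_t) = H((p+δ_t)/2) − H(p)/2;
  the score is max_t [1 − √JSD].  It is 1 exactly on one-hot profiles and
  ≈ 0.442 / ≈ 0.140 on uniform profiles over 2 / 9 groups.
* **tau**: Σ_i (1 − x_i/max) / (n − 1); 0 on uniform, 1 on one-hot rows.

Both are scale-invariant and computed on linear mean RPKM by default,
following the JS score's original construction; a log2(x+1) option exists
because the tau benchmark literature often log-transforms.  All-zero rows
score missing and are excluded from distribution comparisons.  Expression
tiers follow RPKM_max: low < 5.0 ≤ moderate < 50.0 ≤ high (boundaries
inclusive on the upper tier).  The threshold defining "highly
tissue-specific" is not a published constant; the default is JS ≥ 0.95 and
it is configurable — downstream counts are not treated as reproduction
targets.  lncRNA-vs-PCG score distributions are compared with the
two-sample two-sided Kolmogorov-Smirnov test.

## Genomic features and TE overlap

Transcript length is the exon-length sum; GC content excludes N and
ambiguity codes from the denominator.  Splice-site matrices tally
strand-corrected base frequencies over a window of `flank` exonic plus
`flank` intronic positions at each donor and acceptor; the canonical
fraction counts GT...AG boundary dinucleotides in transcript orientation.

TE overlap is **exon-based** by default: a feature overlaps a TE iff any
exon shares ≥ 1 bp with any TE record.  The span-based alternative (which
also counts intronic TEs) is available by flag; the published analyses do
not state which was used, so both are provided and the stricter,
transcript-sequence-relevant mode is the default.  Enrichment between two
feature classes uses the two-sided Fisher exact test on the overlap /
non-overlap 2×2 table.  TE-class composition counts each overlapped TE
record once per (feature, record) pair — the tallies describe TEs, not
features.

## Sex bias

Differential-expression tables are consumed, never fitted.  A feature is
biased when adjusted p < 0.05 and |log2FC| ≥ 1.0; the inclusive boundary
follows the procedural description (the results prose uses "> 1"; a strict
flag reproduces that variant).  Rows with missing adjusted p are excluded.
Male-bias enrichment of lncRNAs relative to PCGs uses the conditional
two-sided Fisher test on [[PCG male, PCG female], [lnc male, lnc female]];
a zero margin yields p = 1 by convention.

## Conservation and synteny

BLASTN is run externally; the package summarises outfmt-6 tables at E ≤
1e-3 and E ≤ 1e-10, counting each query (and, for lncRNA targets, each
subject) once.  Counts at the strict cutoff can never exceed the loose
ones, and relative decreases are reported as round-half-up percentages.

Synteny families: a locus's neighbourhood is its three nearest PCGs on each
side by genomic coordinate, strand-agnostic; a PCG overlapping the locus is
assigned to the side of its midpoint.  Two cross-species loci pair when
their neighbourhoods share ≥ 3 distinct ortholog groups (tandem duplicates
collapse to one group, preventing paralog inflation) with ≥ 1 shared group
on each side in *each* species.  An `allow_inversion` flag relaxes the side
requirement to one species, for locally inverted or fragmented
neighbourhoods; it is off by default because the strict rule is the quoted
one.  Families are connected components of the accepted-pair graph;
singleton loci form no family.

## Neighbour pairs, cis candidates, GO

Pairs join an anchor with every PCG whose span lies within 10 kb
(intervening bases, inclusive) or overlaps it; PCG–PCG control pairs use
the same rule with self-pairs excluded.  Pearson correlation uses
replicate-averaged group means over all 14 groups — the sample-level
(21-sample) alternative is supported, but group means match the JS
convention and are the default.  Cis candidates require |PCC| strictly
> 0.5.  Strata (all / overlapping / non-overlapping / overlapping-same /
overlapping-opposite) are compared with the two-tailed Wilcoxon rank-sum
test.  GO enrichment is the hypergeometric upper tail per term over the
declared background, BH-corrected; q < 0.05 marks significance.

## Statistical kernels

Wilcoxon rank-sum uses midranks; for combined n ≤ 20 the two-sided p is an
exact enumeration over all rank subsets (the fraction of assignments at
least as far from the null mean as observed), otherwise the tie-corrected
normal approximation with continuity correction.  Fisher's exact test sums
hypergeometric probabilities ≤ the observed table's (margins fixed) and
reports the sample odds ratio ad/bc.  Chi-squared uses no continuity
correction, df = (R−1)(C−1).  Pearson p comes from the t distribution with
n−2 df.  BH is the standard step-up with a cap at 1.  Every exact mode is
checked against an in-test enumeration oracle.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *downstream structure* of the kind of study
this pipeline serves: three 400-kb chromosomes per species at GC 0.38
(moth-like), 40 PCGs per chromosome with 2–6 exons and canonical GT...AG
introns, and planted candidates of every fate — true u/i/x lncRNAs, coding
decoys (a built-in ≥ 366-nt ORF plus coding-evidence flags), sub-200-nt and
monoexonic decoys, low-abundance decoys (counts clamped so RPKM_max < 1),
and sense-overlap decoys.  The expression design hard-codes the 14-group /
21-sample layout (Ag, Ma, Fa, Tes, Ov, Mhd, Fhd, Mmg, Fmg tissues; E1, E4,
L5, FP, AF stages; sex-matched tissues with two replicates).  Counts are
negative-binomial around RPKM·L·N/10⁹ (dispersion 0.05 by default; 0 gives
deterministic rounding for exact tests).  Profile types are housekeeping
(lognormal around 15 RPKM), tissue-specific (one dominant group at 20–80
RPKM), testis-biased, and explicitly sex-biased PCGs (testis- or
ovary-elevated 4×) so the male-bias Fisher test has a realistic PCG
background.  Planted neighbour pairs share a lognormal latent whose mixing
weight is solved so the *linear*-scale correlation hits the target ρ
(the lognormal transform otherwise attenuates it).

Species B is a block-preserving shuffle of species A's gene order with 1:1
orthology.  Conserved lncRNAs sit in block-interior gaps chosen *first*,
with every other planted locus kept ≥ 4 gene slots away — this guarantees
the planted pairs are exactly the recoverable ones, because two
neighbourhoods four slots apart share at most two ortholog groups.
Rearranged and species-B-only loci are placed in gene-free chromosome
margins, where no flanking orthologs exist and no pair can be accepted.
Problem sizes (120 PCGs, 60 true lncRNAs, 10 conserved families, 8 + 8
planted correlation pairs at genome level, 200 pairs at profile level, 500
genes per class for specificity separation) were chosen as the smallest
sets on which the planted contrasts are statistically unambiguous; a full
fixture generates in about one second.

What the generator does **not** emulate — and hence what green tests do not
show about real data: transcript-assembly artefacts (fragmented or merged
models), read-level noise and mapping bias, non-canonical splice sites,
overlapping gene models, paralogy beyond tandem duplication within
neighbourhoods, genuine TE sequence (TE records are intervals, not
repeats), and count-model misspecification in the consumed DE tables.
Recovery rates on planted truth are upper bounds on real-data performance.

## Degenerate inputs and tie-breaks

All-zero expression rows score missing; zero-variance vectors make Pearson
undefined (pairs are excluded from distributions; the shared kernel raises
instead, since a zero-variance input there is a caller error).  Equal-sized
chromosomes make the count-vs-size correlation undefined and it is skipped.
Empty TE tracks yield all-false flags with the enrichment test skipped.
`tissue_of_max` uses the first maximal group in column order (a tie is
broken deterministically).  Percentages are rounded half-up via decimal
arithmetic, never binary-float rounding.
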