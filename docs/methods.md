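# Methods

This note documents the models and procedures implemented in `mhc-deme-kit`:
what the synthetic metapopulation generator emulates, how each analysis
stage works, the tunable parameters that matter, and the numerical and
design choices that were genuinely open.

## The study design being modelled

House mice live in demes — small, partially isolated breeding groups (one
farm each) — within larger regions. MHC class II loci (H2-Aa and H2-Eb,
exon 2) segregate two kinds of alleles in such a metapopulation: a set of
*shared* alleles found across regions (and often across subspecies), and a
larger set of *region-specific* alleles confined to single regions or even
single demes, generated mostly by recombination or partial gene conversion
between existing alleles rather than by new point mutations. The toolkit
implements the two survey designs used to establish this picture — a
species-wide 454-style amplicon survey with strict allele validation, and a
deme-level diploid typing design combining direct (Sanger-style)
sequencing with Illumina-style re-sequencing — plus the population-genetic
and recombination statistics that characterize the deme structure.

## Synthetic metapopulation generator (`synthdata`)

The generator produces every input the analyses consume, with ground truth
attached, so each downstream stage is testable without external data.

**Allele pool.** Each locus gets a random stop-free coding base sequence
(exon windows 208 bp for H2-Aa and 231 bp for H2-Eb). Ancestral alleles are
generated along a genealogy: each new allele derives from a random existing
allele by mutating 5–9 previously unmutated positions (infinite-sites
style). The ancestral pool is therefore tree-compatible and carries no
four-gamete signal — the minimum-recombination statistic downstream
responds only to the recombinant alleles, which is the property the
analysis is supposed to detect. Regional allele frequencies are drawn from
a Dirichlet (concentration 3 per allele), giving each region a few common
and several rare alleles.

**Demes as extended family groups.** Each deme is founded by 1–3 mating
pairs; offspring (one to two generations) fill the deme to a target size
drawn from 6–14. The target size is drawn independently of the founder
count so that sample size and allele count are not structurally coupled —
important for the sampling-correlation analysis below. This pedigree yields
the elevated within-deme relatedness (microsatellite Queller–Goodnight
means of roughly 0.2–0.6) and deme differentiation that the real demes
show, without a full coalescent model.

**Region-specific recombinant alleles.** With probability 0.6 a deme
receives 1–2 novel alleles, each created from two ancestral donors either
by a single crossover (uniform breakpoint) or by a gene-conversion tract
(20–100 bp, uniform placement), rejecting products with internal stop
codons or collisions with existing alleles. Recombinants are injected into
one or two deme members after breeding (recent-origin alleles at low copy
number, as observed: most region-specific alleles occur once or twice).
All donors and breakpoints are logged, so every recombinant is exactly
reconstructable from the event log.

**Migration.** Each individual migrates with probability 0.03, mostly
(80%) within its region. This produces the occasional cross-deme sharing
of otherwise deme-private alleles and mtDNA haplotypes.

**Neutral markers.** Ten unlinked microsatellites evolve by stepwise
mutation (rate 0.005/transmission, ±1 repeat) along the deme pedigree from
regional founder pools; mtDNA haplotypes are drawn by founding females from
a regional pool of five and inherited matrilineally. Haplotype pools are
disjoint between regions, mirroring the observed absence of cross-region
D-loop sharing.

**454-style survey reads.** Per individual, locus and primer pair (four
pairs, one independent amplification each), template molecules are drawn
from the two alleles at the amplification-bias ratio (uniform in 1–5). A
`chimera_rate` fraction (default 0.1) of templates are single-switch-point
PCR chimeras of the two alleles — the incompletely-extended-primer
mechanism — with the switch point uniform over the amplicon and logged.
Each read is its template with: one-base indels per homopolymer run of
length ≥ 3 (probability 0.02 per run), substitution errors (10⁻⁴ per
base — with quality filtering, amplicon pyrosequencing error is dominated
by homopolymer indels), two-state per-base qualities (Q38/Q12), N emission
at bad-quality bases, whole-read low-quality events (5%) and truncations
(3%). Reads carry a 10-bp MID tag and the primer sequences; half are
emitted reverse-complemented. Errors are applied to the exon insert;
tag/primer bases are error-free, so demultiplexing is exact arithmetic
(tag errors would only change yield, never the statistics under test).
The study gives no quantitative error or chimera rates; all of these are
prominently configurable `SimConfig` fields.

**Direct + Illumina-style data.** The direct-sequencing surrogate is the
position-wise IUPAC consensus of the two alleles with per-site peak
metadata (major base, ratio = bias). At bias ≥ 9:1 the minor allele drops
out of the consensus entirely — the "poor amplification of one allele"
failure mode that creates direct/short-read conflicts. Short reads
(5200–7000 per individual × locus, substitution rate 10⁻³) are drawn with
the same bias, stored as encoded base matrices for speed.

**Determinism.** All randomness flows from per-purpose streams (pedigree,
alleles, recombinants, migration, markers, chimeras, errors, Illumina)
spawned from the master seed, so identical config + seed reproduces every
output byte-identically and changing one rate does not perturb unrelated
draws.

What the generator does *not* model: 454 flow-space signal, chromatogram
traces, PCR efficiency differences between primer pairs, context-dependent
substitution spectra, linkage between the two MHC loci, and selection.
Passing tests therefore demonstrate the correctness of the algorithms
under the stated error models, not performance on any particular real
dataset.

## Survey calling (`survey_calling`)

Reads are filtered (mean quality > 25, length > 200 bp, no Ns — strict
inequalities, read literally from the protocol), demultiplexed by exact
10-bp MID match after orientation detection (exact matching: the tags are
designed for it), trimmed of primers and configured intron margins, and
assigned to the locus of their best-identity reference (edit distance via
edlib). Assignments are flagged ambiguous when the best and second-best
locus identities differ by < 2% (paralog risk), and dropped below an 80%
identity floor.

**Homopolymer correction.** Each read is globally aligned to its closest
reference with mismatch cost well below gap cost (0/−1/−4.5
match/mismatch/gap), so that divergent sites always align as substitutions
— with references tens of substitutions away from a read's true allele, a
cheaper gap penalty lets the aligner realize clusters of mismatches as
compensating indel pairs and corrupts the read. Equal-length reads skip
alignment entirely (they cannot carry a net indel, and per-template indels
come in ±1 events). Single-base gaps inside reference homopolymer runs of
length ≥ 3 are reverted to the reference run length; substitutions are
never altered; reads with other gaps are dropped from full-length support.
This is a deterministic proxy for the original study's manual editing of
platform-typical errors.

**Validation.** Corrected full-length reads are grouped into candidate
alleles. A candidate is accepted iff (it occurs in ≥ 2 amplifications with
different primer pairs within one individual, OR in ≥ 2 individuals) AND
≥ 2 unedited raw reads match it exactly.

**Chimera screen.** The replication rule alone cannot exclude chimeras at
high chimera rates: a chimera of alleles A and B differing at d sites
falls into one of only ~2(d−1) sequence classes, so identical chimeras
recur across independent amplifications and across relatives sharing the
genotype {A, B}. The screen exploits diploidy: within each individual and
locus, taking the top candidate by read count as one parent, any other
candidate that some supported candidate (≥ 2 reads) completes as a
single-crossover hybrid has that individual's support discarded. A true
recombinant allele can never be flagged this way — it cannot co-occur
with both of its donors in one diploid individual at one locus, and one
can show that neither a chimera nor a point-error variant of the true
second allele can make the true allele itself appear as such a hybrid.
This is the same defense used by dedicated MHC amplicon pipelines and is
on by default (`chimera_screen=False` restores the bare replication rule).
In end-to-end runs at chimera rate 0.1 the screen keeps the catalog free
of chimeric sequences while recovering all alleles carried by two or more
individuals. Residual catalog impurity consists of point-error variants
that recur in two individuals by chance (~10–25% of entries at the default
substitution rate); replication-based validation is intrinsically
depth-limited against those, which mirrors the original protocol's
reliance on manual curation for substitution errors.

**Classification.** Validated alleles are classified against the known
catalog: status known/new by exact sequence; non-functional when the
translation hits a premature stop or the length change breaks the frame;
silent when the encoded peptide equals that of a *different* catalog
allele (exon-only windows carry no non-coding positions, so "silent" is
interpreted at the protein level); else normal.

## Deme typing (`deme_typing`)

**Phasing by catalog subtraction.** Heterozygous positions are the
two-base IUPAC codes of the direct consensus (≥ 3-base codes mark the read
unusable). Every catalog allele consistent with the consensus implies a
complement haplotype by subtraction at the het sites; subtraction is an
involution, so phasing is exact whenever a unique consistent pair exists.
Zero het sites give a homozygous pair; one het site phases trivially.
Distinct consistent pairs are ambiguous unless the peak-ratio tiebreak —
one haplotype carrying the taller-peak base at *every* het site — singles
one out (peaks are a secondary criterion only, as in the original
protocol).

**Short-read calling.** Individuals with > 5000 reads (strict) are called:
reads are subsampled to 500 (all-pairs distances on thousands of reads buy
nothing), pairwise Hamming distances feed a UPGMA tree cut at the root
into two groups. Two alleles are reported when the between-group mean
distance exceeds 3× the within-group mean AND, after reassigning every
read to its nearer consensus, the minor cluster holds ≥ 2% of reads;
otherwise one. The 3×/2% thresholds are free parameters (the protocol
says only "checked whether one or two clusters were present"); they were
chosen to separate the bimodal heterozygote geometry (between-cluster
distance ≈ allele divergence ≫ within-cluster error distance) from
homozygote noise, and are validated against simulator truth down to 20:1
amplification bias.

**Consolidation.** Agreement between routes gives support `both`. A
direct-only allele found verbatim in ≥ 10 raw short reads is promoted to
`both` (rescue of a very poorly amplified allele; the count is a free
parameter). A second short-read cluster reveals the allele hidden by
direct-sequencing dropout (`shortread_only`). Individuals with no
short-read verification and no known allele extractable from the direct
sequence are excluded as unphasable; full disagreement without rescue is
excluded as a conflict. Calls never contain alleles outside the union of
the two evidence sets, so errors can only under-count alleles — matching
the deliberate bias direction of the original consolidation.

## Population genetics (`popgen`)

* Heterozygosities: h_obs = fraction heterozygous; h_exp uses Nei's
  unbiased correction 2n/(2n−1)·(1−Σp²); effective allele number 1/Σp².
* Hardy–Weinberg: exact conditional test on allele counts. Genotype
  tables are fully enumerated when a cheap product bound keeps the space
  ≤ 10⁵; otherwise Monte-Carlo by shuffling the 2n gene copies (10⁵ default
  shuffles, seeded, add-one correction). p = mass of tables no more
  probable than observed. Type-I error at α = 0.05 is calibrated to
  0.04–0.06 on equilibrium samples (n = 50, 5 alleles).
* F_ST: Weir–Cockerham θ with components summed over alleles and loci
  before the ratio; small negative estimates are reported as computed.
  Chosen as the field standard — the original study names only the
  software it used.
* Relatedness: symmetrized Queller–Goodnight with pooled-sample
  frequencies; monomorphic loci are skipped. The original study's software
  offers several estimators without saying which produced its table, so
  exact numeric agreement with that column is not promised. Note the
  estimator's known small-sample downward bias when the frequency pool is
  dominated by the families being measured.
* Rarefaction: E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)] computed with
  log-gamma; percentile bootstrap by resampling copies. Saturation is
  summarized as the mean slope over the final third of the curve.
* Sharing classification is observational: an allele seen in ≥ 2 regions
  is shared, else region-specific, with single-deme confinement flagged —
  matching the published figure's column semantics (classes are defined on
  the two sampled regions, not on subspecies).
* Fisher's exact 2×2 test uses the method of small p-values
  (scipy's two-sided test).

## Recombination and gene conversion (`recomb`)

* **Rm (Hudson–Kaplan).** Site pairs showing all four gametes (multi-
  allelic sites are collapsed: any base pair exhibiting four gametes
  counts) define open intervals; intervals containing another interval are
  discarded and a left-to-right greedy scan picks a maximal disjoint set.
  Equality with an exhaustive interval-packing oracle is part of the test
  suite (property-checked on random matrices up to 8 sites × 16
  haplotypes).
* **Gene-conversion fragments.** On the polymorphic sites, an inner
  fragment is the best maximal run of consecutive sites at which a
  sequence pair is identical; an outer fragment the best run at which one
  sequence differs from all others. The permutation null conditions on the
  pair's number of matching sites m: site order is permuted (default 10⁴
  draws, shared across pairs, seeded; the count is recorded in the
  output), and sim_p is the add-one fraction of permutations whose maximal
  run reaches the observed score. Conditioning on m makes near-identical
  pairs (long runs, but expected) non-significant while cross-group pairs
  with an implanted tract stand out. corrected_p multiplies by the number
  of pairs plus sequences tested (Bonferroni — the original analysis says
  only "corrected for multiple comparisons") and caps at 1. Fragments end
  at the first mismatch (zero mismatch penalty, the reference tool's
  default); a configurable penalty is left as an extension. Power is
  assessed on two-haplogroup alignments with a conversion tract copied
  across groups — the low-background-identity regime where a run-length
  score has power — and the false-positive rate on independent-site null
  alignments, where the conditional permutation test is exactly valid and
  Bonferroni keeps the family-wise rate below nominal. The original
  program's Karlin–Altschul-style scoring differs in detail, so its exact
  p-values are not reproduced.
* **Distances.** Kimura two-parameter d = −½ln(1−2P−Q) − ¼ln(1−2Q) with a
  saturation flag when a log argument is non-positive. dN/dS by
  Nei–Gojobori: synonymous site counts per codon (changes to stops count
  as non-synonymous), pathway-averaged difference counts skipping paths
  through stops, Jukes–Cantor correction; the ratio is undefined (None)
  when dS = 0.
* Per-codon amino-acid variability is profiled against a user-supplied
  antigen-binding-site annotation (ABS positions are locus-dependent and
  are an input, not a constant).
* The point-mutation waiting time 1/(μ·L·n_chrom) exposes the chromosome
  count explicitly: with μ = 2×10⁻⁸ and L = 200, the often-quoted
  "new mutation every 2500 generations" requires n_chrom = 100; a deme of
  1000 diploids would give 125 generations. The operation takes n_chrom as
  an argument rather than resolving that ambiguity.

## Problem sizes and runtime choices

Default analysis sizes are desk-scale: 2 regions × 5 demes × ~10 animals,
~100 454-style reads per individual × locus, 500-read subsamples for UPGMA,
10⁴ permutations for conversion fragments (the original analysis used 10⁶;
the permutation count is recorded in the output and the p-value resolution
floor is 1/(N+1)), 10⁵ shuffles for Monte-Carlo HWE. The
sampling-correlation check (allele count vs deme sample size) pools demes
across five replicate metapopulations: with only ten demes, an R² under
exact independence has expectation 1/(n−1) ≈ 0.11, so a single replicate
cannot demonstrate the absence of correlation; ~100 pooled points can.

## Known limitations

* Validation precision against recurrent point-error variants is bounded
  by the replication rule (see above); the catalog's `rejections` table
  and the benchmark's precision metric quantify this per run.
* The gene-conversion score is run-length based; power is poor when the
  background identity between the tested pair is high (tract length must
  be large relative to what the pair's match density predicts).
* Queller–Goodnight means are downward-biased in small pooled samples of
  relatives; comparisons with published relatedness tables are indicative,
  not exact.
* Catalog-subtraction phasing requires at least one allele of each
  heterozygote to be known (or short-read verified); novel/novel
  heterozygotes without short-read support are excluded, as in the
  original consolidation, biasing allele counts downward, never upward.
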