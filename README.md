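# mhc-deme-kit

Amplicon genotyping and deme-level population genetics for hypervariable
MHC class II loci, built around the metapopulation biology of wild house
mice (*Mus musculus*). The package is for researchers genotyping MHC (or
comparably polymorphic) amplicons in structured natural populations who
need (a) artifact-hardened allele validation from parallel amplicon
sequencing, (b) diploid allele calling that reconciles direct
(Sanger-style) and short-read evidence, and (c) the population-genetic and
recombination statistics that characterize allele diversity in demes —
plus a full synthetic data generator so every stage can be verified
against ground truth.

## What it computes

House-mouse demes (single farms) hold two kinds of MHC alleles: widely
*shared* alleles that occur across regions, and *region-specific* alleles
mostly confined to single demes, generated by recombination or partial
gene conversion between existing alleles. The toolkit implements:

* **Survey calling** — 454-style reads are quality-filtered (mean Q > 25,
  length > 200 bp, no Ns), demultiplexed by exact 10-bp MID tags, trimmed,
  locus-assigned, corrected for homopolymer indels against a reference,
  and validated: a sequence is a reliable allele iff it occurs in ≥ 2
  independent amplifications with different primer pairs within an
  individual or in ≥ 2 individuals, and ≥ 2 unedited raw reads confirm it.
  A diploidy-based screen removes PCR chimeras (single-crossover hybrids
  of an individual's two alleles). Validated alleles are classified
  known/new and normal/silent/non-functional.
* **Deme typing** — IUPAC-coded direct consensi are phased by catalog
  subtraction (each consistent known allele *A* implies the complement
  *B* at the double-peak sites); short-read sets (> 5000 reads) are
  clustered with a UPGMA tree cut into one or two clusters; the routes are
  consolidated with rescue of poorly amplified alleles and explicit
  exclusion rules. Alleles are trimmed to common windows (H2-Aa 208 bp,
  H2-Eb 231 bp).
* **Population genetics** — observed and Nei-unbiased expected
  heterozygosity, effective allele number 1/Σp², an exact/Monte-Carlo
  conditional Hardy–Weinberg test, Weir–Cockerham F_ST (θ, ratio of
  summed components), symmetrized Queller–Goodnight relatedness,
  hypergeometric rarefaction E[S_n] = Σᵢ[1 − C(N−Nᵢ,n)/C(N,n)] with
  bootstrap intervals, shared/region-specific classification, two-tailed
  Fisher exact tests, sample-size correlation, mtDNA haplotype sharing.
* **Recombination** — Hudson–Kaplan minimum recombination events (Rm)
  from the four-gamete test, GENECONV-style inner/outer gene-conversion
  fragments with a site-order permutation null and Bonferroni correction,
  Kimura-2P distances, Nei–Gojobori dN/dS with Jukes–Cantor correction,
  per-codon variability against an antigen-binding-site annotation, and
  the point-mutation waiting time 1/(μ·L·n_chrom).
* **Simulator** — metapopulations of extended family groups with a
  genealogical ancestral allele pool, recombinant region-specific alleles,
  PCR chimeras, platform-specific error models, unequal allele
  amplification, microsatellites and matrilineal mtDNA. Identical config +
  seed reproduces every output byte-identically.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

```python
from mhcdemekit.synthdata import SimConfig, simulate_metapopulation
from mhcdemekit.pipeline import run_survey, run_deme_analysis
from mhcdemekit.popgen import fisher_exact_2x2

truth = simulate_metapopulation(SimConfig(seed=42))
survey = run_survey(truth)
print(survey.stats)
bundle = run_deme_analysis(truth, survey.result.catalog)
print(bundle.mhc_summary.head(4).round(3))
print("slopes:", bundle.slopes)
```

With seed 42 this simulates 78 mice in 10 demes (two regions) carrying 15
H2-Aa and 16 H2-Eb alleles, and prints the survey filter ledger

```
{'reads_in': 15432, 'reads_quality_pass': 13229, 'reads_trimmed': 13042,
 'unassigned': {'no_primer_suffix': 187}, 'candidates': 1030,
 'skipped': {'not_full_length': 492}, 'accepted': 35, 'rejected': 995}
```

— 15,432 raw reads collapse to 1030 candidate sequences of which 35
survive the reliability rules — and then per-deme summaries such as

```
deme locus  n  h_obs  h_exp  n_eff_alleles  hwe_p  relatedness_mean
R1D1 H2-Aa  5    1.0  0.911          5.556  1.000            -0.229
R1D1 H2-Eb  5    1.0  0.800          3.571  1.000            -0.225
R1D2 H2-Aa  6    1.0  0.848          4.500  0.923            -0.164
R1D2 H2-Eb  6    1.0  0.864          4.800  1.000            -0.189
```

(heterozygosities near Hardy–Weinberg expectation within demes) and the
saturation contrast `{'shared': 0.0, 'region_specific': 0.187}` — the
rarefaction curve of shared alleles is flat over its final third while
region-specific alleles are still being discovered at ~0.19 new alleles
per sampled gene copy. The locus-by-region allele-count contrast of the
deme survey (22 vs 17 H2-Aa, 13 vs 28 H2-Eb alleles) gives

```python
>>> fisher_exact_2x2([[22, 17], [13, 28]])
0.0418  # two-tailed; the two loci diversify independently
```

The same workflows run from the shell:

```bash
mhc-deme-kit simulate --seed 42 --out sim/
mhc-deme-kit survey-call --reads sim/survey_reads.fastq \
    --mids sim/mid_table.tsv --primers sim/primer_table.tsv \
    --references refs.fasta --out survey/
mhc-deme-kit recomb --alignment alleles.fasta --permutations 10000 --seed 1
```

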