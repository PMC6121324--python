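# Methods

## Statistical model

At a biallelic SNP with per-pool ref/alt read depths, the SNP index of a
pool is the alternate-read fraction alt/(ref+alt), defined only when the
pool's total depth reaches `min_depth` (default 10 reads; indices at lower
depth are undefined — `nan` — rather than zero, so thin coverage can never
masquerade as evidence).  Δ(SNP index) is index(A) − index(B), defined iff
both indices are.  "Alternate" always means non-reference with respect to
the public reference genome the reads were aligned to, not a parental
assembly: variants fixed in the parental line relative to that reference sit
near index 1 in both pools and cancel in Δ, which is the design's
substitute for sequencing the progenitor.

For a fully penetrant recessive causal locus with pools drawn from a
selfed-F1 (F2-type) population: Pool A (recessive phenotype) is fixed for
the mutant allele, Pool B (dominant phenotype) carries dosages 0:1 in ratio
1:2, so the idealized expectations are index A = 1, index B = 1/3,
Δ = 2/3 at the causal SNP and 1/2, 1/2, 0 at unlinked loci.

The pooled-Fst analogue is Nei's G_ST computed from the two pool allele
frequencies p_A, p_B: G_ST = (H_T − H_S)/H_T with
H_T = 2·p̄(1−p̄), H_S the mean within-pool heterozygosity, and G_ST ≔ 0
when H_T = 0.  It is offered as an equivalent view of pool divergence, not
as an unbiased population-genetic estimator (pool read counts, not
individual genotypes, enter the frequencies).

The segregation check is a df=1 chi-square goodness of fit of
dominant:recessive phenotype counts against a stated ratio (default 3:1);
"consistent" means the statistic is below the critical value at the chosen
significance level (3.841 at α = 0.05).

## Genome scan

Windows (default 50 kb, step 10 kb) are anchored at position 1 of each
chromosome and use half-open membership [start, start+window).  A window's
statistic is the *unweighted* mean Δ of the member SNPs with defined Δ —
unweighted because each SNP is one estimate of the local allele-frequency
contrast, and depth-weighting would let a single deep SNP dominate.
Windows with fewer than `min_snps_per_window` (default 1) contributing
SNPs are undefined.

Candidate regions are maximal runs of threshold-passing windows
(`region_threshold`, default 0.5 — halfway between the unlinked expectation
0 and the causal expectation 2/3) evaluated over the subsequence of
*defined* windows: windows with no SNPs are skipped entirely, so empty
stretches neither qualify nor break a run.  Up to `max_gap_windows`
(default 0) defined below-threshold windows may be bridged inside a run.
Regions are ranked by their peak window mean.  Region spans run from the
first window's start to the last window's (exclusive) end, so a single
qualifying SNP yields a span of window+ (cover−1)·step = 90 kb at the
defaults.

A practical caveat quantified by the simulator: when SNP density is low
enough that windows hold at most one SNP, the windowed Δ inherits the full
per-SNP binomial read noise (sd ≈ 0.09 at 30× for the causal pattern), and
the peak-ranked top region frequently lands on a tightly linked neighbour
rather than the causal SNP's own windows.  Under the default simulation
conditions the top region localizes the causal locus (same chromosome,
within 5 Mb) in ~100% of replicates, but *contains* the causal SNP in only
~40%; strict containment would require either denser SNPs (so windows
truly average) or deeper pools.  Tests assert the former property; the
latter is reported as measured.

## Effect annotation and screening

Gene models (one per mRNA; `gene_id` is the parent gene, so isoforms count
once) come from GFF3 via gffutils; sequence from FASTA (pyfaidx) or plain
dicts.  Coding consequences substitute the alternate base into the
strand-corrected codon and translate with the standard genetic code
(Biopython): synonymous, missense, or nonsense when the new codon is a
stop.  A reference codon that is itself a stop (stop-loss) falls outside
the output vocabulary and is reported as missense.  Non-coding classes are
intron, splice_region, five_prime_utr, three_prime_utr (UTRs inferred from
exon−CDS geometry when not annotated), intergenic.  Splice regions follow
the common annotation convention — intronic positions within 8 bp of an
exon boundary (precedence over intron) and non-CDS exonic positions within
3 bp of an intron-adjacent boundary (precedence over UTR labels); CDS
positions always classify by codon consequence, so every position in a
model maps to exactly one class.

The screen keeps SNPs with Δ in [`delta_low`, `delta_high`] (defaults 0.6
and 0.8, inclusive at both ends for predictability), then drops SNPs whose
annotations are all intergenic or synonymous (a SNP overlapping several
genes survives if *any* annotation qualifies).  The third, wet-lab step
(Sanger confirmation) is represented by the exported worklist of survivors
with ±250 bp flanking coordinates for primer design.  EMS-canonical
changes are flagged as G→A or its reverse-strand mirror C→T.

A 19-SNP candidate table from a published white-belly endosperm mapping
study ships as package data for tests (positions, bases, Δ values and
printed mutation-type labels); the gene structures behind it are not
reconstructed, so its effect labels are taken as printed.

## CAPS markers

Recognition sites are IUPAC degenerate strings matched case-insensitively
with overlaps; `N` in the sequence never matches.  Palindromic sites
(HaeII's RGCGCY is its own reverse complement) need only a forward scan;
non-palindromic sites are scanned on both strands and reported at their
forward-strand start.  `caps_check` classifies a SNP by the change in the
number of sites overlapping it between the reference and alternate
amplicon.  Cut geometry is a per-enzyme offset (HaeII RGCGC^Y → 5),
overridable per call; fragment lengths always sum to the amplicon length.

## Cross simulator

The generator emulates the mapping design end to end with one integer
seed driving all randomness (equal seeds ⇒ bit-identical tables).

* **Genome**: 12 chromosomes × 30 Mb (≈360 Mb, rice-like).  500 EMS SNPs
  (70% canonical G:C→A:T by default, matching the EMS spectrum; the causal
  SNP is always a canonical G→A) plus 2,000 background SNPs fixed in both
  parents versus the reference.
* **Meiosis**: Haldane model — per-chromosome crossover count
  ~ Poisson(map length), uniform crossover positions, no interference;
  chromosomes assort independently.  4 cM/Mb gives 1.2 Morgans per
  chromosome.  The backcross-to-progenitor design is modelled as a plain
  two-parent cross plus selfing, which is genetically identical because
  the recurrent parent is the pre-mutagenesis line.
* **Phenotype and pools**: mutant iff mutant-allele dosage 2 at the causal
  SNP, optionally misread per plant at `phenotyping_error_rate` (default
  0).  Pools of 50 + 50 plants are drawn without replacement from the
  observed phenotype classes.  A population of 100 F2 yields only ~25
  recessive plants, so by default the simulator grows the unselected
  population in batches until both classes can fill their pools — the
  in-silico counterpart of the real design's extra plants raised from
  selfed pedigrees (`on_pool_shortfall="fail"` raises instead).
* **Reads**: per SNP and pool, depth ~ Poisson(30) and alternate reads
  ~ Binomial(depth, f′), f′ = f(1−e) + (1−f)e with f the pool allele
  frequency and e = 0.002 the per-read error rate.  Hence the measurable
  expectations are E[index A] = 1−e at the causal SNP, E[index B] =
  (1+e)/3, E[Δ] = 2/3 − 4e/3 ≈ 0.664 — the idealized values shifted by at
  most 0.003.
* **Pedigrees**: `advance_generation` selfs every individual into a
  pedigree (phased haplotypes are retained, so linkage carries through);
  `pool_from_pedigrees` then pools one plant from each pedigree whose
  progeny uniformly show the mutant phenotype (homozygotes breed true),
  which suppresses per-plant phenotyping errors roughly geometrically in
  pedigree size.

What the simulator does **not** model: raw reads and base qualities,
alignment and calling artifacts, mapping bias, crossover interference,
non-uniform recombination or SNP landscapes, segregation distortion, and
genome-scale SNP densities (the study design it emulates detected hundreds
of SNPs within the candidate region alone).  Passing tests therefore
demonstrate correctness of the statistics under the stated sampling model,
not robustness to upstream artifacts of real data.

## Numerical and interface choices

Coordinates are 1-based inclusive everywhere (VCF/GFF3 convention); window
arithmetic converts to half-open internally.  Undefined values are `nan`
in memory and empty strings in TSVs (never `.`).  Tables are sorted by
(chrom, pos) with duplicate (chrom, pos, alt) rejected; only biallelic
ACGT SNPs are retained from VCF input (skipped records are counted in the
table's provenance).  CLI manifests omit timestamps so fixed-seed runs are
byte-identical.  Monte-Carlo problem sizes in the test suite (100
replicates for expectation recovery and region calling, 200 paired seeds
on a one-chromosome genome for the pedigree-variance comparison, 100
random tables for the window oracle) were chosen to keep sampling error
well below the tested effects.

## Known limitations

Region boundaries depend on the invented merging rule and its gap
parameter; the method's published analogue drew its candidate region from
a Manhattan plot without stating a rule.  The Fst analogue is reported but
not used for region calling.  Multi-sample (>2 pools) designs,
confidence intervals on SNP index, and transcript-isoform selection
policies are out of scope.
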