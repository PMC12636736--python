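# Methods

## Inheritance model

The screen assumes a single fully penetrant autosomal-recessive variant with
no phenocopies and no compound heterozygosity: affected individuals are
homozygous for the alternate allele, both parents of an affected individual
are obligate carriers, and unaffected individuals carry at most one alternate
allele. Compound-heterozygous models are deliberately not implemented; the
screen targets a single shared ancestral allele segregating in a closed
breeding colony.

### Trio filters

The SNV/indel filter is the literal genotype predicate

> father = 0/1 ∧ mother = 0/1 ∧ proband = 1/1

over biallelic calls. It is *strict*: a homozygous-alternate parent fails
even though the configuration is recessive-compatible. In a colony where
carrier status of the parents is established by their having produced both
affected and unaffected offspring, a hom-alt parent would itself be affected,
so the strict pattern is the correct ascertainment; `permissive_parents=True`
relaxes the parental condition to "carries ≥ 1 alternate allele" for other
designs. Missing genotypes never pass — a site without evidence in all three
trio members is excluded, not given the benefit of the doubt.

The CNV filter accepts only deletion records with copy number 1 in both
parents and 0 in the proband (a homozygous deletion inherited from two
hemizygous carriers). Copy numbers come exclusively from the `CN` FORMAT
field of symbolic `<DEL>` records; the `GT` field of symbolic records is
never consulted, since SV genotype conventions vary by caller while CN is
unambiguous. The filter requires trio CN values on a single record;
coordinate-matching of per-sample CNV calls across separate records is out
of scope.

Both filters run after an autosome gate (X/Y/MT dropped, with or without a
`chr` prefix, case-insensitive), because the model is autosomal. An explicit
chromosome allow-list can override the gate. An optional `pass_only` switch
drops records whose FILTER column is not PASS; it defaults to off so that
upstream filtering policy stays the caller's decision.

### Genotype and VCF semantics

Genotypes are restricted to biallelic coding. Multiallelic input lines are
split into one biallelic record per alternate allele; in each split record
the reference allele stays 0, the chosen alternate becomes 1, and any
genotype carrying a *different* alternate becomes missing — its carrier
status for the allele under test is real but its diploid configuration is
not representable biallelically, so the conservative choice (missing, hence
filter failure) avoids false positives. Half-missing calls (`./1`) are
likewise treated as missing. Phase separators are preserved but never affect
the call. Coordinates are 1-based inclusive everywhere except inside the
interval-intersection step, which converts to 0-based half-open.

One parsing constraint: symbolic `<DEL>`/`<DUP>` records must carry an
explicit `INFO/END` strictly beyond the anchor base. The reader detects a
missing END by the end coordinate collapsing onto the reference span, so a
single-base symbolic deletion is rejected as malformed — a non-issue for
real CNV segmentations, which span kilobases.

## Impact triage

Consequence terms are mapped to the four-tier impact scale through a frozen,
versioned-in-repo copy of the public VEP Sequence Ontology taxonomy
(transcript_ablation, stop_gained, stop_lost, frameshift_variant … → HIGH;
missense_variant, in-frame indels → MODERATE; synonymous_variant and splice
region terms → LOW; intronic/UTR/intergenic → MODIFIER). Freezing the table
keeps tier counts reproducible offline and independent of annotation-tool
releases. Unknown terms classify as MODIFIER with a warning, so new vocabulary can
never silently promote a variant. A variant's tier is the maximum over its
terms (monotone by construction).

Gene aggregation keeps two deliberately different counts: a variant
annotated against *k* genes appears in all *k* gene candidates but counts
once in the tier tally (at its maximum tier), because variant counts and
gene counts answer different questions. CNV survivors enter every overlapped
gene at HIGH impact — a homozygous deletion ablates the transcript — and are
logged distinctly. Survivors with no annotation (or deletions overlapping no
gene) are reported separately and never tallied, so the tally always
partitions the annotated survivors.

Interval intersection (gene BED vs CNV span, ≥ 1 bp overlap, half-open
semantics) is delegated to an interval tree; a brute-force all-pairs scan
serves as the test oracle.

## Segregation analysis

Candidate validation is the computational form of Sanger follow-up. Per
individual with a non-missing call, three rules apply: affected ⇒ hom-alt;
unaffected ⇒ not hom-alt; parent-of-affected (obligate carrier, regardless
of own phenotype) ⇒ het or hom-alt. Phenotype-unknown non-parents contribute
no rule and are uninformative. A family with zero evaluable rules is
*inconclusive* — the outcome of a failed Sanger assay rather than of a
refuted model. Verdicts are:

* **consistent** — ≥ 1 informative call, no violations;
* **inconsistent** — any violation (each named with observed and allowed calls);
* **inconclusive** — nothing evaluable.

Across families the decision is asymmetric by design: one inconsistent
family **excludes** the candidate outright (under full penetrance a single
incompatible genotype is decisive), while **supported** requires *every*
evaluated family consistent and at least one family with ≥ 3 informative
calls — support from thinner evidence stays *inconclusive*. The evaluator is
verified against an independent literal rule evaluator over the exhaustive
4⁶ = 4,096 call assignments on the six-member family shape.

## Synthetic data generator

The generator emulates the ascertained study family: two carrier parents
and four offspring, two affected and two unaffected. Defaults (chosen once,
as a realistic desk-scale experiment):

| parameter | default | meaning |
|---|---|---|
| `n_background_snvs` | 2,000 | unlinked biallelic background sites, uniform over genes |
| `founder_alt_freq` | 0.2 | founder alternate-allele frequency (Hardy–Weinberg draws) |
| `n_offspring` | 4 | litter size |
| `n_affected_offspring` | 2 | causal-site litter composition (see below) |
| `n_cnv_background` | 20 | background deletion loci, 5–50 kb |
| `cnv_deletion_freq` | 0.15 | founder per-haplotype deletion frequency |
| `genotyping_error_rate` | 0.0 | per-call probability of flipping to a different call |
| `penetrance` | 1.0 | P(affected \| hom-alt at causal site) |

The gene map is a fixed lattice of 300 genes (15 × 100 kb per autosome over
the 20 rat autosomes); the causal SNV sits at the midpoint of a fixed gene
with a configurable consequence (default `stop_gained`), and the planted
recessive deletion removes the core of a gene on another chromosome.

Transmission is Mendelian and unlinked: each offspring receives one
uniformly chosen haplotype per parent per site. Both parents are forced
heterozygous at the causal site. The causal-site transmission vector alone
is conditioned, by rejection sampling, on the litter containing exactly
`n_affected_offspring` homozygous-alternate offspring — the family is
*ascertained* (it entered the study because it showed affected pups), so the
generator reproduces that composition rather than the unconditional
binomial. Background sites are never conditioned, which is why the 1/4
recessive ratio and Hardy–Weinberg founder proportions hold there (both are
property-tested: a 3σ binomial band on the proband hom-alt fraction among
double-carrier sites, and a χ² goodness-of-fit at α = 0.01 on 10,000 sites).
The planted deletion is conditioned analogously: both parents transmit their
deleted haplotype to the proband (CN 0), siblings transmit freely.

Genotyping error corrupts *observed* calls only (each flipped to one of the
other two non-missing calls with probability ε, independently); the
error-free truth is retained in `truth.json`, so error-sensitivity
experiments can measure filter dropout against the planted variant — with
error rate ε the causal variant survives only if all three trio calls are
uncorrupted (or corrupted back), an expected recovery of at least (1−ε)³.

What the generator does **not** emulate: linkage and LD between sites,
variant-caller error modes correlated with depth or context, multiallelic
sites, repeat expansions, CNV breakpoint uncertainty, and population
structure. Passing tests therefore demonstrate the correctness of the
filtering logic and its statistical behavior under the stated model — not
robustness to the artifacts of real short-read callsets.

## Behavioral/histology summaries

`phenostats` implements only the arithmetic the printed group means permit:
percent reduction 100·(ref − test)/ref rounded half away from zero to
integer percent, raw mean differences, and cell-loss percentages to one
decimal — matching the reporting precision of behavioral and histology
figures. Inferential statistics (repeated-measures ANOVA, Welch's t,
confidence intervals) are out of scope because per-animal raw data are not
an input of this package. Note that a mean difference computed on unrounded
data can differ in the last digit from the difference of the rounded means
(e.g. 134.6 − 73.97 = 60.63 while the unrounded difference may print 60.65);
this package computes from the numbers it is given.

## Pipeline and reproducibility

`run_pipeline` chains simulate/load → filter → triage → segregate, writes
each stage's artifact (candidates VCF, triage TSV, segregation JSON) plus a
`report.json` whose provenance block carries the package version, a SHA-256
hash of the scientific configuration (output location excluded) and the
seed. Two runs of the same configuration and seed are identical apart from
the timestamp. Stage failures abort with a stage-named error. In simulated
runs the proband defaults to the first affected offspring.

Problem sizes in the test suite and acceptance script (10,000 sites for the
ratio checks, 100 seeded simulations of 60 background sites for recovery,
4,096 exhaustive segregation assignments) are desk-scale choices: large
enough for tight binomial bands and exhaustive enumeration, small enough to
run in seconds.

## Known limitations

* Single-variant recessive model only — no compound heterozygotes, no
  X-linked or dominant modes, no genotype-likelihood (PL/GQ) modeling.
* CNV trio logic requires all three CN values on one record.
* The strict parental 0/1 pattern will miss a causal variant in families
  where a parent is an affected homozygote.
* Segregation judgments assume complete penetrance and no phenocopies; a
  tolerance knob is intentionally absent.
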