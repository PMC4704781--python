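# Methods

`mitodx` implements, as a reusable and fully tested pipeline, the comprehensive
genomic diagnostic workflow used for cohorts of patients with biochemically
defined mitochondrial respiratory chain complex deficiencies: whole-exome
variant prioritization with inheritance-model reasoning, mtDNA variant /
large-deletion / depletion analysis, SNP-array CNV and homozygosity screening,
evidence-based diagnostic classification, and a resampling-based evaluation of
the prioritization pipeline itself. Because such studies deposit no patient
genomes, the package ships a synthetic cohort generator that emulates the
statistical structure of the data and plants known causal mechanisms, so every
stage can be exercised end-to-end and scored against a truth table.

## Exome variant prioritization

The cascade keeps variants that are protein-altering (nonsense, splice-site,
coding indel, missense), rare in six population panels, not recurrent among
cases, outside segmental duplications, not flagged as alignment artifacts, and
predicted deleterious. Default thresholds (all exclusive upper bounds; a
variant is removed only when a panel frequency *strictly exceeds* its
threshold):

| panel      | max MAF | note |
|------------|---------|------|
| dbSNP 137  | 1.0 %   | applied only to entries without known medical impact |
| ESP6500    | 0.1 %   | |
| 1KG        | 1.0 %   | |
| ExAC       | 0.1 %   | |
| HGVD       | 0.4 %   | Japanese exome reference |
| 1KJPN      | 0.4 %   | Japanese whole-genome panel; threshold configurable, optional homozygote-presence veto |

A frequency missing from a panel is treated as 0 (absence from a reference
panel is the operational definition of novelty). Variants with ≥ 10 alt
alleles among cases are removed (`case_allele_max = 9`; homozygotes count two
alleles, hemizygotes one). SIFT > 0.15 (tolerated) or GERP < 2.5 (unconserved)
removes a variant, but a *missing* score never does — truncating variants have
no SIFT score and must survive. The 1KJPN panel's published filter criterion
is qualitative ("MAF and genotype information"); it is exposed here as a
configurable MAF threshold defaulting to the HGVD value, both being Japanese
population references, plus an optional homozygote veto.

Every filter is an independent predicate, so the surviving set is the
conjunction of predicates and provably order-invariant; the configured order
only decides which failure the short-circuit audit trace reports. A recovery
pass restores variants in mitochondria-related genes removed *solely* by the
segmental-duplication/SIFT/GERP filters — stringent mappability and
deleteriousness filters are the ones most likely to discard true mutations in
the gene set of primary interest. Manual read inspection and Sanger validation
are human curation steps; they enter the pipeline as boolean annotation
columns (`artifact_flag`), not as read-level analysis.

## Inheritance-model reasoning

Per gene and patient, prioritized variants are tested against recessive
configurations: one homozygote, ≥ 2 heterozygotes (compound-het candidate), or
a hemizygous male X variant. A single inherited autosomal heterozygote is
rejected — unless trio genotypes prove it arose de novo, in which case it is
retained as a dominant candidate (heterozygous de novo hits in monogenic
disease genes are real diagnoses in this patient group). Compound-het pairs
are phased from the trio by asking which child haplotype configurations are
producible from the parental genotypes (ignoring intragenic recombination):
if only *trans* is producible the pair stands, if only *cis* it is excluded,
if both the phase is unknown and the candidate is retained with firmness
capped at pVUS. Molecular phase groups (modeling cloned gDNA/cDNA phasing)
override trio inference. Transmission patterns impossible under Mendelian
inheritance are flagged, never silently phased. Heterozygous calls on the male
X are coerced to hemizygous with a warning (array/VCF dialect tolerance).

## mtDNA analysis

All coordinates are 1-based on the 16,569-bp circular rCRS. Heteroplasmy is
the alt-read fraction, no-called below a depth gate (default 20×).
Variants are prioritized against a user-supplied two-tier pathogenicity
catalog (`confirmed` / `reported`): confirmed entries are firm-eligible,
reported-only entries pVUS-eligible. The catalog is an input table because
redistributing curated databases is out of scope; a synthetic catalog ships
with the generator.

Large deletions are called from per-base coverage: a base is "low" below
`drop_factor` (default 0.5) times a robust reference level — the
upper-quartile depth, chosen so that deletions covering up to ~75 % of the
circle do not drag the reference down (a plain median fails once the arc
exceeds half the genome). The maximal circular run of low bases is reported
when it spans ≥ `min_span` (default 100) bases and its mean depth is below
`drop_factor` times the flanking mean; breakpoints are the first and last low
bases, and the inclusive span follows circular arithmetic (an arc from
m.16560 to m.10 deletes 20 bases). Deletion heteroplasmy (1 − arc/flank depth
ratio) is reported but not used for classification. Deletions spanning more
than ~75 % of the genome are a known blind spot.

mtDNA depletion is diagnosed when *every one of exactly four* replicate
mtDNA:nuclear copy-number ratios falls strictly below 35 % of the healthy-
control mean — an all-of-four rule with a strict inequality at the boundary.

## Array screens

Copy-number segmentation is a deterministic threshold/run-length caller
(deletion log2 ≤ −0.3, duplication ≥ +0.26, ≥ 10 qualifying probes, internal
gaps of ≤ 2 non-qualifying probes tolerated), replacing vendor hidden-Markov
software: the scientific content of this stage is the *prioritization*, and a
fully specified segmenter keeps every boundary exactly reproducible from probe
input. Prioritization keeps segments strictly larger than 100 kb whose
reciprocal overlap with every control-cohort CNV is below 50 % (the published
"found in controls" criterion states no overlap rule; 50 % reciprocal overlap
is the conventional choice and is configurable), and annotates survivors
against a known genomic-disorder BED — a machine-readable stand-in for manual
curation against OMIM/DGV/DECIPHER.

LCSH (long contiguous stretches of homozygosity) are maximal runs of
homozygous genotype calls spanning at least `min_mb`; the default tier is
1.0 Mb with a secondary tier down to 0.1 Mb, since diagnostically relevant
stretches range from ~0.1 to > 3 Mb. No-calls are ignored; by default no
heterozygous interruption is tolerated (the greedy allowance for isolated het
calls is exactly maximal only at the default of 0). The pipeline computes
LCSH on autosomes and attaches `lcsh_support` evidence to homozygous-recessive
findings whose gene lies inside a run.

The founder screen is an exact conditional Hardy-Weinberg test: the p-value
sums, over the conditional distribution of the heterozygote count given the
allele counts, all outcomes no more probable than the observed one
(two-sided); it is computed in log-gamma space and verified against an
exhaustive rational-arithmetic enumeration for every genotype triple up to
n = 30. Screening applies Bonferroni correction at α = 0.05 across the
screened variants. Monomorphic sites give p = 1.

Composite events: a heterozygous variant inside a heterozygous deletion hits
both alleles and is promoted to a biallelic candidate; an *apparently
homozygous* variant under a het deletion is really hemizygous and is reported
with an explicit note rather than dropped.

## Classification and bookkeeping

Enzyme-deficiency severity follows residual-activity criteria (percent of
control, normalized to citrate synthase or complex II): major below 20 % in a
tissue, 30 % in fibroblasts, or 30 % in ≥ 2 tissues; minor below 30/40/40 %.
The thresholds nest, so every major record also satisfies the minor clauses.

A finding is **firm** only when (i) a qualifying configuration is established
— biallelic with resolved phase, hemizygous, de novo dominant, a directly
observed CNV segment, or an mtDNA event — and (ii) at least one molecular
evidence tag supports pathogenicity (rescue, segregation, de novo,
known-pathogenic, LCSH support, shared rare variant, absent protein,
functional assay, splice defect). Otherwise it is a pVUS: a prioritized
variant of unknown significance, even in a gene already reported as
disease-causing. Evidence tags are boolean inputs (the underlying assays are
wet-lab), except `de_novo` and `lcsh_support`, which the pipeline derives
itself from trio genotypes and array data. The catalog `confirmed` status
supplies `known_pathogenic` for mtDNA point variants.

Each patient receives the category of their highest-priority firm finding
under the order mtDNA mutation > known nuclear gene > novel mitochondria-
related gene > other monogenic gene > chromosomal aberration (configurable;
this order reproduces the documented resolution of a patient carrying both a
firm de novo point mutation and an inherited pVUS deletion). Patients with
only pVUS findings are `pvus_only`; with none, `unresolved`. Cohort summaries
report per-category counts and percentages rounded half-up to one decimal;
`any_prioritized` counts everything except unresolved, `firm_total` the five
firm categories.

## Enrichment evaluation

The pipeline is evaluated by comparing the percentage of cases versus
controls harboring prioritized genes, for known disease genes,
mitochondria-related genes, and a null of 908 genes drawn 1000 times at
random from the pool after excluding known-disease and mitochondria-related
genes. The evaluation uses a simplified cascade without the
manual-inspection, validation, 1KJPN and HGVD steps (control cohorts
typically contribute to the reference panels being filtered against). By
default an individual "harbors" a gene only when it carries a qualifying
inheritance configuration (a toggle relaxes this to any surviving variant).
The null reports the sample SD over draws (n − 1 denominator). Sequencing-
depth normalization across cases and controls is replaced by an input
contract: both groups must supply variant tables of identical completeness.
With this semantics a clean control cohort can legitimately show 0 % for
known disease genes, making the enrichment fold undefined; both percentages
are still reported.

## Synthetic cohort generator

The generator is first-class, tested code defining the study conditions:

* **Cohort**: 48 cases with parental trios and 48 unrelated controls by
  default; case sex random except where a mechanism requires a male.
* **Genome model**: 22 autosomes + X of 10 Mb each (a desk-scale stand-in:
  coordinates, not chromosome biology, are what downstream code consumes) and
  the 16,569-bp circular MT; 5,000 synthetic genes laid out round-robin, the
  first 150 forming the known disease-gene set and the next 1,200 the
  mitochondria-related set (MitoCarta-like size), leaving > 3,600 genes so
  908-gene null draws are always possible.
* **Planted mechanisms** (defaults; all nine classes): a four-patient
  recessive founder allele inside a 2.8 Mb homozygous stretch, phased
  compound heterozygotes with and without supporting evidence, de novo
  dominant heterozygotes, a male X hemizygote in a mitochondria-related gene,
  confirmed mtDNA point mutations with heteroplasmy drawn uniformly on
  [0.3, 1.0] (heteroplasmy is detected in practice but no distribution is
  established), one large mtDNA deletion (breakpoints m.11359/m.15068), qPCR
  depletion patients (four replicates around 20 % of control, with a causal
  nuclear mutation in a known depletion gene — depletion itself is assigned
  the known-nuclear-gene category, since the diagnostic category enum has no
  depletion box), 1,675 kb de novo deletions annotated against a disorder
  region, and one composite CNV + SNV patient (a 1,387 kb het deletion over a
  known gene plus a maternal het missense on the remaining allele).
* **Background variants**: per individual, a Poisson number (default mean
  1.5) of cascade-surviving rare damaging heterozygotes and a Poisson number
  (default mean 8) of variants constructed to fail exactly one filter class;
  common variants receive correlated panel frequencies via a shared lognormal
  base frequency. Background is confined to autosomal genes outside the
  known/mito sets and to one variant per gene per individual, so the
  surviving count matches the configured rate exactly (variants in
  mitochondria-related genes would otherwise re-enter through the recovery
  pass) and undiagnosed patients deterministically classify as unresolved.
  The published work reports no per-stage variant yields, so the background
  rate is a free parameter chosen for test sensitivity.
* **Arrays / mtDNA**: probes every 20 kb (heterozygous call rate 0.35, log2
  noise SD 0.12; deleted regions at log2 −1 with homozygous calls, as true
  hemizygosity appears on an array); mtDNA coverage Poisson around 1500×,
  deletion arcs at 10 %.

Everything derives from one `numpy` `default_rng(seed)`; a fixed seed gives
byte-identical output files. The generator does **not** model linkage
disequilibrium, population demography, relatedness beyond trios, X-linked
background variation, genotyping error, or read-level data — passing tests
demonstrate the decision logic and its statistical calibration, not
performance on real genomes.

## Numerical and testing choices

Percentages use decimal half-up rounding to one decimal (the bookkeeping
convention of the field's summary tables; note that 65/142 rounds to 45.8 %
under this rule). Variant coordinates are 1-based inclusive (VCF convention);
BED inputs are 0-based half-open and converted only at the reader boundary.
The HWE implementation is checked against a `fractions`-based enumeration
oracle; circular deletion arithmetic against a walk-the-circle counter;
compound-het phasing against exhaustive parental-haplotype enumeration over
all 81 trio genotype combinations; the cascade's order-invariance and
monotonicity over 1,000 randomized variants; and the enrichment null against
the closed-form hypergeometric hit probability. Problem sizes in the test
suite (48 + 48 cohort, 200-profile deletion Monte-Carlo, 1000-draw null) keep
the whole suite under a minute on one CPU while leaving Monte-Carlo standard
errors small enough for 3-SE assertions.
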