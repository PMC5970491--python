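# Methods

`crisprtrio` implements the desk side of a trio-based screen for
CRISPR/Cas9 off-target mutagenesis in an edited animal ("founder") and its
two unedited parents.  The question the analysis answers is: are the
variants private to the founder the footprint of the nuclease, or ordinary
spontaneous germline mutation?  Four instruments address it: an off-target
site scanner, a de novo variant filter cascade, structural-variant
attribution to paired cut sites, and a distance-to-site resampling test
with a germline mutation-rate estimate.  A synthetic trio generator
provides fully specified inputs for validating all of them.

## Off-target site enumeration

A candidate off-target site for a 20-nt SpCas9 protospacer is any genomic
window, on either strand, followed immediately 3′ by a PAM matching the
configured pattern (default `NGG`, IUPAC codes honoured), whose mismatch
counts against the protospacer satisfy

* `m_seed ≤ max_seed_mm` (default 1) in the seed region,
* `m_nonseed ≤ max_nonseed_mm` (default 4) outside it,
* `m_seed + m_nonseed ≤ max_total_mm` (default 5).

The seed region is the 12 PAM-proximal protospacer bases by default.  The
seed length is not a property of the genome but of RNA-guided target
recognition; 12 is the common SpCas9 convention and it is configurable.
The three thresholds are independent knobs: the total-mismatch cap can be
used on top of, or effectively instead of, the seed/non-seed limits, so
both "seed-aware" and "total-mismatch-only" search styles are
configurations of one scanner rather than separate tools.  Ambiguous
genome bases (`N`) always count as mismatches and never satisfy a PAM
position; `N` in the PAM pattern matches only A/C/G/T.

The cut site is the blunt double-strand-break boundary 3 bp 5′ of the PAM
(between protospacer positions 17 and 18), strand-aware.  Deviations of
observed breakpoints from this ideal geometry — NHEJ end resection leaves
breakpoints a few bases off — are absorbed by the attribution tolerance in
the SV module, not by redefining the cut.

Coordinates are 0-based half-open internally; VCF output is 1-based and
BED output 0-based half-open, per those standards.

## De novo variant filter cascade

Input is a three-sample VCF (father, mother, founder) from a primary
caller plus a second caller's VCF used as a site-level confirmation set.
Multi-allelic records are decomposed per alternate allele; alleles are
reduced to a parsimonious representation (shared suffix then prefix
trimmed) before any cross-caller or database comparison.  Indels are
restricted to net length changes of 2–50 bp; 1-bp indels — the most
artifact-prone class under indel realignment — are excluded with a logged
count, as are alleles beyond 50 bp (the domain of the SV module).

Ordered rules, each recording its survivor count:

| rule | default | test |
|------|---------|------|
| R0 | QUAL ≥ 50, founder DP ≤ 300 | site-quality and coverage ceiling |
| R1 | — | founder GT carries the alt; both parents called hom-ref with ≤ 1 alt read; site present in the second caller |
| R2 | — | drop alleles present in the population database (allele key) |
| R3 | — | drop positions present in the population database (position key) |
| R4 | 0.25 / 3 | founder alt fraction AD_alt/DP ≥ 0.25; DP ≥ 3 in all three members |
| R5 | 20 / 20 | PL pattern (below) |
| R6 | 1 / 1 | founder alt allele seen on ≥ 1 forward and ≥ 1 reverse read |
| R7 | 10 bp / 8 bp | artifact screen: no second candidate within 10 bp; not inside a reference homopolymer or dinucleotide run ≥ 8 bp |

SNVs run R0–R7.  Indels run a shortened cascade — R0, then R1∧R4 as a
single step (R14), then R5, then R7 — mirroring how indel candidate lists
are typically consolidated before manual review.

**The PL pattern (R5).**  With A the reference and B the alternate
allele, and PL the phred-scaled genotype likelihoods normalized so the
most likely genotype scores 0, a confident de novo heterozygote requires

* founder: `PL(AA) > 20`, `PL(AB) = 0`, `PL(BB) > 0`;
* each parent: `PL(AA) = 0`, `PL(AB) > 20`, `PL(BB) > 20`.

All inequalities are strict; a founder PL(AA) of exactly 20 fails.  PLs
are taken from the primary caller only.

**Design choices that were genuinely open.**

* *Parental alt-read cap.*  Founder specificity could demand literally
  zero alternate reads in the parents, but at 25× coverage with a
  per-read error of 0.5% the probability that *neither* parent shows a
  single stray alt read is only ≈ 0.78, so an absolute-zero rule discards
  a fifth of true de novo variants for no gain in specificity (parental
  genotype and PL checks already guard against true parental carriers).
  The cap is `max_parent_alt_reads`, default 1; setting it to 0 restores
  the strict rule.
* *Two database filters.*  The database screen is exposed in both allele
  mode (drop only exact alternate-allele matches) and position mode (drop
  any variant at a catalogued position).  Running R2 then R3 is the
  default; either can be disabled by reordering `snv_rules`, since
  published summaries of this filtering style differ on which is meant.
* *Automated stand-in for manual review (R7).*  Visual curation removes
  clustered calls and alignment-slippage artifacts; R7 reproduces the two
  deterministic signatures of that judgment (candidate clusters within
  10 bp — both members dropped — and low-complexity reference context).
  It is a proxy: it cannot see read alignments, and on real data it will
  not reproduce every human call.
* *Depth rule reading.*  "Depth < 3 within a trio" is enforced as DP ≥ 3
  in **all three** members: a parent with no coverage cannot certify the
  absence of an allele.
* *Rule order.*  Survivor counts after each rule depend on order, but the
  final survivor set does not for any permutation of R2–R6 (R1 and R0 are
  record-intrinsic too); only R7 is set-dependent, because clustering is
  evaluated among surviving neighbours.  This is covered by a test.

## SV screening and Cas9 attribution

Per-founder SV calls (DEL/DUP/INV/TRA with a supporting-read fraction)
are reduced to de novo candidates by dropping: calls for which *any*
other founder has a same-type call with reciprocal overlap ≥ 0.5
(the any-pair reading is the stricter of the possible "shared between
founders" definitions); calls with supporting fraction < 0.5; and calls
on contigs matching `^scaffold`.  The filter is symmetric in founder
order.  De novo CNVs are founder copy-number segments whose best
reciprocally-overlapping (≥ 0.5) parental segments both differ by ≥ 1
copy.

A candidate inversion or deletion is attributed to a pair of predicted
cut sites `(c1, c2)` on its contig when `|start − c1| ≤ 10` and
`|end − c2| ≤ 10`.  The 10-bp tolerance covers the asymmetric breakpoint
offsets NHEJ leaves around paired blunt cuts (several bases of resection
on either side).  The attribution reports both offsets and the deviation
of the SV length from the inter-cut gap.  Translocations are never
attributed: there is no paired-cut model for them here.  The cohort
screen (`screen_cohort_for_sv`) reduces per-animal presence calls for one
target SV to a carrier count and percentage (2 decimals).

## Proximity test and mutation rate

If Cas9 caused the founder's de novo variants, they should sit closer to
predicted off-target sites than random positions do.  The null is built
by sampling `n_random` positions uniformly over non-N bases
(length-weighted across contigs) and scoring each by the distance to the
nearest same-contig off-target protospacer interval (0 inside; positions
on contigs without sites are excluded with a logged count rather than
given a cross-contig distance).  Distances are measured to the
protospacer interval by default — that is what "distance to a predicted
off-target site" means operationally — with a cut-site mode available.

Reported per run: the empirical (α/2, 1−α/2) null band, per-variant
inside/outside-band flags, and a two-sided Mann-Whitney rank-sum
comparison of observed vs null distances.  Enrichment is *declared* only
when the two-sided p-value is below α **and** the observed median is
smaller than the null median — a significant shift away from the sites is
reported but is not evidence of off-target mutagenesis.  A degenerate
null (all distances identical) returns p = 1 with a warning.

The germline de novo SNV rate is `n_dnm / (2 × callable_sites)` per base
per generation, with the exact (chi-square inversion) Poisson 95%
interval on the count scaled by the same denominator.  Callable genome
size is an explicit argument: it is a property of the sequencing
experiment, and the estimator makes no attempt to infer it.

## Synthetic data generator

The generator emulates exactly the inputs the analysis consumes.

* **Genome.** `n_contigs` i.i.d. sequences with a configurable GC
  fraction (default 0.42, a mammalian-like value), plus optional decoy
  contigs named `scaffold_*` to exercise the scaffold filter.
* **Planted sites.** Protospacer+PAM occurrences with exact requested
  (seed, non-seed) mismatch counts, random strand, non-overlapping
  placements; or at explicit positions when geometry matters (e.g. two
  on-target sites with a fixed inter-cut gap).
* **Trio genetics.** Parents carry `n_inherited` heterozygous variants
  (one random parent each), transmitted by a fair coin.  The founder
  additionally receives Poisson(2·μ·L) spontaneous heterozygous de novo
  SNVs at uniform positions (μ = `mu_dnm`, per haploid base per
  generation; default 1e-8, the mammalian germline ballpark), configured
  on-target indels at the guides' cut sites, and — with per-site
  probability `offtarget_induced_rate` — one induced heterozygous variant
  at `cut_site + round(Normal(0, induced_distance_sd))`.  The truth table
  lists exactly the founder's non-reference alleles with their origins.
* **Read evidence.** Depth ~ Poisson(`mean_depth`, default 25) truncated
  to ≥ 1; each read reports the alternate allele with probability e, ½,
  1−e for genotypes AA, AB, BB (e = `base_error`, default 0.005); strand
  is a fair coin per read.  PLs are the exact phred-scaled likelihoods of
  this binomial emission model, rounded then normalized to minimum 0.
  Site QUAL is the largest per-sample PL(hom-ref) — the phred evidence
  against "nobody carries the allele".
* **Two callers.** The second caller's VCF is the first with each record
  independently dropped with probability `caller2_discordance` (default
  0.02).  Site-level drop-out is the only caller-2 behaviour the cascade
  consumes, so no discordant-genotype model is included.
* **SV/CN call sets.** When configured, an inversion for the edited
  founder with breakpoints at the paired cut sites shifted by (−8, +2),
  plus decoys: a deletion shared by all founders, a scaffold-contig
  deletion, a distant well-supported inversion, and a low-support
  duplication.  CN segments are diploid baselines with optional de novo
  and inherited deviations.

All randomness is a pure function of the seed; identical configurations
produce byte-identical files.  The pipeline driver derives per-stage
seeds by hashing the stage name into a 31-bit value so stages can be
re-run independently.

**What the generator does not emulate** — and therefore what passing
tests do not demonstrate about real data: alignment and mapping error
(the dominant source of false de novo calls in practice), base-quality
heterogeneity, indel realignment artifacts, PCR duplicates and strand
bias, caller-specific genotype-model disagreements, and population
structure in the variant database.  The cascade's measured recall
(≈ 0.95) and precision (≈ 1.0) on synthetic trios are upper bounds on
real-data performance; the value of the synthetic harness is exactness
(every rule is exercised against a known truth), not realism.

## Validation problem sizes

The shipped validation suite uses: 50 trios on 1-Mb genomes at 25× for
recovery statistics; 200 null and 100 signal replicates with a
10,000-position null for test calibration (the production default for
`n_random` remains 100,000 — calibration is insensitive to the null size
well below that); 50 seeded replicates for SV attribution specificity;
and 500 pooled trios on a 10-Mb genome at μ = 1e-8 for rate recovery.
These sizes give stable statistics at interactive runtimes.

## Known limitations

* The cascade consumes PLs from the primary caller only; a second
  caller's genotype model is not consulted beyond site presence.
* Reference-free indel normalization (suffix/prefix trimming) is
  sufficient for single-source keys but is not full left-alignment;
  integrating heterogeneous real callers would require it.
* The SV attribution model handles one cut pair per event and ignores
  translocations and complex rearrangements.
* `overlap_fraction` and the SV reciprocal-overlap filter are O(n·m);
  adequate for per-trio candidate lists, not for genome-wide catalogues.
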