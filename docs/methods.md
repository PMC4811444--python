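# Methods

This note documents the models, decision rules, thresholds and numerical
choices behind `brcaudit`, and what the synthetic-data generator does and
does not emulate.

## Coordinates and normalisation

All internal coordinates are 0-based half-open; VCF (1-based) and BED
(0-based half-open) are converted at the I/O boundary only. Variant
deduplication requires a canonical representation, so every catalogue
variant is left-normalised on read: shared terminal bases are trimmed,
re-anchoring one reference base to the left whenever an allele would
empty, and shared leading bases are then trimmed. The operation is
idempotent and maps two representations to one key exactly when they
imply the same haplotype (verified in the tests against a brute-force
haplotype-equality oracle). A variant anchored at the first base of a
contig that cannot be re-anchored further stays put rather than erroring.
Merging is a key-wise union: per-source significance strings are kept
side by side, never reconciled, because the audit needs the provenance,
not a consensus.

## Sequence context model

Callability is driven by sequence context plus pileup quality. Context
flags per locus:

* **uncovered** — not fully inside the union of amplicon inserts;
* **in/near homopolymer** — overlapping, or within `proximity_window`
  bp of, a maximal run of one base at least `min_homopolymer_len` long;
* **near amplicon end** — within `amplicon_end_margin` bp of the
  boundary of *every* covering insert (a locus rescued by an overlapping
  neighbour amplicon is not end-artefact-prone);
* **blacklist** — inside a user-supplied artefact BED, the second half
  of our operationalisation of "artefact-prone regions".

Defaults: `min_homopolymer_len = 4`, `proximity_window = 3`,
`amplicon_end_margin = 5`, `max_hp_indel_len = 2`. The 1–2 bp bound on
homopolymer indels reflects the error mechanism of flow/semiconductor
chemistry (single/double-base over/under-calls of a run); the run-length
and proximity thresholds are this package's own operating points — flow
error rates grow steeply from ~4 bp runs — and are all overridable in
`ContextConfig`. Strand is ignored throughout: panel and catalogue are
genomic-coordinate based.

## The forced-call classifier

For each catalogue variant the classifier must output a status
(REFERENCE / VARIANT / NOCALL) and a tier, in a fixed decision order:

1. uncovered locus → NOCALL / UNCALLABLE(`not_covered`);
2. the variant is a pure-repeat indel of ≤ `max_hp_indel_len` bp whose
   bases match a run of ≥ `min_homopolymer_len` bp containing or
   abutting the locus → NOCALL / UNCALLABLE(`homopolymer_indel`). The
   pure-repeat requirement matters: an `AC` insertion beside an A-run is
   *not* confusable with flow error and stays reviewable;
3. pileup failures → NOCALL / REVIEW with reasons: depth below
   `min_depth` (default 100 reads, the coverage floor routinely attained
   by such panels); alt reads on one strand only, or a two-sided Fisher
   exact test of strand × allele at `strand_bias_alpha = 0.001`; mean
   base or mapping quality below 20; alt allele fraction inside the
   noise band [0.02, 0.05) — too high for clean reference, too low for a
   confident call;
4. clean pileup but near-homopolymer / amplicon-end / blacklist context
   → status by the allele-fraction rule, tier REVIEW;
5. otherwise AUTOMATIC: VARIANT if the allele fraction reaches
   `min_vaf = 0.05`, else REFERENCE.

Fisher's exact test was chosen for strand balance as the standard exact
test for small 2×2 tables; the tests verify it against full
hypergeometric enumeration. Visual alignment review cannot be automated
faithfully, so it is modelled as the REVIEW tier plus an optional
override table (variant key → resolved status) merged at report time;
overrides resolve status but never change tier, so a locus that needed
review still counts as review in the report.

Across samples, a variant's panel-level tier is the *worst* tier
observed, and the fraction of samples yielding NOCALL is recorded. The
classifier contains no randomness; identical inputs give identical
results, and removing an amplicon can only worsen tiers (tested).

## Pathogenicity and origin rules

Mutation types come from a deliberately narrow HGVS parser
(substitutions, `del`, `dup`, `ins`, `delins`, `fsTer`, `Ter`, `=`);
anything else raises naming the token, rather than guessing. Coding-level
fallback classifies indels by whether the net length change is a codon
multiple.

Classification rules, in order: (1) recorded pathogenic in a catalogue;
(2) frameshift or nonsense — a premature stop codon in these genes is
pathogenic regardless of database status; (3) an unrecorded missense
sharing a codon with a recorded pathogenic missense is likely
pathogenic; (4) population frequency ≥ 1% with a majority of benign
submitters is benign; (5) otherwise VUS. "Recorded pathogenic" means
strictly more pathogenic than benign submitter entries, so a single
dissenting pathogenic submission among several benign ones (as happens
for the common BRCA2 polymorphisms) cannot force rule 1; "majority
benign" is the strict converse. Rule 1 precedes rule 2 so that a
recorded-pathogenic in-frame deletion or missense classifies from its
annotation; rule 3 applies only to unrecorded missense variants with a
parseable protein codon on both sides.

Origin from matched-normal allele fraction: ≥ 0.20 germline, ≤ 0.05
somatic (allowing FFPE noise and slight tumour contamination of normal
tissue), in between or missing → undetermined. Tumour allele fraction
≥ 0.85 flags homozygosity or loss of heterozygosity. The call is
monotone in normal VAF by construction. These thresholds are the
package's own: published cohorts report the labels, not per-case allele
fractions, so they are validated on synthetic data only.

## Sanger planning

Whole-gene confirmation counts follow the two-regime rule: one reaction
per exon shorter than `reaction_len` (150 bp of readable target),
otherwise ⌈length / 150⌉ per exon. Blind-spot rescue instead ignores exon
boundaries and computes the minimum number of fixed-length windows
covering the uncallable loci; the greedy left-to-right placement (start a
window at the leftmost uncovered locus) is optimal for fixed-length point
covering, and the tests confirm it against exhaustive search.

## Report arithmetic and rounding

Sensitivity is the assay-validation usage — the fraction of catalogue
variants the panel could detect, `100 × (total − uncallable) / total` —
and specificity is the confirmed fraction of reported positives against
an orthogonal method (stated in the report header, since both differ
from the epidemiological TN-based definitions). Every percentage is
computed by exact decimal division and rounded half-up to one decimal
(integers for cohort percentages), so emitted tables are bit-reproducible.
One consistent rule cannot reproduce every published figure: under
half-up, 2,840/2,841 is 100.0 (sometimes printed 99.9) and 829/6,953 is
11.9 (sometimes printed 12.0). We document the discrepancy and keep the
single rule.

## The synthetic-data generator

The generator emulates FFPE amplicon sequencing data well enough to
exercise every decision path with known truth:

* **reference/exons** — two genes laid out on one contig with 300 bp
  introns; default exon models total 5,659 and 10,262 coding bp.
  Background sequence is sampled with accidental runs kept strictly
  shorter than the shortest planted run, then maximal homopolymer runs
  (default: lengths 4–8, 60 runs) are planted at recorded exonic
  positions with their flanks fixed, so a scanner recovers exactly the
  planted list;
* **panel** — amplicons of 150 bp tiled with 30 bp overlap across exons
  ± 50 bp junctions, cycling three primer pools, minus deliberate
  unamplifiable gaps (default 0.5% of coding bases in four segments of
  the larger gene, mirroring where hard-to-amplify regions concentrate);
* **catalogues** — two sources with an exact planted key overlap and a
  planted composition of clean / near-homopolymer / homopolymer-indel /
  in-gap variants (defaults 87.1% / 11.9% / 0.2% / 0.7%); candidate
  sites are chosen so each category is unambiguous under the default
  context thresholds;
* **pileups** — Poisson depth (default mean 500 reads, comfortably
  above the 100× floor while keeping multi-sample audits fast), binomial
  strand splits, spurious 1 bp indel reads at rate
  `min(0.01 × run_length, 0.2)` at loci touching a run, optional
  single-stranded alt reads at planted strand-bias loci, and an optional
  (default off) C>T deamination channel, since FFPE artefact rates
  beyond these are not well quantified;
* **cohort** — 47 samples, 13 mutated (8/5 between the genes, 3 somatic
  in the second gene), tumour purity 0.7; germline heterozygous
  variants at VAF 0.5 in both samples (0.5 + purity/2 under loss of
  heterozygosity, probability 0.3), somatic at purity/2 in tumour and
  absent from normal, all binomially sampled at the simulated depth.

Each sub-generator draws from its own fixed-order stream seeded from
`(seed, stream_id)`, so outputs are bit-reproducible and adding a
generator never perturbs the others.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level alignment and mapping artefacts
(mapping quality is sampled, not earned), PCR duplicate structure,
amplicon dropout correlated with GC or fragment length, the full FFPE
damage spectrum, and real depth profiles (a constant Poisson mean versus
the heavy-tailed coverage of real panels). Tier recovery on synthetic
data demonstrates the classifier implements its stated rules, not that
the thresholds are clinically optimal.

## Problem sizes and determinism

The default test and acceptance runs audit the full 6,953-variant merged
catalogue over 3 simulated samples (enough to exercise worst-tier
aggregation; the classifier is deterministic, so additional samples only
re-draw the same pileup model) and check origin recovery over 8
simulated cohorts (104 tumour/normal pairs). Exhaustive oracle
comparisons are run to the sizes where enumeration is exact and fast:
all strand tables with ≤ 30 reads plus 1,000 random larger tables, and
brute-force rescue covers for up to 12 loci.

## Known limitations

* Visual review is a tier, not a model of a human reviewer; the REVIEW
  fraction measures how often review would be *demanded*, not how it
  would resolve.
* The identities of review-tier and uncallable variants on any real
  panel depend on that panel's amplicon coordinates; only counts and
  composition are meaningful comparisons across panels.
* HGVS support covers the constructs of this problem space; splice and
  UTR notation are rejected rather than classified.
* The same-codon likely-pathogenic rule is weaker evidence than a full
  ACMG/AMP evaluation, which is explicitly out of scope.
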