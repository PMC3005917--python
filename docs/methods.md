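# Methods

## Overview

`editscan` re-implements a transcriptome-wide survey of one-base-conversion
RNA editing built on short expression tags. The data model is that of the
MPSS and PARE platforms: strand-specific 17- or 20-nt sense tags sampled
from poly(A) transcripts (MPSS) or from the 5′ ends of cleaved mRNA decay
fragments (PARE), with per-library expression normalised to transcripts per
million (TPM). Editing evidence is a tag that fails to match any transcript
perfectly but aligns to exactly one location with a single substitution; the
substitution's ordered base pair ("X-to-Y" over {A, C, G, U}) is one of 12
editing patterns.

## Tag mapping

Mapping uses seed-and-extend over half-tag exact seeds. Because a single
substitution leaves at least one half of the tag intact, indexing both the
left ⌊L/2⌋-mer and the complementary right half of every length-L target
window guarantees that every alignment at Hamming distance ≤ 1 is found;
candidates retrieved through either seed are verified by full comparison.
The mapper is tested for exact equivalence against an exhaustive
Hamming-distance scan.

Three rules shape the evidence pool:

* a tag with a perfect hit anywhere is removed from editing evidence
  globally (it is explained without invoking editing);
* a tag whose single-mismatch placement is ambiguous (multiple loci) is
  discarded and counted — paralog divergence would otherwise mimic editing;
* only substitutions are modelled; there are no indels and no quality
  scores (the source platforms provide none).

Mapping is sense-strand only, matching the strand-specific protocols.

## Site calling and editing ratios

Candidate sites are keyed by (transcript, 1-based position, pattern).
Support is the number of *distinct* tag sequences across all libraries — an
abundant tag counts once. The calling thresholds are deliberately blunt
screens against sequencing error, not a statistical model:

* protein-coding (including organellar) transcripts: a site needs ≥ 6
  distinct supporting tags, and a transcript must retain ≥ 3 such sites;
* pre-miRNA hairpins: ≥ 3 distinct tags per site, no per-target minimum.

"More than five"/"more than two" are read strictly (≥ 6 / ≥ 3); thresholds
are configurable in `CallingCriteria`. Support pools libraries; per-library
support is retained for reporting. The ≥ 3-sites rule is applied across
patterns.

The per-library editing ratio is TPM-weighted:

    ratio = TPM(edited tags at the site) /
            (TPM(edited tags at the site) + TPM(perfect tags spanning the site))

A "spanning" perfect tag is one whose alignment covers the site's position.
One-mismatch tags whose mismatch lies elsewhere are excluded from the
denominator: they are neither perfect nor evidence for this site. By
default the numerator is restricted to the site's own pattern —
other-pattern mismatches at the same position belong to their own sites —
with `pool_patterns=True` switching both numerator and denominator to all
patterns at the position. Zero spanning coverage yields a missing value,
never a zero. The rationale for the per-pattern error screen is arithmetic:
a per-signature error rate of 5.00 % (20-nt tags) or 4.25 % (17-nt tags)
spreads over the 12 conversion patterns as ≈ 0.42 % or ≈ 0.35 % per pattern
(PARE: 1.30 ± 0.90 % → ≈ 0.03–0.18 %), far below the ratios of genuine
sites.

## Tissue profiles and clustering

Sites × libraries editing-ratio matrices keep missing values explicit.
Before clustering, rows must exceed a 2 % ratio in at least one library
(strictly greater; the all-libraries reading is available as `mode="all"`,
but it would delete exactly the tissue-specific rows the analysis is after).
Clustering is agglomerative with average linkage (UPGMA) on the
1 − Pearson r distance, correlations computed pairwise-complete over
missing entries; rows with undefined correlations (zero variance or < 2
shared observations) are assigned distance 1 and logged. Results are
deterministic; ties resolve by input order. Sites can be split by the
length (17 vs 20 nt) of their supporting tags for separate analyses, a site
supported by both lengths appearing in both.

## Codon, exon-edge and border annotation

Codon effects are computed only for sites inside the annotated CDS, in the
annotated frame (never re-inferred by ORF scanning). A start gain is a
non-AUG codon becoming AUG; a stop gain is a non-stop codon becoming
UAA/UAG/UGA. `enumerate_feasible_generations` inverts the logic: for a
target codon and a pattern, it lists every source codon one such edit away.
A cell is structurally impossible exactly when the pattern's product base
does not occur in the target codon; over the 4 × 12 start/stop table this
yields 15 guaranteed-zero cells (3 each for AUG, UAG, UGA which lack C; 6
for UAA which lacks both C and G). 5′UTR upstream-AUG creation is excluded
by construction (CDS-resident edits only).

Exon-edge annotation flags sites within the first or last three nucleotides
of their exon (positions with splicing relevance in the mature-mRNA
coordinate system). Distance to the translation border is signed:
`position − (last CDS base)`, negative inside the CDS, positive in the
3′UTR. Border enrichment is reported as counts inside/outside a ± window —
no formal test is attached, as the underlying observation is descriptive.

## Sequence context

For each pattern, 100-nt windows (50 up, site at offset 0, 49 down) are
extracted, N-padded at transcript ends; pad characters are excluded from the
columns they cannot cover. Per-column information content is IC = 2 − H
bits over {A, C, G, U} against a uniform 25 % background (no GC
correction), optionally with the small-sample correction
e_n = 3/(2·ln 2·n) subtracted and clipped at zero. The site column itself
is included: its reference base is fixed by the pattern, so a 2-bit spike
at offset 0 is a built-in sanity check. A random control draws windows
uniformly from transcript positions.

## GO enrichment

One-sided hypergeometric upper-tail tests per annotation term with ≥ 1
edited gene, against the full gene background; Bonferroni correction over
the tested terms (Benjamini–Hochberg available). Significance is strict:
corrected p < 1e-7 by default. The gene→term map is used flat — no
true-path propagation — so pre-propagated maps should be supplied when that
semantics is wanted. One calibration subtlety: because the hypergeometric
test is discrete, the null probability of p < 0.05 is at most — and
typically below — 0.05; the test suite therefore checks the empirical null
rejection rate both for conservativity and for agreement with the exactly
computed discrete rejection probability, rather than asserting equality
with the nominal level.

## Pre-miRNA editing

Edits are applied jointly to hairpin sequences (conflicting products at one
position are an error; re-application is idempotent). Secondary structures
are consumed as externally produced dot-bracket strings — the package
deliberately contains no MFE folder, which would dwarf the analysis itself —
and compared as base-pair sets: pairs lost, pairs gained, and a separate
delta for pairs touching the mature-miRNA interval.

## Synthetic data generator

The generator emulates the study design so every stage is testable offline:

* transcripts with exon/CDS/UTR structure and compartment labels (defaults:
  90 % nuclear, 6 % mitochondrial, 4 % chloroplast); CDSs start with AUG,
  end with a stop, and contain no internal stops;
* pre-miRNA hairpins of 70–200 nt with an annotated mature interval;
* planted editing events with per-library ratios; sites on a transcript are
  independent, so k events yield up to 2^k haplotypes with product-mixture
  weights (no linkage model is implied by the data);
* MPSS-like libraries: 17 or 20-nt sense tags, anchored immediately 3′ of a
  GAUC (DpnII) motif — the MPSS protocol's anchoring — with uniform start
  positions as the documented fallback and as an explicit mode; 17
  libraries of 20 000 tags by default, log-normal transcript abundances
  (σ = 1; σ = 0 gives equal abundances for controlled experiments);
* PARE-like libraries: 20-nt tags from sampled cleavage positions, error
  1.30 % by default;
* the substitution error is per *signature*: with the configured
  probability a tag carries exactly one substituted base, position uniform,
  replacement uniform over the three alternatives. Whether the platform's
  quoted ~5 % figure is per base or per signature is not decidable from the
  published description; per-signature is the default because the 12-way
  division into per-pattern rates treats the signature as the unit, and the
  knob accepts any rate in [0, 1].

TPM is count/total × 1e6 per library. Everything is deterministic given the
seed; per-library seeds are spawned from the master seed.

What the generator does **not** emulate: bead cloning and PCR duplication,
adapter chemistry, indels, position- or context-dependent error rates,
cross-transcript sequence homology (paralogs), introns, and real tissue
covariance structure. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic under its stated error model, not
robustness to every artefact of the historical platforms.

## Numerical and design choices

* Coordinates: 1-based closed intervals on the spliced transcript
  everywhere in memory and in GFF3; BED output converts to 0-based
  half-open. FASTA is written with T and read with T→U conversion.
* Correlation distances are clipped to [0, 2] to absorb floating-point
  drift in |r| ≤ 1; zero-variance rows get distance 1, never NaN.
* Degenerate inputs: all-zero libraries, empty target sets, CDS lengths not
  divisible by 3, unbalanced dot-brackets and from-base mismatches raise
  errors that name the offending record; zero-coverage ratios and all-N
  context columns are encoded as missing rather than thrown.
* Problem sizes in the test and acceptance runs (tens of transcripts,
  2–17 libraries, 10^4–10^5 tags) are chosen so each property is measured
  with comfortable statistical margin — e.g. per-pattern calibration over
  10^5 tags puts 3σ at ≈ 15 % of the expected per-pattern count, and
  planted-ratio recovery at ≥ 200 spanning tags bounds the per-site
  standard error at ≈ 0.035.

## Known limitations

* No statistical model of editing vs error beyond the threshold rules; a
  binomial or Bayesian caller would be an extension, not a reproduction.
* Sense-strand only; no genome-level (intron-aware) alignment.
* GO enrichment without graph propagation.
* The historical headline counts of the original survey depend on the 2010
  databases and are not recomputable from synthetic data; the package
  reproduces the analytic quantities (error arithmetic, codon-table
  structure) and validates the algorithms by parameter recovery instead.
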