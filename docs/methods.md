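# Methods

## Model and procedure

The package measures the population burden of pathogenic variation in a
sequencing cohort and derives allele-frequency thresholds from it. The chain
is:

1. **Consequence calling.** Each alternate allele is normalized (shared
   prefix/suffix trimmed) and classified on the single clinically relevant
   transcript of its gene: coding SNVs by translating the affected codon of
   the mutant CDS (stop gain → nonsense); indels by net length modulo 3;
   any variant whose footprint touches a consensus splice dinucleotide (the
   first or last two intronic bases, in transcription direction) takes the
   splice category, which dominates exonic categories for boundary-spanning
   indels. Variants overlapping no clinically relevant transcript are
   dropped with a logged warning.
2. **PTC localization.** For nonsense variants the premature termination
   codon (PTC) is the variant codon. For frameshifts the mutant spliced
   transcript is reconstructed and translated from the first altered codon
   through the transcript end; the first stop found is the PTC. Its
   coordinate is reported in mutant-transcript spliced coordinates, which
   coincide with reference coordinates upstream of the edit and differ by at
   most the indel length (1–2 nt here) downstream. If no stop occurs before
   the transcript end, no PTC is recorded.
3. **NMD classification.** Decision cascade, first match wins:
   experimental-escape override → `NMD_negative`; splice variant in the
   final intron → `NMD_negative`, in any earlier intron → `NMD_positive`;
   non-truncating category → `NMD_negative`; single-exon transcript →
   `NMD_negative`; no PTC → `NMD_negative`; PTC in the final exon →
   `NMD_negative`; PTC within 50 nt of the final exon–exon junction →
   `NMD_negative`; otherwise `NMD_positive`. The 50-nt window is inclusive
   (distance ≤ 50 escapes), measured from the PTC's first base in spliced
   coordinates; the canonical boundary rule does not specify inclusivity,
   so this is a documented package choice.
4. **Cohort filtering and MAF.** MAF = AC_adj / AN_adj per alternate allele
   (multi-allelic records decomposed; AN shared per site). Only PASS records
   at loci with AN_adj ≥ 80,000 (inclusive) enter the analysis, keeping
   frequency estimates meaningful at the singleton scale. Frequencies are
   displayed as percentages at two significant figures; internal arithmetic
   is full precision.
5. **Consensus pathogenicity.** Assertions from untrusted submitters are
   discarded. Two or more trusted submitters, all P/LP → consensus
   pathogenic; all LB/B → consensus benign; P/LP mixed with anything weaker
   → conflicting; exactly one trusted P/LP → single-submitter pathogenic
   (resolved by an external adjudication table, since a full ACMG criteria
   engine is out of scope). The pathogenic set is the union of consensus
   calls, adjudicated P/LP calls, and NMD-positive variants in genes with an
   established loss-of-function mechanism, each member tagged with its
   provenance.
6. **Burden statistics.** Frequency bins are left-closed/right-open
   (`[0, 0.005%) [0.005, 0.01%) [0.01, 0.05%) [0.05, 0.1%) [0.1%, ∞)`), so
   "above a threshold" consistently means MAF ≥ threshold. Absent variants
   (AC 0) count below every positive threshold and are excluded from bin
   counts (reported separately). Variants at AC > 3 are founder/recurrent
   candidates and always listed for literature review. Distribution
   comparisons use the two-sided Wilcoxon rank-sum test: exact enumeration
   when both n ≤ 8 without ties, tie-corrected normal approximation (no
   continuity correction) otherwise; a degenerate comparison where all
   values coincide reports p = 1. Publication summaries report five-number
   summaries with linear-interpolation quartiles and min/max whiskers, and
   the MAF–publication-count correlation (product-moment by default; the
   estimator is configurable to rank-based since the source analysis does
   not name it).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_total_alleles` | 80,000 | AN_adj depth floor (inclusive) |
| `escape_window` | 50 nt | PTC-to-final-junction escape distance (inclusive) |
| `recurrence_ac` | 3 | founder candidates have AC strictly above this |
| `bin_edges_percent` | 0.005, 0.01, 0.05, 0.1 | frequency bin edges |
| thresholds | 0.0025–0.1% | candidate thresholds in frequency profiles |
| `correlation_method` | pearson | MAF–publication correlation estimator |

## Synthetic worlds

The generator emulates the statistical structure of a large exome cohort
(~60k individuals ≈ 121k alleles) restricted to a panel of loss-of-function
disease genes; it does not emulate real human gene architecture, mutation
rates, or population genetics (no coalescent). Defaults state the emulated
world: 12 genes (1–12 exons, both strands, valid ORFs, GT..AG introns, stop
codon and 3' UTR inside the final exon — where essentially all real stop
codons live), 500 pathogenic truncating variants of which 85.3% are absent
from the cohort and 74.8% of the observed are singletons, 14 planted founder
alleles at AC 4–40 (always PASS at deep loci, emulating well-genotyped
recurrent variants), AN_adj ~ N(121,000, 6,000) with 5% of loci below the
80,000 floor, 5% non-PASS records, benign/background variants spanning MAFs
up to the common-polymorphism range, 0–4 trusted assertions per variant with
a 5% conflict rate, and publication counts that are negative-binomial with
mean rising in MAF for pathogenic variants (planting a positive correlation)
versus 47% zeros for benign ones.

Ground-truth NMD labels in the manifest come from an independent oracle that
mutates the chromosome, shifts exon/CDS coordinates across the edit, splices
and translates the mutant transcript with Biopython, and applies the escape
rules literally — not from the production classifier — so the 100%-agreement
test is a real cross-check of two implementations. A green synthetic test
therefore establishes internal consistency of the pipeline and correct rule
arithmetic; it does not establish performance on real annotation edge cases
(complex delins, multi-transcript genes, non-canonical splice sites), which
are out of scope.

Packaged reference tables (checksummed TSVs) carry the published panel
numbers; where a cohort record must be reconstructed from a printed
frequency, allele counts are taken at a deep (121,000) or shallow (75,000)
seed AN and AN is re-derived so AC/AN reproduces the printed value. Their
chromosome/position/allele fields are synthetic placeholders — only gene,
AC/AN, filter flags and classifications are meaningful.

## Numerical and design choices

- Coordinates are 1-based inclusive genomic (VCF convention) and 1-based
  mRNA in transcription direction; minus-strand handling is confined to
  reverse complement at sequence extraction.
- Intron numbering follows transcription order, so the "final intron" is
  the biologically last one regardless of genomic order.
- Non-final-intron consensus splice variants are `NMD_positive` without
  exon-skipping simulation; boundary-spanning indels classify as splice.
- Frameshifts with no downstream stop are `NMD_negative` (`no_ptc_found`)
  and logged: with no PTC the NMD trigger cannot be met.
- All-VUS or benign-mixed-with-VUS assertion sets yield
  `no_trusted_assertion` rather than `conflicting`: conflict requires a
  P/LP assertion contradicted by a weaker one.
- The BRCA1/2 reconstruction contains one internal tension inherited from
  its source: the founder table implies 7 variants at/above 0.005% (giving
  99.5% below), while the printed summary says 1356/1364 = 99.4%; the
  acceptance test pins the table-derived count and accepts the summary to
  one-variant resolution.
- The 80,000-allele floor is applied per site, and "minimum depth of
  80,000" is read as inclusive (≥).
- Every stage logs input/surviving counts; the JSON summary reconciles with
  the TSV reports.

## Limitations

- One designated clinically relevant transcript per gene; no multi-isoform
  aggregation, UTR-aware start-codon rescanning, or readthrough models.
- No subpopulation-stratified frequencies (global cohort frequencies only).
- Publication counts are an input table; no literature retrieval.
- The rank-sum normal approximation is slightly conservative under the
  extreme zero-inflation typical of pathogenic MAF vectors; the calibration
  test bounds the type-I error at n = 200 per group rather than asserting
  exactness.
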