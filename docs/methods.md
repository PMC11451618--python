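# Methods

## The experimental design being modeled

A comprehensive deletion scan asks, for every contiguous in-frame deletion
of a protein, whether the truncated protein still works. The design this
package implements reaches that goal with a single constant CRISPR cut:

1. The gene is installed as two tandem copies encoding the same protein but
   maximally divergent in DNA sequence, separated by a synthetic Cas9
   target site and a counter-selectable marker (URA3-style).
2. Cas9 plus one constant gRNA cleaves between the copies. A pooled library
   of repair templates directs homology-directed repair: each template's
   two arms anneal to a prefix of copy 1 and a suffix of copy 2, fusing
   them into one gene with codons *m..n* removed and deleting the cut site
   and marker (so repaired cells survive counter-selection).
3. Deletion-allele abundances are read out by amplicon sequencing before
   and after a lethal-selection condition in which only cells carrying a
   functional protein variant survive.

## Synonymous recoding (`recode`)

For each reference codon, the candidate output codons are the synonymous
codons minimizing position-wise base matches (Hamming similarity over the
3 positions) with the reference codon — "share as few bases as possible"
read position-wise, which gives e.g. TCT→AGC (0 shared bases) for serine.
Ties are resolved by a weighted draw proportional to host codon usage
(S. cerevisiae genome fractions are built in; any table can be supplied as
TSV), falling back to a uniform draw if all tied weights are zero. A single
seeded generator is consumed left-to-right, so the output is reproducible
and edits to the input perturb only downstream draws. The terminal stop
codon is recoded by the same rule (the usage table carries stop weights);
divergence there is as useful as anywhere else and costs nothing.

Identity between the two alleles is measured position-wise (the alleles
have equal length by construction, so no alignment is involved). Typical
recoded identity for natural-composition proteins is 50–65%.

## Deletion enumeration and oligo design (`design`)

A deletion is an inclusive 1-based codon interval [m, n]. Deletion
coordinates anchor the arms: the left arm is the `arm_len` (default 100) nt
ending at the last base of codon m−1 of copy 1, the right arm the
`arm_len` nt starting at the first base of codon n+1 of copy 2. Arms
extend into the promoter or terminator flank when the deletion sits near a
gene end; a too-short flank is a hard error, never silent truncation. With
the default 100-nt arms and 15-nt primer sites every oligo is exactly
230 nt. With start and stop codons fixed (the analyzed set), an L-residue
protein has k = L−1 deletable codons and k(k+1)/2 deletions — 3,741 at
L = 87. `include_termini=True` extends the deletable range to codons
1..L+1.

Clean-chimera (no-deletion) templates join copy 1 through codon j to copy 2
from codon j+1, one per internal junction, deduplicated by sequence. For
deletion templates, sequence collisions between distinct deletions are
*reported* but both kept: a collision means the two repairs are physically
identical molecules, which the analyst must know about rather than have
silently merged.

gRNA uniqueness is a brute-force scan: every 20-mer immediately 5′ of an
NGG on either strand, exact PAM, Hamming distance over the 20-nt spacer
only; the minimum distance (optionally excluding the perfect on-target
site) is returned, or a sentinel when the genome has no PAM-adjacent site.

## Exact read counting (`match`)

Reads are assigned by perfect matching only. Constant anchor sequences
(defaults: the 20 nt of promoter and terminator flank abutting the gene for
the genomic amplicon; the primer sites for the plasmid amplicon) are
located in each read — in forward or reverse-complement orientation — and
the intervening core must equal an expected allele core byte-for-byte.
Anchor search makes counting independent of the variable-length prefixes
(staggered primers, random barcodes) that amplicon libraries carry.
Everything else is "unmatched": sequencing errors, NHEJ junctions, escaper
artifacts. The unedited dual-copy locus is indexed as a distinguished
`parental` category rather than folded into unmatched. Quality scores are
ignored; structurally malformed FASTQ records are skipped and counted.
Totals obey `assigned + unmatched + skipped == reads` per library.

## Scoring (`score`)

Frequencies are counts over the total of *allele-assigned* reads in the
library. Unmatched reads are excluded from the denominator deliberately:
their fraction differs systematically between conditions (escaper and NHEJ
products accumulate under selection), so including them would distort the
ratio with a condition-dependent factor. The parental category is likewise
excluded from score denominators.

Per replicate, e(d) = freq_ON(d) / freq_OFF(d), defined only where the
unselected library holds ≥ 5 reads (`min_glucose_reads`); below that the
cell is unobserved. No pseudocounts: a zero selected count is a true 0
(complete depletion), and the unselected-read floor already bounds the
denominator. Merging: median when every replicate observed the allele;
the minimum of the observed values when only some did (conservative
against escaper-driven inflation); missing when none did. A mean-merge
variant is provided for sensitivity checks. Scores are reported unscaled.

## Region test (`stats`)

The triangle of a region [a, b] is every deletion with a ≤ m ≤ n ≤ b. The
observed statistic is the mean score over the triangle's scored cells; the
null resamples the same number of cells uniformly *without replacement*
from all scored cells of the matrix, 1000 times by default, and
p = (1 + #{null ≥ observed}) / (1 + N). Choices made where the procedure
was open: upper tail (dispensability is *high* survival score); sampling
without replacement (the observed triangle is itself a set of distinct
cells); the +1 correction (an empirical p of exactly 0 from finite
resampling is not meaningful). The CLI runs the test per replicate by
default and can also test the merged matrix. The test is shift-invariant
and its p-values are approximately uniform under a permuted global null
(verified in the test suite).

## Homolog gaps (`gaps`)

Within a user-supplied multiple sequence alignment, columns where a homolog
has a gap and the reference a residue are mapped to ungapped reference
coordinates and merged into maximal intervals; reference-gap columns are
recorded separately as insertions. Homologs with identical interval lists
collapse into numbered patterns. Gap intervals inside a homolog's leading
or trailing gap run — usually incomplete sequence, not genuine deletion —
can be excluded with a flag, replacing the manual curation such sets
otherwise need. Overlay classification looks up the exact cell (m=a, n=b),
falls back to the best-scoring cell inside the interval's triangle when
that cell is blank, and labels the interval dispensable when the score
exceeds the threshold (default 0.5).

## Synthetic data (`simdata`)

The generator emulates the statistical structure of a pooled scan:

- **Construct**: ATG + random body codons + TAA, recoded second copy,
  random promoter/terminator flanks (150 nt), a cassette with the constant
  equal-base-composition spacer `ACGTATCGGTACATGCGCAT` + AGG. Body codons
  are drawn from a restricted alphabet — the nine two-codon amino acids
  plus serine via TCT→AGC — chosen so recoding is deterministic and the two
  copies share no codon anywhere. Without this, deletions (m, n) and
  (m+k, n+k) can yield byte-identical repaired molecules whenever a copy-1
  codon block equals a copy-2 block, making ground truth ill-defined; the
  restricted alphabet guarantees every deletion allele is a unique
  sequence, which is the property a real scan's recoded allele pair is
  engineered to approximate.
- **Libraries**: per-replicate allele abundances are log-normal (σ = 1 by
  default; pooled cloning is uneven), with a per-replicate dropout fraction
  (default 0.10, matching the ~88–95% representation real oligo pools
  achieve). Unselected counts are multinomial from the abundances at depth
  = `reads_per_allele` × alleles; selected counts are multinomial from
  abundance × survival.
- **Survival**: 1.0 inside planted dispensable domains, a small escaper
  floor elsewhere (default 0.01; per-allele overrides available). Escape
  is modeled as a uniform background rate, the phenomenon the median merge
  is designed to resist.
- **Reads**: exact amplicons with a random 0–6-nt stagger prefix; an
  optional decoy fraction carries exactly one core substitution and must be
  rejected by the matcher. Output is byte-identical per seed. The ledger
  records per-library intact counts and functional labels; with the decoy
  rate at 0, exact matching must reproduce it perfectly.

Not modeled: quality-correlated errors, indels, PCR chimeras, and
between-replicate shared synthesis dropout. Passing tests therefore show
the pipeline's bookkeeping and statistics are correct under the assay's
idealized statistical structure — not that real libraries are free of
systematic artifacts (chimeric PCR, index hopping, jackpot clones), which
land in the unmatched pool or require upstream QC.

## Problem sizes and numerical choices

The test suite and the acceptance script run full-scale design (L = 87,
3,741 oligos) but read-level simulation at L = 30 (435 alleles,
200 reads/allele, 3 replicates — ~0.5 M reads), which exercises every code
path at a size a laptop handles in seconds. Null-calibration checks use a
neutral simulation (all survival 1) because a strongly bimodal selected
matrix ties region means and makes the empirical p conservative; the
matrix is re-permuted per tested region so the 500 p-values are independent
draws from the global null. Classification in the end-to-end recovery
check thresholds merged scores at 0.5, the midpoint on the ratio scale
between the two planted survival regimes.

## Known limitations

- Exact matching cannot rescue reads with any core error; depth budgeting
  should anticipate the platform error rate.
- Sequence-identical deletion collisions are possible for repeat-containing
  genes even with recoding; the design and index stages surface them, but
  resolving them (e.g. merging equivalence classes) is left to the analyst.
- The region test treats cells as exchangeable under the null; spatial
  correlation in real score surfaces (neighboring deletions overlap) makes
  the test anti-conservative for very small regions, so significant regions
  should be read as candidates, not proof.
- No multiple-testing correction across regions is applied.
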