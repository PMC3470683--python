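# Methods

## The model

Peanut GDH charge isomers polymerize non-genomic, isomeric RNAs whose
sequences are statistical functions of the enzyme's binomial subunit
composition. A GDH-synthesized RNA silences mRNAs homologous to it; an
mRNA that shares only imperfect homology (roughly 70–80 % identity) with
some silencing RNA is cross-recognized weakly and thereby *protected*
from knockout. The package formalizes this as a pipeline of four coupled
models:

1. **Homology / protection.** Percent identity between probe cDNAs is the
   protection signal. Two probes from different pathways whose identity
   falls in the protection window `[protection_low, protection_high)`
   (default [70, 100)) form an undirected protection edge; a pathway is
   protected when any edge touches it. The upper bound is exclusive
   because perfect homology is the silencing trigger itself, not
   protection.
2. **Silencing call.** For each (treatment, pathway), with GDH-RNA
   intensity *g* and target mRNA intensity *m* (arbitrary densitometry
   units, used raw): NOT_DOWNREGULATED if *g* is at or below the
   detection floor or *g* < θ·*m* (θ = 2, the minimum 2:1
   normalization ratio, inclusive); otherwise PARTIAL if the pathway is
   protected, FULL if not. Residual mRNA is 1, 0.5, 0 for NOT / PARTIAL /
   FULL. The study observed no FULL downregulation of arachin or
   desaturase mRNAs; in the model this is a theorem — FULL is unreachable
   for protected pathways — not an input. "FULL = silenced and
   unprotected" is itself a modeling assumption: the source work never
   operationalized full downregulation because none occurred.
3. **Permutation counting.** A treatment's state assignment over the
   n = 10 regulatory pathways (phosphate translocator, GBSS, PGM,
   glucosyltransferase, ACCase, GAR synthase/transformylase, nitrate
   reductase, NADH-GOGAT, fatty-acid desaturation, arachin biosynthesis)
   is reduced to its multiset of state-group sizes; the number of distinct
   sequential arrangements is the multinomial coefficient n!/(a!b!c!),
   computed in exact integer arithmetic (k-class generic, default 3). The
   inverse map (count → candidate splits) is exhaustive over all
   non-increasing 3-part compositions of n; it is not injective — 1,260
   is attained by both (5,4,1) and (6,2,2) — and the package reports all
   preimages rather than choosing.
4. **Fatty-acid phenotype.** O/L = C18:1 / C18:2 (scale-invariant),
   percent unsaturated = Σ of C16:1, C18:1, C18:2, C18:3, C20:1, C22:1.
   O/L bands LOW/MID/HIGH_NORMAL cut at 1.50 and 2.50 — midpoints of the
   gaps between the observed bands (1.26–1.38, 1.60–1.81, 3.31) — and are
   configurable; the observed mid band reaches down to an O/L of 1.59, so
   the defaults are a choice, not a fact of nature.

## Alignment details

Semi-global (free end gaps) pairwise alignment via
`Bio.Align.PairwiseAligner` with an IUPAC-intersection substitution
matrix: codes match iff their base sets intersect (N matches anything),
match +1, mismatch −1, gap open −2, gap extend −1; a length-L gap costs
open + (L−1)·extend. The original homology figures came from unspecified
BLASTn runs, so the scheme is configurable; the defaults approximate
"plus/plus" BLAST-style identity on near-full-length homologs while being
fully deterministic. Reverse-complement ("plus/minus") comparison is
computed only on request.

Identity = 100 × compatible columns / aligned columns, where internal gap
columns count in the denominator and never as matches, and end-gap
columns are excluded when end gaps are free (when both sequences have
unmatched flanking characters at the same end, all those flanking
gap-containing columns are trimmed, although the DP necessarily penalizes
one of the two runs as internal). Among co-optimal alignments the
*maximum* identity is reported, implemented by enumerating co-optimal
tracebacks lazily (capped at `max_alignments`, default 1000) — this
realizes the "best identity among optimal-score alignments" contract
directly instead of privileging one traceback order. For sequences short
enough to enumerate completely the result provably equals an exhaustive
brute-force search (the test suite checks this against an independent
monotone-matching enumerator up to length 12); for the packaged ~280-nt
probe pair the identity spread across the first 1000 co-optimal
alignments is under 0.4 points. A degenerate alignment with zero aligned
columns (mutually incompatible sequences under free end gaps) reports
identity 0.

On the two packaged probe cDNAs (279 and 284 nt, the desaturase probe
containing many N calls) the default scheme yields 77.6 % identity,
within the ±2-point comparison band used for the printed integer 77 %
(printed rounding and unknown BLAST parameters). Identity matrices are
reported to 1 decimal.

## Synthetic data

The generators emulate the study's unpublished densitometry, not its
chemistry:

- **Band intensities.** Baseline 100 (arbitrary units). mRNA intensity =
  baseline × residual fraction of the true state; GDH-RNA intensity =
  baseline × 3.0 for silenced (PARTIAL/FULL) and × 0.5 for unsilenced
  pathways — putting silenced pathways comfortably above and unsilenced
  ones comfortably below the 2:1 call threshold. Both signals carry
  independent multiplicative lognormal noise with unit mean and
  configurable CV (default 0.1); lognormal because densitometry signals
  are strictly positive. With CV 0 classification recovers the truth
  exactly; at CV 0.1 mean recovery accuracy over 200 replicates exceeds
  0.95.
- **True states.** Drawn consistently with a protection set (protected →
  {NOT, PARTIAL}, unprotected → {NOT, FULL}, silenced with probability
  0.5), since protection is a network property and an inconsistent truth
  would be unrecoverable by construction.
- **Sequences.** `mutate_to_identity` substitutes exactly
  round(L·(1−t/100)) unambiguous positions with different concrete bases,
  hitting the target ungapped identity within ±1 point for L ≥ 50.
- **Fatty acids.** Linear knockdown model: linoleate = wild linoleate ×
  residual desaturase fraction, with the removed mass added to oleate —
  conserving the C18:1+C18:2 pool and total unsaturation, and making O/L
  strictly decreasing in the residual. This is the simplest response
  consistent with knockdown moving linoleate from ~34 % toward ~19 %; the
  true dose–response is unknown (only endpoint compositions exist), so a
  different response curve can be supplied by transforming the residual
  before calling the generator.
- **Hexamers.** GDH's hexameric isoenzymes over k subunit types are
  enumerated as all multisets of size 6 with exact multinomial
  probabilities (28 classes for k = 3; probabilities sum to 1 within
  1e-12).

What passing recovery tests shows is internal consistency of
simulate-then-classify under these assumptions; real Northern blots add
background, saturation, lane effects and probe cross-hybridization that
the generator does not model, so recovery accuracy here is an upper
bound on what real densitometry would give.

## Numerical and data-handling choices

- Multinomial counts use arbitrary-precision integers; no floating-point
  factorials anywhere in the combinatorial core.
- Reported metric rounding is decimal round-half-to-even at printed
  precision (O/L to 2 decimals, percents to 1), computed with `decimal`
  on the quotient/sum to avoid binary-float rounding artifacts; unrounded
  values are returned alongside.
- Censored "<0.1" composition cells are stored as 0 with a flag
  (reproducing the printed percent-unsaturated values on the consistent
  columns); half-bound imputation (0.05) is available per profile.
- The packaged composition table is transcribed as printed, including its
  internal inconsistencies; the fixture manifest lists the columns whose
  printed O/L or percent-unsaturated cells cannot be reproduced from
  their own printed components (truncation in four O/L cells, an
  irreconcilable NS linoleate cell, two percent-unsaturated sums).
  Exact checks run only on consistent columns; nothing is "corrected".
- The packaged per-treatment state table is a *derived completion*:
  arachin and desaturase states follow the published qualitative
  statements, the remaining eight pathways are assigned so each
  treatment's state multiset reproduces its published permutation count.
  It is metadata for end-to-end demonstration, not measured data.
- Distribution summaries use the arithmetic mean of the supplied counts.
  The ten packaged counts have mean 2,016 and adjusted sample skewness
  +0.40; five treatments exceed that mean. (The source work quotes a mean
  of 2,520 under an unstated averaging rule and places only two
  treatments right of it; that rule is not reproduced here.)
- A ratio exactly at the 2:1 threshold counts as silenced (the threshold
  is a minimum). mRNA intensity 0 with silencing RNA present is treated
  as an infinite ratio — the state is then decided by protection alone —
  and the pathway is flagged in the output.

## Problem sizes

All fixture computations are desk-scale: two ~280-nt probes, 10
treatments × 10 pathways, 200-replicate recovery simulations; the full
test suite runs in a few seconds on one CPU. Brute-force alignment
oracles in the tests enumerate all monotone matchings and are run on
sequence pairs up to length 12 (against a partner of length ≤ 8, keeping
enumeration around 10^5 matchings).

## Known limitations

- Protection is binary and global (any edge protects everywhere); the
  per-treatment presence/absence of specific silencing RNAs can be
  expressed only through the explicit protected-set override.
- Band intensities are consumed as digitized tables; image densitometry,
  background subtraction and housekeeping normalization are out of scope
  (the study's protocol itself rejects housekeeping references).
- Only the two printed probe sequences ship; the nitrate-reductase and
  NADH-GOGAT homologies (73/79/80 %) involve sequences published
  elsewhere and are representable in the network only if the user
  supplies them.
- Permutation counts are combinatorial bookkeeping over states, not a
  mechanistic flux model.
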