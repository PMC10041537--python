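# Methods

## The measurement model

The package models the standard duplex-sequencing design for a short
reporter target.  A double-stranded fragment (300–350 bp) is tagged with
two random 12-nt arms (α, β); reads from the two physical strands carry the
arm pair in opposite order (αβ vs βα) ahead of a fixed 5-nt spacer.  Read
pairs cover the two fragment ends: read 1 is the first 137 nt of the
originating strand, read 2 the first 137 nt of the opposite strand.  The
top strand's read 1 and the bottom strand's read 2 therefore cover the same
fragment end in the same orientation, and those two single-strand
consensuses are the pair that forms a double-strand consensus (DCS) for
that window.  With single-window data (no mates) top pairs with bottom
directly; the pairing rule is the only place mate information is used.

The duplex acceptance rule is implemented at base resolution: a DCS base
exists only where both strand consensuses are non-N and identical,
otherwise the position is masked to N.  Masking (rather than whole-read
rejection) preserves read coordinates so trimming and pileup need no
shifts; a `reject_on_disagreement` switch provides the stricter whole-read
behavior for sensitivity analyses.  Families whose two tag arms are
identical have no defined strand and are dropped; with 12-nt arms this is a
~6e-8 event per molecule.

Trimming is a mask over read coordinates (defaults: bases 1–8 and 120–137,
1-based inclusive), applied before placement.  Because the right-window DCS
reads in reverse orientation, the asymmetric trim maps to opposite ends in
reference coordinates; the truth oracle used in testing accounts for this.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tag_length` | 12 nt/arm | duplex tag arm length |
| `fragment_length_range` | (300, 350) bp | sonication size window emulated |
| `read_length` | 137 nt | consensus-visible read span |
| `min_family_size` | 3 reads/strand | SSCS admission |
| `consensus_threshold` | 0.7 | plurality fraction for an SSCS base |
| trim | 1–8, 120–137 | masked read positions (111 nt retained) |
| `per_base_error_rate` | 1e-3 | strand-independent artifact rate |
| `family_size_mean` / `min` | 5 / 0 | Poisson read-pairs per strand |
| `seed_length` / `min_identity` | 20 / 0.9 | placement seeding and acceptance |
| pLOGO `flank` / `alpha` | 7 / 0.05 | window half-width; significance level |

The family-size minimum and consensus threshold are the conventional
defaults of published duplex consensus tools; both are exposed because the
upstream literature does not fix them.  Fragment range, read span and trim
window are the values a 137-nt consensus protocol uses.

## Synthetic data: what it emulates and what it does not

The generator draws fragment intervals uniformly, injects true mutations at
Binomial(length, rate) per molecule — each mutation first draws a spectrum
channel, then a concrete site uniformly among fragment positions matching
that channel's trinucleotide context on either strand — and adds
independent per-base artifacts to every read.  Channels with spectrum mass
but no matching site in the region are renormalized away with a warning;
channels unmatched within one fragment are redrawn.  All randomness flows
from a single seed and output FASTQ is byte-identical across reruns.

Deliberately *not* modeled: PCR amplification trees (artifacts are i.i.d.
per read, real jackpot errors are correlated within a strand family), tag
synthesis/sequencing errors (tags must match exactly; no tag clustering),
indels, quality-score structure, GC/coverage bias, and mapping ambiguity of
repetitive targets.  Passing tests therefore demonstrate correctness of the
consensus/calling/spectrum logic under the duplex error model, not
robustness to chimeric reads, tag collisions at extreme depth, or gapped
alignment — real data with indels should be placed by an external aligner
and fed in as ready-made placements, which the calling stage accepts.

Fixture spectra are synthetic look-alikes constructed in code: an
alkylation-style shape (C>T with 3' C/T, i.e. G>A with a 5' purine on the
purine strand, plus a small T>C component and a diffuse transversion floor)
and a CpG-deamination control (C>T at NCG).  They reproduce the *structure*
of the corresponding catalogued signatures — their hot channels are
disjoint, cosine ≈ 0.13 — but are not the catalogued vectors, which users
supply as 96-row TSVs.  The reference is likewise a seeded random 6382-nt
sequence standing in for a reporter target of that length.

## Statistics and numerical choices

**Spectrum normalization** divides each channel's share of the mutation
total by the strand-collapsed relative frequency of its trinucleotide in
the target, then rescales to sum 1.  With a uniform composition this is a
pure rescaling.  Background subtraction operates on normalized frequencies
(subtract, clamp at 0, renormalize); a count-scale mode is available since
the scale matching between treated and control libraries is a judgment
call.  Cohort spectra average per-sample *normalized* spectra so that
sequencing depth does not weight animals; pooling counts first is available
via the same API.

**Binomial log-odds** are computed from exact tail sums in log space
(`gammaln` + `logsumexp`); both the tail and its complement are summed
directly, so heights remain accurate when either side underflows a double
(tail probabilities below 1e-300 occur in strongly enriched cells and are
handled without capping).  The signed two-branch convention (over: P =
Pr[X ≥ k]; under: P = Pr[X ≤ k]; boundary k = np → 0) satisfies the exact
mirror identity h(k, n, p) = −h(n−k, n, 1−p), which the suite verifies
against an arbitrary-precision rational oracle to 1e-9.  A background
frequency of exactly 0 (or 1) is floored (ceiled) at 1/(n_bg+1) to keep
heights finite on small backgrounds, with a warning.  The Bonferroni bound
log10((1−α′)/α′), α′ = α/56, equals 3.0488 for the default 14 positions ×
4 bases; 56 is the number of scored cells when the center position is
excluded.

**Null calibration** of the pLOGO statistics draws foregrounds from the
background *without replacement* — the null hypothesis is exactly "the
foreground is an unenriched subset of the sequenced context space" — and
Bonferroni plus binomial discreteness make the familywise error rate
conservative: across 100 seeded replicates, ≥95 clean replicates is the
acceptance property and ~99–100 is typical.

**Mann–Whitney** p-values are exact by full enumeration of all
C(na+nb, na) labelings with midranks for ties, two-sided as twice the
smaller tail (tail includes the observed statistic), capped at 1; U is
reported as min(U1, U2).  Enumeration is limited to 12 observations per
group, far above the group sizes of animal studies.  The implementation is
cross-checked against an independent exact implementation on untied data.

**Placement** requires a 20-nt exact seed among non-N stretches (several
disjoint seed offsets are tried, so an N-masked or singly-mutated read
still seeds) and accepts the best ungapped identity ≥ 0.9 over non-N
positions, trying both orientations.

**Uniqueness** deduplicates by (region, position, alt), preserving channel
integrity when two different substitutions occur at one site; the stricter
one-per-position reading is available (`by_position=True`, keeping the
most-observed alt, ties alphabetical).

## Problem sizes used by the tests and acceptance script

The end-to-end recovery experiment simulates a cohort of 10 animals × 2000
molecules at mutation rate 1e-3 per base.  A cohort (rather than one deep
sample) matches how reporter-target studies reach thousands of foreground
mutations: on a 6.4-kb target only ~3200 distinct C:G sites exist, so a
single sample with ≥3000 unique mutations is necessarily saturated and its
spectrum converges to site availability rather than the generating process;
pooling unique mutations per animal (inter-individual replicates retained)
and averaging per-animal normalized spectra recovers the generator spectrum
with cosine ≈ 0.998 while still pooling >3000 foreground mutations.  Error
suppression uses 800 error-only molecules (≈1.3e5 DCS bases, expected zero
calls); truth-set exactness uses 1500 error-free molecules; the enrichment
experiment injects ~1000 unique purine-context mutations.  These sizes keep
the full suite under a minute while leaving wide statistical margins.

## Known limitations

* The placer is ungapped and substitution-only by design; indel-bearing
  data needs external alignment.
* Colony-count simulation uses a lognormal titer × (optionally
  gamma-overdispersed) Poisson model; at control-level mutant frequencies
  (~1e-6) per-animal counts are tiny and fold-change estimates from n = 5
  are intrinsically noisy, as in the real assay.
* The heights of extremely saturated pLOGO cells depend on the background
  set; published tables from other tools may cap or approximate deep tails,
  so exact numeric agreement with such tables is not expected.
* Multi-region (panel) targets are supported throughout, but composition
  normalization pools regions; per-region spectra require separate runs.
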