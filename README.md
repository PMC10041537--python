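# duplexspectra

Analysis pipeline for duplex-sequencing mutagenesis studies on reporter
targets: error-corrected consensus calling, high-resolution 96-channel
mutational spectra, signature comparison by cosine similarity, sequence
context enrichment by binomial log-odds (probability-logo) statistics, and
reporter-assay (gpt-style fluctuation) mutant-frequency statistics.

It is written for genetic-toxicology and mutational-signature work, where a
short (kilobase-scale) target is sequenced to very high depth with duplex
molecular tags and the questions are: *which substitutions occurred, in
which trinucleotide contexts, how does the spectrum compare to known
mutational signatures, and which neighboring bases are over-represented
around the mutated base?*  A seeded synthetic duplex-read generator is
included so every stage is testable end to end without any external data.

## What it computes

**Duplex consensus (SSCS/DCS).**  Reads carry two random tag arms
(α, β) ahead of a fixed spacer; top-strand reads are prefixed αβ, bottom
strand βα, so complementary families share an orientation-invariant
canonical key.  Each strand family is collapsed into a single-strand
consensus (SSCS: plurality base with fraction ≥ 0.7, else N; families
smaller than 3 rejected).  The two complementary SSCS combine into a
double-strand consensus (DCS) in which a base is accepted **only where both
strands agree exactly**; disagreements are masked to N and unpaired SSCS
are dropped.  DCS ends are mask-trimmed (default bases 1–8 and 120–137 of a
137-nt read, keeping 111 informative positions).

**Mutation calling.**  DCS reads are placed on the reference by exact
k-mer seeding with ungapped identity scoring (substitution-only data),
piled up, and every (position, alt) with support becomes a call.  Calls are
collapsed to *unique* mutations — a substitution at a given site counts
once however many molecules carry it.

**Spectra.**  Each unique mutation maps to one of 96 pyrimidine-centered
channels `5'[ref>alt]3'` (e.g. `A[C>T]G`; purine-centered mutations fold on
by reverse complement).  Channel proportions are normalized by the
strand-collapsed trinucleotide composition of the target, optionally
background-subtracted (clamped at 0, renormalized), and compared by

&nbsp;&nbsp;&nbsp;&nbsp;cos(a, b) = a·b / (‖a‖‖b‖).

**Context enrichment (pLOGO-style).**  For 15-nt windows centered on a
fixed mutated base (e.g. G of G>A), each flanking position × base cell is
scored against a background window set by the signed log-odds of the exact
binomial tail: overrepresentation uses P = Pr[X ≥ k | Bin(n, p)] and height
+log10((1−P)/P); underrepresentation uses P = Pr[X ≤ k] and
−log10((1−P)/P).  Tails are summed exactly in log space, so deep tails keep
finite heights.  Significance uses the Bonferroni-corrected log-odds bound
log10((1−α′)/α′) with α′ = α/(14·4) = 0.05/56, i.e. **±3.05**.

**Assay statistics.**  Mutant frequency = 6-TG-resistant colonies / mean
chloramphenicol-resistant colonies; group comparisons use the *exact*
two-sided Mann–Whitney U test by full enumeration (for two groups of five,
complete separation gives p = 0.0079 and one crossing gives p = 0.0159).

## Worked example

Run the whole pipeline on synthetic data (a seeded 6382-nt target, 2000
duplex molecules, mutations drawn from the shipped alkylation-style
spectrum, strand artifacts at 1e-3/base):

```
duplexspectra run-all --outdir run --n-molecules 2000 --mutation-rate 1e-3 --seed 7
```

The manifest (`run/manifest.json`) records every filtering step:

```
simulate   n_molecules 2000, n_read_pairs 20115
consensus  reads_total 40230, families 7948, sscs_built 7034,
           sscs_rejected_size 914, sscs_unpaired 890, dcs_built 3072,
           masked_base_fraction 0.19
call       dcs_mapped 3072, dcs_bases 340676, unique_mutations 315
plogo      n_fg 250, n_bg 3160, threshold 3.05
```

Reading it: 40,230 raw reads collapse to 3,072 double-strand consensus
reads (340,676 error-corrected bases); sequencing artifacts vanish and 315
unique substitutions remain.  The normalized spectrum
(`run/spectrum_normalized.tsv`) has cosine similarity 0.983 with the
generator's alkylation-style spectrum and 0.113 with the CpG-deamination
control — the sample is unambiguously assigned to the right mutational
process.  The context analysis (`run/plogo.tsv`) restricted to significant
cells shows the 5'-purine preference of the injected process:

```
position base   k   n     frequency_pct   height   significant
      -1    A 100 250              40.0     +6.0          True
      -1    G 128 250              51.2    +16.3          True
      -1    C   6 250               2.4    -19.9          True
      -1    T  16 250               6.4    -13.7          True
```

G and A are strongly over-represented immediately 5' of the mutated G
(91% of foreground windows), far beyond the ±3.05 bound.

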