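# Methods

## Quantification model

All quantification is anchored to a single amplicon reference with
0-based half-open coordinates internally (1-based inclusive in
reports). Reads pass a mean-Phred filter (default ≥ Q30), are globally
aligned to the amplicon with affine gap penalties, and are then
classified against a quantification window:

* a read whose alignment identity — identical aligned bases over
  `max(len(read), len(ref))` — falls below 0.6 is counted unaligned and
  excluded from all denominators;
* an aligned read with any insertion or deletion overlapping the window
  is **discarded** and contributes to the indel rate; an insertion
  sitting exactly on a window boundary counts as overlapping
  (conservative: ambiguous placements are treated as editing
  byproducts);
* retained reads populate a per-position nucleotide count matrix.

All percentages are normalized to the aligned-read total, not the
retained total, so categories close exactly:
`indel% + Σ_base genotype%(pos, base) = 100` at every window position.
The genotype formula is the product form
(nucleotide frequency among retained reads) × (retained/aligned)
collapsed to a single ratio, which is exact when one amplicon is in
play; multi-amplicon batch denominators are out of scope.

Pathogenic-allele correction rescales the wild-type genotype against
the line's ploidy baseline, `100·max(0, g − b)/(100 − b)` with
`b = 100·wt_alleles/ploidy`. The normalized form (fraction of *mutant*
alleles converted) is used rather than the raw difference `g − b`; a
raw-difference reading would understate correction for lines that start
with wild-type alleles, and the normalized form reproduces the
reference points we test (71.5% genotype at a 50% baseline ↔ 43%
correction). A fully wild-type baseline has no pathogenic alleles and
raises rather than returning a vacuous 0/0.

### Windows

* **Prime editing**: 10 bp beyond the outermost nicks over all guides
  (pegRNA/epegRNA/ngRNA/dsgRNA). If the reverse-transcribed 3′ flap
  end + 10 bp passes a bound, it replaces that bound; the rule is
  applied symmetrically for − strand pegRNAs whose flap extends toward
  lower coordinates.
* **Base editing**: a 20-bp window centered 10 bp upstream of the cut
  site, which coincides exactly with the 20-nt protospacer; this is the
  coordinate mapping we adopt for the (center −10, size 20) convention.
* **Off-target sites**: protospacer start − 10 through PAM end + 10
  (43 bp for a 20+3 site), one physical interval regardless of strand.

Nicks are placed 3 nt 5′ of the PAM on the protospacer strand (between
protospacer positions 17 and 18 for a 20-nt spacer) — standard SpCas9
nickase geometry, exposed as `GuideSite.nick_position`.

### Alignment

Global pairwise alignment uses match +2, mismatch −4, gap open −10,
gap extend −1 (a gap of length L costs −10 −(L−1)); these are
implementation defaults chosen to strongly prefer a single contiguous
indel over scattered gaps on near-identical amplicon reads, and are
validated against an independent quadratic-time Gotoh dynamic program
in the test suite. Alignment results are memoized by read sequence:
amplicon read sets are highly redundant, so the effective cost scales
with the number of distinct reads. Tie-breaking among co-optimal
alignments follows the aligner's deterministic first-path order; indel
placement inside homopolymers can therefore shift by a few bases, which
never changes window-overlap classification in our fixtures (indels
are planted mid-window).

## Base-editing product alleles

Protospacer positions are 1-based with position 1 PAM-distal and the
PAM at 21–23. Product alleles are all non-empty subsets of
substrate-base positions (A for ABE, C for CBE), `2^k − 1` patterns for
k substrate bases; enumeration is lazy and classification never
materializes the list, so substrate-rich protospacers stay tractable.
Read categories: precise WT (conversion subset equals the target set
exactly), bystander (any non-target conversion, with or without the
target — also reported split into with/without-target), unedited
(empty subset), other (a protospacer change that is not a substrate
conversion). For multi-position targets a non-empty proper subset of
the target with no bystander falls into a separate `partial_target`
tally so that all categories sum to 100 × retained/aligned; with a
single-position target this category is empty. Substitutions inside
the quantification window but outside the protospacer do not
disqualify precise-WT classification.

The ABE off-target metric counts reads with ≥1 A→G conversion
(protospacer-strand orientation) at protospacer positions 4–10,
normalized to all aligned reads.

## Guide design rules

* **5′ spacer rule**: protospacers starting with G are used as 20-nt
  spacers; if position 2 is G the spacer is truncated to 19 nt with a
  genome-matched 5′ G; otherwise a mismatched 5′ G is appended (21 nt)
  and the variant tagged disfavored.
* **PBS × RTT grids** keep only designs whose RTT covers every
  intended edit (corrective + silent); the flap end is
  nick ± RTT length in the edited-strand direction.
* **Silent-edit sets** are synonymous single-base substitutions within
  a codon frame (standard nuclear code via Biopython), emitted as sets
  of 1–3 edits verified *jointly* synonymous (two edits in one codon
  can interact), never touching the corrected base, ranked
  lexicographically: PAM-disrupting, then protospacer-seed-disrupting
  (positions 13–20), then proximity to the corrected base. No editing
  activity model is implied by the ranking.
* **PE3b** is an ngRNA whose protospacer+PAM matches only the edited
  sequence (its nick site is created by the edit); an ngRNA matching
  both, or the reference only, is PE3; matching neither is an error.
* **dsgRNAs** (14–15-nt dead spacers) are enumerated at signed
  nick-to-nick distances of −60..−30 or +30..+60 bp from the pegRNA,
  measured in the pegRNA's PAM-strand orientation (negative = 5′ of the
  pegRNA nick); this convention reproduces labels such as "+49" and
  "non-PAM −44" and is configurable since distance labels are not
  otherwise standardized. No PAM match is required by default — dead
  guides are reported at non-canonical PAMs — and candidates
  overlapping a supplied ngRNA footprint are dropped.

## Off-target panel

Top-k selection (default 32/guide) ranks by nomination read count with
ties broken by ascending coordinate. Padded amplicons are the 23-nt
protospacer+PAM ±25 nt (73 nt interior; clipped with a warning at
contig ends). Both arms are quantified identically; fold-changes use
`log2((t + ε)/(m + ε))` with ε = 0.01 percentage points to keep
zero-mock sites finite, and flagging is inclusive at 0.5 log2 units.
Note that 0.5 log2 units is a ≈1.414-fold ratio; a literal 1.40-fold
site sits at 0.485 and is correctly not flagged. An arm with no aligned
reads marks the site not amplifiable: it is excluded from flagging and
carries missing metrics rather than zeros. Genomic-context annotation
uses the fixed precedence exonic > UTR > promoter > lncRNA > intronic >
intergenic when a site overlaps several features.

## Synthetic data

The generator emulates targeted amplicon sequencing of editing
experiments: full-length single-end reads drawn from an explicit allele
mixture (wild-type, pathogenic, corrected, bystander, indel alleles),
constant per-read Phred quality with optional Gaussian jitter clipped
to [2, 41], and i.i.d. per-base substitution errors to a uniformly
chosen other base. Defaults follow the study conditions the package
models: 3,000 reads per sample (sequencing depth is otherwise
unstated; 3,000 is a typical targeted-amplicon depth and fixes
counting noise at ≲1%), Q30 filtering, error rate 0.002 where error
robustness is exercised, 2,000 reads per off-target arm. With
`exact_counts`, allele counts are apportioned by largest remainder so
they sum exactly to the requested depth, which makes error-free
round-trips exact to 1/n.

What the generator deliberately omits — and what passing tests
therefore do not demonstrate about real data: paired-end structure and
merging, adapter/quality trimming, PCR duplicates and chimeras,
platform-specific error profiles, and sequencing indel errors (indels
enter only through allele specifications, isolating the
indel-classification logic from aligner gap artifacts). Off-target
pairs are simulated with exact counts and no sequencing error by
default, so panel recovery measures the selection/flagging logic
rather than error robustness, which is covered separately by the
mixture-recovery tests at error rate 0.002.

## Problem sizes and numerics

Test and acceptance runs use 120–200-bp amplicons, 150–3,000 reads per
sample, 96-site panels at 2,000 reads/arm, and 20–50 seeds per
property — sizes at which every metric is also recomputable by the
naive per-read oracles the suite carries. Degenerate inputs are
explicit: zero aligned reads yield missing (None) rates, not zeros; an
all-wild-type baseline raises on correction; windows are clipped to the
amplicon with warnings; conflicting planted sites and malformed feature
intervals raise errors naming the offending positions.
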