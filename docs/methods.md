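# Methods

## The divergence assay and its model

Sequencing multiple clones of one telomere from a clonal population yields a
set of sequences that agree over a centromere-proximal region and differ
distally. The analysis assigns each clone an *undiverged length* on the
coordinates of a reference telomere and a reason for where that span ends.
Three processes are modelled: end-replication shortening (3–4 nt per
generation, which only shortens the shared prefix), distal replacement
events (recombination in telomerase-null cells, re-extension in
telomerase-positive cells), and technical artifacts of PCR, cloning, and
sequencing.

Event counts per lineage are Bernoulli per generation, so the diverged-clone
fraction after `g` population doublings at per-generation rate `r` is
`f = 1 − (1−r)^g`, inverted as `r = 1 − (1−f)^(1/g)`. The technical layer is
treated as an independent second process, giving the background correction
`f_adj = 1 − (1−f_obs)/(1−f_bg)`; because independence is an assumption, the
adjusted figure is supplementary output and never replaces raw fractions.

## Reference selection

The reference is the longest telomere without divergent sequence. Candidates
are ranked by length (ties broken by clone id); a candidate is demoted when
the majority of the other clones are called diverged against it *in a
candidate-specific way*: either with divergence points in the candidate's
proximal half, or with tightly clustered divergence points (median absolute
deviation ≤ 10 nt). Clustering is the signature of the candidate carrying
its own event — every clone then "diverges" at the candidate's junction —
whereas genuine per-clone events scatter their breakpoints. If every
candidate is demoted (as in heavily diverged telomerase-positive sets) the
longest clone is used with a warning.

The accepted reference is then *polished toward the set consensus*: at each
reference position where a majority of covering clones agree on the same
substitution, deletion, or insertion, the consensus overrides the reference
read. This removes the reference's own technical lesions (which would
otherwise appear as a shared lesion in every clone) and mirrors the assay's
comparison of clones to a consensus rather than to a raw read. Diverged
tails cannot reach a majority because they are mutually independent.

## Alignment

Clones are aligned to the reference by an affine-gap *prefix alignment*:
both sequences are anchored at the proximal end with no free gaps, the
alignment ends wherever the score peaks, and the distal remainders of both
sequences stay unaligned. This matters for degenerate repeats: a forced
global alignment of a clone whose tail has been replaced will drag the true
proximal register out of position to buy coincidental tail matches, whereas
a prefix alignment simply stops near the junction.

Scoring defaults: match +1, mismatch −2.5, gap open −4, gap extend −1. The
mismatch penalty is deliberately not half the gap-open penalty: at −2, a
single 1-nt indel inside a periodic repeat block is score-degenerate with
two adjacent mismatches plus a displaced gap, and that representation would
spuriously violate the point-mutation tolerance rule. Ties are resolved
deterministically: the earliest score peak is chosen, and the backward
traceback prefers gap states, which floats score-equivalent gaps to the
distal end of periodic blocks and keeps the proximal region clean. The
implementation is a row-vectorised Gotoh DP with a shared-prefix fast path
(the common proximal region, minus a 50-nt safety margin, is skipped); an
independent recursive DP oracle verifies scores exactly in the tests.

## Divergence calling

Alignment columns are scanned proximal→distal as maximal runs (lesions).
The explicit tolerance rules are: substitution runs of length ≤ 1 (isolated
point mutations, unlimited in number), gap runs of total length ≤ 6 nt, and
the free distal remainder of a shorter clone. A composite lesion (mismatch
adjacent to a gap), a longer substitution run, or a longer indel is a
violation, as is a 20-column window with less than 50% identity (a tail from
a non-homologous donor).

Degenerate TG₁₋₃ repeats need more than these rules. Two independent repeat
stretches align at ~70–80% coincidental identity, with differences mostly
isolated 1–2-nt gaps where G-run lengths differ — every lesion individually
tolerated. What distinguishes a replaced tail is the *density and
persistence* of lesions, captured by a changepoint walk that falls 1 per
column and jumps +33 at each lesion start (+6 for substitutions introducing
a non-repeat base, A or C on the G-rich strand, which are characteristic of
technical noise; coalesced multi-fragment gap groups count proportionally
more). Two additional detectors use this walk:

* **Unaligned-remainder rule** — when more than 12 nt of *both* the
  reference and the clone remain unaligned past the score peak, the distal
  sequences are not each other's: a diverged tail. Smaller two-sided
  remainders contribute a terminal bonus to the walk.
* **Rise rule** — a maximal proximal→distal rise of the walk ≥ 65 marks a
  lesion-dense region. The threshold is immune to any two isolated lesions
  (maximum rise 64), and the rule only applies when lesions persist to the
  distal end of the aligned region: a dense cluster followed by a long clean
  stretch is clustered noise, not a tail, because real divergence extends to
  the end of the molecule.

Two alignment artifacts of periodic repeats are handled explicitly:
same-side gap runs separated by ≤ 8 matching columns (span-capped) are
judged as one indel of their total length — a physically single indel can
scatter into score-equivalent fragments, and conversely a 7-nt indel must
not evade the 6-nt rule by splitting; and adjacent mismatch pairs that swap
two bases (ref `GT` read as `TG`, an indel shift boundary) are violations
only when lesions persist distally, otherwise tolerated.

The divergence point is the changepoint of the walk (earliest argmin),
which coincides exactly with the first violating event when the prefix is
clean and otherwise walks back across coincidental matches near the
junction. Reported positions are 1-based on reference coordinates;
`undiverged_length = divergence_point − 1`. Undiverged lengths strictly
below 125 nt are flagged as truncations (biologically meaningful in
telomerase-positive sets, where the undiverged span records how short the
telomere was before re-extension).

Calibration of the walk weights, rise threshold, and remainder cutoff used
the simulator's ground truth under the default study conditions: the
operating point gives zero false positives in 20 000 clones carrying only
tolerated-class technical noise, and detection with ±5-nt breakpoint
localisation of 93–98% of planted replacements of ≥ 30 nt across seeds
(n = 10³ clone sets). Short distal tails (30–50 nt) overlapping the
reference by little more than their own length are the residual misses;
below ~30 nt of replaced sequence the assay has intrinsically little signal,
since fresh degenerate repeats frequently reproduce a short stretch by
chance. The simulator's truth records account for this by storing the
*effective* breakpoint — the first position where the new sequence actually
differs from the old.

## Rates and tests

Diverged fractions carry exact Clopper–Pearson 95% intervals (appropriate
for the assay's ~30–40-clone sets); count comparisons use two-sided Fisher's
exact test (sum of all tables at most as probable as the observed one);
genotype comparisons of PDs at maximum senescence use the unpaired
two-tailed Welch t-test, chosen because replicate numbers typically differ
between genotypes and the equal-variance assumption is not needed. No
multiple-testing correction is applied; raw pairwise p-values are reported.

## Senescence curves

Each replicate's daily densities convert to PD increments
log₂(density / 2×10⁵); negative increments (shrinking cultures) are retained
so cumulative PD honestly reflects decline, and flagged. The point of
maximum senescence is the passage of minimum density (earliest on ties) —
the natural reading in a daily-dilution design, consistent with survivor
sampling at "the first time point after" it. Replicates are aligned by
passage number for averaging (each passage is one measurement event); both
density and cumulative-PD means ± SE are emitted per passage, since either
may serve as the error bar of record.

## Simulator

The generator's defaults are the study conditions: initial repeat length
300 nt over a fixed 30-nt non-telomeric proximal anchor, 30 generations,
35 clones per set, shortening drawn uniformly from {3, 4} nt per generation,
divergence rate 0.003 per telomere per generation, telomerase re-extension
threshold 160 nt with geometric extension lengths (mean 120 nt), and a
technical layer of 4% per-clone artifactual distal replacement plus
background isolated substitutions (10⁻³/nt) and small ≤ 6-nt indels
(2×10⁻⁴/nt). The repeat grammar emits units T·Gᵏ, k ∈ {1,2,3}, with
probabilities 0.2/0.5/0.3 — invented defaults calibrated only so the
technical layer reproduces the ~4% control-scale divergence fraction;
all are configurable.

Each clone evolves independently from a shared founder sequence; because
divergence events replace the distal tail, this immediately yields the
shared-proximal/divergent-distal structure of real clone sets without
modelling full pedigrees. Replacement tails have the same length as the
replaced segment, so final lengths are driven only by shortening and
truncation. Tolerated-class noise is tolerated *by construction*:
substitutions are spaced, never adjacent, and change the base; indels are
kept apart from each other and from substitutions so lesions cannot merge
into a divergent-looking composite. Truth records store the effective
breakpoint and never let tolerated noise flip the diverged flag.

All randomness flows from one master seed through `numpy.random.SeedSequence`
spawning (one stream per emitted artifact), making outputs byte-identical
per seed and artifacts independently regenerable.

What the simulator does *not* emulate: chromatogram/trace quality, primer
trimming, pedigree structure within the clonal population, survivor
emergence and Y′ amplification, donor choice in recombination, and any
length-dependence of event rates. Passing tests therefore demonstrate the
correctness of the analysis under the stated stochastic model, not the
absence of such effects in real data.

## Problem sizes

The test suite and acceptance script use 10⁵ lineages for the closed-form
consistency check, 10³-clone sets for caller null correctness and detection
(three independent sets for the detection aggregate), 10²-clone sets for the
telomerase-positive end-replication property, and 10-replicate senescence
fixtures — sizes at which the binomial error of every checked quantity is
well below its acceptance margin.

## Known limitations

* Detection of replaced tails shorter than ~30 nt, or of any event whose
  fresh sequence coincidentally reproduces the original, is intrinsically
  limited by the information content of degenerate repeats.
* The divergence point is reported on reference coordinates; when tolerated
  indels precede the junction, clone coordinates would differ by their net
  length (configurable conventions were considered and rejected for
  simplicity).
* The background correction assumes technical and in-vivo events are
  independent.
* The reference-demotion heuristic can reject every candidate in heavily
  diverged sets; the fallback (longest clone, with a warning) then bounds
  every measured undiverged span by the fallback reference's own junction.
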