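# Methods

This note documents the statistical procedures, the synthetic-data model,
and the design choices made where the analysis conventions in this field
leave the details open.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); parsers convert on
read.  Strand is ignored throughout — none of the analyses here are
strand-aware.  The minimum overlap for two peaks to "overlap" is 1 bp; no
published convention suggested a larger threshold.

"Overlapping peaks" between two peak sets is defined as the number of
**connected components** of the pairwise-overlap graph (including chains
formed through same-set overlaps).  This choice makes a single overlap
count expressible as a percentage of either set, which is how such Venn
figures are conventionally labelled; the per-set matched-peak counts are
reported alongside, so nothing is lost.  Reported percentages are
*truncated*, not rounded, at the displayed precision — this mirrors how
integer percentage labels relate to the underlying ratios in the source
analyses — and full-precision values are always kept in the outputs.

Interval primitives (component intersection, gap-merge, base-pair
subtraction, recurrence depth sweep) are sorted-sweep implementations
validated against per-base brute-force oracles on thousands of random
instances (see `tests/test_acceptance.py`).

## Random-region permutation null

Each null draw places |reference| regions uniformly over the genome with
lengths resampled (with replacement) from the reference set's length
multiset, then scores the percentage of placed regions overlapping the
target set; the median over draws (10 by default) is the summary.  Draws
preserve the length distribution but not the chromosome distribution —
the placement is uniform over all valid genome positions — since nothing
in the underlying protocol suggests chromosome-matched shuffling.  No
gap/blacklist masking is implemented (out of scope).

## Knockdown differential and N1 peaks

Signal per peak is the length-weighted mean of the bin track over the
peak.  The fold-change rule uses a pseudocount of 0.5 (avoids infinite
ratios at zero signal; standard practice): *decreased* iff
(ctrl+pc)/(kd+pc) > cutoff, *increased* symmetrically, else *unchanged*;
cutoff 1.2 by default.  Mean signal over the peak was chosen over
peak-caller scores as the quantity the cutoff applies to.

N1 peaks are expressed on ORC1 intervals (the licensing substrate): an
overlapped ORC1 peak enters N1 when it is decreased and at least one
*directly overlapping* NFIB peak is decreased.  The consistency
percentage is |N1| over all overlapped, decreased ORC1 peaks; an empty
denominator is reported as missing, not 0.

The accessibility caller is a deliberate simplification of a
dispersion-sharing GLM workflow: counts are normalized to the mean
library size and compared by a pooled-variance two-sample t-test on
log(count + 0.5), calling *open* (accessibility falls on depletion) or
*close* at |log2FC| > log2 1.2 and p < 0.01.  With two replicates this
per-peak test has df = 2 and is very conservative at p < 0.01; it calls
only the cleanest peaks, which is acceptable for its role here and is
flagged as a limitation.

## Nascent-strand filter and origin classes

The RNase-control filter tests each candidate peak for enrichment in the
untreated library with a **one-sided** Fisher exact test on
[(count, library−count) × (untreated, treated)] — one-sided because the
filter's only purpose is retaining RNase-sensitive nascent signal.  The
p-value is computed as the upper hypergeometric tail.  FDR control is
Benjamini-Hochberg (the generic "FDR" of peak-calling practice).  The
log2 untreated/treated ratio uses library-size-normalized counts with
pseudocount 0.5.  A peak is a true NS peak iff q ≤ 0.05 **and**
log2 ratio ≥ log2 1.2.

Kept peaks are classified S1/S2/S3 with the same fold-change engine as
the binding differential (S1 = decreased, S2 = increased, S3 = unchanged
at cutoff 1.2).  Note that a plain fold-change partition with no
significance test labels a substantial share of truly stable peaks S1 or
S2 under count noise; this is inherent to the rule, not a defect of the
implementation.

Replication timing is assigned per peak as the argmax of the mean signal
across the three S-phase fraction tracks, each normalized to global mean
1 (per-library scaling); ties break toward the earlier fraction, and a
peak with no signal in any fraction is "unassigned".  The fraction-based
argmax was chosen over continuous early/late log-ratios (out of scope).

## Compartment dynamics

PC1 eigenvectors arrive per replicate and condition at 250-kb bins; sign
is arbitrary per chromosome, so each chromosome is flipped, if needed, to
make the mean PC1 correlate positively with gene density (A = positive =
gene-dense).  Bins are compared between conditions with a pooled-variance
two-sample t-test (df = 2 at two replicates; Welch available behind a
flag) at alpha 0.05.  Significant bins get one of six change categories
from the condition means: same-sign magnitude shrink/growth gives
A/B-weakened/strengthened, sign changes give A-to-B or B-to-A; the
seven-way scheme (with unchanged) covers every sign/magnitude case and is
a reconstruction, since no exhaustive taxonomy is spelled out in the
conventions this follows.  Degenerate bins with zero variance in both
conditions are unchanged when means agree and flagged significant (p
reported as 0) when they differ.

N1 enrichment counts N1 peaks per bin — a peak spanning a bin boundary
counts in every bin it overlaps (midpoint assignment available behind a
flag, and used where exact count conservation is needed) — and compares
each category's per-bin counts against the unchanged bins with a
two-sided Mann-Whitney U test; categories with fewer than two bins are
skipped and flagged.

## EM occupancy and copy-number analysis

The R-value of a traced DNA stretch is the combined contour length of its
nucleosome bubbles divided by the total contour length; it is
scale-invariant and lies in [0, 1].

Copy-number segments are called gain above copy number 2.3 and loss below
1.7 (diploid baseline 2).  These thresholds are a config-exposed choice —
segment-calling pipelines vary and no numeric thresholds were given.
Control subtraction removes the merged union of control-clone gains from
each sample clone's gains base-pair-wise; recurrence keeps maximal
regions gained in ≥ 2 clones (the default meaning of "recurrent" here).
Cohort co-occurrence tests each locus against the NFIB-amplified flag
with a one-sided Fisher exact test (positive association) and BH across
loci; the one-sided direction is what "co-occurrence" asks of the data.
The validation fraction is the share of sample regions overlapping a
significant locus in at least one cohort.

## Synthetic study generator

The generator emulates the study design on a toy genome (3 × 10 Mb, 1-kb
signal bins, 250-kb compartment bins) with a planted-truth ledger.  Key
parameters, defaults, and rationale:

* **Causal core** — 300 NFIB sites; each hosts an NFIB-dependent ORC1
  site with probability 0.45; 120 ORC1 sites bind independently (placed
  off NFIB sites).  Knockdown halves the factor signal (fold change 2.0)
  at all NFIB sites and at dependent ORC1 sites only.
* **Count noise** — negative binomial with var = m + 0.1·m² (dispersion
  0.1, a typical bulk-sequencing overdispersion); dispersion 0 is the
  exact zero-noise limit (values equal their means), used by the
  truth-recovery limit tests.  PC1 replicate noise is Gaussian
  (sd 0.1) — standard models, since no noise model is prescribed by the
  protocols emulated.
* **Site geometry** — binding sites are 5–8 kb with per-bin amplitude 120
  over background 2, and nascent-strand signal is quantified at 250-bp
  sub-bins.  These were set so that a peak's mean signal averages over
  roughly five independent noise units, which is what makes a 2-fold
  effect reliably exceed a 1.2 cutoff at dispersion 0.1 (the dispersion
  floor of a single negative-binomial draw is cv ≈ 0.32, too noisy for
  any single-unit rule); real peak quantification integrates many
  positions in the same way.
* **Nascent strands** — fragments 0.5–2 kb; active origins draw untreated
  counts around 60 and RNase-treated counts from a background at 10% of
  that; dormant origins and decoy peaks draw both from background, so the
  RNase filter should remove them.  S2 (compensatory) origins gain
  2-fold on knockdown; S3 are stable.
* **Timing and compartments** — each chromosome is split into
  early/mid/late thirds; A/B compartments alternate in 5-bin blocks with
  gene density high in A.  15 weakened-A bins are drawn from
  A-compartment bins inside early domains; dependent sites are placed
  into a weakened bin with probability 0.5, otherwise into early domains
  with probability 0.7 — encoding the planted claims that
  NFIB-dependent origins are early-replicating and concentrate where the
  A compartment weakens.
* **CNA/cohorts** — 3 overexpressing and 3 control clones; 12 planted
  amplifications each shared by ≥ 2 overexpressing clones; a pool of 8
  "fragile" regions gained spontaneously by any clone (what control
  subtraction removes); 4 cohorts of 200 patients with NFIB amplified in
  30%, co-amplified loci at 55% among NFIB-amplified vs 8% background,
  plus 30 decoy loci.

One global seed drives everything; each output family uses its own named
sub-stream, so adding outputs never perturbs existing ones, and emitted
files are byte-identical across runs of the same seed.

**What the generator does not model:** read-level data or sequence
content, fragment-length effects beyond the NS window, peak-calling
uncertainty (peaks are known intervals), trans effects, replication-timing
gradients within a domain, GC/mappability bias, or subclonal copy-number
mixtures.  Passing recovery tests therefore shows the pipeline's logic is
correct under the planted causal structure and realistic count noise —
not that the biological conclusions would survive the additional noise
sources of real libraries.

## Problem sizes and numerics

Default analyses run on a 30-Mb toy genome with ~500–700 peaks per set
and 120 compartment bins; the full pipeline completes in a few seconds,
and the validation suite (including twenty full pipeline replicates)
in about a minute.  These sizes were chosen to make the statistics
well-populated (hundreds of events per class) while keeping every run
interactive.  Fisher p-values are clipped into (0, 1] before BH;
percentages are truncated only at the reporting layer; the report JSON
contains no timestamps, so identical configurations reproduce identical
bytes.

## Known limitations

* The accessibility caller and the compartment t-test use two replicates
  (df = 2); they are conservative and their per-peak/per-bin power is
  low by construction.
* The S1/S2/S3 fold-change partition has no significance gate, so class
  counts include noise-driven assignments (visible in the stable-origin
  class being under-counted at realistic dispersion).
* The permutation null places regions uniformly; it does not exclude
  assembly gaps or match chromosome composition.
* Segment-level CNA classes only; no structural-variant calling, no
  survival analysis, no dose-response fitting.
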