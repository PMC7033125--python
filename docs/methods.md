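# Methods

## Synteny diversity

For a panel of n haploid-coded genomes and a chosen coordinate frame,
every unordered pair (i, j) carries a boolean syntenic-status vector:
a frame position is syntenic iff it is covered by a top-level SYN block
of that pair's structural annotation. Everything else — NOTAL blocks,
inversions, translocations, duplications without a SYN backbone, and
gaps between records — is non-syntenic. Positions unannotated for a
pair therefore count as non-syntenic, not as missing: the statistic
measures non-syntenic sites, not callability. A flag
(`inversions_syntenic`) lets inverted-but-positionally-conserved blocks
count as syntenic instead; the default treats them as non-syntenic
because they break collinearity in the orientation sense.

π<sub>ij</sub> of a region is the non-syntenic fraction of its
positions. Two combination conventions are implemented:

* `pairwise_mean` (default): the average of π<sub>ij</sub> over the
  n(n−1)/2 unordered pairs. This matches the worked one-of-eight
  outlier value 7/28 = 0.25 and makes π_syn = 1 attainable (every pair
  fully non-syntenic).
* `frequency_weighted`: Σ<sub>ij</sub> x<sub>i</sub> x<sub>j</sub>
  π<sub>ij</sub> over ordered pairs with π<sub>ii</sub> = 0 and
  frequencies x<sub>i</sub> (1/n each unless supplied). For equal
  frequencies this equals the pairwise mean times (n−1)/n — 0.21875
  rather than 0.25 for the outlier configuration — and cannot reach 1.

The implementation accumulates raw per-pair fractions and divides once,
so rational values (7/28) are exact in floating point. One consequence
worth noting: a balanced two-class split of eight genomes gives
16/28 ≈ 0.571 under the pairwise mean, so the reading "π_syn > 0.5
implies more than two haplotype classes" holds only under the
frequency-weighted form (where the same split gives 0.5); we document
this rather than resolve it, and use the pairwise mean throughout.

Sliding profiles default to 5-kb windows with a 1-kb step (a 100-kb /
50-kb variant serves as a coarse overview). Windows are anchored at
multiples of the step; if the chromosome length minus the window size
is not a step multiple, a single truncated final window is appended and
normalized by its actual length. A window size exceeding the
chromosome yields one whole-chromosome window with a logged warning.

### Coordinate frame

All masks, windows and region calls live in one frame accession's
coordinates. Comparisons between two non-frame genomes must therefore
be expressed in frame coordinates, the lift-to-reference a real
pipeline performs upstream with whole-genome alignments; annotation
objects carry an explicit `frame` field for this. The bundled simulator
owns the ancestral truth and performs the lift exactly. Non-frame
insertions are invisible in frame coordinates (zero width); the frame
genome's own insertions are unalignable novel sequence and are emitted
NOTAL for every pair.

## HOT regions and window classes

Seed intervals are the union of full 5-kb spans of windows with π_syn
strictly above 0.5 ("larger than 0.5" read literally); seeds separated
by less than 2 kb merge into one HOT region. Using full window spans
(not step-sized cores) makes boundaries reproducible at the price of up
to one window of slack on each side; the recovery tests bound the
boundary error accordingly. With `merge_dist=0` the call reduces to the
plain union of qualifying spans. Region classification paints each
position SYN (window value 0), PARTIAL (0 < value ≤ 0.5) or HOT
(> 0.5); where overlapping windows disagree the higher-diversity label
wins, then same-label runs merge. The SYN/PARTIAL boundary rule is a
declared convention of this package, not an established one.

Collapsed-assembly candidates are flagged from a mean-normalized
short-read coverage track in non-overlapping 100-bp bins: bins at or
above two-fold coverage are flagged ("two-fold increase" read as
≥ 2.0 on a track normalized to expectation 1.0) and adjacent flagged
bins merge.

## Pan- and core-genome

Inputs are, for every ordered genome pair (q, p), the intervals of q
longer than 100 bp without an alignment to p at over 90% identity
(produced upstream by an aligner, or exactly by the simulator). For an
ordered subset, the pan-genome starts from the first genome's size and
adds, per further genome, the length of the intersection of its
non-aligned sets against all previously added genomes, re-filtered to
> 100 bp after the intersection (the filter's position relative to the
intersection is not canonical; we apply it after, and also to the
inputs). The core genome is the first genome minus the union of its
non-aligned sets against the other members. One point is evaluated per
non-empty subset in canonical sorted order — 2ⁿ − 1 points, i.e. the
sum of binomial coefficients C(n, k) — and per-n medians feed the fit.

The model y = A·e^{Bx} + C is fitted by Levenberg-style damped least
squares (tolerances 1e-10, ≤ 10,000 evaluations) with initialization
C₀ = last median, A₀ = first median − C₀, and B₀ = −0.3 for the pan
side or a log-slope estimate of |y − C₀| for the core side. An exactly
constant median vector short-circuits to the degenerate limit (A = 0,
C = mean). Noiseless synthetic medians are recovered to 1e-6 relative;
under 1% multiplicative noise the asymptote estimate stays within 5%
(median over replicates).

On the bundled simulator the pan curve is nearly linear in n: almost
all non-reference sequence (novel insertions, haplotype-specific
duplication copies) is private to one accession, so each genome adds a
roughly constant increment and the exponential fit approaches its
linear limit (B → 0 with large compensating A). Real panels saturate
because novel sequence segregates across accessions; only the
simulator's deletions (sequence shared by all but one genome) produce
saturation here, and they are rare under the default rates. Pan/core
monotonicity under adding genomes, and the bounds pan ≥ largest and
core ≤ smallest member, hold exactly.

Gene-level pan/core uses an orthogroup copy-count table: pan counts
families present in at least one subset member, core the families
present in all. The copy-number summary splits families into
copy-conserved vs variable, and families absent from a designated
reference into shared (≥ 2 carriers) vs accession-specific.

## Population statistics

Genotypes are haploid-coded; heterozygous VCF calls are treated as
missing and counted (the intended material is inbred lines).
Nucleotide diversity uses the unbiased per-site estimator
2j(n−j)/(n(n−1)) over non-missing calls, averaged per window (per-site
mode) or summed and divided by window length (per-bp mode); windows
without usable sites report 0 with a recorded site count of 0.
Haplotype diversity is (k/(k−1))(1 − Σ p<sub>h</sub>²) over the k
accessions with complete calls in the window; k < 2 flags the window
missing. LD is the squared Pearson correlation of genotype vectors
over jointly non-missing accessions, undefined (NaN) if a site becomes
monomorphic after the intersection.

The LD contrast computes, per HOT region, mean pairwise r² of markers
within the region, within 4-kb flanking windows, and across each
border; border windows straddle the boundary symmetrically (2 kb each
side), with across-border pairs required to span the border. Regions
lacking two usable markers in a category are excluded and counted. A
single pooled one-sided Mann-Whitney U tests across < within.

The crossover test filters to unique intervals shorter than 5 kb; an
interval "partially overlaps" the non-syntenic space if it intersects
at least one non-syntenic base. Expected counts are crossover-count
times the genomic non-syntenic span fraction; the 1-df χ² compares
(non-syntenic, syntenic) counts to expectation. The one-sided p (fixed
alternative: crossovers depleted in non-syntenic sequence) is half the
two-sided tail when observed < expected and one minus the half-tail
when observed > expected; exact equality reports p = 1.0 by convention
(no evidence for the alternative). Expected counts below 5 trigger a
warning about the χ² approximation.

MAF spectra by region class use strict filters (MAF > 0.005, missing
rate < 0.2, both configurable; the diversity profiles use MAF ≥ 0.05);
markers outside every class are reported as unclassified. The
deleterious contrast consumes per-variant boolean flags produced by an
upstream effect annotator and compares per-region burden (deleterious
fraction, or per-kb rate) between HOT and SYN regions with a one-sided
U test (HOT > SYN); regions without variants are excluded with a
warning.

## The simulator

Eight (by default) inbred accessions derive from one shared random
ancestor. Per accession and Mb: 2 inversions (5–50 kb), 1 reciprocal
translocation (2–10 kb), 2 indels (200 bp – 2 kb, half insertions of
novel sequence); tandem duplications (units 0.5–2 kb, 2–4 copies,
forward-oriented unless an inverted-copy fraction is set) are confined
to declared hotspot loci, where by default 6 of 8 accessions each carry
a distinct haplotype that tiles the locus — conserved borders, private
unit boundaries and copy numbers. Hotspot sequence is optionally seeded
with a mutated 200-bp tandem repeat array, the proposed substrate of
the duplication mechanism. SNPs arrive at 2/kb outside rearranged
sequence with derived counts drawn from a 1/k spectrum (plus 3/kb
singleton-biased SNPs inside hotspots, emulating the low-frequency
excess expected in non-recombining regions), with a 5% missing-call
rate; crossover intervals (0.5–4 kb, ~50/Mb) fall only in sequence
untouched by any event. Event placement is rejection sampling with at
most 1000 retries and an explicit failure naming the event.

Two structural constraints are design properties, not calibrations:
outside hotspots at most two accessions may be rearranged at any
position, and indels never overlap any other accession's event. The
first guarantees that windows with more than two independent
non-collinear haplotypes — the defining signature of a HOT region —
arise only at planted loci, so hotspot recovery is well-posed; the
second keeps pan/core interval bookkeeping exact (overlapping private
deletions would otherwise interact with the 100-bp filter
non-monotonically). Translocations are modelled as reciprocal
equal-length intra-chromosomal swaps, which keeps them length-neutral.

Coordinate bookkeeping runs through per-accession monotone maps built
from length-changing edits (duplication expansions, insertions,
deletions), giving exact projections ancestral → derived → frame.
Ground-truth pairwise annotations are emitted by painting each pair's
event intervals into frame coordinates and run-length encoding the
result; isolated (non-hotspot) duplications keep their syntenic
backbone with DUP records over the extra copies, while hotspot
duplication haplotypes suppress the backbone, reflecting the
fragmented alignments complex loci produce. An independent per-position
oracle in the test suite reproduces every mask from the raw event list.

What the generator does not emulate: sequence-evolution realism (no
substitution model), recombination genealogies (SNP sites are
exchangeable draws, so background LD is near zero — the LD contrast
therefore uses a dedicated block-structured genotype generator),
read-level artefacts, and shared (segregating) structural alleles;
every structural event is private to one accession. Passing tests
demonstrate the statistics and the calling machinery, not robustness
to alignment noise or to annotation errors in real comparisons.

## Problem sizes

The bundled study uses a 1-Mb chromosome with five hotspots of
25–40 kb; oracle-equivalence checks run on 10-kb chromosomes, and the
demo pipeline on the same 1-Mb scale. These sizes were chosen so the
whole analysis reruns from scratch in well under a minute per stage
while every code path (all event classes, truncated windows, merging,
255-subset enumeration) is exercised.
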