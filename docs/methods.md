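# Methods

This note documents the models, defaults and numerical choices behind
`promarch`, and what the synthetic generators do and do not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open. BED/BEDPE are read
natively; BAM is converted by pysam on read; bedGraph/bigWig tracks are
expanded to a regular grid (1 bp for the occupancy tracks consumed
here). ATAC fragments from BAM are defined by the leftmost mate start
and the template length, keeping only properly paired primary,
non-duplicate alignments; the default retained length range is
30–250 bp (sub-nucleosomal through mono-nucleosomal), overridable.
Fragment midpoints of even-length fragments are the floor of the true
center, making all counts reproducible.

## Dinucleotide periodicity

The score of a sequence set is built from the distribution of distances
between all pairs of occurrences of a dinucleotide class within each
sequence (never across sequences), up to `d_max` = 300 bp — matching a
−50..+300 bp TSS-anchored analysis span. Occurrences overlap ("AAA"
contains two AA) and windows containing N never match.

Normalisation proceeds in three steps: (1) scale the histogram to unit
sum; (2) subtract a centered moving-average baseline of width
`decay_window` = 15 bp — the histogram decays monotonically with
distance because long distances have fewer chances to occur, and a
15-bp window (more than one 10-bp period) tracks that decay while
leaving the 10-bp oscillation intact; (3) smooth with a centered moving
average of 3. Edge windows shrink symmetrically. The exact decay
estimator is a design choice of this package; it is configurable.

The PSD is `|rfft(x, L)|² / L` with `L` the next multiple of 10 that is
at least max(len, 500), so the 0.1 bp⁻¹ target frequency lies exactly
on the frequency grid and no interpolation is needed. The headline
score is the PSD at the period of interest (default 10 bp). An
all-zero histogram yields an all-zero flagged result.

**Running track.** Windows of 100 bp slide in 2-bp steps; each window's
spectrum is computed as above but kept on the raw pair-count scale (the
unit-sum distribution multiplied back by the window's pair total)
before the PSD is taken, and the score sits at the window center
(floored). The rescaling matters: a 100-bp window holds few pairs, and
on the unit-sum scale a window with two or three chance occurrences
produces spectral spikes as large as a genuinely periodic window's
peak. Weighting by pair abundance makes the track reflect both
periodicity and the amount of periodic material, and planted-cassette
fixtures are then located reliably. N-containing windows score 0;
regions shorter than the window are skipped with a warning.

## V-plots

A V-plot accumulates one event per (fragment, anchor) pair at
(midpoint − anchor center, fragment length) whenever the midpoint falls
within ±`x_range` (default 500 bp) of the anchor center, in 1-bp bins;
the x offset is negated for minus-strand anchors so all anchors read in
their transcription direction. A fragment spanning several anchor
windows counts once per anchor (per-anchor density semantics).
Normalisation is raw counts × 10⁶ / (total fragments × anchors);
raw counts are always retained so conservation can be checked.

The flanking-nucleosome enrichment score divides the mean density over
two mirrored nucleosome boxes (x ∈ ±[70, 180] bp, y ∈ [150, 250] bp)
by the mean over mirrored background boxes (x ∈ ±[250, 400] bp, same
y). Uniform density scores exactly 1; zero background leaves the score
undefined (NaN, flagged). The box geometry is a documented default of
this package and fully configurable.

## Nucleosome calls and promoter metrics

The +1 dyad is the occupancy argmax strictly within
(tss_fwd, tss_fwd + 200]; the −1 dyad within [tss_rev − 200, tss_rev).
"Maximum" is the window argmax, not the first local peak; ties break
toward the TSS — the conservative choice that minimises d₁. Edges are
dyad ± 73 bp (147-bp core particle; the half-width is configurable).
Flat-zero windows yield no call. Metrics on the genome axis:
d₁ = (+1 dyad − 73) − tss_fwd, d₂ = tss_fwd − tss_rev,
w = (+1 dyad − 73) − (−1 dyad + 73); overlapping calls give w < 0 and
are flagged rather than suppressed.

**Occupancy–periodicity binning.** Calls are sorted by occupancy and
chunked into bins of 20 (a trailing partial bin is dropped); each bin's
200-bp dyad-centered sequences are scored together and the PSD at
10 bp is paired with the bin's mean occupancy; the association is
summarised by Pearson correlation across bins. Zero variance in either
axis flags the correlation as undefined.

## Phasing

The binary occurrence matrix (sequence × position) of a dinucleotide
class is clustered by k-means (default k = 6, 10 restarts, fixed
seed). Clusters are phased progressively: the largest cluster anchors
the reference at lag 0, and each remaining cluster (largest first, ties
by index) is shifted by the lag in ±5 bp maximising the overlap
cross-correlation between its mean profile and the mean profile of the
rows already phased; lag ties prefer the smallest shift magnitude.
A fixed global-mean reference was rejected: when cluster phases tile
the period uniformly (e.g. shifts −4, −2, 0, +2, +4 of one 10-bp
comb), the global mean profile is flat at the period and carries no
phase information, so lags become arbitrary; the incremental reference
recovers planted lags exactly in that regime. Out-shifted positions
are zero-filled. The summed occurrence profile before and after
phasing is returned; its 10-bp PSD (mean-centered, same FFT
conventions) quantifies the alignment gain.

## Specificity classification

Inputs are a replicate-averaged signal matrix over the five tissues
(germline, neurons, muscle, hypodermis, intestine) and a table of
pairwise differential statistics computed upstream by a count-based
test. Fold changes are symmetrised to max(fc, 1/fc); the direction of
an effect is taken from the signal matrix. The decision tree (detection
8 RPM for sites, 5 TPM for genes; significance FC > 3 and padj < 0.01):

1. nothing detected → unclassified;
2. the max-signal tissue significantly exceeds every other → specific;
3. 2–4 detected tissues, each significantly above every non-detected
   tissue, and no detected tissue significant against all its peers →
   restricted;
4. all five detected, spread < 3-fold and no significant pair →
   ubiquitous-uniform; all five detected otherwise → ubiquitous-biased;
5. anything else → unclassified.

The rules are evaluated in that order, so a row detected in all five
tissues with one dominant, universally significant tissue is
*specific*, not biased. This tree is the documented contract of the
package; borderline interactions (e.g. two-tissue restricted vs
specific) follow the order above. A missing tissue pair for any tested
id is an error naming the id. Raising the fold-change threshold can
only grow the ubiquitous-uniform set (fewer significant pairs, easier
spread bound).

**CV groups.** CV = sd/mean per gene across ≥2 samples; the lowest
20% are "broad", the highest 20% "regulated", with exact floor(n·q)
counts and ties broken by stable input order. Zero-mean genes are
excluded and flagged. An optional operon pre-filter keeps non-operon
genes and first genes in operons, since downstream operon genes do not
report on their own promoter.

## Synthetic generators

All generators are deterministic under a fixed seed; a root seed fans
out to per-task child seeds via `crc32(name) XOR seed` (31-bit). They
emulate the *analysis-level* structure of the data — planted
periodicity, positioned or diffuse nucleosomal fragments, Gaussian
occupancy peaks, class-structured signal matrices — not read-level
realism: no sequencing errors, no mappability or GC bias, no replicate
structure, and differential P-values derived from design truth rather
than a count model. Passing tests therefore demonstrate that the
implementations recover known structure under controlled noise, not
performance on real libraries.

Defaults: background DNA is i.i.d. at GC 0.35 (C. elegans-like);
planted sequences receive a W dinucleotide every 10 bp with optional
jitter and a random per-sequence phase. Fragment libraries mix ~40%
NDR fragments (length ≈ N(60, 15) clipped to 35–99 bp; midpoint
≈ N(0, 25) bp around the center), ~50% nucleosomal fragments (length
≈ N(170, 12) clipped to 140–200 bp; midpoints at ±110 ± 8 bp for the
germline-like architecture or uniform over ±200 bp for somatic-like)
and 10% diffuse background over ±450 bp — the background mirrors the
genome-wide Tn5 insertion floor of real ATAC libraries and gives the
enrichment score a defined denominator. Occupancy tracks are sums of
Gaussian bumps (σ = 20 bp) with optional additive noise, clipped at 0.
Class matrices plant on/off means of 20/2 (10× effect) under
multiplicative lognormal noise of a chosen CV; the ubiquitous-biased
design co-elevates two tissues so that the row is detected everywhere
yet no single tissue dominates all others.

## Problem sizes and numerical notes

The test and acceptance workloads use 100 × 350 bp sequence sets,
20 000-fragment libraries over 20 anchors, 100 promoters with
two bumps each, 36-sequence phasing fixtures and 110-row class
matrices — sizes at which every planted structure is comfortably
recoverable while the whole suite runs in seconds. The
occupancy–periodicity null check reports the median |r| over five
independent shuffle draws: a single 20-bin draw of r under the null
has a standard deviation near 1/√17 ≈ 0.24, so any single-draw bound
close to 0.3 would fail a fair fraction of seeds by construction;
the median is stable. FFT/DFT agreement is asserted at 1e-9 absolute;
dyad recovery at ±1 bp; metric arithmetic exactly.

## Known limitations

- The decay baseline and the flanking-score box geometry are documented
  package defaults, not community standards; compare like with like.
- The classifier consumes differential tables; it does not compute
  them, and its behaviour on borderline rule interactions follows the
  documented evaluation order rather than any external reference.
- Occupancy tracks are consumed, not inferred: the package does not
  reimplement occupancy-probability estimation from fragment data.
- The running periodicity track scores windows independently; no
  post-smoothing is applied (configurable upstream of plotting).
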