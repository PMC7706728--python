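# promarch

Promoter-architecture analysis from ATAC-seq fragments and DNA sequence:
spectral detection of 10-bp WW dinucleotide periodicity, fragment-density
V-plots, +1/−1 nucleosome calling with promoter metrics, phasing of
nucleosomal dinucleotide matrices, and rule-based tissue-specificity
classification of accessible sites and genes.

## The problem

Active promoters sit in a nucleosome-depleted region (NDR) flanked by a
−1 and a +1 nucleosome. In germline-active promoters the flanking
nucleosomes are well positioned, the NDR is narrow (~120–140 bp), and
the underlying DNA carries a periodic signal: WW dinucleotides
(W = A or T) recurring every ~10 bp — one helical turn — which
facilitates rotational nucleosome positioning. Somatic tissue–specific
promoters lack both the positioned nucleosomes and the periodic signal.
`promarch` provides the computational toolkit to measure all of this
from standard genomics formats, for anyone studying promoter chromatin
organisation in worm or other genomes.

## Methods at a glance

**Periodicity.** For a sequence set, all overlapping occurrences of a
dinucleotide class (WW = {AA, AT, TA, TT}) are located; the histogram
*h(d)* of within-sequence pairwise distances *d* ≤ 300 bp is scaled to
unit sum, corrected for distance decay by subtracting a 15-bp
moving-average baseline, smoothed with a centered window of 3, and the
power spectral density *P(f) = |FFT|²/L* is read out at *f* = 0.1 bp⁻¹.
A running track applies the same spectrum to 100-bp windows in 2-bp
steps.

**V-plots.** Each paired-end fragment contributes an event at
(*x* = midpoint − anchor center, *y* = fragment length) for every
anchor window it falls in; density is normalised per million fragments
per anchor. The flanking-nucleosome enrichment score is the mean
density over the two nucleosome boxes (*x* ∈ ±[70, 180], *y* ∈
[150, 250] bp) divided by background boxes further out.

**Nucleosome calls.** The +1 (−1) dyad is the maximum of a nucleosome
occupancy-probability track within 200 bp downstream (upstream) of the
forward (reverse) TSS mode; edges are dyad ± 73 bp. Metrics:
d₁ = +1 5′ edge − forward mode, d₂ = mode separation, w = NDR width.

**Phasing.** Binary dinucleotide occurrence matrices of 400-bp
dyad-centered sequences are clustered by k-means and each cluster is
shifted by the ±5-bp lag that best aligns it with the already-phased
rows, exposing the shared 10-bp register.

**Classification.** Sites (RPM) and genes (TPM) are classified across
five tissues from a signal matrix plus pairwise fold-change/adjusted-P
tables: detection thresholds 8 RPM / 5 TPM, significance FC > 3 and
padj < 0.01, yielding specific / restricted / ubiquitous-uniform /
ubiquitous-biased / unclassified. Genes are also grouped by expression
CV (lowest 20% = broadly expressed, highest 20% = regulated).

Seeded generators in `promarch.simulate` produce every input with
ground truth, so the full pipeline runs without external data.

## Worked example

```sh
python examples/01_periodicity_spectrum.py
```

```
sequences: 100 x 350 bp, 18384 WW occurrences, 1656428 pairs within 300 bp
PSD at 10 bp (planted):  1.500e-06
PSD at 10 bp (shuffled): 6.084e-09
best period in 5-15 bp:  10 bp
```

One hundred synthetic 350-bp sequences carry a W dinucleotide every
10 bp (10% jitter). The spectrum of their pairwise-distance
distribution peaks at the 10-bp period, ~250× above the same sequences
after mononucleotide shuffling — the shuffle destroys positional
structure while preserving base composition, so the gap is pure
periodicity signal. The other scripts in `examples/` walk through
V-plots, nucleosome calling, phasing and classification the same way.

Each capability is also exposed as a `promarch` subcommand
(`simulate`, `periodicity`, `ptrack`, `vplot`, `nuccall`, `phase`,
`classify`); every run writes a JSON manifest with input checksums for
reproducibility.

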