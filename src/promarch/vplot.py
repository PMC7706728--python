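"""Fragment-density V-plots over anchor sets.

A V-plot is the 2D density of paired-end fragments as a function of the
distance between the fragment midpoint and an anchor center (x) and the
fragment length (y). Over promoters flanked by positioned nucleosomes
it shows a central concentration of short fragments at the
nucleosome-depleted region and clusters of nucleosome-length fragments
about 100 bp to either side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from promarch.core import FragmentRecord, GenomicInterval


@dataclass
class VplotMatrix:
    """2D fragment density over (midpoint offset x fragment length).

    ``density[j, i]`` covers fragment length ``y_values[j]`` at offset
    ``x_values[i]``, both in 1-bp bins. ``raw`` keeps the unnormalized
    event counts so count conservation can always be checked.
    """

    density: np.ndarray
    x_values: np.ndarray
    y_values: np.ndarray
    n_fragments: int
    n_anchors: int
    normalization: str = "raw"
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw is None:
            self.raw = self.density.copy()

    def mean_in_box(self, x_box: tuple[int, int], y_box: tuple[int, int]) -> float:
        """Mean density over x in [x0, x1] and y in [y0, y1] (inclusive)."""
        xi = (self.x_values >= x_box[0]) & (self.x_values <= x_box[1])
        yi = (self.y_values >= y_box[0]) & (self.y_values <= y_box[1])
        if not xi.any() or not yi.any():
            raise ValueError(f"box x={x_box}, y={y_box} outside matrix extent")
        return float(self.density[np.ix_(yi, xi)].mean())


@dataclass
class FlankingScore:
    """Flanking-nucleosome enrichment: nucleosome-box over background-box density."""

    score: float
    boxes: dict[str, list[tuple[tuple[int, int], tuple[int, int]]]]

    @property
    def defined(self) -> bool:
        return np.isfinite(self.score)


def compute_vplot(
    fragments: Sequence[FragmentRecord],
    anchors: Sequence[GenomicInterval],
    x_range: int = 500,
    y_range: tuple[int, int] = (30, 250),
    normalization: str = "per-million-per-anchor",
) -> VplotMatrix:
    """Accumulate a V-plot of fragments over anchor centers.

    Each fragment contributes one event at
    ``(midpoint - anchor_center, length)`` for every anchor whose
    ``x_range`` window contains its midpoint; the x offset changes sign
    for minus-strand anchors so all anchors read in their direction of
    transcription. A fragment overlapping several anchors counts once
    per anchor (per-anchor density semantics).

    ``normalization='per-million-per-anchor'`` scales raw counts by
    ``1e6 / (n_fragments * n_anchors)``; ``'raw'`` keeps counts.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors given")
    if normalization not in {"raw", "per-million-per-anchor"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    x_values = np.arange(-x_range, x_range + 1)
    y_values = np.arange(y_range[0], y_range[1] + 1)
    counts = np.zeros((len(y_values), len(x_values)), dtype=np.int64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in fragments}:
        sub = [(f.midpoint, f.length) for f in fragments if f.chrom == chrom]
        sub.sort()
        mids = np.array([m for m, _ in sub], dtype=np.int64)
        lens = np.array([l for _, l in sub], dtype=np.int64)
        by_chrom[chrom] = (mids, lens)

    for anchor in anchors:
        if anchor.chrom not in by_chrom:
            continue
        mids, lens = by_chrom[anchor.chrom]
        center = anchor.center
        lo = np.searchsorted(mids, center - x_range, side="left")
        hi = np.searchsorted(mids, center + x_range, side="right")
        x = mids[lo:hi] - center
        y = lens[lo:hi]
        if anchor.strand == "-":
            x = -x
        ok = (x >= -x_range) & (x <= x_range) & (y >= y_range[0]) & (y <= y_range[1])
        np.add.at(counts, (y[ok] - y_range[0], x[ok] + x_range), 1)

    if counts.sum() == 0:
        warnings.warn("no fragments fell inside any anchor window", stacklevel=2)

    if normalization == "per-million-per-anchor" and fragments:
        density = counts * 1e6 / (len(fragments) * len(anchors))
    else:
        density = counts.astype(float)
    return VplotMatrix(
        density=density,
        x_values=x_values,
        y_values=y_values,
        n_fragments=len(fragments),
        n_anchors=len(anchors),
        normalization=normalization,
        raw=counts.astype(float),
    )


def flanking_enrichment(
    v: VplotMatrix,
    nuc_box_x: tuple[int, int] = (70, 180),
    nuc_box_y: tuple[int, int] = (150, 250),
    bg_box_x: tuple[int, int] = (250, 400),
) -> FlankingScore:
    """Enrichment of nucleosome-length fragments flanking the anchor.

    The score is the mean density over the two mirrored flanking
    nucleosome boxes (x in +/-[70, 180] bp, fragment length 150-250 bp
    by default) divided by the mean over mirrored background boxes
    further out at the same fragment lengths. Uniform density gives
    exactly 1; a zero-density background leaves the score undefined
    (NaN, flagged via ``defined``).
    """
    nuc_boxes = [((nuc_box_x[0], nuc_box_x[1]), nuc_box_y),
                 ((-nuc_box_x[1], -nuc_box_x[0]), nuc_box_y)]
    bg_boxes = [((bg_box_x[0], bg_box_x[1]), nuc_box_y),
                ((-bg_box_x[1], -bg_box_x[0]), nuc_box_y)]
    nuc = float(np.mean([v.mean_in_box(x, y) for x, y in nuc_boxes]))
    bg = float(np.mean([v.mean_in_box(x, y) for x, y in bg_boxes]))
    if bg == 0:
        warnings.warn("zero background density; flanking score undefined", stacklevel=2)
        score = float("nan")
    else:
        score = nuc / bg
    return FlankingScore(score=score, boxes={"nucleosome": nuc_boxes, "background": bg_boxes})


def plot_vplot(v: VplotMatrix, path, cmap: str = "viridis", title: str | None = None) -> None:
    """Export a basic heatmap of the V-plot to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        v.density,
        origin="lower",
        aspect="auto",
        extent=(v.x_values[0], v.x_values[-1], v.y_values[0], v.y_values[-1]),
        cmap=cmap,
    )
    ax.set_xlabel("fragment midpoint offset from anchor center (bp)")
    ax.set_ylabel("fragment length (bp)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=f"density ({v.normalization})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
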