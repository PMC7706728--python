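"""Shared genomic domain types and readers/writers for standard formats.

All coordinates are 0-based half-open throughout the package: BED/BEDPE
are native, BAM records are converted on read by pysam, and any 1-based
format is converted at the boundary. A single convention avoids
off-by-one drift between modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pyfaidx
import pysam

logger = logging.getLogger("promarch")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default paired-end fragment length window (bp) retained for V-plot
#: style analyses; spans the sub-nucleosomal to mono-nucleosomal range.
DEFAULT_LENGTH_RANGE = (30, 250)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint base (floor of the true center for odd lengths)."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter with experimentally defined forward/reverse TSS modes.

    ``tss_fwd_mode``/``tss_rev_mode`` are genome-axis positions of the
    most frequent initiation base on each strand; for divergent
    promoters the reverse mode lies upstream (left) of the forward mode.
    ``class_label`` optionally carries a tissue-specificity class.
    """

    interval: GenomicInterval
    center: int
    tss_fwd_mode: int | None = None
    tss_rev_mode: int | None = None
    directionality: str = "unidirectional"
    class_label: object | None = None

    def __post_init__(self) -> None:
        if not self.interval.start <= self.center < self.interval.end:
            raise ValueError(f"promoter center {self.center} outside {self.interval}")
        if (
            self.tss_fwd_mode is not None
            and self.tss_rev_mode is not None
            and not self.tss_rev_mode < self.tss_fwd_mode
        ):
            raise ValueError(
                f"divergent promoter at {self.interval}: reverse TSS mode "
                f"({self.tss_rev_mode}) must lie left of the forward mode "
                f"({self.tss_fwd_mode}) on the genome axis"
            )

    @property
    def is_divergent(self) -> bool:
        return self.tss_fwd_mode is not None and self.tss_rev_mode is not None


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced paired-end fragment span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end} has length <= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor of the true center so even-length fragments are reproducible
        return (self.start + self.end) // 2


@dataclass
class SignalTrack:
    """Per-chromosome real-valued signal sampled on a regular grid.

    ``data`` maps chromosome name to ``(origin, values)`` where
    ``values[i]`` covers the bin starting at ``origin + i * step``.
    """

    data: dict[str, tuple[int, np.ndarray]] = field(default_factory=dict)
    step: int = 1

    def add(self, chrom: str, origin: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if origin < 0:
            raise ValueError("track origin must be non-negative")
        if not np.all(np.isfinite(values)):
            raise ValueError("track values must be finite")
        self.data[chrom] = (int(origin), values)

    def positions(self, chrom: str) -> np.ndarray:
        origin, values = self.data[chrom]
        return origin + self.step * np.arange(len(values))

    def values_between(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Grid positions and values with ``start <= pos < end``."""
        origin, values = self.data[chrom]
        pos = self.positions(chrom)
        mask = (pos >= start) & (pos < end)
        return pos[mask], values[mask]

    @property
    def chroms(self) -> list[str]:
        return list(self.data)


# ---------------------------------------------------------------------------
# Sequence I/O


def read_sequences(
    fasta_path: str | Path,
    intervals: Sequence[GenomicInterval],
    flip_minus: bool = True,
) -> list[str]:
    """Extract uppercase sequences for a list of intervals.

    Sequences on the minus strand are reverse-complemented when
    ``flip_minus`` is set, so all returned sequences read in the
    direction of transcription of their interval.
    """
    fasta = pyfaidx.Fasta(str(fasta_path))
    out: list[str] = []
    try:
        for iv in intervals:
            if iv.chrom not in fasta:
                raise KeyError(f"unknown chromosome {iv.chrom!r} in {fasta_path}")
            chrom_len = len(fasta[iv.chrom])
            if iv.end > chrom_len:
                raise ValueError(
                    f"interval {iv} out of bounds for {iv.chrom} (length {chrom_len})"
                )
            seq = fasta[iv.chrom][iv.start : iv.end].seq.upper()
            if flip_minus and iv.strand == "-":
                seq = reverse_complement(seq)
            out.append(seq)
    finally:
        fasta.close()
    return out


# ---------------------------------------------------------------------------
# Promoter tables


def read_promoters(path: str | Path) -> list[PromoterRecord]:
    """Read a promoter table (TSV with header).

    Columns: chrom, start, end, center, tss_fwd, tss_rev [, class].
    Empty/NA tss fields mean the mode is absent.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "center", "tss_fwd", "tss_rev"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"promoter table {path} missing columns {sorted(missing)}")
    records = []
    for row in table.itertuples(index=False):
        fwd = None if pd.isna(row.tss_fwd) else int(row.tss_fwd)
        rev = None if pd.isna(row.tss_rev) else int(row.tss_rev)
        records.append(
            PromoterRecord(
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                center=int(row.center),
                tss_fwd_mode=fwd,
                tss_rev_mode=rev,
                directionality="bidirectional" if fwd is not None and rev is not None
                else "unidirectional",
            )
        )
    return records


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED3+/BED6 file (strand from column 6)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return intervals


# ---------------------------------------------------------------------------
# Fragment I/O


def _iter_bedpe(path: str | Path) -> Iterable[FragmentRecord]:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: BEDPE needs >= 6 columns, got {len(fields)}")
            c1, s1, e1, c2, s2, e2 = fields[:6]
            if c1 != c2:
                continue  # inter-chromosomal pairs carry no fragment span
            start = min(int(s1), int(s2))
            end = max(int(e1), int(e2))
            yield FragmentRecord(c1, start, end)


def _iter_bam(path: str | Path) -> Iterable[FragmentRecord]:
    # one fragment per properly-paired primary pair, defined by the
    # leftmost mate start and the template length
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if (
                not aln.is_proper_pair
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
                or aln.is_unmapped
            ):
                continue
            if aln.template_length <= 0:  # count each pair once, from the left mate
                continue
            yield FragmentRecord(
                aln.reference_name,
                aln.reference_start,
                aln.reference_start + aln.template_length,
            )


def read_fragments(
    path: str | Path,
    format: str | None = None,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> list[FragmentRecord]:
    """Read paired-end fragments from BEDPE or coordinate-sorted BAM.

    Fragments outside ``length_range`` (inclusive bounds, bp) are
    dropped; the retained count is logged. Returns an empty list (with
    a warning) if nothing survives the filter.
    """
    path = Path(path)
    if format is None:
        format = "bam" if path.suffix == ".bam" else "bedpe"
    if format not in {"bam", "bedpe"}:
        raise ValueError(f"unknown fragment format {format!r}")
    source = _iter_bam(path) if format == "bam" else _iter_bedpe(path)
    lo, hi = length_range
    n_total = 0
    fragments: list[FragmentRecord] = []
    for frag in source:
        n_total += 1
        if lo <= frag.length <= hi:
            fragments.append(frag)
    logger.info(
        "read_fragments: %d/%d fragments in length range [%d, %d] from %s",
        len(fragments), n_total, lo, hi, path,
    )
    if n_total and not fragments:
        warnings.warn(
            f"no fragments within length range {length_range} in {path}", stacklevel=2
        )
    return fragments


# ---------------------------------------------------------------------------
# Track I/O


def write_track(
    track: SignalTrack,
    path: str | Path,
    format: str = "bedgraph",
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Write a :class:`SignalTrack` as bedGraph or bigWig.

    An empty track yields an empty bedGraph (no header lines are
    written). bigWig needs chromosome sizes; when not given they are
    taken as the end of the last bin per chromosome.
    """
    path = Path(path)
    if format == "bedgraph":
        with open(path, "w") as fh:
            for chrom, (origin, values) in track.data.items():
                for i, v in enumerate(values):
                    s = origin + i * track.step
                    fh.write(f"{chrom}\t{s}\t{s + track.step}\t{v:.6g}\n")
    elif format == "bigwig":
        import pyBigWig

        sizes = dict(chrom_sizes or {})
        for chrom, (origin, values) in track.data.items():
            sizes.setdefault(chrom, origin + len(values) * track.step)
        bw = pyBigWig.open(str(path), "w")
        try:
            bw.addHeader(sorted(sizes.items()))
            for chrom in sorted(track.data):
                origin, values = track.data[chrom]
                starts = (origin + track.step * np.arange(len(values))).tolist()
                ends = [s + track.step for s in starts]
                bw.addEntries([chrom] * len(starts), starts, ends=ends,
                              values=values.astype(float).tolist())
        finally:
            bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(path: str | Path, format: str | None = None) -> SignalTrack:
    """Read a bedGraph or bigWig file into a :class:`SignalTrack`.

    Intervals are expanded to a regular grid at the smallest interval
    width seen per file (1 bp for the per-base occupancy tracks this
    package consumes).
    """
    path = Path(path)
    if format is None:
        format = "bigwig" if path.suffix.lower() in {".bw", ".bigwig"} else "bedgraph"
    entries: dict[str, list[tuple[int, int, float]]] = {}
    if format == "bedgraph":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                entries.setdefault(chrom, []).append((int(s), int(e), float(v)))
    elif format == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        try:
            for chrom in bw.chroms():
                for s, e, v in bw.intervals(chrom) or []:
                    entries.setdefault(chrom, []).append((s, e, v))
        finally:
            bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")

    step = min(
        (e - s for ivs in entries.values() for s, e, _ in ivs),
        default=1,
    )
    track = SignalTrack(step=step)
    for chrom, ivs in entries.items():
        ivs.sort()
        origin = ivs[0][0]
        n = (ivs[-1][1] - origin) // step
        values = np.zeros(n)
        for s, e, v in ivs:
            values[(s - origin) // step : (e - origin) // step] = v
        track.add(chrom, origin, values)
    return track
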