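"""Seeded synthetic generators for every input the toolkit consumes.

Each generator is deterministic under a fixed seed and returns (or
writes) both the data and a ground-truth table sufficient for automated
recovery scoring. A single root seed fans out to per-generator child
seeds through :func:`child_seed`, so individual fixtures are
reproducible in isolation.

The generators emulate the study conditions, not raw sequencing:
promoter-proximal sequence sets of a few hundred bp with an optional
planted 10-bp W signal at C. elegans-like GC content, ATAC fragment
libraries mixing sub-nucleosomal NDR fragments with nucleosome-length
fragments over positioned (germline-like) or diffuse (somatic-like)
flanking nucleosomes, Gaussian-bump occupancy tracks, and five-tissue
signal matrices with planted specificity classes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from promarch.core import FragmentRecord, GenomicInterval, SignalTrack
from promarch.classify import TISSUES, SpecificityLabel

#: Genome-wide GC content used for background sequence (C. elegans ~0.35).
DEFAULT_GC = 0.35


def child_seed(root_seed: int, name: str) -> int:
    """Derive a stable per-generator seed (< 2^31) from a root seed.

    ``child = crc32(name) XOR root, folded to 31 bits`` — documented so
    any fixture can be regenerated in isolation.
    """
    return (zlib.crc32(name.encode()) ^ int(root_seed)) & 0x7FFFFFFF


def _random_dna(rng: np.random.Generator, n: int, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.array(list("ACGT"))
    draws = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in alphabet[draws]]


def gen_periodic_sequences(
    n: int = 100,
    length: int = 350,
    period: int = 10,
    planted_fraction: float = 1.0,
    jitter: float = 0.0,
    gc: float = DEFAULT_GC,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Sequences with an optional planted periodic W dinucleotide signal.

    Background is i.i.d. at the stated GC. A planted sequence receives
    a W/W dinucleotide (drawn from AA/AT/TA/TT) every ``period`` bp,
    displaced by a uniform offset of up to ``round(jitter * period)``
    bp; the phase of the comb is random per sequence. Returns
    ``(sequences, truth)`` where truth records the planted flag and
    phase per sequence.
    """
    rng = np.random.default_rng(seed)
    seqs = _random_dna(rng, n, length, gc)
    n_planted = int(round(planted_fraction * n))
    planted = np.zeros(n, dtype=bool)
    planted[:n_planted] = True
    w_members = ["AA", "AT", "TA", "TT"]
    max_off = int(round(jitter * period))
    phases = np.full(n, -1)
    out = []
    for i, seq in enumerate(seqs):
        if not planted[i]:
            out.append(seq)
            continue
        chars = list(seq)
        phase = int(rng.integers(0, period))
        phases[i] = phase
        for anchor in range(phase, length - 1, period):
            off = int(rng.integers(-max_off, max_off + 1)) if max_off else 0
            p = min(max(anchor + off, 0), length - 2)
            dinuc = w_members[rng.integers(0, 4)]
            chars[p], chars[p + 1] = dinuc[0], dinuc[1]
        out.append("".join(chars))
    truth = pd.DataFrame(
        {"id": [f"seq{i}" for i in range(n)], "planted": planted, "phase": phases}
    )
    return out, truth


def mononucleotide_shuffle(sequences: Sequence[str], seed: int = 0) -> list[str]:
    """Independently permute the bases of each sequence.

    Preserves mononucleotide composition while destroying all
    positional structure — the null for periodicity scores.
    """
    rng = np.random.default_rng(seed)
    return ["".join(rng.permutation(list(s))) for s in sequences]


@dataclass
class FragmentArchitecture:
    """Mixture model for per-anchor fragment placement.

    ``germline_like``: a narrow NDR emitting short fragments around the
    anchor center plus well-positioned 147-bp flanking nucleosomes at
    +/- ``nucleosome_offset`` bp emitting nucleosome-length fragments.
    ``somatic_like``: a wide NDR and diffuse nucleosome-length
    fragments spread uniformly over a 400-bp band.
    """

    name: str
    short_fraction: float
    ndr_sd: float  # midpoint spread of short fragments (bp)
    nucleosome_offset: int  # planted dyad offset (bp); ignored when diffuse
    dyad_sd: float  # positioning noise of nucleosomal midpoints (bp)
    diffuse: bool
    background_fraction: float = 0.1  # diffuse library background over +/-450 bp


GERMLINE_LIKE = FragmentArchitecture(
    "germline-like", short_fraction=0.40, ndr_sd=25.0,
    nucleosome_offset=110, dyad_sd=8.0, diffuse=False,
)
SOMATIC_LIKE = FragmentArchitecture(
    "somatic-like", short_fraction=0.40, ndr_sd=80.0,
    nucleosome_offset=110, dyad_sd=8.0, diffuse=True,
)

_ARCHITECTURES = {"germline-like": GERMLINE_LIKE, "somatic-like": SOMATIC_LIKE}


def gen_fragments(
    anchors: Sequence[GenomicInterval],
    architecture: str | FragmentArchitecture = "germline-like",
    n: int = 10_000,
    seed: int = 0,
) -> tuple[list[FragmentRecord], pd.DataFrame]:
    """ATAC-like fragment library around a set of anchors.

    Short (< 100 bp) fragments are drawn in the NDR around the anchor
    center; 140-200-bp fragments are centered on the planted +/-1 dyads
    (germline-like) or spread uniformly over a 400-bp band
    (somatic-like). Returns ``(fragments, truth)``; truth records each
    fragment's anchor index, component and midpoint offset.
    """
    if isinstance(architecture, str):
        architecture = _ARCHITECTURES[architecture]
    if not anchors:
        raise ValueError("no anchors given")
    rng = np.random.default_rng(seed)
    arch = architecture
    records: list[FragmentRecord] = []
    rows = []
    for _ in range(n):
        ai = int(rng.integers(0, len(anchors)))
        anchor = anchors[ai]
        center = anchor.center
        draw = rng.random()
        if draw < arch.background_fraction:
            component = "background"
            length = int(rng.integers(35, 201))
            offset = int(rng.integers(-450, 451))
        elif draw < arch.background_fraction + arch.short_fraction:
            component = "ndr"
            length = int(np.clip(rng.normal(60, 15), 35, 99))
            offset = int(np.clip(rng.normal(0, arch.ndr_sd), -230, 230))
        else:
            component = "nucleosomal"
            length = int(np.clip(rng.normal(170, 12), 140, 200))
            if arch.diffuse:
                offset = int(rng.integers(-200, 201))
            else:
                side = -1 if rng.random() < 0.5 else 1
                offset = int(np.clip(rng.normal(side * arch.nucleosome_offset,
                                                arch.dyad_sd), -230, 230))
        mid = center + offset
        start = mid - length // 2
        records.append(FragmentRecord(anchor.chrom, start, start + length))
        rows.append((ai, component, offset, length))
    truth = pd.DataFrame(rows, columns=["anchor", "component", "offset", "length"])
    return records, truth


def write_bedpe(fragments: Sequence[FragmentRecord], path: str | Path) -> None:
    """Write fragments as a minimal BEDPE (each mate = half the span)."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            mid = f.midpoint
            fh.write(
                f"{f.chrom}\t{f.start}\t{mid}\t{f.chrom}\t{mid}\t{f.end}\t"
                f"frag{i}\t.\t+\t-\n"
            )


def gen_occupancy_track(
    chrom: str,
    chrom_length: int,
    dyads: Sequence[int],
    amplitudes: Sequence[float] | None = None,
    sigma: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SignalTrack, pd.DataFrame]:
    """Gaussian-bump nucleosome occupancy-probability track.

    ``values[pos] = sum_k amp_k * exp(-(pos - dyad_k)^2 / (2 sigma^2))``
    plus optional truncated Gaussian noise, clipped at 0. Returns the
    1-bp track and a truth table of planted dyads and amplitudes.
    """
    rng = np.random.default_rng(seed)
    if amplitudes is None:
        amplitudes = [1.0] * len(dyads)
    if len(amplitudes) != len(dyads):
        raise ValueError("amplitudes must align with dyads")
    pos = np.arange(chrom_length, dtype=float)
    values = np.zeros(chrom_length)
    for dyad, amp in zip(dyads, amplitudes):
        values += amp * np.exp(-((pos - dyad) ** 2) / (2 * sigma**2))
    if noise_sd:
        values = np.clip(values + rng.normal(0, noise_sd, chrom_length), 0, None)
    track = SignalTrack(step=1)
    track.add(chrom, 0, values)
    truth = pd.DataFrame({"dyad": list(dyads), "amplitude": list(amplitudes)})
    return track, truth


# ---------------------------------------------------------------------------
# Classification fixtures

#: Per-class design means (detection thresholds are 8 RPM / 5 TPM; the
#: "off" level sits below, the "on" level is effect x off).
_OFF_MEAN = 2.0
_UNIFORM_MEAN = 50.0


def _design_means(label: SpecificityLabel, effect: float) -> np.ndarray:
    on = _OFF_MEAN * effect
    means = np.full(len(TISSUES), _OFF_MEAN)
    if label.category == "specific":
        (t,) = label.tissues
        means[TISSUES.index(t)] = on
    elif label.category == "restricted":
        for t in label.tissues:
            means[TISSUES.index(t)] = on
    elif label.category == "ubiquitous-uniform":
        means[:] = _UNIFORM_MEAN
    elif label.category == "ubiquitous-biased":
        # all detected, two tissues tilted up together: significant pairs
        # exist but no single tissue dominates every other, so the row is
        # neither uniform nor specific
        means[:] = 20.0
        means[0] = means[1] = 20.0 * effect
    # unclassified: everything below the detection threshold
    return means


def gen_class_matrix(
    design: dict[str, int] | None = None,
    effect: float = 10.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    fc_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Signal matrix + differential table with planted specificity labels.

    ``design`` maps label strings (e.g. ``"specific:germline"``,
    ``"restricted:muscle+neurons"``, ``"ubiquitous-uniform"``) to row
    counts. Observed values are the design means under multiplicative
    lognormal noise of the given CV. The differential table is derived
    from the generator truth: a pair is "significant" (padj 1e-6) when
    the design-mean ratio exceeds ``fc_threshold``, otherwise padj = 1;
    fold changes are design-mean ratios.

    Returns ``(matrix, diff_table, truth_labels)``.
    """
    if design is None:
        design = {
            "specific:germline": 20,
            "specific:neurons": 20,
            "restricted:muscle+neurons": 20,
            "ubiquitous-uniform": 20,
            "ubiquitous-biased": 20,
            "unclassified": 10,
        }
    rng = np.random.default_rng(seed)
    ids, rows, diff_rows, truth = [], [], [], []
    if noise_cv > 0:
        log_sd = float(np.sqrt(np.log1p(noise_cv**2)))
    idx = 0
    for label_str, count in design.items():
        label = SpecificityLabel.parse(label_str)
        means = _design_means(label, effect)
        for _ in range(count):
            id_ = f"id{idx:04d}"
            idx += 1
            if noise_cv > 0:
                obs = means * rng.lognormal(-log_sd**2 / 2, log_sd, len(means))
            else:
                obs = means.astype(float)
            ids.append(id_)
            rows.append(obs)
            truth.append(label)
            for i, a in enumerate(TISSUES):
                for b in TISSUES[i + 1:]:
                    ma, mb = means[TISSUES.index(a)], means[TISSUES.index(b)]
                    fc = max(ma, mb) / min(ma, mb)
                    padj = 1e-6 if fc > fc_threshold else 1.0
                    diff_rows.append((id_, a, b, fc, padj))
    matrix = pd.DataFrame(rows, index=ids, columns=list(TISSUES))
    diffs = pd.DataFrame(
        diff_rows, columns=["id", "tissue_a", "tissue_b", "fold_change", "padj"]
    )
    truth_s = pd.Series(truth, index=ids, name="truth")
    return matrix, diffs, truth_s


def gen_coupled_nucleosome_set(
    n: int = 400,
    seq_length: int = 200,
    coupled: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """+1 nucleosome occupancies with periodicity-coupled sequences.

    Occupancy is uniform on [0.2, 1]; each dyad-centered sequence
    carries a planted 10-bp W comb in a random subset of its periodic
    slots, with the planted density proportional to occupancy when
    ``coupled`` (the rotational-positioning scenario) and independent
    of it otherwise. Returns ``(occupancies, sequences)``.
    """
    rng = np.random.default_rng(seed)
    occ = rng.uniform(0.2, 1.0, n)
    strength = occ if coupled else rng.permutation(occ)
    w_members = ["AA", "AT", "TA", "TT"]
    seqs = []
    for i in range(n):
        chars = list(_random_dna(rng, 1, seq_length, DEFAULT_GC)[0])
        phase = int(rng.integers(0, 10))
        for anchor in range(phase, seq_length - 1, 10):
            if rng.random() < strength[i]:
                d = w_members[rng.integers(0, 4)]
                chars[anchor], chars[anchor + 1] = d[0], d[1]
        seqs.append("".join(chars))
    return occ, seqs


def write_provenance(path: str | Path, **params) -> None:
    """Echo generator parameters into a JSON sidecar next to a fixture."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
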