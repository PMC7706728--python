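"""Shared fixtures: tiny genomes, fragment files and helper writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from promarch.core import GenomicInterval


@pytest.fixture
def write_fasta(tmp_path):
    """Write {name: sequence} to an indexed FASTA and return its path."""

    def _write(seqs: dict[str, str], name: str = "genome.fa") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, seq in seqs.items():
                fh.write(f">{chrom}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_bedpe_file(tmp_path):
    """Write fragment spans as a BEDPE file and return its path."""

    def _write(spans: list[tuple[str, int, int]], name: str = "frags.bedpe") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, (chrom, start, end) in enumerate(spans):
                mid = (start + end) // 2
                fh.write(
                    f"{chrom}\t{start}\t{mid}\t{chrom}\t{mid}\t{end}\t"
                    f"f{i}\t.\t+\t-\n"
                )
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


@pytest.fixture
def anchor_set():
    """20 anchors spaced 3 kb apart on one synthetic chromosome."""
    return [
        GenomicInterval("chrS", 5_000 + 3_000 * i, 6_000 + 3_000 * i, "+")
        for i in range(20)
    ]
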