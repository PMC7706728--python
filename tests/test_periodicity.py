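"""Dinucleotide periodicity: occurrences, pair histograms, spectra, tracks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from promarch.core import GenomicInterval, reverse_complement
from promarch.periodicity import (
    DINUCLEOTIDE_CLASSES,
    find_occurrences,
    get_periodicity,
    normalize_distribution,
    pairwise_distance_hist,
    periodicity_track,
    power_spectral_density,
)
from promarch.simulate import gen_periodic_sequences, mononucleotide_shuffle


def brute_force_pairs(sequences, motif, d_max):
    """Independent O(k^2) double-loop pair count per sequence."""
    total = 0
    members = DINUCLEOTIDE_CLASSES.get(motif, frozenset({motif}))
    for seq in sequences:
        pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] in members]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if pos[j] - pos[i] <= d_max:
                    total += 1
    return total


def naive_dft_psd(x, L):
    """Direct O(L^2) DFT-sum power spectral density oracle."""
    x = np.concatenate([x, np.zeros(L - len(x))])
    n = np.arange(L)
    out = []
    for k in range(L // 2 + 1):
        coeff = np.sum(x * np.exp(-2j * np.pi * k * n / L))
        out.append(abs(coeff) ** 2 / L)
    return np.array(out)


class TestFindOccurrences:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("AAAA", "WW", [0, 1, 2]),
            ("GGGG", "WW", []),
            ("ATAT", "TA", [1]),
            ("ATAT", "AT", [0, 2]),
            ("ANAA", "WW", [2]),  # N-containing windows never match
            ("A", "WW", []),
        ],
    )
    def test_overlapping_matches(self, seq, motif, expected):
        assert list(find_occurrences(seq, motif)) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            find_occurrences("ACGT", "XX")


class TestPairwiseDistanceHist:
    def test_overlapping_pair_histogram(self):
        hist = pairwise_distance_hist(["AAAA"], "WW", d_max=10)
        assert hist[0] == 2 and hist[1] == 1 and hist[2:].sum() == 0

    def test_no_cross_sequence_pairs(self):
        # one W-dinucleotide per sequence: no within-sequence pair exists
        assert pairwise_distance_hist(["GGAAGG", "GGTTGG"], "WW", 20).sum() == 0

    def test_all_gc_is_zero(self):
        assert pairwise_distance_hist(["GG", "CC"], "WW", 10).sum() == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_hist([], "WW", 10)

    def test_count_conservation_vs_brute_force(self, rng):
        seqs = [random_dna(rng, 200) for _ in range(20)]
        for d_max in (10, 50, 199):
            hist = pairwise_distance_hist(seqs, "WW", d_max)
            assert hist.sum() == brute_force_pairs(seqs, "WW", d_max)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_count_conservation_property(self, seed):
        r = np.random.default_rng(seed)
        seqs = [random_dna(r, int(r.integers(2, 80))) for _ in range(3)]
        hist = pairwise_distance_hist(seqs, "WW", 40)
        assert hist.sum() == brute_force_pairs(seqs, "WW", 40)


class TestNormalizeDistribution:
    def test_flat_histogram_detrends_to_near_zero(self):
        norm, ok = normalize_distribution(np.full(100, 7.0))
        assert ok
        assert np.abs(norm).max() < 1e-12

    def test_all_zero_flagged(self):
        with pytest.warns(UserWarning, match="all-zero"):
            norm, ok = normalize_distribution(np.zeros(50))
        assert not ok and not norm.any()

    def test_periodic_comb_survives_decay_correction(self):
        hist = np.zeros(200)
        hist[9::10] = 100  # spikes at distances 10, 20, ...
        hist += np.linspace(50, 5, 200)  # monotone decay background
        norm, _ = normalize_distribution(hist)
        freqs, psd = power_spectral_density(norm)
        peak = freqs[1:][np.argmax(psd[1:])]  # ignore DC
        assert peak == pytest.approx(0.1, abs=1e-9)

    def test_short_histogram_rejected(self):
        with pytest.raises(ValueError):
            normalize_distribution(np.ones(5))


class TestPowerSpectralDensity:
    def test_zero_input_zero_psd(self):
        freqs, psd = power_spectral_density(np.zeros(100))
        assert not psd.any()
        assert 0.1 in freqs  # grid includes the 10-bp frequency exactly

    def test_cosine_peak_at_one_tenth(self):
        d = np.arange(1, 201)
        freqs, psd = power_spectral_density(np.cos(2 * np.pi * d / 10))
        assert freqs[np.argmax(psd)] == pytest.approx(0.1)

    @pytest.mark.parametrize("length", [13, 50, 64])
    def test_fft_equals_naive_dft(self, rng, length):
        x = rng.normal(size=length)
        L = 500
        freqs, psd = power_spectral_density(x, pad_to=L)
        np.testing.assert_allclose(psd, naive_dft_psd(x, L), atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            power_spectral_density(np.array([1.0, np.inf]))


class TestGetPeriodicity:
    def test_planted_ten_bp_signal_dominates_neighbor_periods(self):
        seqs, _ = gen_periodic_sequences(n=100, length=350, period=10,
                                         planted_fraction=1.0, jitter=0.1, seed=3)
        res = get_periodicity(seqs, "WW")
        for p in (7, 8, 9, 11, 12):
            assert res.psd_at_period(10) > res.psd_at_period(p)

    def test_planted_period_eight_recovered(self):
        seqs, _ = gen_periodic_sequences(n=100, length=350, period=8,
                                         planted_fraction=1.0, jitter=0.1, seed=3)
        res = get_periodicity(seqs, "WW")
        best = max(range(5, 16), key=res.psd_at_period)
        assert best == 8

    def test_shuffle_null_collapses_score(self):
        seqs, _ = gen_periodic_sequences(n=100, length=350, seed=3)
        planted = get_periodicity(seqs, "WW").psd_at_period(10)
        shuffled = get_periodicity(mononucleotide_shuffle(seqs, seed=4), "WW")
        assert planted >= 5 * shuffled.psd_at_period(10)

    def test_score_monotone_in_planted_fraction(self):
        scores = []
        for frac in (0.0, 0.25, 0.5, 1.0):
            seqs, _ = gen_periodic_sequences(n=100, length=350,
                                             planted_fraction=frac, seed=7)
            scores.append(get_periodicity(seqs, "WW").psd_at_period(10))
        assert scores == sorted(scores)

    def test_ww_score_strand_symmetric(self, rng):
        # WW is closed under reverse complement, so the pair-distance
        # spectrum of a set equals that of its reverse complement
        seqs = [random_dna(rng, 300) for _ in range(10)]
        fwd = get_periodicity(seqs, "WW")
        rev = get_periodicity([reverse_complement(s) for s in seqs], "WW")
        assert fwd.n_pairs == rev.n_pairs
        np.testing.assert_allclose(fwd.psd, rev.psd, atol=1e-12)

    def test_uniform_sequences_within_shuffle_null(self):
        r = np.random.default_rng(11)
        seqs = [random_dna(r, 150) for _ in range(20)]
        observed = get_periodicity(seqs, "WW").psd_at_period(10)
        null = np.array([
            get_periodicity(mononucleotide_shuffle(seqs, seed=s), "WW").psd_at_period(10)
            for s in range(200)
        ])
        assert abs(observed - null.mean()) <= 3 * null.std()

    def test_pair_total_matches_histogram(self, rng):
        seqs = [random_dna(rng, 120) for _ in range(5)]
        res = get_periodicity(seqs, "WW")
        assert res.n_pairs == res.hist.sum()
        assert res.n_occurrences == sum(len(find_occurrences(s, "WW")) for s in seqs)


class TestPeriodicityTrack:
    def test_planted_cassette_located(self, write_fasta):
        r = np.random.default_rng(5)
        bg = random_dna(r, 1000, gc=0.6)
        cassette, _ = gen_periodic_sequences(n=1, length=300, seed=6)
        chrom = bg[:400] + cassette[0] + bg[700:]
        fasta = write_fasta({"chrT": chrom})
        track = periodicity_track(fasta, [GenomicInterval("chrT", 0, 1000)], "WW")
        pos = track.positions("chrT")
        best = pos[np.argmax(track.data["chrT"][1])]
        assert 400 <= best < 700

    def test_all_g_chromosome_scores_zero(self, write_fasta):
        fasta = write_fasta({"chrG": "G" * 400})
        track = periodicity_track(fasta, [GenomicInterval("chrG", 0, 400)], "WW")
        assert not track.data["chrG"][1].any()

    def test_window_step_arithmetic(self, write_fasta, rng):
        fasta = write_fasta({"chrT": random_dna(rng, 200)})
        track = periodicity_track(fasta, [GenomicInterval("chrT", 0, 200)],
                                  "WW", window=100, step=2)
        assert len(track.data["chrT"][1]) == 51
        assert track.data["chrT"][0] == 50  # first window center

    def test_region_shorter_than_window_warns(self, write_fasta, rng):
        fasta = write_fasta({"chrT": random_dna(rng, 50)})
        with pytest.warns(UserWarning, match="shorter than window"):
            track = periodicity_track(fasta, [GenomicInterval("chrT", 0, 50)], "WW")
        assert "chrT" not in track.data
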