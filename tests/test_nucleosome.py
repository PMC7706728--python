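"""Nucleosome calling, promoter metrics, occupancy binning and phasing."""

import numpy as np
import pytest

from conftest import random_dna
from promarch.core import GenomicInterval, PromoterRecord, SignalTrack
from promarch.nucleosome import (
    NucleosomeCall,
    architecture_metrics,
    call_nucleosomes,
    periodicity_by_occupancy_bins,
    phase_sequences,
    profile_psd_at_period,
)
from promarch.simulate import gen_coupled_nucleosome_set, gen_occupancy_track


def make_promoter(center=1000, fwd_off=30, rev_off=30):
    iv = GenomicInterval("chrS", center - 500, center + 500)
    return PromoterRecord(iv, center, tss_fwd_mode=center + fwd_off,
                          tss_rev_mode=center - rev_off)


class TestCallNucleosomes:
    def test_triangular_peak_and_d1_arithmetic(self):
        prom = make_promoter(center=1000, fwd_off=0, rev_off=10)
        tss_fwd = prom.tss_fwd_mode  # 1000
        values = np.zeros(2000)
        peak = tss_fwd + 95
        values[peak - 20 : peak + 21] = np.concatenate(
            [np.linspace(0, 1, 21), np.linspace(1, 0, 21)[1:]]
        )
        track = SignalTrack(step=1)
        track.add("chrS", 0, values)
        plus1, _ = call_nucleosomes(track, prom)
        assert plus1.dyad == peak
        assert plus1.edge5 == peak - 73
        assert plus1.edge5 - tss_fwd == 95 - 73 == 22

    def test_gaussian_bump_recovery_within_one_bp(self):
        """Dyads recovered within +/-1 bp over 100 seeded promoters."""
        rng = np.random.default_rng(12)
        n = 100
        centers = 2_000 + 2_000 * np.arange(n)
        dyads, proms = [], []
        for c in centers:
            fwd, rev = c + 30, c - 30
            d_plus = fwd + int(rng.integers(40, 161))
            d_minus = rev - int(rng.integers(40, 161))
            dyads += [d_plus, d_minus]
            proms.append(PromoterRecord(GenomicInterval("chrS", c - 500, c + 500), c,
                                        tss_fwd_mode=fwd, tss_rev_mode=rev))
        track, _ = gen_occupancy_track("chrS", int(centers[-1]) + 2_000, dyads,
                                       sigma=20.0, noise_sd=1e-3, seed=13)
        for i, prom in enumerate(proms):
            plus1, minus1 = call_nucleosomes(track, prom)
            assert abs(plus1.dyad - dyads[2 * i]) <= 1
            assert abs(minus1.dyad - dyads[2 * i + 1]) <= 1

    def test_flat_nonzero_ties_break_toward_tss(self):
        prom = make_promoter()
        track = SignalTrack(step=1)
        track.add("chrS", 0, np.ones(2000))
        plus1, minus1 = call_nucleosomes(track, prom)
        assert plus1.dyad == prom.tss_fwd_mode + 1  # first position past the mode
        assert minus1.dyad == prom.tss_rev_mode - 1

    def test_flat_zero_window_yields_no_call(self):
        prom = make_promoter()
        track = SignalTrack(step=1)
        track.add("chrS", 0, np.zeros(2000))
        with pytest.warns(UserWarning, match="flat-zero"):
            plus1, minus1 = call_nucleosomes(track, prom)
        assert plus1 is None and minus1 is None

    def test_requires_divergent_promoter(self):
        iv = GenomicInterval("chrS", 0, 2000)
        prom = PromoterRecord(iv, 1000, tss_fwd_mode=1030)
        track = SignalTrack(step=1)
        track.add("chrS", 0, np.ones(2000))
        with pytest.raises(ValueError, match="forward and reverse"):
            call_nucleosomes(track, prom)


class TestArchitectureMetrics:
    def test_hand_computed_case(self):
        # dyads at center +/- 95, TSS modes at center +/- 30
        prom = make_promoter(center=1000)
        plus1 = NucleosomeCall("chrS", 1095, 1.0, "plus1")
        minus1 = NucleosomeCall("chrS", 905, 1.0, "minus1")
        arch = architecture_metrics(prom, plus1, minus1)
        assert arch.d1 == (1095 - 73) - 1030 == -8
        assert arch.d2 == 60
        assert arch.w == (1095 - 73) - (905 + 73) == 44
        assert not arch.overlapping_calls

    def test_symmetric_promoter_mirror(self):
        # mirrored geometry gives the same metrics computed on the reverse axis
        prom = make_promoter(center=1000, fwd_off=25, rev_off=25)
        plus1 = NucleosomeCall("chrS", 1000 + 120, 1.0, "plus1")
        minus1 = NucleosomeCall("chrS", 1000 - 120, 1.0, "minus1")
        arch = architecture_metrics(prom, plus1, minus1)
        d1_rev = (prom.tss_rev_mode) - (minus1.dyad + 73)  # reverse-axis d1
        assert arch.d1 == d1_rev
        assert arch.w == 2 * ((120 - 73) + 25) - 2 * 25

    def test_overlapping_calls_flagged(self):
        prom = make_promoter()
        plus1 = NucleosomeCall("chrS", 1040, 1.0, "plus1")
        minus1 = NucleosomeCall("chrS", 960, 1.0, "minus1")
        with pytest.warns(UserWarning, match="overlap"):
            arch = architecture_metrics(prom, plus1, minus1)
        assert arch.w < 0 and arch.overlapping_calls

    def test_missing_call_gives_none(self):
        prom = make_promoter()
        assert architecture_metrics(prom, None, NucleosomeCall("chrS", 0, 1, "minus1")) is None


class TestOccupancyPeriodicityBins:
    def test_coupled_generator_positive_correlation(self):
        occ, seqs = gen_coupled_nucleosome_set(n=400, coupled=True, seed=20)
        _, _, r = periodicity_by_occupancy_bins(occ, seqs, "WW", bin_size=20)
        assert r > 0.5

    def test_shuffled_coupling_near_zero(self):
        # a single 20-bin null draw of r has sd ~ 1/sqrt(17); the median of
        # five independent draws is a stable check that the null sits near 0
        rs = []
        for seed in range(5):
            occ, seqs = gen_coupled_nucleosome_set(n=400, coupled=False, seed=seed)
            _, _, r = periodicity_by_occupancy_bins(occ, seqs, "WW", bin_size=20)
            rs.append(abs(r))
        assert np.median(rs) < 0.3

    def test_identical_sequences_flagged_undefined(self):
        seqs = ["ACGTACGTAC" * 20] * 40
        occ = np.linspace(0.2, 1, 40)
        with pytest.warns(UserWarning, match="zero variance"):
            _, _, r = periodicity_by_occupancy_bins(occ, seqs, "WW", bin_size=20)
        assert np.isnan(r)

    def test_too_few_calls_rejected(self):
        with pytest.raises(ValueError, match="at least 40"):
            periodicity_by_occupancy_bins([1.0] * 30, ["AT" * 100] * 30, bin_size=20)


class TestPhasing:
    def test_identical_sequences_all_lags_zero(self, rng):
        seq = random_dna(rng, 400)
        res = phase_sequences([seq] * 12, "TT", k=3, seed=0)
        assert not res.lags.any()
        np.testing.assert_array_equal(res.summed_profile, res.unshifted_profile)

    def test_k1_single_global_lag_zero(self, rng):
        seqs = [random_dna(rng, 400) for _ in range(8)]
        res = phase_sequences(seqs, "TT", k=1, seed=0)
        assert list(res.lags) == [0]

    def test_planted_circular_lags_recovered(self):
        """Shifted copies of one periodic template recover the planted lags."""
        rng = np.random.default_rng(21)
        template = list(random_dna(rng, 400, gc=0.6))
        for p in range(3, 396, 10):  # strong 10-bp TT comb
            template[p], template[p + 1] = "T", "T"
        template = "".join(template)
        planted = {-4: 6, -2: 7, 0: 10, 2: 7, 4: 6}  # unshifted cluster anchors
        seqs, truth = [], []
        for lag, count in planted.items():
            shifted = template[-lag:] + template[:-lag]  # circular shift by lag
            seqs += [shifted] * count
            truth += [lag] * count
        res = phase_sequences(seqs, "TT", k=5, max_lag=5, seed=0)
        recovered = -res.lags[res.labels]  # applied shift undoes the planted one
        np.testing.assert_array_equal(recovered, truth)

    def test_phasing_does_not_degrade_ten_bp_psd(self):
        rng = np.random.default_rng(22)
        template = list(random_dna(rng, 400, gc=0.6))
        for p in range(5, 396, 10):
            template[p], template[p + 1] = "T", "T"
        template = "".join(template)
        seqs = [template] * 10
        for lag in (-4, -2, 2, 4):
            seqs += [template[-lag:] + template[:-lag]] * 8
        res = phase_sequences(seqs, "TT", k=5, max_lag=5, seed=0)
        post = profile_psd_at_period(res.summed_profile, 10)
        pre = profile_psd_at_period(res.unshifted_profile, 10)
        assert post >= pre

    def test_input_validation(self):
        with pytest.raises(ValueError, match="share one length"):
            phase_sequences(["AAAA", "AAA"], "TT")
        with pytest.raises(ValueError, match="out of range"):
            phase_sequences(["AAAA"] * 3, "TT", k=5)
        with pytest.raises(ValueError, match="empty"):
            phase_sequences([], "TT")
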