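"""Enhancer calling: binarization, HMM segmentation, promoter filtering,
stitching, and signal quantification."""
import numpy as np
import pytest
from scipy import stats as sps

from sescape.enhancers import (
    binarize_track,
    call_enhancers,
    decode_enriched_regions,
    filter_promoter_proximal,
    quantify_region_signal,
    stitch_regions,
)
from sescape.hmm import fit_two_state_hmm, viterbi_path
from sescape.types import BinnedSignalTrack, GeneRecord, GenomicInterval

from conftest import balanced_accuracy


def make_track(counts, sample_id="s1", bin_size=200, total_mapped=None):
    counts = np.asarray(counts, dtype=np.int64)
    if total_mapped is None:
        total_mapped = int(counts.sum())
    return BinnedSignalTrack(sample_id, bin_size, {"chr1": counts}, total_mapped)


def poisson_min_flagged(lam, threshold):
    """Smallest count whose upper tail is below threshold, by pmf summation."""
    import math

    c = 0
    while True:
        tail = 1.0 - sum(
            np.exp(-lam) * lam**j / math.factorial(j) for j in range(c)
        )
        if tail < threshold:
            return c
        c += 1


class TestBinarize:
    def test_minimal_flagged_count_matches_pmf_oracle(self):
        """At background mean 2 the flagging threshold equals the smallest
        count whose Poisson upper tail drops below 1e-4."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=20_000)
        track = make_track(counts)
        lam = counts.mean()
        expected_min = poisson_min_flagged(lam, 1e-4)
        bits = binarize_track(track)["chr1"]
        flagged = counts[bits == 1]
        unflagged = counts[bits == 0]
        assert flagged.min() >= expected_min if flagged.size else True
        assert unflagged.max() < expected_min

    def test_uniform_counts_never_flagged(self):
        bits = binarize_track(make_track(np.full(500, 3)))["chr1"]
        assert bits.sum() == 0

    def test_zero_counts_never_flagged(self):
        counts = np.concatenate([np.zeros(100, dtype=int), np.full(5, 100)])
        bits = binarize_track(make_track(counts))["chr1"]
        assert np.all(bits[:100] == 0)

    def test_all_zero_track_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            bits = binarize_track(make_track(np.zeros(100, dtype=int)))
        assert bits["chr1"].sum() == 0


def sample_hmm_bits(n, p_enr=0.9, p_bg=0.02, stay=0.99, seed=0):
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=np.int8)
    states[0] = 0
    flips = rng.random(n) >= stay
    for t in range(1, n):
        states[t] = 1 - states[t - 1] if flips[t] else states[t - 1]
    p = np.where(states == 1, p_enr, p_bg)
    bits = (rng.random(n) < p).astype(np.int8)
    return bits, states


class TestHMM:
    def test_loglik_monotone_nondecreasing(self):
        bits, _ = sample_hmm_bits(5000, seed=2)
        params = fit_two_state_hmm(bits, seed=2)
        trace = np.array(params.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_parameter_recovery(self):
        """Emissions recovered within +/-0.05 on a 50k-bin simulation."""
        bits, _ = sample_hmm_bits(50_000, seed=7)
        params = fit_two_state_hmm(bits, seed=7)
        assert params.emission[1] == pytest.approx(0.9, abs=0.05)
        assert params.emission[0] == pytest.approx(0.02, abs=0.05)
        assert params.emission[1] > params.emission[0]  # canonical order

    def test_decoding_stable_across_initializations(self):
        bits, _ = sample_hmm_bits(20_000, seed=11)
        paths = [
            viterbi_path(bits, fit_two_state_hmm(bits, seed=s)) for s in (0, 1, 2)
        ]
        assert np.array_equal(paths[0], paths[1])
        assert np.array_equal(paths[1], paths[2])

    def test_degenerate_input_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            params = fit_two_state_hmm(np.zeros(200, dtype=np.int8))
        assert params.emission[1] >= params.emission[0]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            fit_two_state_hmm(np.zeros(50, dtype=np.int8))


class TestDecode:
    def test_all_background_gives_no_regions(self):
        bits, _ = sample_hmm_bits(2000, seed=3)
        params = fit_two_state_hmm(bits, seed=3)
        regions = decode_enriched_regions(
            {"chr1": np.zeros(500, dtype=np.int8)}, params, 200
        )
        assert regions == []

    def test_single_planted_run_recovered(self):
        bits = np.zeros(5000, dtype=np.int8)
        rng = np.random.default_rng(1)
        bits[rng.random(5000) < 0.01] = 0  # background stays clean
        bits[2000:2100] = (rng.random(100) < 0.9).astype(np.int8)
        params = fit_two_state_hmm(bits, seed=1)
        regions = decode_enriched_regions({"chr1": bits}, params, 200)
        assert len(regions) == 1
        r = regions[0]
        inter = min(r.end, 2100 * 200) - max(r.start, 2000 * 200)
        union = max(r.end, 2100 * 200) - min(r.start, 2000 * 200)
        assert inter / union >= 0.9
        assert r.start % 200 == 0 and r.end % 200 == 0


class TestPromoterFilter:
    GENES = [GeneRecord("g1", "chr1", 100_000, "+")]

    def test_one_bp_overlap_removes(self):
        tss = 100_000
        region = GenomicInterval("chr1", tss + 2499, tss + 3000)
        assert filter_promoter_proximal([region], self.GENES) == []

    def test_boundary_region_retained(self):
        tss = 100_000
        region = GenomicInterval("chr1", tss + 2500, tss + 3000)
        assert filter_promoter_proximal([region], self.GENES) == [region]

    def test_empty_annotation_passthrough(self):
        region = GenomicInterval("chr1", 0, 500)
        assert filter_promoter_proximal([region], []) == [region]

    def test_never_removes_distant_region(self):
        """Exhaustive sweep: only regions within the window are dropped."""
        genes = [GeneRecord("g1", "chr1", 50_000, "-")]
        for start in range(40_000, 60_000, 500):
            region = GenomicInterval("chr1", start, start + 400)
            kept = filter_promoter_proximal([region], genes)
            overlaps = start < 52_500 and 47_500 < start + 400
            assert (kept == []) == overlaps


class TestStitch:
    def test_gap_zero_keeps_disjoint(self):
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        assert stitch_regions(regions, 0) == regions

    def test_gap_bridges_exact_distance(self):
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        assert stitch_regions(regions, 100) == [GenomicInterval("chr1", 0, 300)]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in np.sort(rng.choice(np.arange(0, 50_000, 150), 80, replace=False))
        ]
        once = stitch_regions(regions, 120)
        assert stitch_regions(once, 120) == once


class TestQuantify:
    def test_uniform_density_arithmetic(self):
        # 1 read per 200-bp bin over 1400 bp = 7 reads; 1e6 mapped -> rpm = 7
        track = make_track(np.ones(100, dtype=int), total_mapped=1_000_000)
        rpm, density = quantify_region_signal(GenomicInterval("chr1", 0, 1400), track)
        assert rpm == pytest.approx(7.0)
        assert density == pytest.approx(0.005)

    def test_partial_bin_proportional(self):
        track = make_track([10, 0], total_mapped=1_000_000)
        rpm, _ = quantify_region_signal(GenomicInterval("chr1", 100, 200), track)
        assert rpm == pytest.approx(5.0)  # half of the first bin

    def test_empty_overlap_zero(self):
        track = make_track([0, 0, 5], total_mapped=1_000_000)
        rpm, density = quantify_region_signal(GenomicInterval("chr1", 0, 400), track)
        assert rpm == 0.0 and density == 0.0

    def test_doubling_library_halves_density(self):
        track1 = make_track(np.ones(50, dtype=int), total_mapped=1_000_000)
        track2 = make_track(np.ones(50, dtype=int), total_mapped=2_000_000)
        region = GenomicInterval("chr1", 0, 1000)
        _, d1 = quantify_region_signal(region, track1)
        _, d2 = quantify_region_signal(region, track2)
        assert d1 == pytest.approx(2 * d2)

    def test_zero_total_mapped_rejected(self):
        track = make_track(np.ones(10, dtype=int), total_mapped=0)
        with pytest.raises(ValueError, match="total_mapped"):
            quantify_region_signal(GenomicInterval("chr1", 0, 200), track)


class TestEndToEnd:
    def test_recovers_planted_enriched_bins(self, small_cohort):
        """Per-bin balanced accuracy vs planted enrichment >= 0.95 and
        >= 90% of planted enriched bp recovered."""
        annotation, tracks, truth = small_cohort
        bs = truth.bin_size
        sid = "A01"
        regions, _ = call_enhancers(tracks[sid], annotation, seed=0)
        n_bins = len(tracks[sid].counts["chr1"])
        truth_mask = np.zeros(n_bins, dtype=bool)
        for iv in truth.enriched_intervals("A"):
            truth_mask[iv.start // bs : iv.end // bs] = True
        called_mask = np.zeros(n_bins, dtype=bool)
        for r in regions:
            called_mask[r.interval.start // bs : r.interval.end // bs] = True
        # promoter-filtered truth is unchanged: planted loci avoid promoters
        assert balanced_accuracy(truth_mask, called_mask) >= 0.95
        recovered = (truth_mask & called_mask).sum() / truth_mask.sum()
        assert recovered >= 0.90
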