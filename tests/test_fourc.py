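"""4C computation: digestion, counting, masking, RPM smoothing, subtraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crmkit import fourc, simulate


def brute_force_cut_starts(genome: str, motif: str) -> list[int]:
    """Independent oracle: every motif occurrence start by direct slicing."""
    w = len(motif)
    return [i for i in range(len(genome) - w + 1) if genome[i : i + w] == motif]


class TestDigest:
    def test_motif_free_genome_is_one_invalid_fragment(self):
        lib = fourc.digest("AAAA")
        (frag,) = lib.fragments["chr"]
        assert (frag.start, frag.end) == (0, 4)
        assert not frag.has_secondary_site and not frag.valid

    def test_worked_example_boundaries_and_validity(self):
        # GATC at 2 and 12; the middle fragment holds CATG but is 10 bp < 20
        lib = fourc.digest("AAGATCCATGAAGATCAA")
        frags = lib.fragments["chr"]
        assert [(f.start, f.end) for f in frags] == [(0, 2), (2, 12), (12, 18)]
        assert [f.has_secondary_site for f in frags] == [False, True, False]
        assert all(not f.valid for f in frags)

    @given(st.integers(0, 2**31 - 1))
    def test_boundaries_match_brute_force_and_tile_genome(self, seed):
        genome = simulate.make_genome(2_000, 0.5, seed=seed)
        lib = fourc.digest(genome)
        frags = lib.fragments["chr"]
        cuts = brute_force_cut_starts(genome, "GATC")
        expected = sorted({0} | {c for c in cuts}) + [len(genome)]
        observed = [f.start for f in frags] + [frags[-1].end]
        assert observed == expected
        assert sum(f.length for f in frags) == len(genome)
        # tiling: each fragment starts where the previous ended
        assert all(a.end == b.start for a, b in zip(frags, frags[1:]))

    def test_validity_monotone_in_min_length(self, small_genome):
        short = fourc.digest(small_genome, min_length=10)
        long = fourc.digest(small_genome, min_length=40)
        for f_short, f_long in zip(short.fragments["chr"], long.fragments["chr"]):
            if f_long.valid:
                assert f_short.valid

    def test_ambiguous_motif_rejected(self):
        with pytest.raises(ValueError):
            fourc.digest("ACGT", primary_motif="GATN")


class TestFilterPrimerReads:
    def test_matching_prefix_kept_and_trimmed(self):
        kept, nd, ns = fourc.filter_primer_reads([("r", "ACGTTTTT")], "ACGT")
        assert kept == [("r", "TTTT")] and nd == 0 and ns == 0

    def test_mismatch_discarded(self):
        kept, nd, ns = fourc.filter_primer_reads([("r", "AGGTTTTT")], "ACGT")
        assert kept == [] and nd == 1

    def test_short_read_counted_separately(self):
        kept, nd, ns = fourc.filter_primer_reads([("r", "AC")], "ACGT")
        assert kept == [] and nd == 0 and ns == 1

    def test_max_mismatch_tolerance(self):
        kept, nd, _ = fourc.filter_primer_reads([("r", "AGGTTTTT")], "ACGT", max_mismatch=1)
        assert kept == [("r", "TTTT")]


class TestAssignReads:
    def test_read_at_valid_fragment_start_counts(self, small_genome):
        genome = {"chr": small_genome}
        lib = fourc.digest(genome)
        frag = next(f for f in lib.fragments["chr"] if f.valid)
        read = small_genome[frag.start : frag.start + 25]
        counts, n_un, n_amb = fourc.assign_reads([("r", read)], genome, lib, "chr")
        assert counts[frag.index] == 1 and n_un == 0 and n_amb == 0

    def test_read_from_invalid_fragment_unassigned(self, small_genome):
        genome = {"chr": small_genome}
        lib = fourc.digest(genome)
        frag = next(f for f in lib.fragments["chr"] if not f.valid and f.length >= 25)
        read = small_genome[frag.start : frag.start + 25]
        counts, n_un, _ = fourc.assign_reads([("r", read)], genome, lib, "chr")
        assert counts.sum() == 0 and n_un == 1

    def test_simulated_counts_reproduce_ground_truth_exactly(self, small_genome):
        genome = {"chr": small_genome}
        lib = fourc.digest(genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=500)
        reads, truth = simulate.simulate_4c_reads(lib, genome, vp, 1.0, 2_000, seed=8)
        kept, _, _ = fourc.filter_primer_reads(reads, vp.primer)
        counts, n_un, n_amb = fourc.assign_reads(kept, genome, lib, "chr")
        assert n_un == 0 and n_amb == 0
        assert counts.sum() == 2_000
        assert set(np.flatnonzero(counts)) <= set(truth.fragment_capture_probs)


class TestInformativeMask:
    def test_zero_radius_excludes_viewpoint_and_neighbours_only(self, small_genome):
        lib = fourc.digest(small_genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=0)
        mask = fourc.informative_mask(lib, vp)
        vp_frag = lib.fragment_at("chr", 15_000)
        valid = np.array([f.valid for f in lib.fragments["chr"]])
        excluded = np.flatnonzero(valid & ~mask)
        assert set(excluded) <= {vp_frag.index - 1, vp_frag.index, vp_frag.index + 1}

    def test_radius_excludes_every_overlapping_fragment(self, small_genome):
        lib = fourc.digest(small_genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=10_000)
        mask = fourc.informative_mask(lib, vp)
        for f in lib.fragments["chr"]:
            if f.start < 25_000 and f.end > 5_000:
                assert not mask[f.index]

    def test_analysis_interval_restricts_mask(self, small_genome):
        lib = fourc.digest(small_genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG",
                                 exclusion_radius=500,
                                 analysis_interval=("chr", 10_000, 20_000))
        mask = fourc.informative_mask(lib, vp)
        for f in lib.fragments["chr"]:
            if mask[f.index]:
                assert f.end > 10_000 and f.start < 20_000

    def test_all_invalid_raises(self):
        lib = fourc.digest("A" * 50 + "GATC" + "A" * 50)  # no fragment has a CATG
        vp = fourc.ViewpointSpec("chr", 20, "ACGTACGTACGTACG", exclusion_radius=0)
        with pytest.raises(ValueError):
            fourc.informative_mask(lib, vp)


def _profile_with_counts(small_genome, counts_map, window=5):
    lib = fourc.digest(small_genome)
    vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=500)
    mask = fourc.informative_mask(lib, vp)
    counts = np.zeros(len(lib.fragments["chr"]), dtype=np.int64)
    idx = np.flatnonzero(mask)
    for rel, c in counts_map.items():
        counts[idx[rel]] = c
    profile = fourc.ViewpointProfile(lib, vp, counts, mask, window_width=window)
    profile.rpm = fourc.smooth_rpm(profile)
    return profile, idx


class TestSmoothRpm:
    def test_constant_counts_give_constant_rpm(self, small_genome):
        lib = fourc.digest(small_genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=500)
        mask = fourc.informative_mask(lib, vp)
        counts = np.where(mask, 3, 0)
        profile = fourc.ViewpointProfile(lib, vp, counts, mask, window_width=5)
        rpm = fourc.smooth_rpm(profile)
        total = counts[mask].sum()
        assert np.allclose(rpm[mask], 3 * 1e6 / total)

    def test_isolated_spike_window_mean(self, small_genome):
        # counts [0,0,10,0,0] in a width-5 window, total 10 -> centre 2e6/10
        profile, idx = _profile_with_counts(small_genome, {10: 10}, window=5)
        assert profile.rpm[idx[10]] == pytest.approx(2 * 1e6 / 10)

    def test_window_one_is_identity_scaling(self, small_genome):
        profile, idx = _profile_with_counts(small_genome, {4: 7, 9: 3}, window=1)
        assert profile.rpm[idx[4]] == pytest.approx(7 * 1e6 / 10)
        assert profile.rpm[idx[9]] == pytest.approx(3 * 1e6 / 10)

    def test_even_window_rejected(self, small_genome):
        profile, _ = _profile_with_counts(small_genome, {4: 1})
        with pytest.raises(ValueError):
            fourc.smooth_rpm(profile, 4)

    def test_zero_total_rejected(self, small_genome):
        lib = fourc.digest(small_genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=500)
        mask = fourc.informative_mask(lib, vp)
        profile = fourc.ViewpointProfile(lib, vp, np.zeros(len(mask), dtype=int), mask)
        with pytest.raises(ValueError):
            fourc.smooth_rpm(profile)


class TestSubtractProfiles:
    def test_self_subtraction_is_exactly_zero(self, small_genome):
        profile, _ = _profile_with_counts(small_genome, {3: 5, 8: 2})
        diff = fourc.subtract_profiles(profile, profile)
        assert np.all(diff[profile.informative] == 0.0)

    def test_antisymmetry(self, small_genome):
        a, _ = _profile_with_counts(small_genome, {3: 5, 8: 2})
        b, _ = _profile_with_counts(small_genome, {3: 1, 12: 9})
        ab = fourc.subtract_profiles(a, b)
        ba = fourc.subtract_profiles(b, a)
        m = a.informative
        assert np.allclose(ab[m], -ba[m])

    def test_doubled_capture_yields_largest_positive_difference(self, small_genome):
        genome = {"chr": small_genome}
        lib = fourc.digest(genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=500)
        idx, probs = simulate.capture_probabilities(lib, vp, 1.0)
        boosted = probs.copy()
        target_rel = len(idx) // 3
        boosted[target_rel] *= 8
        boosted /= boosted.sum()
        rng = np.random.default_rng(0)
        n = 200_000
        counts_a = np.zeros(len(lib.fragments["chr"]), dtype=np.int64)
        counts_b = np.zeros_like(counts_a)
        np.add.at(counts_b, idx[rng.choice(len(idx), n, p=probs)], 1)
        np.add.at(counts_a, idx[rng.choice(len(idx), n, p=boosted)], 1)
        pa = fourc.count_profile(counts_a, lib, vp, 1)
        pb = fourc.count_profile(counts_b, lib, vp, 1)
        diff = fourc.subtract_profiles(pa, pb)
        assert np.nanargmax(diff) == idx[target_rel]

    def test_mismatched_masks_rejected(self, small_genome):
        a, _ = _profile_with_counts(small_genome, {3: 5})
        lib = fourc.digest(small_genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=2_000)
        mask = fourc.informative_mask(lib, vp)
        counts = np.where(mask, 1, 0)
        b = fourc.ViewpointProfile(lib, vp, counts, mask)
        b.rpm = fourc.smooth_rpm(b)
        with pytest.raises(ValueError):
            fourc.subtract_profiles(a, b)


class TestAtacRpkm:
    def test_four_ends_in_one_bin(self):
        # 2 fragments, all 4 ends in bin 0 -> RPKM = 4/(4*10)*1e9
        track = fourc.atac_rpkm([(0, 5), (2, 9)], bin_size=10)
        assert track.rpkm[0] == pytest.approx(4 / (4 * 10) * 1e9)

    def test_uniform_ends_give_equal_rpkm(self):
        frags = [(10 * i, 10 * i + 10) for i in range(8)]
        track = fourc.atac_rpkm(frags, bin_size=10)
        assert np.allclose(track.rpkm, track.rpkm[0])

    def test_rpkm_invariant_under_count_doubling(self):
        frags = [(0, 15), (20, 44), (31, 59)]
        once = fourc.atac_rpkm(frags, bin_size=10)
        twice = fourc.atac_rpkm(frags * 2, bin_size=10)
        assert np.allclose(once.rpkm, twice.rpkm)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fourc.atac_rpkm([], bin_size=10)


class TestEndToEndRecovery:
    def test_rpm_rank_correlates_with_capture_probability(self, small_genome):
        from scipy.stats import spearmanr

        genome = {"chr": small_genome}
        lib = fourc.digest(genome)
        vp = fourc.ViewpointSpec("chr", 15_000, "ACGTACGTACGTACG", exclusion_radius=1_000)
        reads, truth = simulate.simulate_4c_reads(lib, genome, vp, 1.0, 100_000, seed=13)
        kept, _, _ = fourc.filter_primer_reads(reads, vp.primer)
        counts, _, _ = fourc.assign_reads(kept, genome, lib, "chr")
        profile = fourc.count_profile(counts, lib, vp, 5)
        idx = sorted(truth.fragment_capture_probs)
        probs = [truth.fragment_capture_probs[i] for i in idx]
        rho = spearmanr(profile.rpm[idx], probs).statistic
        assert rho > 0.9
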