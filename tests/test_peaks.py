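"""Peak filtering, greedy window binning, abundance filter, consensus."""

from itertools import combinations

import numpy as np
import pytest

import trflpkit as tk

from conftest import make_binned, make_profile


def oracle_bins(peaks, window):
    """Exhaustive-partition oracle for window binning.

    Enumerates every set partition of the peaks and keeps the unique one
    in which, walking the blocks in order of decreasing seed area (seed =
    max-area member, ties to smaller size), each block contains exactly
    the not-yet-binned peaks within ``window`` of its seed.
    """
    idx = list(range(len(peaks)))

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    def seed(block):
        return min(block, key=lambda i: (-peaks[i][1], peaks[i][0]))

    valid = []
    for part in partitions(idx):
        blocks = sorted(part, key=lambda b: (-peaks[seed(b)][1],
                                             peaks[seed(b)][0]))
        remaining = set(idx)
        ok = True
        for block in blocks:
            s = peaks[seed(block)][0]
            expected = {i for i in remaining
                        if abs(peaks[i][0] - s) <= window}
            if set(block) != expected:
                ok = False
                break
            remaining -= expected
        if ok:
            valid.append(part)
    assert len(valid) == 1, "oracle partition must be unique"
    return sorted((peaks[seed(b)][0], sum(peaks[i][1] for i in b))
                  for b in valid[0])


class TestQCDynamicRange:
    @pytest.mark.parametrize("height,verdict", [
        (5000.0, "pass"), (1999.0, "rerun"), (8000.0, "pass"),
        (2000.0, "pass"), (8000.5, "rerun"),
    ])
    def test_verdicts(self, height, verdict):
        prof = make_profile([(100.0, height, height, "HEX"),
                             (200.0, 100.0, 100.0, "HEX")])
        assert tk.qc_dynamic_range(prof) == verdict

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            tk.qc_dynamic_range(tk.PeakProfile("s", []))


class TestFilterPeaks:
    def test_size_bounds_inclusive(self):
        prof = make_profile([(s, 100.0, 100.0, "HEX")
                             for s in (30.0, 49.9, 50.0, 600.0, 601.0)])
        kept = tk.filter_peaks(prof)
        assert [p.size_bp for p in kept.peaks] == [50.0, 600.0]

    def test_amplitude_threshold_is_a_floor(self):
        prof = make_profile([(100.0, 49.0, 500.0, "HEX"),
                             (110.0, 50.0, 500.0, "HEX")])
        kept = tk.filter_peaks(prof)
        assert [p.height_rfu for p in kept.peaks] == [50.0]

    def test_empty_in_empty_out(self):
        assert len(tk.filter_peaks(tk.PeakProfile("s", []))) == 0


class TestBinPeaks:
    def test_three_peak_example(self):
        prof = make_profile([(100.0, 500.0, 500.0, "HEX"),
                             (101.0, 300.0, 300.0, "HEX"),
                             (102.5, 200.0, 200.0, "HEX")])
        bins = tk.bin_peaks(prof).bins
        assert list(zip(bins["size_bp"], bins["area"])) == [(100.0, 800.0),
                                                            (102.5, 200.0)]

    def test_single_peak_identity(self):
        prof = make_profile([(150.0, 400.0, 400.0, "HEX")])
        bins = tk.bin_peaks(prof).bins
        assert bins.loc[0, "size_bp"] == 150.0 and bins.loc[0, "area"] == 400.0

    def test_gap_beyond_window_splits(self):
        prof = make_profile([(100.0, 10.0, 10.0, "HEX"),
                             (101.3, 10.0, 10.0, "HEX")])
        assert len(tk.bin_peaks(prof).bins) == 2

    def test_dyes_binned_independently(self):
        prof = make_profile([(100.0, 10.0, 10.0, "HEX"),
                             (100.5, 10.0, 10.0, "FAM")])
        assert len(tk.bin_peaks(prof).bins) == 2

    def test_agrees_with_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            sizes = np.round(rng.uniform(50, 56, size=n), 2)
            areas = np.round(rng.uniform(1, 1000, size=n), 1)
            prof = make_profile([(s, a, a, "HEX")
                                 for s, a in zip(sizes, areas)])
            bins = tk.bin_peaks(prof).bins
            got = sorted(zip(bins["size_bp"], bins["area"]))
            want = oracle_bins(list(zip(sizes, areas)), 1.2)
            np.testing.assert_allclose(np.array(got), np.array(want),
                                       atol=1e-9)

    def test_idempotent_on_binned_output(self):
        rng = np.random.default_rng(37)
        prof = make_profile([(s, a, a, "HEX") for s, a in
                             zip(rng.uniform(50, 70, 20),
                                 rng.uniform(1, 100, 20))])
        once = tk.bin_peaks(prof)
        again = tk.bin_peaks(make_profile(
            [(r.size_bp, r.area, r.area, r.dye)
             for r in once.bins.itertuples()]))
        assert np.allclose(once.bins["size_bp"], again.bins["size_bp"])
        assert np.allclose(once.bins["area"], again.bins["area"])

    def test_area_conservation_before_abundance_filter(self):
        rng = np.random.default_rng(41)
        prof = make_profile([(s, a, a, "HEX") for s, a in
                             zip(rng.uniform(50, 600, 50),
                                 rng.uniform(1, 100, 50))])
        binned = tk.bin_peaks(prof)
        assert binned.bins["area"].sum() == pytest.approx(
            sum(p.area for p in prof.peaks))

    def test_representatives_separated_beyond_window(self):
        rng = np.random.default_rng(43)
        prof = make_profile([(s, a, a, "HEX") for s, a in
                             zip(rng.uniform(50, 60, 40),
                                 rng.uniform(1, 100, 40))])
        reps = tk.bin_peaks(prof).bins["size_bp"].to_numpy()
        assert (np.diff(np.sort(reps)) > 1.2).all()


class TestAbundanceFilter:
    def test_one_percent_exactly_is_kept(self):
        binned = make_binned([("HEX", 100.0, 990.0), ("HEX", 200.0, 10.0)])
        out = tk.abundance_filter(binned)
        assert list(out.bins["rel_abundance"]) == pytest.approx([0.99, 0.01])

    def test_below_one_percent_removed_and_renormalized(self):
        binned = make_binned([("HEX", 100.0, 995.0), ("HEX", 200.0, 5.0)])
        out = tk.abundance_filter(binned)
        assert len(out.bins) == 1
        assert out.bins.loc[0, "rel_abundance"] == pytest.approx(1.0)

    def test_all_above_threshold_kept(self):
        binned = make_binned([("HEX", 100.0, 400.0), ("HEX", 200.0, 300.0),
                              ("HEX", 300.0, 300.0)])
        out = tk.abundance_filter(binned)
        assert list(out.bins["rel_abundance"]) == pytest.approx([0.4, 0.3, 0.3])

    def test_everything_filtered_is_an_error(self):
        binned = make_binned([("HEX", 100.0 + i, 1.0) for i in
                              np.arange(0, 300, 2.0)])
        with pytest.raises(ValueError, match="empty profile"):
            tk.abundance_filter(binned, min_fraction=0.5)

    def test_abundances_sum_to_one(self):
        rng = np.random.default_rng(47)
        binned = make_binned([("HEX", s, a) for s, a in
                              zip(np.arange(50, 250, 2.0),
                                  rng.uniform(0.1, 100, 100))])
        out = tk.abundance_filter(binned)
        assert out.bins["rel_abundance"].sum() == pytest.approx(1.0, abs=1e-12)


class TestConsensusProfile:
    def test_identical_replicates_idempotent(self):
        reps = [make_binned([("HEX", 100.0, 60.0), ("HEX", 105.0, 40.0)])
                for _ in range(3)]
        out = tk.consensus_profile(reps)
        assert list(out.bins["size_bp"]) == [100.0, 105.0]
        assert list(out.bins["area"]) == pytest.approx([60.0, 40.0])

    def test_single_replicate_identity(self):
        rep = make_binned([("FAM", 88.0, 10.0)])
        out = tk.consensus_profile([rep])
        assert out.bins[["dye", "size_bp", "area"]].equals(
            rep.bins[["dye", "size_bp", "area"]])

    def test_jittered_replicates_merge_to_one_bin(self):
        reps = [make_binned([("HEX", s, 30.0)]) for s in (100.0, 100.4, 100.8)]
        out = tk.consensus_profile(reps, match_window=1.2)
        assert len(out.bins) == 1
        assert out.bins.loc[0, "area"] == pytest.approx(30.0)

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            tk.consensus_profile([])


def test_noiseless_profile_recovers_truth_abundances(base_community,
                                                     noiseless_chain):
    """Noiseless chain: each dye channel's relative abundances equal the
    ground truth exactly."""
    _, binned = noiseless_chain
    truth = np.sort(base_community.abundances)
    for dye in (tk.HEX, tk.FAM):
        np.testing.assert_allclose(np.sort(binned.abundances(dye)), truth,
                                   atol=1e-12)
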