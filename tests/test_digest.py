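"""In-silico digestion: site scanning, T-RF prediction, RFLP typing."""

import numpy as np
import pandas as pd
import pytest
from Bio.Restriction import HinfI
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

import trflpkit as tk
from trflpkit.digest import IUPAC, UNASSIGNED

from conftest import make_binned

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def naive_sites(bases, motif="GANTC"):
    """Positional scan against IUPAC classes — the reference scanner."""
    hits = []
    for p in range(len(bases) - len(motif) + 1):
        if all(bases[p + k] in IUPAC[c] for k, c in enumerate(motif)):
            hits.append(p)
    return hits


def random_seq(rng, length=800):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestFindSites:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAGACTCTTTT", [3]),
        ("GACTCGACTC", [0, 5]),
        ("AAAATTTTCCCC", []),
    ])
    def test_examples(self, seq, expected):
        assert tk.find_sites(seq) == expected

    def test_overlapping_matches_reported(self):
        # GAGTC starting at 0 and GACTC? craft overlap: GAGTC at 0, GTCAC no.
        # GANTC overlapping itself needs G at offset<5; "GAGTCGAGTC" adjacent
        assert tk.find_sites("GAGTCAGTC") == [0]

    def test_agrees_with_naive_scanner_and_biopython(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = random_seq(rng)
            sites = tk.find_sites(s)
            assert sites == naive_sites(s)
            # Biopython reports 1-based cut boundaries = start + cut + 1
            assert [p + 2 for p in sites] == HinfI.search(Seq(s))

    def test_bad_cut_offset(self):
        with pytest.raises(ValueError):
            tk.find_sites("ACGT", cut_offset=9)


class TestPredictTRF:
    def test_manual_example(self):
        p = tk.predict_trf(tk.AmpliconSequence("x", "AAAGACTCTTTT"))
        assert (p.forward_trf_bp, p.reverse_trf_bp) == (4, 5)

    def test_uncut_returns_full_length(self):
        p = tk.predict_trf(tk.AmpliconSequence("x", "A" * 120))
        assert (p.forward_trf_bp, p.reverse_trf_bp) == (120, 120)

    def test_dye_offsets_shift_apparent_sizes(self):
        seq = tk.AmpliconSequence("x", "AAAGACTCTTTT")
        p = tk.predict_trf(seq, dye_offsets=(1.0, -1.0))
        assert (p.forward_trf_bp, p.reverse_trf_bp) == (5, 4)
        assert (p.forward_length, p.reverse_length) == (4, 5)

    def test_strand_consistency(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            s = random_seq(rng, 300)
            fwd = tk.predict_trf(tk.AmpliconSequence("a", s))
            rev = tk.predict_trf(
                tk.AmpliconSequence("b", tk.reverse_complement(s)))
            assert fwd.forward_trf_bp == rev.reverse_trf_bp
            assert fwd.reverse_trf_bp == rev.forward_trf_bp


class TestRFLPPattern:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAGACTCTTTT", (4, 8)),
        ("A" * 800, (800,)),
        ("AAA" + "GACTC" + "GATTC", (4, 4, 5)),  # cuts at 4 and 9, length 13
    ])
    def test_examples(self, seq, expected):
        assert tk.rflp_pattern(tk.AmpliconSequence("x", seq)) == expected

    def test_fragments_sum_to_length(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = random_seq(rng, int(rng.integers(5, 400)))
            assert sum(tk.rflp_pattern(tk.AmpliconSequence("x", s))) == len(s)

    @settings(derandomize=True, max_examples=200)
    @given(dna)
    def test_length_conservation_property(self, s):
        seq = tk.AmpliconSequence("x", s)
        pattern = tk.rflp_pattern(seq)
        assert sum(pattern) == len(s)
        assert pattern == tuple(sorted(pattern))
        pred = tk.predict_trf(seq)
        assert 0 < pred.forward_trf_bp <= len(s)
        assert 0 < pred.reverse_trf_bp <= len(s)


class TestClusterPatterns:
    def test_identical_patterns_one_otu(self):
        out = tk.cluster_patterns([(100, 700), (100, 700), (100, 700)])
        assert out["otu_id"].nunique() == 1
        assert (out["otu_size"] == 3).all()

    def test_within_tolerance_merge(self):
        out = tk.cluster_patterns([(100, 700), (101, 699)], fragment_tolerance=2)
        assert out["otu_id"].nunique() == 1

    def test_different_cardinality_never_merges(self):
        out = tk.cluster_patterns([(100, 700), (100, 300, 400)],
                                  fragment_tolerance=1000)
        assert out["otu_id"].nunique() == 2

    def test_tolerance_zero_is_equality_partitioning(self):
        rng = np.random.default_rng(23)
        pats = [tuple(sorted(rng.integers(50, 60, size=rng.integers(1, 4))))
                for _ in range(10)]
        out = tk.cluster_patterns(pats, fragment_tolerance=0)
        # brute force: same OTU <=> equal pattern
        for i in range(len(pats)):
            for j in range(len(pats)):
                same = out["otu_id"].iloc[i] == out["otu_id"].iloc[j]
                assert same == (pats[i] == pats[j])


class TestAssignTRFs:
    preds = [tk.PredictedTRF("P1", 150.0, 400.0),
             tk.PredictedTRF("P2", 310.0, 520.0)]

    def test_within_tolerance_matched(self):
        binned = make_binned([("HEX", 151.4, 100.0)])
        out = tk.assign_trfs(binned, self.preds, tolerance=2.0)
        assert out.loc[0, "assigned_to"] == "P1"
        assert out.loc[0, "delta_bp"] == pytest.approx(1.4)

    def test_boundary_two_point_zero_matched(self):
        binned = make_binned([("HEX", 152.0, 100.0)])
        out = tk.assign_trfs(binned, self.preds, tolerance=2.0)
        assert out.loc[0, "assigned_to"] == "P1"

    def test_beyond_tolerance_unassigned(self):
        binned = make_binned([("HEX", 152.5, 100.0)])
        out = tk.assign_trfs(binned, self.preds, tolerance=2.0)
        assert out.loc[0, "assigned_to"] == UNASSIGNED

    def test_shared_trf_pair_pooled(self):
        preds = [tk.PredictedTRF("P1", 150.0, 400.0),
                 tk.PredictedTRF("P2", 150.0, 400.0)]
        binned = make_binned([("HEX", 150.0, 60.0), ("FAM", 400.0, 60.0)])
        out = tk.assign_trfs(binned, preds, tolerance=2.0)
        assert set(out["assigned_to"]) == {"P1+P2"}

    def test_equidistant_tie_goes_to_smaller_size(self):
        preds = [tk.PredictedTRF("Plo", 149.0, 400.0),
                 tk.PredictedTRF("Phi", 153.0, 500.0)]
        binned = make_binned([("HEX", 151.0, 100.0)])
        out = tk.assign_trfs(binned, preds, tolerance=2.0)
        assert out.loc[0, "assigned_to"] == "Plo"

    def test_require_both_dyes_demotes_half_matches(self):
        binned = make_binned([("HEX", 150.0, 50.0), ("HEX", 310.0, 50.0),
                              ("FAM", 400.0, 50.0)])
        loose = tk.assign_trfs(binned, self.preds, require_both_dyes=False)
        strict = tk.assign_trfs(binned, self.preds, require_both_dyes=True)
        assert tk.phylotypes_present(loose) == {"P1", "P2"}
        assert tk.phylotypes_present(strict) == {"P1"}

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            tk.assign_trfs(make_binned([("HEX", 150.0, 1.0)]), [])


def test_noiseless_assignment_recovers_ground_truth(base_community,
                                                    noiseless_chain):
    """With zero noise and well-separated T-RFs, assignment finds every
    phylotype and the exact abundances."""
    _, binned = noiseless_chain
    out = tk.assign_trfs(binned, base_community.predicted_trfs(), tolerance=2.0)
    assert tk.phylotypes_present(out) == set(base_community.phylotype_ids)
    assert (out["assigned_to"] != UNASSIGNED).all()
    est = tk.estimate_abundances(out)
    np.testing.assert_allclose(
        est.reindex(base_community.phylotype_ids).to_numpy(),
        base_community.abundances, atol=1e-12)
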