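import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeval.distances import (
    barcoding_gap,
    group_distance_summary,
    k2p_distance,
    pairwise_matrix,
    write_phylip,
    DistanceMatrix,
)
from barcodeval.errors import (
    AlignmentError,
    DistanceError,
    GapUndefinedError,
)

from conftest import make_aln, two_species_aln

BASES = "ACGT"


def _brute_k2p(s1, s2, min_overlap=50):
    """Independent per-pair oracle: explicit column loop, no numpy."""
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a in BASES and b in BASES:
            n += 1
            if a != b:
                if (a, b) in ts_pairs:
                    ts += 1
                else:
                    tv += 1
    if n < min_overlap:
        return math.nan, False
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return math.nan, False
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q), True


class TestK2PDistance:
    def test_closed_form_p01_q005(self):
        # 100 sites, 10 transitions, 5 transversions
        s1 = "A" * 100
        s2 = "A" * 85 + "G" * 10 + "C" * 5
        d, ok = k2p_distance(s1, s2)
        assert ok
        assert d == pytest.approx(-0.5 * math.log(0.75) - 0.25 * math.log(0.9))
        assert d == pytest.approx(0.170181, abs=1e-6)

    def test_single_transition(self):
        d, ok = k2p_distance("AAAA", "AAAG", min_overlap=1)
        assert ok
        assert d == pytest.approx(-0.5 * math.log(0.5))
        assert d == pytest.approx(0.346574, abs=1e-6)

    def test_identical_zero(self):
        d, ok = k2p_distance("ACGT" * 20, "ACGT" * 20)
        assert ok and d == 0.0

    def test_saturation_invalid(self):
        # P = 0.5, Q = 0 -> log argument hits zero
        d, ok = k2p_distance("AG" * 50, "GA" * 50)
        assert not ok

    def test_min_overlap(self):
        _, ok = k2p_distance("ACGT", "ACGT", min_overlap=5)
        assert not ok
        _, ok = k2p_distance("ACGT", "ACGT", min_overlap=4)
        assert ok

    def test_pairwise_deletion(self):
        # gap/N columns ignored on either side
        d1 = k2p_distance("AAN-AAAG", "AAAAAA-C", min_overlap=1)
        d2 = k2p_distance("AAAAG", "AAAAC", min_overlap=1)
        assert d1[0] == pytest.approx(d2[0])

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            k2p_distance("ACGT", "ACG")

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_random(self, seed):
        rng = np.random.default_rng(seed)
        s1 = "".join(rng.choice(list("ACGTN-"), 80))
        s2 = "".join(rng.choice(list("ACGTN-"), 80))
        d_ab, ok_ab = k2p_distance(s1, s2, 10)
        d_ba, ok_ba = k2p_distance(s2, s1, 10)
        assert ok_ab == ok_ba
        if ok_ab:
            assert d_ab == d_ba

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s1 = "".join(rng.choice(list("ACGTN-"), 120))
            s2 = "".join(rng.choice(list("ACGTN-"), 120))
            d, ok = k2p_distance(s1, s2, 30)
            db, okb = _brute_k2p(s1, s2, 30)
            assert ok == okb
            if ok:
                assert d == pytest.approx(db)


class TestPairwiseMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = two_species_aln("ACGT" * 20, "ACGT" * 20)
        dm = pairwise_matrix(aln)
        assert np.all(dm.d == 0.0)
        assert np.all(dm.valid)

    def test_symmetry_and_oracle(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGTN-"), 100))
            for i in range(6)
        }
        species = {f"s{i}": f"sp{i % 2}" for i in range(6)}
        aln = make_aln(seqs, species)
        dm = pairwise_matrix(aln, min_overlap=20)
        assert np.allclose(dm.d, dm.d.T)
        for i, a in enumerate(dm.sample_ids):
            for j, b in enumerate(dm.sample_ids):
                if i >= j:
                    continue
                d, ok = _brute_k2p(seqs[a], seqs[b], 20)
                assert bool(dm.valid[i, j]) == ok
                if ok:
                    assert dm.d[i, j] == pytest.approx(d)

    def test_diagonal(self):
        aln = two_species_aln("ACGT" * 20, "AGGT" * 20)
        dm = pairwise_matrix(aln)
        assert np.all(np.diag(dm.d) == 0.0)
        assert np.all(np.diag(dm.valid))

    def test_phylip_output(self, tmp_path):
        aln = two_species_aln("ACGT" * 20, "AGGT" * 20)
        dm = pairwise_matrix(aln)
        path = tmp_path / "dm.phy"
        write_phylip(dm, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "4"
        assert len(lines) == 5


def _dm_from_values(ids, values):
    """Build a DistanceMatrix from {(a, b): distance}."""
    n = len(ids)
    d = np.zeros((n, n))
    valid = np.ones((n, n), dtype=bool)
    for (a, b), v in values.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(ids), d, valid)


class TestGroupSummary:
    def test_two_species_hand_example(self):
        ids = ["a1", "a2", "b1", "b2"]
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        vals = {("a1", "a2"): 0.0, ("b1", "b2"): 0.0}
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                vals[(a, b)] = 0.03
        g = group_distance_summary(_dm_from_values(ids, vals), labels)
        assert g.mean_inter == pytest.approx(0.03)
        assert g.mean_intra == pytest.approx(0.0)
        assert g.theta == pytest.approx(0.0)
        assert g.coalescence_depth == pytest.approx(0.0)
        assert g.n_inter_pairs == 4
        assert g.n_intra_pairs == 2

    def test_theta_and_depth_single_species_contribution(self):
        # species A intra {0.01, 0.02, 0.03}; species B has one sample
        ids = ["a1", "a2", "a3", "b1"]
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        vals = {
            ("a1", "a2"): 0.01,
            ("a1", "a3"): 0.02,
            ("a2", "a3"): 0.03,
            ("a1", "b1"): 0.1,
            ("a2", "b1"): 0.1,
            ("a3", "b1"): 0.1,
        }
        g = group_distance_summary(_dm_from_values(ids, vals), labels)
        assert g.theta == pytest.approx(0.02)
        assert g.coalescence_depth == pytest.approx(0.03)
        assert g.se_theta == 0.0  # one contributing species
        assert "B" not in g.per_species_theta

    def test_brute_force_reaverage(self, rng):
        base = rng.choice(list("ACGT"), 200)
        seqs = {}
        for i in range(8):
            seq = base.copy()
            mut = rng.random(200) < 0.08
            seq[mut] = rng.choice(list("ACGT"), int(mut.sum()))
            seqs[f"s{i}"] = "".join(seq)
        labels = {f"s{i}": f"sp{i % 2}" for i in range(8)}
        aln = make_aln(seqs, labels)
        dm = pairwise_matrix(aln, min_overlap=10)
        g = group_distance_summary(dm, labels)
        inter, intra = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                if not dm.valid[i, j]:
                    continue
                (inter, intra)[labels[f"s{i}"] == labels[f"s{j}"]].append(
                    dm.d[i, j]
                )
        assert g.mean_inter == pytest.approx(np.mean(inter))
        assert g.mean_intra == pytest.approx(np.mean(intra))
        assert g.n_inter_pairs == len(inter)

    def test_trnh_like_pattern(self):
        # zero intraspecific variation, constant interspecific divergence
        aln = two_species_aln("ACGT" * 64, "ACGT" * 32 + "AGGT" * 32, 4, 4)
        dm = pairwise_matrix(aln)
        g = group_distance_summary(dm, aln.species_map())
        assert g.mean_intra == pytest.approx(0.0)
        assert g.se_intra == pytest.approx(0.0)
        assert g.mean_inter > 0

    def test_single_species_error(self):
        aln = make_aln(
            {"x": "ACGT" * 20, "y": "ACGT" * 20},
            {"x": "sp1", "y": "sp1"},
        )
        dm = pairwise_matrix(aln)
        with pytest.raises(DistanceError):
            group_distance_summary(dm, aln.species_map())


class TestBarcodingGap:
    def test_disjoint_ranges_gap_present(self):
        ids = ["a1", "a2", "b1", "b2"]
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        vals = {("a1", "a2"): 0.005, ("b1", "b2"): 0.01}
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                vals[(a, b)] = 0.025
        g = barcoding_gap(_dm_from_values(ids, vals), labels)
        assert g.gap_present
        assert g.overlap_interval is None
        assert g.max_intra == pytest.approx(0.01)
        assert g.min_inter == pytest.approx(0.025)

    def test_overlap_reported(self):
        ids = ["a1", "a2", "b1", "b2"]
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        vals = {("a1", "a2"): 0.05, ("b1", "b2"): 0.01}
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                vals[(a, b)] = 0.02
        g = barcoding_gap(_dm_from_values(ids, vals), labels)
        assert not g.gap_present
        assert g.overlap_interval == pytest.approx((0.02, 0.05))

    def test_histogram_binning(self):
        ids = ["a1", "a2", "b1"]
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        vals = {("a1", "a2"): 0.0062, ("a1", "b1"): 0.021, ("a2", "b1"): 0.021}
        g = barcoding_gap(_dm_from_values(ids, vals), labels, bin_width=0.005)
        assert (0.005, 1) in g.intra_histogram
        assert g.inter_histogram[-1] == (0.02, 2)

    def test_no_intra_pairs_error(self):
        ids = ["a1", "b1"]
        labels = {"a1": "A", "b1": "B"}
        with pytest.raises(GapUndefinedError):
            barcoding_gap(_dm_from_values(ids, {("a1", "b1"): 0.1}), labels)

    def test_adding_low_inter_pair_is_monotone(self):
        # exhaustive small case: a new inter pair below max_intra can only
        # destroy a gap, never create one
        ids = ["a1", "a2", "b1"]
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        base = {("a1", "a2"): 0.01, ("a1", "b1"): 0.03, ("a2", "b1"): 0.04}
        before = barcoding_gap(_dm_from_values(ids, base), labels)
        assert before.gap_present
        for low in (0.0, 0.002, 0.009, 0.0099):
            ids2 = ids + ["b2"]
            labels2 = {**labels, "b2": "B"}
            vals = {
                **base,
                ("b1", "b2"): 0.0,
                ("a1", "b2"): low,
                ("a2", "b2"): 0.05,
            }
            after = barcoding_gap(_dm_from_values(ids2, vals), labels2)
            assert not after.gap_present
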