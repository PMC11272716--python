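"""Binary fingerprint distance, bootstrap grouping and fragment mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grouprax.simulate import GroundTruth, SimConfig, simulate_fingerprints
from grouprax.structure import (
    binary_distance,
    binary_distance_matrix,
    cluster_fingerprints,
    map_fragments,
    read_fingerprints,
    write_fingerprints,
)


class TestBinaryDistance:
    def test_hand_counted_example(self):
        # union 3 bits, discordant 2: distance 2/3, Tanimoto 1/3
        assert binary_distance([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(2 / 3)

    def test_identity_and_disjoint(self):
        assert binary_distance([1, 0, 1], [1, 0, 1]) == 0.0
        assert binary_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_both_all_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert binary_distance([0, 0], [0, 0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            binary_distance([1, 0], [1, 0, 1])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(*[st.integers(0, 1)] * 8).map(np.array),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_inequality_brute_force(self, fps):
        a, b, c = fps
        if not (a.any() or b.any()) or not (b.any() or c.any()) or not (a.any() or c.any()):
            return  # degenerate 0/0 pairs exempt from metric axioms
        dab = binary_distance(a, b)
        dbc = binary_distance(b, c)
        dac = binary_distance(a, c)
        assert dac <= dab + dbc + 1e-12

    def test_zero_only_bits_do_not_change_distances(self):
        rng = np.random.default_rng(0)
        fps = pd.DataFrame(
            rng.integers(0, 2, size=(5, 40)), index=[f"s{i}" for i in range(5)]
        )
        fps.iloc[:, 25:] = 0  # jointly-absent bits
        full = binary_distance_matrix(fps).to_numpy()
        restricted = binary_distance_matrix(fps.iloc[:, :25]).to_numpy()
        assert np.allclose(full, restricted)


class TestClusterFingerprints:
    def test_planted_families_strongly_supported(self):
        cfg = SimConfig(seed=0)
        truth = GroundTruth({}, {}, {})
        fps = simulate_fingerprints(cfg, truth, np.random.default_rng(7))
        res = cluster_fingerprints(fps, n_boot=1000, seed=3)
        for fam in ("G1", "G2", "G3"):
            sup = res.support_for(cfg.partition[fam])
            assert sup is not None, fam
            assert sup.si >= 0.95
            assert "strongly_supported" in sup.flags

    def test_three_substances_give_two_internal_nodes(self):
        rng = np.random.default_rng(5)
        fps = pd.DataFrame(rng.integers(0, 2, size=(3, 32)), index=list("abc"))
        res = cluster_fingerprints(fps, n_boot=50, seed=0)
        assert len(res.supports) == 2

    def test_seed_fixed_rerun_identical(self):
        rng = np.random.default_rng(1)
        fps = pd.DataFrame(rng.integers(0, 2, size=(5, 64)))
        a = cluster_fingerprints(fps, n_boot=100, seed=9)
        b = cluster_fingerprints(fps, n_boot=100, seed=9)
        assert [s.counts for s in a.supports] == [s.counts for s in b.supports]

    def test_too_few_substances_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cluster_fingerprints(pd.DataFrame([[1, 0], [0, 1]]))


class TestMapFragments:
    def test_hand_evaluated_shared_and_unique(self):
        fps = pd.DataFrame(
            {"b1": [1, 1, 0], "b2": [1, 1, 1], "b3": [0, 0, 1], "b4": [0, 0, 0]},
            index=["A", "B", "C"],
        )
        fmap = map_fragments(fps, {"G": ["A", "B"]})
        assert fmap.shared["G"] == ["b1", "b2"]
        assert fmap.unique["G"] == ["b1"]

    def test_singleton_group_shares_its_nonzero_bits(self):
        fps = pd.DataFrame({"b1": [1, 0], "b2": [0, 1]}, index=["A", "B"])
        fmap = map_fragments(fps, {"G": ["A"]})
        assert fmap.shared["G"] == ["b1"]

    def test_identical_substances_have_no_unique_fragments(self):
        fps = pd.DataFrame(np.ones((4, 6), dtype=int), index=list("abcd"))
        fmap = map_fragments(fps, {"G1": ["a", "b"], "G2": ["c", "d"]})
        assert fmap.unique["G1"] == [] and fmap.unique["G2"] == []

    def test_unique_sets_disjoint_across_groups(self):
        rng = np.random.default_rng(2)
        fps = pd.DataFrame(rng.integers(0, 2, size=(6, 50)), index=list("abcdef"))
        fmap = map_fragments(fps, {"G1": ["a", "b"], "G2": ["c", "d"], "G3": ["e", "f"]})
        for g1, g2 in itertools.combinations(fmap.unique, 2):
            assert not set(fmap.unique[g1]) & set(fmap.unique[g2])

    def test_missing_fingerprint_rejected(self):
        fps = pd.DataFrame({"b": [1]}, index=["A"])
        with pytest.raises(ValueError, match="without fingerprints"):
            map_fragments(fps, {"G": ["A", "Z"]})

    def test_planted_unique_counts_recovered_exactly(self):
        cfg = SimConfig(seed=0)
        truth = GroundTruth({}, {}, {})
        fps = simulate_fingerprints(cfg, truth, np.random.default_rng(12))
        fmap = map_fragments(fps, cfg.partition)
        for fam, bits in truth.unique_bits.items():
            assert sorted(fmap.unique[fam]) == sorted(bits)


def test_fingerprint_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    fps = pd.DataFrame(
        rng.integers(0, 2, size=(4, 16)),
        index=list("wxyz"),
        columns=[f"bit_{i}" for i in range(16)],
    )
    path = tmp_path / "fps.csv"
    write_fingerprints(fps, path)
    assert read_fingerprints(path).equals(fps)
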