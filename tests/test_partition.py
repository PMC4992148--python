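import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from befstress.partition import (
    stress_change,
    stress_change_table,
    partition_table,
    tripartite_partition,
)


class TestTripartitePartition:
    def test_null_expectation_gives_zero_everywhere(self):
        r = tripartite_partition([100, 50], [50, 25])
        assert r.delta_y == pytest.approx(0)
        assert r.components == pytest.approx((0, 0, 0))

    def test_two_species_worked_example(self):
        # M=(100,50), Y=(60,10), equal expected shares
        r = tripartite_partition([100, 50], [60, 10])
        assert r.delta_y == pytest.approx(-5)
        assert r.dominance == pytest.approx(12.5)
        assert r.trait_dependent == pytest.approx(-2.5)
        assert r.trait_independent == pytest.approx(-15)
        assert sum(r.components) == pytest.approx(r.delta_y)

    def test_monoculture_deviation_is_all_trait_independent(self):
        r = tripartite_partition([100], [80], ry_e=[1.0])
        assert r.delta_y == pytest.approx(-20)
        assert r.dominance == pytest.approx(0)
        assert r.trait_dependent == pytest.approx(0)
        assert r.trait_independent == pytest.approx(-20)

    def test_additive_identity_on_random_instances(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 9)
            M = rng.uniform(1e3, 1e9, n)
            Y = rng.uniform(0, 1e9, n)
            r = tripartite_partition(M, Y)
            assert sum(r.components) == pytest.approx(r.delta_y, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.integers(2, 8),
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10.0),
    )
    def test_order_invariance_and_homogeneity(self, n, seed, k):
        rng = np.random.default_rng(seed)
        M = rng.uniform(1e2, 1e6, n)
        Y = rng.uniform(0, 1e6, n)
        base = tripartite_partition(M, Y)
        perm = rng.permutation(n)
        permuted = tripartite_partition(M[perm], Y[perm])
        assert permuted.components == pytest.approx(base.components, rel=1e-9, abs=1e-9)
        scaled = tripartite_partition(k * M, k * Y)
        assert scaled.delta_y == pytest.approx(k * base.delta_y, rel=1e-9)
        assert scaled.components == pytest.approx(
            tuple(k * c for c in base.components), rel=1e-9, abs=1e-6
        )

    def test_nonpositive_monoculture_rejected(self):
        with pytest.raises(ValueError, match="monoculture"):
            tripartite_partition([100, 0], [10, 10])

    def test_all_extinct_mixture_rejected(self):
        with pytest.raises(ValueError, match="extinct"):
            tripartite_partition([100, 50], [0, 0])

    def test_zero_yield_species_retained(self):
        r = tripartite_partition([100, 50], [60, 0])
        assert r.ry_o[1] == 0
        assert np.isfinite(r.delta_y)


class TestStressChange:
    def test_identity_gives_zero(self):
        a = tripartite_partition([100, 50], [60, 10], assemblage="A", day=28)
        d = stress_change(a, a)
        assert d["delta_dominance"] == 0
        assert d["delta_trait_dependent"] == 0
        assert d["delta_trait_independent"] == 0

    def test_sign_convention_stress_minus_control(self):
        ctrl = tripartite_partition([100, 50], [60, 10], assemblage="A", day=28)
        strs = tripartite_partition([100, 50], [50, 25], assemblage="A", day=28)
        d = stress_change(ctrl, strs)
        assert d["delta_dominance"] == pytest.approx(-12.5)
        assert d["delta_trait_dependent"] == pytest.approx(2.5)
        assert d["delta_trait_independent"] == pytest.approx(15)
        total = (d["delta_dominance"] + d["delta_trait_dependent"]
                 + d["delta_trait_independent"])
        assert total == pytest.approx(d["delta_delta_y"])

    def test_mismatched_pair_rejected(self):
        a = tripartite_partition([100], [80], ry_e=[1.0], assemblage="A", day=21)
        b = tripartite_partition([100], [80], ry_e=[1.0], assemblage="B", day=21)
        with pytest.raises(ValueError, match="mismatched"):
            stress_change(a, b)


class TestPartitionTables:
    def test_partition_table_covers_mixtures(self, tiny_dataset):
        _, design, data = tiny_dataset
        parts = partition_table(data, design)
        mixed = design.mixed_assemblages()
        days = len(design.sampling_days)
        stresses = len(design.stress_levels)
        assert len(parts) == len(mixed) * days * stresses
        resid = (
            parts["dominance"] + parts["trait_dependent"]
            + parts["trait_independent"] - parts["delta_y"]
        )
        assert np.abs(resid).max() <= 1e-6 * np.abs(parts["delta_y"]).max()

    def test_stress_change_table_matches_componentwise_difference(self, tiny_dataset):
        _, design, data = tiny_dataset
        parts = partition_table(data, design)
        changes = stress_change_table(parts)
        row = changes.iloc[0]
        ctrl = parts[
            (parts["assemblage"] == row["assemblage"])
            & (parts["day"] == row["day"]) & (parts["stress"] == 0.0)
        ].iloc[0]
        strs = parts[
            (parts["assemblage"] == row["assemblage"])
            & (parts["day"] == row["day"]) & (parts["stress"] == row["stress"])
        ].iloc[0]
        assert row["delta_dominance"] == pytest.approx(
            strs["dominance"] - ctrl["dominance"]
        )
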