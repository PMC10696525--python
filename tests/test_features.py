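"""Partition semantics, normalizations, and feature-matrix assembly."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evprofile import features
from evprofile.features import (
    THREE_BIN,
    SampleProfile,
    SizePartition,
    assemble_features,
    assign_group,
    expression_level,
    percentile_normalize,
    zscore_rows,
)

partitions = st.sets(
    st.integers(1, 12).map(lambda i: 30.0 + 10.0 * i), max_size=12
).map(lambda inner: SizePartition(tuple(sorted({30.0, 160.0} | inner))))


class TestSizePartition:
    def test_three_bin_boundary_convention(self):
        # 70.0 opens the middle group (half-open convention)
        assert assign_group(70.0, THREE_BIN) == 1
        assert assign_group(160.0, THREE_BIN) == 2  # top edge closes the last group
        assert assign_group(25.0, THREE_BIN) == features.OUT_OF_RANGE
        assert assign_group(161.0, THREE_BIN) == features.OUT_OF_RANGE

    def test_from_string_round_trip(self):
        p = SizePartition.from_string("30-70,70-120,120-160")
        assert p == THREE_BIN
        assert p.to_string() == "30-70,70-120,120-160"

    @pytest.mark.parametrize("text", ["30-80,70-160", "30-70;70-160", "70-30", "30-70,90-160"])
    def test_malformed_partition_strings(self, text):
        with pytest.raises(ValueError):
            SizePartition.from_string(text)

    def test_invalid_boundaries(self):
        with pytest.raises(ValueError):
            SizePartition((30.0,))
        with pytest.raises(ValueError):
            SizePartition((30.0, 30.0, 160.0))

    @settings(max_examples=100, derandomize=True)
    @given(p=partitions, d=st.floats(30.0, 160.0))
    def test_in_range_diameter_lands_in_exactly_one_group(self, p, d):
        idx = p.assign(d)
        assert 0 <= idx < p.n_groups
        lo, hi = p.edges[idx]
        assert lo <= d < hi or (d == hi == p.boundaries[-1])
        assert p.assign_array(np.array([d]))[0] == idx

    @settings(max_examples=50, derandomize=True)
    @given(p=partitions)
    def test_refinement_preserves_assigned_count(self, p):
        base = SizePartition(tuple(30.0 + 10.0 * i for i in range(14)))  # finest
        rng = np.random.default_rng(0)
        d = rng.uniform(10.0, 180.0, size=500)
        coarse = p.assign_array(d)
        fine = base.assign_array(d)
        assert (coarse != features.OUT_OF_RANGE).sum() == (fine != features.OUT_OF_RANGE).sum()


class TestExpressionLevel:
    def test_basic_values(self):
        assert expression_level(0, 1000) == 0.0
        assert expression_level(250, 1000) == 0.25

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            expression_level(5, 0)

    def test_group_levels_sum_to_overall(self, rng):
        d = rng.uniform(30.0, 160.0, size=400)
        total = 1700
        per_group = [
            expression_level((THREE_BIN.assign_array(d) == g).sum(), total)
            for g in range(3)
        ]
        assert sum(per_group) == pytest.approx(expression_level(len(d), total))


class TestPercentileNormalize:
    def test_percentile_values_map_to_zero_and_one(self, rng):
        # build a column that contains its own 2.5th/97.5th percentiles exactly
        x = np.linspace(0.0, 1.0, 41)  # p2.5 = 0.025, p97.5 = 0.975 are data points
        z, (lo, hi) = percentile_normalize(x)
        assert lo in x and hi in x
        assert z[np.where(x == lo)[0][0]] == 0.0
        assert z[np.where(x == hi)[0][0]] == 1.0
        assert z.min() < 0 < 1 < z.max()  # no clipping outside the band

    def test_against_order_statistic_oracle(self):
        x = np.arange(41.0)

        def brute_percentile(xs, q):
            # linear interpolation of sorted order statistics
            xs = np.sort(xs)
            pos = q / 100 * (len(xs) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return xs[lo] if lo == len(xs) - 1 else xs[lo] * (1 - frac) + xs[lo + 1] * frac

        z, (lo, hi) = percentile_normalize(x)
        assert lo == pytest.approx(brute_percentile(x, 2.5))
        assert hi == pytest.approx(brute_percentile(x, 97.5))
        assert np.allclose(z, (x - lo) / (hi - lo))

    def test_constant_column_degenerate(self):
        with pytest.raises(ValueError):
            percentile_normalize(np.full(10, 3.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        z1, _ = percentile_normalize(x)
        z2, _ = percentile_normalize(a * x + b)
        assert np.allclose(z1, z2, atol=1e-9)


class TestZScore:
    def test_hand_computed_row(self):
        out = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 0.0, 1.0]])

    def test_rows_standardized_to_machine_precision(self, rng):
        out = zscore_rows(rng.normal(size=(8, 12)))
        assert np.all(np.abs(out.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(out.std(axis=1, ddof=1) - 1) < 1e-12)

    def test_constant_row_raises(self):
        with pytest.raises(ValueError, match="zero-SD"):
            zscore_rows(np.array([[5.0, 5.0, 5.0]]))


def _profiles(n=12, markers=("CD63", "EpCAM", "HER2", "PSMA", "PTK7"), partition=THREE_BIN, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        p = SampleProfile(
            sample_id=f"s{i}", class_label="a" if i % 2 else "b",
            markers=tuple(markers), total_count=1000.0,
        )
        for m in markers:
            for g in partition.group_labels():
                p.values[(m, g)] = {
                    "expression": float(rng.uniform(0, 1)),
                    "k": float(rng.uniform(1e-3, 1e-2)),
                    "n_max": float(rng.uniform(50, 500)),
                }
        out.append(p)
    return out


class TestAssembleFeatures:
    def test_feature_count_three_groups(self):
        fm = assemble_features(_profiles(), THREE_BIN, quantities=("expression", "k"))
        assert len(fm.feature_names) == 5 * 3 * 2  # markers x groups x quantities
        assert fm.values.shape == (12, 30)
        assert set(fm.normalization) == set(fm.feature_names)

    def test_bulk_partition_gives_ten_features(self):
        bulk = SizePartition.single_group()
        fm = assemble_features(_profiles(partition=bulk), bulk)
        assert len(fm.feature_names) == 10

    def test_missing_kinetics_take_column_median(self):
        profiles = _profiles(n=7)
        removed = profiles[0].values[("CD63", "30-70")].pop("k")
        fm = assemble_features(profiles, THREE_BIN, normalize=False)
        col = fm.feature_names.index("CD63:30-70:k")
        others = [p.values[("CD63", "30-70")]["k"] for p in profiles[1:]]
        assert fm.values[0, col] == pytest.approx(np.median(others))
        assert removed not in fm.values[0]

    def test_identical_profiles_drop_zero_variance_columns(self, caplog):
        profiles = _profiles(n=1) * 6
        with caplog.at_level(logging.WARNING, logger="evprofile.features"):
            fm = assemble_features(profiles, THREE_BIN)
        assert fm.values.shape[1] == 0
        assert len(fm.dropped_features) == 30
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_inconsistent_panels_raise(self):
        profiles = _profiles(n=4)
        profiles[2].markers = ("CD63",)
        with pytest.raises(ValueError, match="panel"):
            assemble_features(profiles, THREE_BIN)
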