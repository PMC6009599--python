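import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from thx import (
    ArraySample,
    assemble_probe_matrix,
    build_gem,
    compute_log_ratios,
    filter_and_average,
    median_center,
    scale_normalize,
)
from thx.gem_pipeline import GEM, _mad


def _gem(values, stage="raw", fractions=None):
    values = np.asarray(values, dtype=float)
    fractions = fractions or ["total"] * values.shape[1]
    samples = [
        ArraySample(f"s{j}", frac, 30, j + 1) for j, frac in enumerate(fractions)
    ]
    return GEM([f"r{i}" for i in range(values.shape[0])], samples, values, stage=stage)


class TestLogRatios:
    def test_plain_ratio(self, make_probe_table):
        t = make_probe_table([("p1", "g1", False, 8.0, 2.0)])
        assert compute_log_ratios(t) == pytest.approx([2.0])

    def test_both_negative_gives_zero(self, make_probe_table):
        t = make_probe_table(
            [("p1", "g1", False, -5.0, -3.0), ("p2", "g1", False, 4.0, 4.0)]
        )
        assert compute_log_ratios(t)[0] == 0.0

    def test_single_negative_channel_replaced_by_channel_minimum(self, make_probe_table):
        # min positive signal on this array is 1 -> log2(1/4) = -2
        t = make_probe_table(
            [
                ("p1", "g1", False, -5.0, 4.0),
                ("p2", "g1", False, 1.0, 2.0),
                ("p3", "g1", False, 6.0, 2.0),
            ]
        )
        assert compute_log_ratios(t)[0] == pytest.approx(-2.0)

    def test_zero_treated_as_negative(self, make_probe_table):
        t = make_probe_table(
            [("p1", "g1", False, 0.0, 2.0), ("p2", "g1", False, 4.0, 2.0)]
        )
        # signal 0 replaced by min positive signal (4) -> log2(4/2) = 1
        assert compute_log_ratios(t)[0] == pytest.approx(1.0)

    def test_all_negative_channel_errors(self, make_probe_table):
        t = make_probe_table(
            [("p1", "g1", False, -1.0, 2.0), ("p2", "g1", False, -2.0, 3.0)]
        )
        with pytest.raises(ValueError, match="no positive values"):
            compute_log_ratios(t)


class TestMedianCenter:
    def test_example_column(self):
        out = median_center(_gem([[1.0], [2.0], [3.0]]))
        assert out.values[:, 0].tolist() == [-1.0, 0.0, 1.0]
        assert out.stage == "centered"

    def test_constant_column_becomes_zero(self):
        out = median_center(_gem([[5.0], [5.0], [5.0]]))
        assert (out.values == 0).all()

    def test_already_centered_unchanged(self):
        vals = np.array([[-1.0, 2.0], [0.0, 0.0], [1.0, -2.0]])
        out = median_center(_gem(vals))
        np.testing.assert_array_equal(out.values, vals)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            (7, 3),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        )
    )
    def test_column_medians_zero_and_shift_invariance(self, vals):
        centered = median_center(_gem(vals))
        assert np.abs(np.median(centered.values, axis=0)).max() <= 1e-9
        shifted = vals.copy()
        shifted[:, 1] += 123.25
        centered2 = median_center(_gem(shifted))
        np.testing.assert_allclose(centered2.values, centered.values, atol=1e-9)


class TestScaleNormalize:
    def test_two_columns_equalize_to_geometric_mean(self, rng):
        base = rng.normal(size=50)
        base -= np.median(base)
        vals = np.column_stack([base / _mad(base), 4.0 * base / _mad(base)])
        out = scale_normalize(_gem(vals, stage="centered"))
        mads = [_mad(out.values[:, j]) for j in range(2)]
        assert mads[0] == pytest.approx(2.0)
        assert mads[1] == pytest.approx(2.0)

    def test_single_column_batch_unchanged(self, rng):
        vals = rng.normal(size=(30, 1))
        vals -= np.median(vals)
        out = scale_normalize(_gem(vals, stage="centered"))
        np.testing.assert_allclose(out.values, vals)

    def test_batches_independent(self, rng):
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(40, 2))
        gem1 = _gem(
            np.column_stack([a, b]),
            stage="centered",
            fractions=["total", "total", "polysome", "polysome"],
        )
        out1 = scale_normalize(gem1)
        # permute batch A's data: batch B's output must be bit-identical
        gem2 = _gem(
            np.column_stack([a[::-1], b]),
            stage="centered",
            fractions=["total", "total", "polysome", "polysome"],
        )
        out2 = scale_normalize(gem2)
        np.testing.assert_array_equal(out1.values[:, 2:], out2.values[:, 2:])

    def test_zero_mad_names_array(self):
        vals = np.column_stack([np.zeros(10), np.arange(10.0) - 4.5])
        with pytest.raises(ValueError, match="s0"):
            scale_normalize(_gem(vals, stage="centered"))

    def test_within_batch_mads_equal_invariant(self, rng):
        vals = rng.normal(0, [0.5, 1.0, 2.0, 4.0], size=(101, 4))
        gem = _gem(
            vals,
            fractions=["total", "total", "polysome", "polysome"],
        )
        out = scale_normalize(median_center(gem))
        for cols in ([0, 1], [2, 3]):
            mads = [_mad(out.values[:, j]) for j in cols]
            assert abs(mads[0] - mads[1]) <= 1e-9


class TestFilterAndAverage:
    def test_probe_averaging(self, make_probe_table):
        t = make_probe_table(
            [
                ("p1", "gA", False, 2.0, 1.0),  # log2 = 1
                ("p2", "gA", False, 8.0, 1.0),  # log2 = 3
                ("p3", "gB", False, 4.0, 1.0),
                ("p4", "", False, 4.0, 1.0),  # unmapped, dropped
                ("c1", "", True, 1.0, 1.0),  # control, filtered
            ]
        )
        raw, info = assemble_probe_matrix([t])
        out = filter_and_average(raw, info)
        assert out.row_ids == ["gA", "gB"]
        assert out.values[:, 0].tolist() == pytest.approx([2.0, 2.0])

    def test_single_probe_identity(self, make_probe_table):
        t = make_probe_table([("p1", "gA", False, 4.0, 1.0)])
        raw, info = assemble_probe_matrix([t])
        out = filter_and_average(raw, info)
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_nonuniform_platform_rejected(self, make_probe_table):
        t1 = make_probe_table([("p1", "gA", False, 1.0, 1.0)])
        t2 = make_probe_table(
            [("pX", "gA", False, 1.0, 1.0)],
            sample=ArraySample("a2", "total", 42, 1),
        )
        with pytest.raises(ValueError, match="uniform"):
            assemble_probe_matrix([t1, t2])


class TestPipeline:
    def test_deterministic(self, small_sim):
        g1 = build_gem(small_sim.experiment.tables)
        g2 = build_gem(small_sim.experiment.tables)
        np.testing.assert_array_equal(g1.values, g2.values)
        assert g1.row_ids == g2.row_ids

    def test_gene_set_uniform_across_arrays(self, small_sim, small_cfg):
        gem = build_gem(small_sim.experiment.tables)
        assert len(gem.row_ids) == small_cfg.n_genes
        assert gem.stage == "normalized"
        assert not np.isnan(gem.values).any()

    def test_array_shift_removed_by_centering(self, make_probe_table):
        rows = [(f"p{i}", f"g{i}", False, float(2**i), 1.0) for i in range(1, 8)]
        t1 = make_probe_table(rows)
        shifted = [(p, g, c, s * 16.0, r) for p, g, c, s, r in rows]  # +4 log2 on every probe
        t2 = make_probe_table(shifted, sample=ArraySample("a2", "total", 42, 1))
        raw, _ = assemble_probe_matrix([t1, t2])
        centered = median_center(raw)
        np.testing.assert_allclose(centered.values[:, 0], centered.values[:, 1], atol=1e-12)
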