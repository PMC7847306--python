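"""Transforms, imputation, RLE normalization and the per-metabolite
Gaussian linear model, checked against closed-form and scipy oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sortmet as sm
from sortmet.io import meta_frame


def matrix_from(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return sm.IntensityMatrix(
        pd.DataFrame(
            values,
            index=[f"m{i + 1}" for i in range(values.shape[0])],
            columns=samples,
        )
    )


class TestLog2P1:
    def test_zero_maps_to_zero_and_7_to_3(self):
        out = sm.log2p1(matrix_from([[0.0, 7.0]]), pseudo_count=1.0)
        np.testing.assert_allclose(out.data.to_numpy(), [[0.0, 3.0]])
        assert out.log_scale

    def test_inverse_recovers_input(self):
        rng = np.random.default_rng(0)
        raw = matrix_from(rng.uniform(0, 1e6, size=(5, 4)))
        logged = sm.log2p1(raw, 1.0)
        back = np.exp2(logged.data.to_numpy()) - 1.0
        np.testing.assert_allclose(back, raw.data.to_numpy(), rtol=1e-12)

    def test_negative_pseudo_count_rejected(self):
        with pytest.raises(sm.ValidationError):
            sm.log2p1(matrix_from([[1.0]]), pseudo_count=-0.5)


class TestHalfMinImpute:
    def test_zeros_replaced_by_half_minimum(self):
        out, undetected = sm.half_min_impute(matrix_from([[0, 4, 8, 0]]))
        np.testing.assert_allclose(out.data.to_numpy(), [[2, 4, 8, 2]])
        assert undetected == []

    def test_all_zero_row_unchanged_and_flagged(self):
        out, undetected = sm.half_min_impute(matrix_from([[0, 0], [1, 2]]))
        np.testing.assert_allclose(out.data.iloc[0].to_numpy(), [0, 0])
        assert undetected == ["m1"]

    def test_no_zeros_is_identity(self):
        raw = matrix_from([[1, 2], [3, 4]])
        out, _ = sm.half_min_impute(raw)
        pd.testing.assert_frame_equal(out.data, raw.data)


class TestRLE:
    def test_identical_samples_unit_factors(self):
        factors = sm.rle_size_factors(matrix_from([[5, 5], [9, 9]]))
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_median_of_ratios_oracle(self):
        """B = 2A elementwise: after the geometric-mean-1 rescaling the
        factors are (1/sqrt(2), sqrt(2)) by hand computation."""
        factors = sm.rle_size_factors(matrix_from([[10, 20], [300, 600]]))
        np.testing.assert_allclose(
            factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )
        normalized = sm.rle_normalize(matrix_from([[10, 20], [300, 600]]))
        np.testing.assert_allclose(
            normalized.data["s1"], normalized.data["s2"], rtol=1e-12
        )

    def test_permutation_equivariance(self):
        raw = matrix_from(np.random.default_rng(1).uniform(1, 100, (6, 4)))
        factors = sm.rle_size_factors(raw)
        permuted = sm.IntensityMatrix(raw.data[["s3", "s1", "s4", "s2"]])
        np.testing.assert_allclose(
            sm.rle_size_factors(permuted).to_numpy(),
            factors[["s3", "s1", "s4", "s2"]].to_numpy(),
        )

    def test_scale_equivariance_of_factor_ratios(self):
        """Multiplying one sample by c multiplies its factor by c relative
        to the others (the geometric-mean-1 constraint spreads a global
        rescale, so compare factor ratios)."""
        rng = np.random.default_rng(2)
        raw = matrix_from(rng.uniform(1, 100, (8, 3)))
        before = sm.rle_size_factors(raw)
        scaled = raw.data.copy()
        scaled["s2"] *= 7.0
        after = sm.rle_size_factors(sm.IntensityMatrix(scaled))
        ratio = (after / before) / (after["s1"] / before["s1"])
        np.testing.assert_allclose(ratio[["s1", "s2", "s3"]], [1.0, 7.0, 1.0])

    def test_idempotence(self):
        raw = matrix_from(np.random.default_rng(3).uniform(1, 1e4, (10, 5)))
        normalized = sm.rle_normalize(raw)
        refactors = sm.rle_size_factors(normalized)
        np.testing.assert_allclose(refactors.to_numpy(), 1.0, atol=1e-9)

    def test_single_sample_identity(self):
        raw = matrix_from([[5.0], [7.0]])
        normalized = sm.rle_normalize(raw)
        pd.testing.assert_frame_equal(normalized.data, raw.data)

    def test_all_zero_rows_demand_imputation(self):
        with pytest.raises(sm.ValidationError, match="impute"):
            sm.rle_size_factors(matrix_from([[0, 1], [2, 0]]))


class TestMeanEqualize:
    def test_already_equal_is_identity(self):
        raw = matrix_from([[4, 4], [6, 6]])
        out = sm.mean_equalize(raw, ["m1", "m2"])
        pd.testing.assert_frame_equal(out.data, raw.data.astype(float))

    def test_tripled_sample_scaled_back(self):
        raw = matrix_from([[4, 12], [6, 18]])
        out = sm.mean_equalize(raw, ["m1", "m2"])
        implied = out.data["s2"] / raw.data["s2"]
        relative = implied / (out.data["s1"] / raw.data["s1"])
        np.testing.assert_allclose(relative, 1.0 / 3.0, rtol=1e-12)

    def test_per_sample_means_equal_afterwards(self):
        rng = np.random.default_rng(4)
        raw = matrix_from(rng.uniform(1, 1e5, (12, 6)))
        ids = [f"m{i + 1}" for i in range(8)]
        out = sm.mean_equalize(raw, ids)
        means = out.data.loc[ids].mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0], rtol=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(sm.ValidationError):
            sm.mean_equalize(matrix_from([[1, 2]]), [])


class TestGroupTest:
    def _meta(self, n=5, pair=False):
        rows = []
        for g in ("A", "B"):
            for i in range(n):
                rows.append(
                    sm.SampleMeta(
                        f"{g}{i}", "cell", group=g,
                        pair=f"p{i}" if pair else "",
                    )
                )
        return rows

    def test_identical_groups_no_effect_convention(self):
        y = pd.Series(3.0, index=[s.sample_id for s in self._meta()])
        coef, _, p = sm.fit_group_test(y, self._meta(), sm.DesignSpec("A", "B"))
        assert coef == 0.0 and p == 1.0

    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(5)
        meta = self._meta()
        y = pd.Series(
            rng.normal(0, 1, 10), index=[s.sample_id for s in meta]
        )
        coef, _, p = sm.fit_group_test(y, meta, sm.DesignSpec("A", "B"))
        oracle = sps.ttest_ind(y[5:], y[:5])
        assert p == pytest.approx(oracle.pvalue, abs=1e-10)
        assert coef == pytest.approx(y[5:].mean() - y[:5].mean(), abs=1e-12)

    def test_pair_covariate_matches_paired_t(self):
        rng = np.random.default_rng(6)
        meta = self._meta(pair=True)
        base = rng.normal(10, 2, 5)
        y = pd.Series(
            np.concatenate([base, base + rng.normal(1, 0.3, 5)]),
            index=[s.sample_id for s in meta],
        )
        _, _, p = sm.fit_group_test(
            y, meta, sm.DesignSpec("A", "B", ("pair",))
        )
        oracle = sps.ttest_rel(y[5:].to_numpy(), y[:5].to_numpy())
        assert p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_batch_covariate_removes_batch_shift(self):
        meta = []
        values = {}
        rng = np.random.default_rng(7)
        for g, delta in (("A", 0.0), ("B", 1.5)):
            for i in range(6):
                batch = f"b{i % 2}"
                sid = f"{g}{i}"
                meta.append(sm.SampleMeta(sid, "cell", group=g, batch=batch))
                values[sid] = delta + (3.0 if batch == "b1" else 0.0) + rng.normal(0, 0.1)
        y = pd.Series(values)
        coef, _, p = sm.fit_group_test(
            y, meta, sm.DesignSpec("A", "B", ("batch",))
        )
        assert coef == pytest.approx(1.5, abs=0.2)
        assert p < 1e-6

    def test_collinear_covariate_named(self):
        meta = [
            sm.SampleMeta(f"{g}{i}", "cell", group=g, batch=g)
            for g in ("A", "B")
            for i in range(3)
        ]
        y = pd.Series(
            np.arange(6, dtype=float), index=[s.sample_id for s in meta]
        )
        with pytest.raises(sm.ValidationError, match="batch"):
            sm.fit_group_test(y, meta, sm.DesignSpec("A", "B", ("batch",)))

    def test_incomplete_pairs_rejected(self):
        meta = [
            sm.SampleMeta("A0", "cell", group="A", pair="p0"),
            sm.SampleMeta("A1", "cell", group="A", pair="p1"),
            sm.SampleMeta("B0", "cell", group="B", pair="p0"),
            sm.SampleMeta("B1", "cell", group="B", pair="p2"),
        ]
        y = pd.Series(np.arange(4.0), index=[s.sample_id for s in meta])
        with pytest.raises(sm.ValidationError, match="pair"):
            sm.fit_group_test(y, meta, sm.DesignSpec("A", "B", ("pair",)))


def bh_step_up(p):
    """Brute-force BH from the step-up definition (independent oracle)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


class TestBenjaminiHochberg:
    def test_two_value_definition(self):
        np.testing.assert_allclose(
            sm.benjamini_hochberg([0.01, 0.04]), [0.02, 0.04]
        )

    def test_single_and_tied_inputs_unchanged(self):
        np.testing.assert_allclose(sm.benjamini_hochberg([0.3]), [0.3])
        np.testing.assert_allclose(
            sm.benjamini_hochberg([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2]
        )

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(
                sm.benjamini_hochberg(p), bh_step_up(p), atol=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(sm.ValidationError):
            sm.benjamini_hochberg([0.5, 1.5])


class TestAboveBackground:
    def _meta(self):
        return [sm.SampleMeta(f"b{i}", "blank") for i in range(3)] + [
            sm.SampleMeta(f"c{i}", "cell", group="G") for i in range(3)
        ]

    def test_clear_signal_called(self):
        raw = matrix_from(
            [[0, 0, 0, 100, 110, 90], [50, 55, 45, 50, 55, 45]],
            samples=["b0", "b1", "b2", "c0", "c1", "c2"],
        )
        calls = sm.above_background(raw, self._meta()).set_index("metabolite_id")
        assert bool(calls.loc["m1", "above_background"])
        assert not bool(calls.loc["m2", "above_background"])

    def test_cells_equal_blanks_not_called(self):
        raw = matrix_from(
            [[5, 6, 7, 5, 6, 7]], samples=["b0", "b1", "b2", "c0", "c1", "c2"]
        )
        calls = sm.above_background(raw, self._meta())
        assert not calls["above_background"].any()

    def test_fold_change_exactly_two_not_called(self):
        """Fold change = 2.000 fails the strict > 2 cutoff even at FDR ~ 0:
        cells at exactly 2x on the log2(x+1) scale are not above background."""
        raw = matrix_from(
            [[100, 100, 100, 201, 201, 201], [0, 0, 0, 900, 1000, 1100]],
            samples=["b0", "b1", "b2", "c0", "c1", "c2"],
        )
        calls = sm.above_background(raw, self._meta()).set_index("metabolite_id")
        assert calls.loc["m1", "fold_over_blank"] == pytest.approx(2.0, abs=1e-12)
        assert not bool(calls.loc["m1", "above_background"])
        assert bool(calls.loc["m2", "above_background"])

    def test_missing_blanks_rejected(self):
        raw = matrix_from([[1, 2]], samples=["c0", "c1"])
        meta = [sm.SampleMeta(f"c{i}", "cell", group="G") for i in range(2)]
        with pytest.raises(sm.ValidationError, match="blank"):
            sm.above_background(raw, meta)


class TestDifferentialAbundance:
    def _fixture(self, scale=1.0):
        rng = np.random.default_rng(9)
        base = rng.uniform(1e4, 1e6, size=30)
        values = base[:, None] * np.exp(rng.normal(0, 0.2, size=(30, 8)))
        values[0, 4:] *= 8.0  # planted 8-fold up in group B
        meta = [
            sm.SampleMeta(f"A{i}", "cell", group="A") for i in range(4)
        ] + [sm.SampleMeta(f"B{i}", "cell", group="B") for i in range(4)]
        samples = [s.sample_id for s in meta]
        return matrix_from(values * scale, samples=samples), meta

    def test_planted_effect_recovered_up(self):
        raw, meta = self._fixture()
        results = sm.differential_abundance(
            raw, meta, sm.DesignSpec("A", "B")
        ).set_index("metabolite_id")
        assert bool(results.loc["m1", "significant"])
        assert results.loc["m1", "direction"] == "up"
        assert results.loc["m1", "log2_fc"] == pytest.approx(3.0, abs=0.6)

    def test_group_swap_negates_log2fc_preserves_p(self):
        raw, meta = self._fixture()
        fwd = sm.differential_abundance(raw, meta, sm.DesignSpec("A", "B"))
        rev = sm.differential_abundance(raw, meta, sm.DesignSpec("B", "A"))
        np.testing.assert_allclose(
            fwd["log2_fc"].to_numpy(), -rev["log2_fc"].to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            fwd["p_value"].to_numpy(), rev["p_value"].to_numpy(), atol=1e-12
        )

    def test_invariant_to_global_scaling(self):
        raw, meta = self._fixture()
        scaled, _ = self._fixture(scale=137.0)
        a = sm.differential_abundance(raw, meta, sm.DesignSpec("A", "B"))
        b = sm.differential_abundance(scaled, meta, sm.DesignSpec("A", "B"))
        np.testing.assert_allclose(
            a["log2_fc"].to_numpy(), b["log2_fc"].to_numpy(), atol=1e-9
        )
        np.testing.assert_allclose(
            a["p_value"].to_numpy(), b["p_value"].to_numpy(), atol=1e-9
        )

    def test_empty_universe_rejected(self):
        raw, meta = self._fixture()
        with pytest.raises(sm.ValidationError, match="universe"):
            sm.DifferentialAbundanceModel(
                raw, meta, sm.DesignSpec("A", "B"), universe=[]
            )

    def test_results_object_counts(self):
        raw, meta = self._fixture()
        fitted = sm.DifferentialAbundanceModel(
            raw, meta, sm.DesignSpec("A", "B")
        ).fit()
        assert fitted.n_significant >= 1
        assert "m1" in fitted.significant_ids
        assert "Differential abundance" in fitted.summary()


class TestCountSignificant:
    def test_empty_is_zero(self):
        assert sm.count_significant(pd.DataFrame(), 2.0) == 0

    def test_manual_enumeration(self):
        results = pd.DataFrame(
            {
                "metabolite_id": list("abcd"),
                "log2_fc": [2.0, -1.5, 0.5, 3.0],
                "fdr": [0.01, 0.01, 0.01, 0.2],
            }
        )
        # beyond 2-fold at fdr<0.05: a (4x), b (2.83x down); d fails fdr
        assert sm.count_significant(results, 2.0) == 2
        assert sm.count_significant(results, 2.5) == 2
        assert sm.count_significant(results, 3.0) == 1  # only a (4x)
        assert sm.count_significant(results, 4.0) == 0  # 4.000 fails strict >

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(10)
        from tests.conftest import random_results

        results = random_results(rng, 100)
        assert sm.count_significant(results, 2.5) <= sm.count_significant(
            results, 2.0
        )


def test_meta_frame_round_trip(two_group_meta):
    frame = meta_frame(two_group_meta)
    assert list(frame.columns) == [
        "sample_id", "role", "group", "batch", "pair", "cell_number",
    ]
    assert frame.loc["A1", "pair"] == "p1"


class TestProperties:
    """Seeded property tests of the core statistical invariants."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40
        )
    )
    def test_bh_equals_oracle_and_stays_in_unit_interval(self, p):
        adjusted = sm.benjamini_hochberg(p)
        np.testing.assert_allclose(adjusted, bh_step_up(p), atol=1e-12)
        assert ((adjusted >= 0) & (adjusted <= 1)).all()
        # step-up output is monotone in the sorted order of the raw p-values
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=80.0, max_value=1200.0),
        st.floats(min_value=-20.0, max_value=20.0),
    )
    def test_ppm_error_antisymmetric_in_offset(self, mass, ppm):
        observed_up = mass * (1 + ppm * 1e-6)
        observed_down = mass * (1 - ppm * 1e-6)
        up = sm.ppm_error(observed_up, mass)
        down = sm.ppm_error(observed_down, mass)
        assert up == pytest.approx(-down, abs=1e-9)
        assert up == pytest.approx(ppm, abs=1e-6)
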