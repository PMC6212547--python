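"""Preprocessing: thresholds, filters, normexp, quantile, median polish."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from parasnail import (
    ArrayDesign,
    IntensityMatrix,
    background_threshold,
    compute_log_ratios,
    filter_cgh_probes,
    filter_expression_genes,
    intersect_filters,
    median_polish,
    normexp_correct,
    quantile_normalize,
    summarize_genes,
)
from parasnail.preprocess import ConfigurationError, PipelineError, _normexp_conditional_mean


def small_design(n_genes=2, ppg=5, empty=2) -> ArrayDesign:
    rows = []
    for g in range(1, n_genes + 1):
        for j in range(1, ppg + 1):
            rows.append((f"g{g}_p{j}", f"g{g}", j, False))
    for e in range(1, empty + 1):
        rows.append((f"EMPTY_{e}", "EMPTY", 0, True))
    return ArrayDesign(
        pd.DataFrame(rows, columns=["probe_id", "gene_id", "probe_index", "is_empty"])
    )


def matrix_for(design, fill=12.0, empties=10.0, n_samples=4, channels="single"):
    cols = [f"s{i}" for i in range(n_samples)]
    if channels == "two":
        cols = [c for s in cols for c in (f"{s}__cy3", f"{s}__cy5")]
    values = pd.DataFrame(fill, index=design.probe_ids, columns=cols, dtype=float)
    values.loc[design.empty_probe_ids] = empties
    return IntensityMatrix(values, scale="log2", channels=channels)


class TestBackgroundThreshold:
    def test_constant_empties(self):
        design = small_design()
        mat = matrix_for(design, empties=10.0)
        assert background_threshold(mat, design) == pytest.approx(10.0)

    def test_mean_over_probes_and_samples(self):
        design = small_design(empty=2)
        mat = matrix_for(design)
        mat.values.loc["EMPTY_1"] = 10.0
        mat.values.loc["EMPTY_2"] = 11.0
        assert background_threshold(mat, design) == pytest.approx(10.5)

    def test_override_returned_unchanged(self):
        design = small_design()
        mat = matrix_for(design, channels="two")
        assert background_threshold(mat, design, "cy3", override=10.7) == 10.7

    def test_no_empty_spots_is_configuration_error(self):
        design = small_design(empty=0)
        mat = matrix_for(design)
        with pytest.raises(ConfigurationError, match="threshold"):
            background_threshold(mat, design)


class TestExpressionFilter:
    @pytest.mark.parametrize("n_below,kept", [(0, True), (1, True), (2, False)])
    def test_strict_20_percent_rule(self, n_below, kept):
        design = small_design(n_genes=1, ppg=5)
        mat = matrix_for(design, fill=12.0, empties=8.0)
        for j in range(n_below):
            mat.values.loc[f"g1_p{j + 1}"] = 9.0
        report = filter_expression_genes(mat, design, threshold=10.0)
        assert ("g1" in report.kept_genes) is kept

    def test_idempotent(self):
        design = small_design(n_genes=3, ppg=5)
        mat = matrix_for(design)
        mat.values.loc["g2_p1":"g2_p3"] = 0.0
        r1 = filter_expression_genes(mat, design, 10.0)
        kept = mat.copy_with(mat.values.loc[mat.values.index.isin(r1.kept_probes | set(design.empty_probe_ids))])
        r2 = filter_expression_genes(kept, design, 10.0)
        assert r1.kept_genes == r2.kept_genes


class TestNormexp:
    def test_sigma_zero_limit_is_subtract_and_floor(self):
        design = small_design()
        mat = matrix_for(design, fill=100.0, empties=10.0)
        mat = mat.copy_with(mat.values, scale="linear")
        with pytest.warns(RuntimeWarning):
            out = normexp_correct(mat, design, offset=5.0)
        gp = design.gene_probe_table["probe_id"]
        assert out.values.loc[gp].to_numpy() == pytest.approx(100.0 - 10.0 + 5.0)

    def test_outputs_strictly_positive(self):
        design = small_design()
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.normal(30, 10, size=(len(design.probe_ids), 4)).clip(0.01),
            index=design.probe_ids,
            columns=[f"s{i}" for i in range(4)],
        )
        vals.loc[design.empty_probe_ids] = rng.normal(20, 5, size=(2, 4)).clip(0.01)
        mat = IntensityMatrix(vals, scale="linear", channels="single")
        out = normexp_correct(mat, design, offset=0.0)
        assert (out.values.to_numpy() > 0).all()

    def test_conditional_mean_matches_quadrature(self):
        """E[S|X=x] against numerical integration of the posterior."""
        mu, sigma, theta = 0.0, 1.0, 10.0
        for x in (mu, mu + 2.0, mu - 3.0):
            def integrand_num(s):
                return s * np.exp(-s / theta) * stats.norm.pdf(x - s, mu, sigma)

            def integrand_den(s):
                return np.exp(-s / theta) * stats.norm.pdf(x - s, mu, sigma)

            num, _ = integrate.quad(integrand_num, 0, np.inf)
            den, _ = integrate.quad(integrand_den, 0, np.inf)
            expected = num / den
            got = _normexp_conditional_mean(np.array([x]), mu, sigma, theta)[0]
            assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_x(self):
        x = np.linspace(-5, 50, 200)
        y = _normexp_conditional_mean(x, 2.0, 1.5, 8.0)
        assert (np.diff(y) > 0).all()


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        design = small_design()
        mat = matrix_for(design)
        mat.values.iloc[:, :] = np.tile(
            np.linspace(8, 14, len(mat.values))[:, None], (1, 4)
        )
        out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_hand_worked_two_columns(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        mat = IntensityMatrix(values, scale="log2", channels="single")
        out = quantile_normalize(mat)
        assert list(out.values["a"]) == [1.5, 3.0, 4.5]
        assert list(out.values["b"]) == [1.5, 3.0, 4.5]

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.integers(3, 40), st.integers(2, 6))
    def test_sorted_columns_identical_and_ranks_preserved(self, seed, n, m):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"s{i}" for i in range(m)])
        mat = IntensityMatrix(values, scale="log2", channels="single")
        out = quantile_normalize(mat).values.to_numpy()
        ref = np.sort(out, axis=0)
        for j in range(1, m):
            np.testing.assert_allclose(ref[:, j], ref[:, 0], atol=1e-9)
            orig = values.iloc[:, j].to_numpy()
            assert (np.argsort(orig, kind="stable") == np.argsort(out[:, j], kind="stable")).all()

    def test_single_column_warns_identity(self):
        values = pd.DataFrame({"a": [1.0, 2.0]})
        mat = IntensityMatrix(values, scale="log2", channels="single")
        with pytest.warns(RuntimeWarning):
            out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out.values, values)


def medpolish_oracle(block, tol=1e-4, max_iter=10):
    """Scalar-loop median polish, independent of the vectorized code path."""
    import statistics

    b = [row[:] for row in block]
    P, S = len(b), len(b[0])
    overall, row, col = 0.0, [0.0] * P, [0.0] * S
    for _ in range(max_iter):
        deltas = []
        for i in range(P):
            d = statistics.median(b[i])
            deltas.append(abs(d))
            row[i] += d
            for j in range(S):
                b[i][j] -= d
        cm = statistics.median(col)
        overall += cm
        col = [c - cm for c in col]
        for j in range(S):
            d = statistics.median([b[i][j] for i in range(P)])
            deltas.append(abs(d))
            col[j] += d
            for i in range(P):
                b[i][j] -= d
        rm = statistics.median(row)
        overall += rm
        row = [r - rm for r in row]
        if max(deltas) < tol:
            break
    return [overall + c for c in col]


class TestMedianPolish:
    def test_single_probe_gene_is_identity(self):
        design = small_design(n_genes=1, ppg=1, empty=0)
        values = pd.DataFrame({"s0": [3.0], "s1": [5.0]}, index=["g1_p1"])
        mat = IntensityMatrix(values, scale="log2", channels="single")
        out = summarize_genes(mat, design)
        assert list(out.values.loc["g1"]) == [3.0, 5.0]

    def test_constant_block(self):
        overall, _, col, _ = median_polish(np.full((3, 4), 7.0))
        np.testing.assert_allclose(overall + col, 7.0)

    @pytest.mark.parametrize(
        "block",
        [
            [[1.0, 2.0], [3.0, 4.0]],
            [[1.0, 5.0, 2.0], [8.0, 1.0, 3.0], [4.0, 4.0, 4.0]],
            [[0.0, 1.0], [10.0, -3.0], [2.0, 2.0], [5.0, 5.0]],
        ],
    )
    def test_matches_independent_oracle(self, block):
        overall, _, col, _ = median_polish(np.array(block))
        np.testing.assert_allclose(overall + col, medpolish_oracle(block), atol=1e-10)

    def test_rank_one_block_recovers_sample_effects(self):
        rng = np.random.default_rng(5)
        gene, sample = 3.0, rng.normal(size=6)
        block = gene + np.zeros((5, 1)) + sample[None, :]
        overall, _, col, _ = median_polish(block)
        got = overall + col
        np.testing.assert_allclose(got - got[0], sample - sample[0], atol=1e-8)


class TestCghFilterAndRatios:
    def test_both_channels_must_clear_threshold(self):
        design = small_design(n_genes=1, ppg=2, empty=1)
        mat = matrix_for(design, fill=11.0, empties=9.0, channels="two")
        mat.values.loc["g1_p2", mat.channel_columns("cy5")] = 10.5
        report = filter_cgh_probes(mat, design, {"cy3": 10.7, "cy5": 10.7})
        assert report.kept_probes == {"g1_p1"}

    def test_minus_inf_thresholds_keep_everything(self):
        design = small_design()
        mat = matrix_for(design, channels="two")
        report = filter_cgh_probes(mat, design, {"cy3": -np.inf, "cy5": -np.inf})
        assert report.kept_probes == set(design.gene_probe_table["probe_id"])

    def test_log_ratios(self):
        design = small_design(n_genes=1, ppg=1, empty=0)
        values = pd.DataFrame(
            {"s0__cy3": [4.0], "s0__cy5": [2.0]}, index=["g1_p1"], dtype=float
        )
        mat = IntensityMatrix(values, scale="linear", channels="two")
        m = compute_log_ratios(mat)
        assert m.values.loc["g1_p1", "s0"] == pytest.approx(1.0)
        swapped = IntensityMatrix(
            values.rename(columns={"s0__cy3": "s0__cy5", "s0__cy5": "s0__cy3"}),
            scale="linear",
            channels="two",
        )
        assert compute_log_ratios(swapped).values.loc["g1_p1", "s0"] == pytest.approx(-1.0)

    def test_nonpositive_linear_intensity_rejected(self):
        values = pd.DataFrame({"s0__cy3": [0.0], "s0__cy5": [2.0]}, index=["p"])
        mat = IntensityMatrix(values, scale="linear", channels="two")
        with pytest.raises(ValueError, match="background-correct"):
            compute_log_ratios(mat)


class TestIntersectFilters:
    def test_identity_when_all_pass(self):
        design = small_design(n_genes=2, ppg=2, empty=0)
        from parasnail import FilterReport

        expr = FilterReport({"single": 10.0}, kept_genes={"g1", "g2"})
        cgh = FilterReport(
            {"cy3": 10.7, "cy5": 10.7},
            kept_probes={"g1_p1", "g1_p2", "g2_p1", "g2_p2"},
        )
        sets = intersect_filters(expr, cgh, design)
        assert set(sets.genes) == {"g1", "g2"}
        assert len(sets.probes) == 4

    def test_gene_with_no_cgh_probe_excluded(self):
        design = small_design(n_genes=2, ppg=2, empty=0)
        from parasnail import FilterReport

        expr = FilterReport({"single": 10.0}, kept_genes={"g1", "g2"})
        cgh = FilterReport({"cy3": 0, "cy5": 0}, kept_probes={"g2_p1"})
        sets = intersect_filters(expr, cgh, design)
        assert set(sets.genes) == {"g2"}
        assert set(sets.probes) == {"g2_p1"}

    def test_disjoint_sets_raise_pipeline_error(self):
        design = small_design(n_genes=2, ppg=2, empty=0)
        from parasnail import FilterReport

        expr = FilterReport({"single": 10.0}, kept_genes={"g1"})
        cgh = FilterReport({"cy3": 0, "cy5": 0}, kept_probes={"g2_p1"})
        with pytest.raises(PipelineError):
            intersect_filters(expr, cgh, design)
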