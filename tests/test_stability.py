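"""Entropy flatness and I-index reproducibility of stable-gene selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from braintx.models import ExpressionMatrix
from braintx.stability import (
    DegenerateColumnError,
    UndefinedEntropyError,
    flat_across_regions,
    i_index,
    reproducibility_resample,
    shannon_entropy,
    stable_within_region,
    stability_report,
)


def matrix_from_array(values, regions, subjects, gene_ids=None):
    sample_ids = [f"{s}.{r}" for s in subjects for r in regions]
    samples = pd.DataFrame(
        {
            "subject": [sid.split(".")[0] for sid in sample_ids],
            "region": [sid.split(".", 1)[1] for sid in sample_ids],
            "smoker": False,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(
        values,
        index=gene_ids or [f"g{i}" for i in range(len(values))],
        columns=samples.index,
    )
    return ExpressionMatrix(values=values, samples=samples)


class TestShannonEntropy:
    def test_uniform_vector_attains_maximum(self):
        h, norm = shannon_entropy([1.0] * 10)
        assert h == pytest.approx(math.log2(10), abs=1e-12)
        assert norm == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_vector_has_zero_entropy(self):
        h, norm = shannon_entropy([1, 0, 0, 0])
        assert h == 0.0 and norm == 0.0

    def test_half_half_is_one_bit(self):
        h, _ = shannon_entropy([0.5, 0.5, 0.0, 0.0])
        assert h == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_vector_is_an_error(self):
        with pytest.raises(UndefinedEntropyError):
            shannon_entropy([0.0, 0.0, 0.0])

    def test_short_or_negative_vectors_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.0])
        with pytest.raises(ValueError):
            shannon_entropy([1.0, -1.0])


class TestIIndex:
    def test_identical_columns_give_exactly_one(self):
        assert i_index([[3, 3], [1, 1], [7, 7]]) == 1.0

    def test_proportional_columns_give_exactly_one(self):
        assert i_index([[2, 1], [4, 2], [6, 3]]) == 1.0

    def test_diagonal_table_gives_zero(self):
        # joint [[.5,0],[0,.5]]: MI = 1 bit, H(row) = H(col) = 1 bit
        assert i_index([[10, 0], [0, 10]]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_column_raises(self):
        with pytest.raises(DegenerateColumnError):
            i_index([[1, 0], [2, 0]])

    def test_randomized_tables_stay_in_unit_interval(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            shape = (int(rng.integers(2, 8)), int(rng.integers(2, 8)))
            table = rng.gamma(1.0, 1.0, size=shape)
            assert 0.0 <= i_index(table) <= 1.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_column_rescaling_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        table = rng.gamma(1.0, 1.0, size=(4, 3)) + 1e-9
        scaled = table.copy()
        scaled[:, 1] *= scale
        assert i_index(scaled) == pytest.approx(i_index(table), abs=1e-9)


class TestFlatAcrossRegions:
    def test_planted_stable_selected_and_selective_rejected(self, expr, truth):
        out = flat_across_regions(expr)
        selected = set(out.index[out["selected"]])
        assert set(truth.stable_gene_ids) <= selected
        assert not (set(truth.selective_genes) & selected)

    def test_exactly_three_fpkm_everywhere_is_rejected(self):
        m = matrix_from_array([[3.0] * 6], ["r1", "r2", "r3"], ["s1", "s2"])
        out = flat_across_regions(m, min_fpkm=3.0)
        assert len(out) == 0  # strict > 3 FPKM

    def test_perfectly_equal_means_score_one(self):
        m = matrix_from_array([[10.0] * 6], ["r1", "r2", "r3"], ["s1", "s2"])
        out = flat_across_regions(m)
        assert out.loc["g0", "norm_entropy"] == pytest.approx(1.0)
        assert bool(out.loc["g0", "selected"])


class TestStableWithinRegion:
    def test_stable_genes_selected_in_every_region(self, expr, truth):
        for region in truth.regions:
            out = stable_within_region(expr, region)
            assert set(truth.stable_gene_ids) <= set(out.index[out["selected"]])

    def test_single_subject_expression_scores_zero_entropy(self):
        m = matrix_from_array(
            [[40.0, 0.0, 0.0, 0.0]], ["r1"], ["s1", "s2", "s3", "s4"]
        )
        out = stable_within_region(m, "r1")
        assert out.loc["g0", "norm_entropy"] == 0.0
        assert not bool(out.loc["g0", "selected"])

    def test_subject_permutation_leaves_result_unchanged(self, expr):
        out1 = stable_within_region(expr, expr.regions[0])
        perm = expr.values.sample(frac=1.0, axis=1, random_state=3)
        m2 = ExpressionMatrix(values=perm, samples=expr.samples.loc[perm.columns])
        out2 = stable_within_region(m2, expr.regions[0])
        pd.testing.assert_series_equal(
            out1["norm_entropy"].sort_index(), out2["norm_entropy"].sort_index()
        )

    def test_unknown_region_raises_key_error(self, expr):
        with pytest.raises(KeyError):
            stable_within_region(expr, "nonexistent")


class TestReproducibilityResample:
    def test_exactly_proportional_subjects_give_min_one(self):
        regions = [f"r{i}" for i in range(5)]
        subjects = [f"s{j}" for j in range(4)]
        base = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        # one gene whose expression is proportional across all subjects
        vals = np.empty((1, 20))
        for j in range(4):
            vals[0, j * 5:(j + 1) * 5] = base * (1.0, 2.0, 0.5, 3.0)[j]
        m = matrix_from_array(vals, regions, subjects)
        out = reproducibility_resample(m, k_values=[2, 3], seed=0)
        assert out.loc["g0", "min_i_index"] == 1.0

    def test_same_seed_reproduces_min_i_index(self, expr):
        a = reproducibility_resample(expr, k_values=[2, 3], seed=5)
        b = reproducibility_resample(expr, k_values=[2, 3], seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_stable_rank_above_noisy(self, expr, truth):
        out = reproducibility_resample(expr, k_values=[2, 3, 4], seed=2)
        stable_scores = out.loc[
            [g for g in truth.stable_gene_ids if g in out.index], "min_i_index"
        ]
        others = out.drop(stable_scores.index)["min_i_index"].dropna()
        assert stable_scores.min() > others.median()

    def test_k_exceeding_subjects_raises(self, expr):
        with pytest.raises(ValueError):
            reproducibility_resample(expr, k_values=[len(expr.subjects)])


def test_parameter_recovery_of_planted_stable_genes(expr, truth):
    """>=95% of planted stable genes sit in the intersection of the
    flatness selection and the top-2N of the resampled I-index ranking."""
    n = len(truth.stable_gene_ids)
    flat = flat_across_regions(expr)
    rep = reproducibility_resample(expr, seed=1)
    top = set(rep.index[: 2 * n])
    flat_sel = set(flat.index[flat["selected"]])
    recovered = set(truth.stable_gene_ids) & top & flat_sel
    assert len(recovered) >= 0.95 * n


def test_stability_report_bundles_all_flags(expr, truth):
    rep = stability_report(expr, seed=0, i_index_threshold=0.9)
    assert {"mean_fpkm", "norm_entropy", "flat_across_regions",
            "min_i_index", "reproducible"} <= set(rep.columns)
    stable = rep.loc[truth.stable_gene_ids]
    assert stable["flat_across_regions"].all()
    for region in truth.regions:
        assert stable[f"stable_in_{region}"].all()
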