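"""Cohort normalization, ratio-median scoring and MYC-high/low classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycsig import (
    DEFAULT_SIGNATURE,
    MYC_HIGH,
    MYC_LOW,
    ExpressionValidationError,
    MycScoreResult,
    SignatureDefinition,
    classify,
    cohort_normalize,
    score_cohort,
    score_table,
)
from conftest import make_matrix

MINI = SignatureDefinition(up_genes=("u1",), down_genes=("d1",), housekeeping_genes=("h1",))


def naive_scores(values, sig, genes, samples):
    """Triple-loop reference: normalize, form ratios sample-by-sample, median."""
    df = pd.DataFrame(values, index=genes, columns=samples)
    norm = {}
    for g in sig.signature_genes:
        row = df.loc[g]
        norm[g] = 100.0 * row / row.sum()
    out = {}
    for s in samples:
        ratios = []
        for u in sig.up_genes:
            for d in sig.down_genes:
                ratios.append(norm[u][s] / norm[d][s])
        out[s] = float(np.median(ratios))
    return out


class TestSignatureDefinition:
    def test_default_counts(self):
        assert len(DEFAULT_SIGNATURE.up_genes) == 10
        assert len(DEFAULT_SIGNATURE.down_genes) == 6
        assert DEFAULT_SIGNATURE.n_ratios == 60

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SignatureDefinition(up_genes=("A", "B"), down_genes=("B",))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SignatureDefinition(up_genes=())

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sig.yaml"
        DEFAULT_SIGNATURE.to_yaml(str(path))
        assert SignatureDefinition.from_yaml(str(path)) == DEFAULT_SIGNATURE


class TestCohortNormalize:
    def test_row_already_summing_to_100_unchanged(self):
        m = make_matrix([[30.0, 70.0], [80.0, 20.0], [1.0, 1.0]],
                        genes=["u1", "d1", "h1"])
        out = cohort_normalize(m, MINI)
        np.testing.assert_allclose(out.data.loc["u1"], [30.0, 70.0], atol=1e-12)

    def test_quarter_three_quarter_split(self):
        m = make_matrix([[1.0, 3.0], [2.0, 2.0]], genes=["u1", "d1"])
        out = cohort_normalize(m, MINI)
        np.testing.assert_allclose(out.data.loc["u1"], [25.0, 75.0], atol=1e-12)

    def test_single_sample_forces_100(self):
        m = make_matrix([[42.0], [7.0]], genes=["u1", "d1"])
        out = cohort_normalize(m, MINI)
        np.testing.assert_allclose(out.values, [[100.0], [100.0]], atol=1e-12)

    def test_rows_sum_to_100(self, random_cohort):
        out = cohort_normalize(random_cohort, DEFAULT_SIGNATURE)
        np.testing.assert_allclose(out.values.sum(axis=1),
                                   np.full(16, 100.0), rtol=1e-9)

    def test_output_restricted_to_signature(self, random_cohort):
        out = cohort_normalize(random_cohort, DEFAULT_SIGNATURE)
        assert out.genes == list(DEFAULT_SIGNATURE.signature_genes)

    def test_missing_gene_listed(self, random_cohort):
        m = make_matrix(random_cohort.values[2:], genes=random_cohort.genes[2:],
                        samples=random_cohort.samples)
        with pytest.raises(ExpressionValidationError, match="CAD"):
            cohort_normalize(m, DEFAULT_SIGNATURE)

    def test_zero_row_sum_names_gene(self):
        m = make_matrix([[0.0, 0.0], [1.0, 2.0]], genes=["u1", "d1"])
        with pytest.raises(ExpressionValidationError, match="u1"):
            cohort_normalize(m, MINI)


class TestScoreCohort:
    def test_worked_mini_example(self):
        """Raw up [30,70] / down [80,20]: scores 0.375 and 3.5, low then high."""
        m = make_matrix([[30.0, 70.0], [80.0, 20.0]], genes=["u1", "d1"],
                        samples=["S1", "S2"])
        res = score_cohort(m, MINI)
        assert res[0].score == pytest.approx(0.375, abs=1e-15)
        assert res[1].score == pytest.approx(3.5, abs=1e-15)
        assert [r.label for r in res] == [MYC_LOW, MYC_HIGH]

    def test_single_sample_all_ratios_one(self):
        genes = list(DEFAULT_SIGNATURE.signature_genes)
        m = make_matrix(np.arange(1.0, 17.0).reshape(-1, 1), genes=genes)
        with pytest.warns(UserWarning, match="threshold"):
            res = score_cohort(m)
        assert res[0].score == pytest.approx(1.0)
        assert res[0].ratios == tuple([1.0] * 60)
        assert res[0].label == MYC_LOW

    def test_identical_genes_score_one(self, rng):
        base = rng.gamma(2.0, 100.0, size=8)
        genes = list(DEFAULT_SIGNATURE.signature_genes)
        m = make_matrix(np.tile(base, (16, 1)), genes=genes)
        with pytest.warns(UserWarning, match="threshold"):
            res = score_cohort(m)
        for r in res:
            assert r.score == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_triple_loop(self, random_cohort):
        res = score_cohort(random_cohort)
        expected = naive_scores(random_cohort.values, DEFAULT_SIGNATURE,
                                random_cohort.genes, random_cohort.samples)
        for r in res:
            assert r.score == pytest.approx(expected[r.sample], abs=1e-12)
            assert len(r.ratios) == 60

    def test_ratio_order_up_major(self):
        sig = SignatureDefinition(up_genes=("u1", "u2"), down_genes=("d1", "d2"),
                                  housekeeping_genes=("h1",))
        m = make_matrix([[10.0, 10.0], [20.0, 20.0], [40.0, 40.0], [5.0, 5.0]],
                        genes=["u1", "u2", "d1", "d2"])
        with pytest.warns(UserWarning):
            res = score_cohort(m, sig)
        # normalized values are 50 each; ratios follow u1/d1, u1/d2, u2/d1, u2/d2
        assert res[0].ratios == (1.0, 1.0, 1.0, 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_gene_scale_invariance(self, seed):
        """Multiplying one gene row by a positive constant changes no score."""
        rng = np.random.default_rng(seed)
        genes = list(DEFAULT_SIGNATURE.signature_genes)
        values = rng.gamma(3.0, 200.0, size=(16, 6)) + 1.0
        m = make_matrix(values, genes=genes)
        base = [r.score for r in score_cohort(m)]
        i = int(rng.integers(0, 16))
        c = float(rng.uniform(0.01, 100.0))
        bumped = values.copy()
        bumped[i] *= c
        pert = [r.score for r in score_cohort(make_matrix(bumped, genes=genes))]
        np.testing.assert_allclose(pert, base, atol=1e-10)

    def test_swap_antisymmetry_odd_ratio_count(self, rng):
        """Exchanging up and down genes inverts each score when |up|x|down| is odd."""
        sig = SignatureDefinition(up_genes=("u1", "u2", "u3"), down_genes=("d1",),
                                  housekeeping_genes=("h1",))
        swapped = SignatureDefinition(up_genes=("d1",), down_genes=("u1", "u2", "u3"),
                                      housekeeping_genes=("h1",))
        values = rng.gamma(3.0, 100.0, size=(4, 5)) + 1.0
        m = make_matrix(values, genes=["u1", "u2", "u3", "d1"])
        s = np.array([r.score for r in score_cohort(m, sig)])
        s_swap = np.array([r.score for r in score_cohort(m, swapped)])
        np.testing.assert_allclose(s_swap, 1.0 / s, rtol=1e-12)

    def test_monotone_in_up_gene(self, rng):
        """Raising one sample's up-gene count never lowers its own score and
        never raises any other sample's score."""
        genes = list(DEFAULT_SIGNATURE.signature_genes)
        values = rng.gamma(3.0, 200.0, size=(16, 6)) + 1.0
        m = make_matrix(values, genes=genes)
        base = np.array([r.score for r in score_cohort(m)])
        bumped = values.copy()
        bumped[0, 2] *= 3.0  # raise sample 2's CAD
        new = np.array([r.score for r in score_cohort(make_matrix(bumped, genes=genes))])
        assert new[2] >= base[2] - 1e-12
        others = np.delete(np.arange(6), 2)
        assert (new[others] <= base[others] + 1e-12).all()

    def test_reference_sums_reproduce_cohort_scale(self, random_cohort):
        """Scoring one sample against stored cohort sums matches its in-cohort
        normalized values."""
        sums = random_cohort.data.loc[list(DEFAULT_SIGNATURE.signature_genes)].sum(axis=1)
        full = cohort_normalize(random_cohort, DEFAULT_SIGNATURE)
        one = make_matrix(random_cohort.values[:, :1], genes=random_cohort.genes,
                          samples=[random_cohort.samples[0]])
        solo = cohort_normalize(one, DEFAULT_SIGNATURE, reference_sums=sums)
        np.testing.assert_allclose(solo.values[:, 0], full.values[:, 0], rtol=1e-12)


class TestClassify:
    @pytest.mark.parametrize("score,label", [(3.5, MYC_HIGH), (0.375, MYC_LOW),
                                             (1.0 + 1e-9, MYC_HIGH)])
    def test_threshold_rule(self, score, label):
        assert classify(score) == label

    def test_tie_is_low_with_warning(self):
        with pytest.warns(UserWarning, match="threshold"):
            assert classify(1.0) == MYC_LOW

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            classify(0.0)


class TestScoreTable:
    def _result(self, sample, score):
        label = MYC_HIGH if score > 1 else MYC_LOW
        return MycScoreResult(sample, (score,), score, label)

    def test_counts_and_percentages(self):
        table, summary = score_table([self._result("a", 3.5), self._result("b", 0.375)])
        assert list(table["sample"]) == ["a", "b"]
        assert dict(zip(summary["label"], summary["n"])) == {MYC_HIGH: 1, MYC_LOW: 1}
        assert set(summary["percent"]) == {50.0}

    def test_24_sample_split_percentages(self, rng):
        scores = [1.5] * 11 + [0.5] * 13
        results = [self._result(f"P{i}", s) for i, s in enumerate(scores)]
        _, summary = score_table(results)
        pct = dict(zip(summary["label"], summary["percent"]))
        assert pct[MYC_HIGH] == 45.8
        assert pct[MYC_LOW] == 54.2

    def test_descending_order_matches_independent_sort(self, rng):
        scores = rng.uniform(0.2, 5.0, size=20)
        results = [self._result(f"P{i}", float(s)) for i, s in enumerate(scores)]
        table, _ = score_table(results)
        assert list(table["score"]) == sorted(scores, reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            score_table([])
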