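"""Rank test, BH correction, response construction, and error scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from compobench import (
    ScenarioSpec,
    TruthTable,
    bh_adjust,
    clr_transform,
    default_design,
    detect_responders,
    error_rates,
    kruskal_wallis,
    kruskal_wallis_matrix,
    per_subject_response,
    simulate_cohort_study,
)
from compobench.community import BASELINE, POST
from compobench.normalization import NormalizedMatrix, as_absolute


def _norm_from(base, post, design, method="absolute"):
    values = pd.concat(
        [
            pd.DataFrame(base, columns=design.sample_names(BASELINE)),
            pd.DataFrame(post, columns=design.sample_names(POST)),
        ],
        axis=1,
    )
    values.index = [f"t{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(values=values, method=method)


class TestPerSubjectResponse:
    def test_identical_timepoints_give_zero_change(self):
        design = default_design(2)
        x = np.random.default_rng(0).lognormal(1, 1, size=(5, 4))
        norm = _norm_from(x, x, design)
        resp = per_subject_response(norm, design)
        np.testing.assert_allclose(resp.to_numpy(), 0.0, atol=1e-12)
        assert list(resp.columns) == list(design.subject_ids)

    def test_clr_change_is_difference_of_clr_values(self):
        design = default_design(2)
        rng = np.random.default_rng(1)
        base = rng.integers(1, 100, size=(6, 4)).astype(float)
        post = rng.integers(1, 100, size=(6, 4)).astype(float)
        norm = _norm_from(base, post, design)
        clr_all = clr_transform(norm.values, pseudocount=0.0)
        resp = per_subject_response(clr_all, design)
        expected = (
            clr_all.values[design.sample_names(POST)].to_numpy()
            - clr_all.values[design.sample_names(BASELINE)].to_numpy()
        )
        np.testing.assert_allclose(resp.to_numpy(), expected, atol=1e-12)

    def test_doubling_effect_gives_log_two_change_on_absolute_scale(self):
        design = default_design(2)
        base = np.full((3, 4), 10.0)
        post = base.copy()
        post[0, 2:] *= 2.0  # up-responder, treatment subjects only, no noise
        resp = per_subject_response(_norm_from(base, post, design), design)
        np.testing.assert_allclose(resp.to_numpy()[0, 2:], np.log(2.0), atol=1e-12)
        np.testing.assert_allclose(resp.to_numpy()[0, :2], 0.0, atol=1e-12)

    def test_post_only_mode_returns_post_values(self):
        design = default_design(2)
        base = np.ones((2, 4))
        post = np.arange(8.0).reshape(2, 4) + 1
        resp = per_subject_response(_norm_from(base, post, design), design, mode="post_only")
        np.testing.assert_array_equal(resp.to_numpy(), post)

    def test_missing_timepoint_rejected(self):
        design = default_design(2)
        norm = _norm_from(np.ones((2, 4)), np.ones((2, 4)), design)
        truncated = NormalizedMatrix(values=norm.values.iloc[:, :-1], method="absolute")
        with pytest.raises(ValueError):
            per_subject_response(truncated, design)


class TestKruskalWallis:
    def test_textbook_two_group_example(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(3.857142857142854, abs=1e-12)
        assert p == pytest.approx(0.049534613435627, abs=1e-12)

    def test_total_tie_convention(self):
        h, p = kruskal_wallis([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert (h, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])

    @pytest.mark.parametrize("tie_heavy", [False, True])
    def test_vectorized_rows_match_scipy(self, tie_heavy):
        rng = np.random.default_rng(12)
        if tie_heavy:
            X = rng.integers(0, 4, size=(200, 20)).astype(float)
        else:
            X = rng.normal(size=(200, 20))
        mask = np.zeros(20, dtype=bool)
        mask[10:] = True
        h, p = kruskal_wallis_matrix(X, mask)
        for i in range(X.shape[0]):
            row = X[i]
            if np.all(row == row[0]):
                assert h[i] == 0.0 and p[i] == 1.0
                continue
            hs, ps = stats.kruskal(row[~mask], row[mask])
            assert h[i] == pytest.approx(hs, abs=1e-10)
            assert p[i] == pytest.approx(ps, abs=1e-10)

    def test_flags_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 20))
        mask = np.arange(20) >= 10
        _, p0 = kruskal_wallis_matrix(X, mask)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
            _, p1 = kruskal_wallis_matrix(f(X), mask)
            np.testing.assert_allclose(p0, p1, atol=1e-12)


class TestBH:
    def test_step_up_collapse_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04, atol=1e-12)

    def test_single_and_constant_inputs(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.2] * 7), 0.2, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_hand_rolled_step_up_rule(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=101)

        def step_up(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, pvals[i] * m / rank)
                adj[i] = running
            return adj

        np.testing.assert_allclose(bh_adjust(p), step_up(p), atol=1e-12)
        # adjusted values never drop below raw ones
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestDetectResponders:
    def test_constant_taxa_never_flagged(self):
        design = default_design(5)
        values = np.ones((10, 10))
        norm = _norm_from(values, values, design)
        res = detect_responders(norm, design)
        assert not res["flagged"].any()
        assert (res["padj"] == 1.0).all()

    def test_matches_per_taxon_reference_pipeline(self):
        """End-to-end flags equal a scalar scipy + step-up reference."""
        spec = ScenarioSpec("unidirectional", 1.0, 0.25)
        abund, truth, design = simulate_cohort_study(spec, np.random.default_rng(21))
        norm = as_absolute(abund)
        res = detect_responders(norm, design)

        resp = per_subject_response(norm, design)
        in_t = np.array([g == "t" for g in design.group_labels])
        pvals = []
        for i in range(resp.shape[0]):
            row = resp.to_numpy()[i]
            pvals.append(stats.kruskal(row[~in_t], row[in_t]).pvalue)
        padj = bh_adjust(np.array(pvals))
        np.testing.assert_allclose(res["pvalue"].to_numpy(), pvals, atol=1e-10)
        np.testing.assert_array_equal(res["flagged"].to_numpy(), padj < 0.1)


class TestErrorRates:
    def _truth(self, n, responders):
        flags = np.zeros(n, dtype=bool)
        flags[:responders] = True
        direction = np.where(flags, 1, 0)
        return TruthTable(responder=flags, direction=direction)

    def test_perfect_detection_scores_zero(self):
        truth = self._truth(100, 25)
        r = error_rates(truth.responder, truth)
        assert (r.fp_rate, r.fn_rate) == (0.0, 0.0)
        assert r.tp + r.fp + r.tn + r.fn == 100

    def test_nothing_flagged_conventions(self):
        truth = self._truth(100, 25)
        none = np.zeros(100, dtype=bool)
        half = error_rates(none, truth)  # default: errors / (2 x class size)
        assert half.fn_rate == pytest.approx(0.5)
        assert half.fp_rate == 0.0
        total = error_rates(none, truth, convention="total_taxa")
        assert total.fn_rate == pytest.approx(0.25)

    def test_everything_flagged_conventions(self):
        truth = self._truth(100, 50)
        every = np.ones(100, dtype=bool)
        assert error_rates(every, truth).fp_rate == pytest.approx(0.5)
        assert error_rates(every, truth, convention="total_taxa").fp_rate == pytest.approx(0.5)
        assert error_rates(every, truth).fn_rate == 0.0

    def test_empty_classes_define_zero_rates(self):
        truth = self._truth(10, 0)
        r = error_rates(np.zeros(10, dtype=bool), truth)
        assert r.fn_rate == 0.0

    def test_length_mismatch_rejected(self):
        truth = self._truth(10, 2)
        with pytest.raises(ValueError):
            error_rates(np.zeros(9, dtype=bool), truth)

    def test_rates_bounded(self):
        rng = np.random.default_rng(0)
        truth = self._truth(40, 10)
        for _ in range(20):
            flags = rng.uniform(size=40) < 0.5
            r = error_rates(flags, truth)
            assert 0.0 <= r.fp_rate <= 0.5
            assert 0.0 <= r.fn_rate <= 0.5
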