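"""Bootstrap ensemble and stability summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stablasso.bootstrap import (
    BootstrapConfig,
    BootstrapEnsemble,
    EmptyEnsembleError,
    bootstrap_ensemble,
    summarize_stability,
)


def _fake_ensemble(or_draws, names=None):
    or_draws = np.asarray(or_draws, dtype=float)
    sel = (or_draws != 1.0).astype(np.int8)
    B, p = or_draws.shape
    names = names or [f"x{j + 1}" for j in range(p)]
    return BootstrapEnsemble(
        B=B, selection=sel, or_draws=or_draws, lambdas=np.zeros(B),
        master_seed=0, redraw_count=0, column_names=names,
    )


@pytest.fixture(scope="module")
def noise_design():
    rng = np.random.default_rng(77)
    X = rng.standard_normal((100, 5))
    X = (X - X.mean(0)) / X.std(0)
    y = (rng.random(100) < 0.4).astype(float)
    return X, y


class TestSummaryArithmetic:
    def test_vip_from_selection_counts(self):
        draws = np.ones((500, 1))
        draws[:450, 0] = 1.5
        recs = summarize_stability(_fake_ensemble(draws))
        assert recs[0].vip == pytest.approx(90.0)
        assert recs[0].selected

    def test_never_selected_gives_unit_or_and_degenerate_ci(self):
        recs = summarize_stability(_fake_ensemble(np.ones((200, 1))))
        r = recs[0]
        assert r.vip == 0.0 and r.mean_or == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)
        assert r.direction == "none" and not r.selected

    def test_threshold_case_100x1_400x12(self):
        draws = np.ones((500, 1))
        draws[100:, 0] = 1.2
        recs = summarize_stability(_fake_ensemble(draws))
        r = recs[0]
        assert r.vip == pytest.approx(80.0)
        assert r.selected  # at-threshold counts as selected
        assert r.mean_or == pytest.approx(1.16)
        assert r.ci_low == pytest.approx(1.0)
        assert r.ci_high == pytest.approx(1.2)
        assert r.direction == "positive"

    def test_mean_or_within_draw_range(self):
        rng = np.random.default_rng(4)
        draws = np.exp(rng.normal(0, 0.5, size=(100, 3)))
        for r in summarize_stability(_fake_ensemble(draws)):
            lo, hi = draws[:, int(r.variable[1:]) - 1].min(), draws[:, int(r.variable[1:]) - 1].max()
            assert lo <= r.mean_or <= hi

    def test_null_dilution_identity(self):
        """mean OR − 1 equals (VIP/100) × (selected-only mean OR − 1)."""
        draws = np.ones((50, 1))
        draws[:20, 0] = 1.8
        r = summarize_stability(_fake_ensemble(draws))[0]
        sel_mean = 1.8
        assert (r.mean_or - 1.0) == pytest.approx((r.vip / 100.0) * (sel_mean - 1.0))

    def test_ci_matches_exponentiated_coefficient_percentiles(self):
        rng = np.random.default_rng(9)
        draws = np.exp(rng.normal(0.2, 0.4, size=(500, 1)))
        r = summarize_stability(_fake_ensemble(draws))[0]
        lo_log = np.exp(np.percentile(np.log(draws[:, 0]), 2.5))
        hi_log = np.exp(np.percentile(np.log(draws[:, 0]), 97.5))
        assert r.ci_low == pytest.approx(lo_log, rel=2e-3)
        assert r.ci_high == pytest.approx(hi_log, rel=2e-3)

    def test_variable_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        draws = np.exp(rng.normal(0, 0.3, size=(60, 4)))
        recs = summarize_stability(_fake_ensemble(draws))
        perm = [2, 0, 3, 1]
        recs_p = summarize_stability(
            _fake_ensemble(draws[:, perm], names=[f"x{j + 1}" for j in perm])
        )
        by_name = {r.variable: r for r in recs}
        for r in recs_p:
            assert r.vip == by_name[r.variable].vip
            assert r.mean_or == by_name[r.variable].mean_or

    def test_resample_order_invariance(self):
        rng = np.random.default_rng(11)
        draws = np.exp(rng.normal(0, 0.3, size=(60, 2)))
        a = summarize_stability(_fake_ensemble(draws))
        b = summarize_stability(_fake_ensemble(draws[rng.permutation(60)]))
        for ra, rb in zip(a, b):
            assert ra.vip == rb.vip and ra.mean_or == pytest.approx(rb.mean_or)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(2, 40), st.integers(1, 4)),
            elements=st.floats(-1.5, 1.5),
        ),
        st.integers(0, 100),
    )
    def test_summary_invariants_hold_for_any_ensemble(self, coefs, thresh):
        """CI ordering, mean-OR range, VIP bounds and the direction rule
        hold for arbitrary coefficient draws."""
        draws = np.exp(coefs)
        recs = summarize_stability(_fake_ensemble(draws), vip_threshold=float(thresh))
        for j, r in enumerate(recs):
            assert 0.0 <= r.vip <= 100.0
            assert r.ci_low <= r.ci_high
            assert draws[:, j].min() - 1e-12 <= r.mean_or <= draws[:, j].max() + 1e-12
            if r.direction == "positive":
                assert r.selected and r.mean_or > 1.0
            elif r.direction == "negative":
                assert r.selected and r.mean_or < 1.0
            else:
                assert not r.selected or r.mean_or == 1.0

    def test_empty_ensemble_raises(self):
        ens = _fake_ensemble(np.ones((1, 1)))
        ens.B = 0
        ens.selection = ens.selection[:0]
        ens.or_draws = ens.or_draws[:0]
        with pytest.raises(EmptyEnsembleError):
            summarize_stability(ens)


class TestEnsemble:
    def test_deterministic_given_master_seed(self, noise_design):
        a = bootstrap_ensemble(noise_design, B=8, master_seed=42)
        b = bootstrap_ensemble(noise_design, B=8, master_seed=42)
        np.testing.assert_array_equal(a.selection, b.selection)
        np.testing.assert_array_equal(a.or_draws, b.or_draws)
        np.testing.assert_array_equal(a.lambdas, b.lambdas)

    def test_single_resample_vip_is_zero_or_hundred(self, noise_design):
        ens = bootstrap_ensemble(noise_design, B=1, master_seed=3)
        for r in summarize_stability(ens):
            assert r.vip in (0.0, 100.0)

    def test_selection_iff_or_not_one(self, noise_design):
        ens = bootstrap_ensemble(noise_design, B=10, master_seed=5)
        np.testing.assert_array_equal(ens.selection == 0, ens.or_draws == 1.0)
        assert (ens.or_draws > 0).all()

    def test_pure_noise_vip_below_hundred(self, noise_design):
        """CV must discard pure-noise predictors in at least one resample."""
        ens = bootstrap_ensemble(noise_design, B=50, master_seed=7)
        for r in summarize_stability(ens):
            assert r.vip < 100.0

    def test_single_class_resamples_redrawn(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((12, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = np.zeros(12)
        y[:3] = 1.0  # minority of 3: single-class resamples are common
        ens = bootstrap_ensemble((X, y), B=30, master_seed=2,
                                 config=BootstrapConfig(cv_folds=2))
        assert ens.redraw_count > 0

    def test_constant_column_in_resample_frozen(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 3))
        X = (X - X.mean(0)) / X.std(0)
        X[:, 2] = 0.0
        X[0, 2] = 5.0  # rare spike: often absent from a resample
        y = (rng.random(30) < 0.5).astype(float)
        if y.min() == y.max():
            y[0] = 1.0 - y[0]
        ens = bootstrap_ensemble((X, y), B=20, master_seed=9,
                                 config=BootstrapConfig(cv_folds=3))
        # resamples without the spike must report the column unselected
        assert (ens.or_draws[:, 2] == 1.0).any()

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ensemble((np.empty((10, 0)), np.r_[np.ones(5), np.zeros(5)]), B=2)

    def test_ensemble_persists_and_reloads(self, noise_design, tmp_path):
        import pandas as pd

        ens = bootstrap_ensemble(noise_design, B=5, master_seed=1)
        ens.to_tsv(tmp_path)
        sel = pd.read_csv(tmp_path / "ensemble_selection.tsv", sep="\t", index_col=0)
        ors = pd.read_csv(tmp_path / "ensemble_or.tsv", sep="\t", index_col=0)
        np.testing.assert_array_equal(sel.to_numpy(), ens.selection)
        np.testing.assert_allclose(ors.to_numpy(), ens.or_draws)
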