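"""Tests for OOB perturbation, EPE decomposition, zeta and the grid search."""

import numpy as np
import pytest

from decodemap import (
    ToyConfig,
    epe_bias_variance,
    evaluate_lambda,
    make_toy,
    normalize_map,
    oob_partitions,
    scalarize,
    select_model,
)
from conftest import gaussian_dataset


class TestOobPartitions:
    def test_determinism(self):
        a = oob_partitions(5, 3, seed=42)
        b = oob_partitions(5, 3, seed=42)
        for (ia, oa), (ib, ob) in zip(a.partitions, b.partitions):
            np.testing.assert_array_equal(ia, ib)
            np.testing.assert_array_equal(oa, ob)

    def test_oob_fraction_approaches_e_inverse(self):
        plan = oob_partitions(1000, 50, seed=7)
        frac = np.mean([len(oob) / 1000 for _, oob in plan.partitions])
        assert frac == pytest.approx(np.exp(-1.0), abs=0.03)

    def test_in_bag_size_and_nonempty_oob(self):
        plan = oob_partitions(2, 200, seed=1)
        for in_bag, oob in plan.partitions:
            assert len(in_bag) == 2
            assert len(oob) >= 1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            oob_partitions(1, 5, seed=0)


class TestEpeBiasVariance:
    def test_all_correct(self):
        epe, bias, var = epe_bias_variance([[1, 1, 1], [-1, -1]], [1, -1])
        assert (epe, bias, var) == (0.0, 0.0, 0.0)

    def test_all_wrong_is_pure_bias(self):
        epe, bias, var = epe_bias_variance([[-1] * 50], [1])
        assert (epe, bias, var) == (1.0, 1.0, 0.0)

    def test_split_vote(self):
        preds = [[1] * 30 + [-1] * 20]
        epe, bias, var = epe_bias_variance(preds, [1])
        assert bias == 0.0
        assert var == pytest.approx(0.4)
        assert epe == pytest.approx(0.4)

    def test_tie_breaks_positive(self):
        epe, bias, var = epe_bias_variance([[1, -1]], [1])
        assert bias == 0.0  # main prediction is +1 on a tie

    def test_never_oob_rejected(self):
        with pytest.raises(ValueError, match="never out-of-bag"):
            epe_bias_variance([[1], []], [1, -1])

    def test_pooled_loss_identity(self, rng):
        """EPE equals the event-weighted sum of bias plus signed variance."""
        for _ in range(20):
            n = int(rng.integers(3, 30))
            truth = np.where(rng.random(n) < 0.5, 1, -1)
            preds = [
                list(np.where(rng.random(int(rng.integers(1, 40))) < 0.6,
                              truth[i], -truth[i]))
                for i in range(n)
            ]
            epe, _, _ = epe_bias_variance(preds, truth)
            events = np.array([len(p) for p in preds], float)
            w = events / events.sum()
            contrib = []
            for i in range(n):
                p = np.asarray(preds[i])
                main = 1 if p.sum() >= 0 else -1
                b = float(main != truth[i])
                v = float(np.mean(p != main))
                contrib.append(b + (1.0 - 2.0 * b) * v)
            assert epe == pytest.approx(float(w @ np.array(contrib)),
                                        abs=1e-12)


class TestScalarize:
    def test_threshold_filters_poor_performance(self):
        assert scalarize(0.9, 0.55, 1, 1, 0.6) == 0.0

    def test_weighted_average_above_threshold(self):
        assert scalarize(1.0, 0.9292) == pytest.approx(0.9646)
        assert scalarize(0.4484, 0.9884) == pytest.approx(0.7184)

    def test_equal_objectives_collapse_to_delta(self):
        assert scalarize(0.8, 0.8) == pytest.approx(0.8)

    def test_monotone_in_interpretability(self):
        vals = [scalarize(e, 0.9) for e in (0.1, 0.4, 0.7, 1.0)]
        assert vals == sorted(vals)

    def test_invalid_weights_and_kappa(self):
        with pytest.raises(ValueError):
            scalarize(0.5, 0.9, 0, 0)
        with pytest.raises(ValueError):
            scalarize(0.5, 0.9, kappa=1.5)


class TestEvaluateLambda:
    def test_single_replicate_has_unit_reproducibility(self, rng):
        data = gaussian_dataset(rng, n=60, p=4, separation=2.0)
        plan = oob_partitions(data.n, 1, seed=3)
        row = evaluate_lambda(data, 1.0, plan, normalize_map(np.ones(4)))
        assert row.psi == pytest.approx(1.0, abs=1e-12)

    def test_all_degenerate_reports_zeta_zero(self, rng):
        data = gaussian_dataset(rng, n=40, p=4, separation=0.1)
        plan = oob_partitions(data.n, 5, seed=3)
        row = evaluate_lambda(data, 1e6, plan, normalize_map(np.ones(4)))
        assert row.degenerate_count == 5
        assert row.zeta == 0.0
        assert np.isnan(row.eta_tilde)


class TestSelectModel:
    def test_singleton_grid_returns_that_value(self, rng):
        data = gaussian_dataset(rng, n=80, p=4, separation=2.0)
        table = select_model(data, [5.0], m=8, seed=1)
        assert table.chosen_lambda == 5.0

    def test_same_seed_bit_identical(self, rng):
        data = gaussian_dataset(rng, n=60, p=4, separation=1.5)
        t1 = select_model(data, [1.0, 10.0, 100.0], m=6, seed=9)
        t2 = select_model(data, [1.0, 10.0, 100.0], m=6, seed=9)
        assert t1.to_dataframe().equals(t2.to_dataframe())
        assert t1.chosen_lambda == t2.chosen_lambda

    def test_inadmissible_when_labels_are_noise(self, rng):
        X = rng.normal(size=(60, 4))
        labels = np.where(rng.random(60) < 0.5, 1, -1)
        from decodemap import EpochedDataset

        data = EpochedDataset(X, labels)
        table = select_model(data, [1.0, 10.0], m=10, seed=2, kappa=0.95)
        assert not table.admissible
        assert table.chosen_lambda is None
        assert table.advisory_lambda in (1.0, 10.0)

    def test_toy_dissociation_of_accuracy_and_interpretability(self):
        """The most accurate toy model is not the most interpretable one:
        delta peaks before the sparse end while eta peaks at it."""
        data, true_map = make_toy(ToyConfig(seed=5))
        table = select_model(
            data, [0.001, 10.0, 100.0, 500.0, 1000.0], m=20, seed=6,
            reference=true_map, standardize=False, fit_full=False,
        )
        df = table.to_dataframe()
        delta_argmax = df.loc[df.delta.idxmax(), "lambda"]
        eta_argmax = df.loc[df.eta_tilde.idxmax(), "lambda"]
        assert delta_argmax != eta_argmax
        assert delta_argmax <= 100.0
        assert eta_argmax >= 500.0
        # zeta prefers the interpretable sparse plateau
        assert table.chosen_lambda >= 500.0

    def test_ties_break_toward_larger_lambda(self):
        # both grid values sit in the toy's fully-sparse [1, 0] plateau
        # (n=300 trials), where eta is identically 1; if their OOB deltas
        # also coincide the sparser (larger-lambda) model must win
        data, true_map = make_toy(ToyConfig(n_per_class=150, seed=8))
        table = select_model(data, [300.0, 600.0], m=10, seed=3,
                             reference=true_map, standardize=False)
        assert table.admissible
        df = table.to_dataframe()
        if df.zeta.nunique() == 1:
            assert table.chosen_lambda == 600.0
        else:
            assert table.chosen_lambda == df.loc[df.zeta.idxmax(), "lambda"]
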