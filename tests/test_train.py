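"""Training losses, augmentation, folds and the training loop contracts."""

import numpy as np
import pytest

from deepsuvr.io import DESK_GRID
from deepsuvr.model import NetworkSpec
from deepsuvr.natural_history import NaturalHistoryCurve
from deepsuvr.synthetic import SimConfig, VisitSchedule, make_cohort
from deepsuvr.train import (
    CentiloidBatch,
    LossWeights,
    PairDataset,
    TrainConfig,
    TrainResult,
    _loss_and_grads,
    anchor_fit,
    assign_folds,
    augment,
    fit_curve_from_pairs,
    loss_anchor,
    loss_curve,
    loss_decrease,
    select_best_restart,
    total_loss,
    train_fold,
)
from deepsuvr.natural_history import build_pairs


def _flat_curve(value: float) -> NaturalHistoryCurve:
    return NaturalHistoryCurve(grid=np.array([-1000.0, 1000.0]), values=np.array([value, value]))


class TestLossDecrease:
    @pytest.mark.parametrize("cl0,cl1,expected", [(50, 40, 10), (40, 50, 0), (33, 33, 0)])
    def test_formula(self, cl0, cl1, expected):
        assert loss_decrease(cl0, cl1) == expected


class TestLossCurve:
    def test_on_curve_pair_has_zero_loss(self):
        curve = _flat_curve(5.0)
        assert loss_curve(10.0, 15.0, 1.0, curve) == pytest.approx(0.0)

    def test_flat_zero_curve(self):
        assert loss_curve(0.0, 5.0, 1.0, _flat_curve(0.0)) == pytest.approx(5.0)

    def test_flat_two_curve_static_pair(self):
        assert loss_curve(10.0, 10.0, 1.0, _flat_curve(2.0)) == pytest.approx(2.0)


class TestLossAnchor:
    def test_identity_gives_zero(self, rng):
        u = rng.normal(50, 30, 40)
        assert loss_anchor(u, u) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_pure_shift(self, rng):
        u = rng.normal(50, 30, 40)
        ls, li = loss_anchor(u + 3.0, u)
        assert ls == pytest.approx(0.0, abs=1e-9)
        assert li == pytest.approx(3.0)

    def test_doubling_on_known_points(self):
        u = np.array([0.0, 10.0, 20.0])
        ls, li = loss_anchor(2 * u, u)
        assert ls == pytest.approx(1.0)
        assert li == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_batch_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anchor_fit(np.array([1.0, 2.0, 3.0]), np.ones(3))


class TestTotalLoss:
    def _batch(self, cl0, cl1, u0=None, u1=None, dt=None):
        cl0, cl1 = np.asarray(cl0, float), np.asarray(cl1, float)
        return CentiloidBatch(
            cl_t0=cl0,
            cl_t1=cl1,
            uncorrected_t0=cl0.copy() if u0 is None else np.asarray(u0, float),
            uncorrected_t1=cl1.copy() if u1 is None else np.asarray(u1, float),
            interval_years=np.ones_like(cl0) if dt is None else np.asarray(dt, float),
        )

    def test_vanishes_for_on_curve_identity_corrected_batch(self):
        batch = self._batch([0.0, 10.0, 20.0], [5.0, 15.0, 25.0])
        assert total_loss(batch, LossWeights(), _flat_curve(5.0)) == pytest.approx(0.0)

    def test_zero_weights_reduce_to_mean_decrease(self):
        batch = self._batch([10.0, 30.0, 20.0], [0.0, 35.0, 20.0])
        loss = total_loss(batch, LossWeights(0.0, 0.0, 0.0), _flat_curve(0.0))
        assert loss == pytest.approx(10.0 / 3.0)

    def test_hand_built_two_pair_batch(self):
        # pair 1: 20 -> 10 over 1 y; pair 2: 0 -> 8 over 2 y; fc == 2
        # Ld = (10 + 0)/2 = 5;  Lc = (|-10-2| + |4-2|)/2 = 7
        # corrected == uncorrected + 1 => Ls = 0, Li = 1
        cl0, cl1 = np.array([20.0, 0.0]), np.array([10.0, 8.0])
        batch = CentiloidBatch(cl0 + 1, cl1 + 1, cl0, cl1, np.array([1.0, 2.0]))
        w = LossWeights(alpha=0.2, beta=1.0, gamma=0.01)
        expected = 5.0 + 0.2 * 7.0 + 1.0 * 0.0 + 0.01 * 1.0
        assert total_loss(batch, w, _flat_curve(2.0)) == pytest.approx(expected)

    def test_analytic_gradients_match_finite_differences(self, rng):
        curve = NaturalHistoryCurve(
            grid=np.linspace(0, 100, 11), values=np.linspace(0, 100, 11) * 0.05
        )
        n = 12
        batch = self._batch(
            rng.uniform(0, 80, n), rng.uniform(0, 90, n),
            rng.uniform(0, 80, n), rng.uniform(0, 90, n), rng.uniform(0.5, 3.0, n),
        )
        _, _, d0, d1 = _loss_and_grads(batch, LossWeights(), curve)
        eps = 1e-5
        for j in [0, 3, 7]:
            for which, grad in ((0, d0), (1, d1)):
                arr = batch.cl_t0 if which == 0 else batch.cl_t1
                arr[j] += eps
                up = total_loss(batch, LossWeights(), curve)
                arr[j] -= 2 * eps
                down = total_loss(batch, LossWeights(), curve)
                arr[j] += eps
                assert grad[j] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-8)

    def test_gradient_flows_for_decreasing_pair(self):
        """A pair violating monotonicity feels a restoring gradient."""
        batch = self._batch([50.0, 10.0, 30.0], [40.0, 15.0, 35.0])
        _, _, d0, d1 = _loss_and_grads(batch, LossWeights(), _flat_curve(0.0))
        assert d0[0] > 0 and d1[0] < 0  # push CL_T0 down-weighted, CL_T1 up


class TestAugment:
    def test_excessive_psf_rejected(self, rng):
        with pytest.raises(ValueError, match="8"):
            augment(np.zeros(DESK_GRID.shape), 8.5, rng, DESK_GRID)

    def test_at_ceiling_no_added_smoothing(self, rng):
        """With an 8 mm scanner PSF the quadrature headroom is zero, so
        disabling rotation/deformation must return the input unchanged."""
        vol = rng.random(DESK_GRID.shape)
        out = augment(vol, 8.0, rng, DESK_GRID, max_rotation_deg=0.0, deform_magnitude=0.0)
        assert np.allclose(out, vol)

    def test_headroom_is_quadrature(self):
        assert np.sqrt(8.0**2 - 6.0**2) == pytest.approx(5.2915, abs=1e-4)

    def test_seeded_determinism(self):
        vol = np.random.default_rng(1).random(DESK_GRID.shape)
        a = augment(vol, 6.0, np.random.default_rng(9), DESK_GRID)
        b = augment(vol, 6.0, np.random.default_rng(9), DESK_GRID)
        assert np.array_equal(a, b)


class TestFoldAssignment:
    def test_each_participant_in_exactly_one_fold(self, small_cohort):
        folds = assign_folds(small_cohort.records, None, n_folds=5, seed=0)
        pids = {r.participant_id for r in small_cohort.records}
        assert set(folds) == pids
        assert set(folds.values()) <= set(range(5))

    def test_folds_roughly_balanced_in_size(self):
        cohort = make_cohort(SimConfig(n_participants=50, seed=9))
        folds = assign_folds(cohort.records, None, n_folds=5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert counts.max() - counts.min() <= 2


class TestSelectBestRestart:
    @staticmethod
    def _result(rho, loss, seed):
        return TrainResult(model=None, history=None, best_val_loss=loss,
                           best_epoch=1, val_spearman=rho, seed=seed)

    def test_argmax_spearman(self):
        cands = [self._result(r, 1.0, i) for i, r in enumerate([0.2, 0.5, 0.4, 0.5 - 1e-9, 0.1])]
        assert select_best_restart(cands).seed == 1

    def test_tie_broken_by_val_loss_then_seed(self):
        cands = [self._result(0.5, 2.0, 0), self._result(0.5, 1.0, 1), self._result(0.5, 1.0, 2)]
        assert select_best_restart(cands).seed == 1

    def test_dominating_candidate_selected(self):
        cands = [self._result(0.1, 5.0, 0), self._result(0.9, 0.1, 1)]
        assert select_best_restart(cands).seed == 1


@pytest.fixture(scope="module")
def tiny_training_setup():
    cohort = make_cohort(
        SimConfig(
            n_participants=24,
            seed=5,
            tracers={"PIB": 1.0},
            visit_schedule=VisitSchedule(n_visits=2, spacing_mean_years=1.5, spacing_sd_years=0.15),
        )
    )
    masks = cohort.layout.standard_masks()
    pairs = build_pairs(cohort.records)
    pids = sorted({r.participant_id for r in cohort.records})
    val_pids = set(pids[:8])
    train_pairs = [p for p in pairs if p.scan_t0.participant_id not in val_pids]
    val_pairs = [p for p in pairs if p.scan_t0.participant_id in val_pids]
    curve = fit_curve_from_pairs(pairs, masks, cohort.transforms)
    return (
        PairDataset.from_pairs(train_pairs, masks, cohort.transforms),
        PairDataset.from_pairs(val_pairs, masks, cohort.transforms),
        curve,
        cohort.grid,
    )


class TestTrainFold:
    def test_patience_contract_stops_after_exactly_patience_epochs(self, tiny_training_setup):
        """With a zero learning rate the validation loss never improves
        after epoch 1, so training stops at epoch 1 + patience."""
        train_data, val_data, curve, grid = tiny_training_setup
        config = TrainConfig(
            learning_rate=0.0, max_epochs=100, patience=20,
            network=NetworkSpec(channels=(8,), fc_widths=(8, 4)),
        )
        result = train_fold(train_data, val_data, curve, grid, config, seed=0)
        assert len(result.history) == 21
        assert result.best_epoch == 1

    def test_seeded_determinism(self, tiny_training_setup):
        train_data, val_data, curve, grid = tiny_training_setup
        config = TrainConfig(
            learning_rate=1e-3, max_epochs=4, patience=10,
            network=NetworkSpec(channels=(8,), fc_widths=(8, 4)),
        )
        h1 = train_fold(train_data, val_data, curve, grid, config, seed=3).history
        h2 = train_fold(train_data, val_data, curve, grid, config, seed=3).history
        assert np.allclose(h1["train_loss"], h2["train_loss"])
        assert np.allclose(h1["val_loss"], h2["val_loss"])

    def test_overlapping_participants_rejected(self, tiny_training_setup):
        train_data, _, curve, grid = tiny_training_setup
        with pytest.raises(ValueError, match="overlap"):
            train_fold(train_data, train_data, curve, grid, TrainConfig(max_epochs=1), seed=0)
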