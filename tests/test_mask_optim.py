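"""Mask-derivation losses and the gradient-descent optimiser."""

import numpy as np
import pytest

from deepsuvr.io import BrainMask
from deepsuvr.mask_optim import (
    MaskOptConfig,
    binarity_loss,
    dice,
    optimize_masks,
    pearson_loss,
    recalibrate,
)
from deepsuvr.quantify import compute_suvr
from deepsuvr.synthetic import SimConfig, SigmoidParams, VisitSchedule, make_cohort


class TestPearsonLoss:
    def test_exact_match_gives_zero(self, rng):
        s = rng.normal(1.5, 0.3, 20)
        assert pearson_loss({"PIB": s}, {"PIB": s.copy()}) == pytest.approx(0.0)

    def test_affine_invariance(self, rng):
        s = rng.normal(1.5, 0.3, 20)
        assert pearson_loss({"PIB": s}, {"PIB": 3 * s - 1}) == pytest.approx(0.0)

    def test_average_over_tracers(self, rng):
        s = np.repeat(np.arange(10.0), 2)  # each level seen with both outcomes
        uncorrelated = np.tile([0.0, 1.0], 10)  # exactly zero covariance with s
        loss = pearson_loss({"PIB": s, "FBB": s}, {"PIB": s, "FBB": uncorrelated})
        assert loss == pytest.approx(0.5, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_loss({"PIB": np.ones(5)}, {"PIB": np.arange(5.0)})


class TestBinarityLoss:
    @pytest.fixture()
    def brain(self):
        mask = np.zeros((8, 8, 8))
        mask[2:6, 2:6, 2:6] = 1  # B = 64
        return BrainMask(mask)

    def test_binary_mask_scores_zero(self, brain):
        mask = np.zeros((8, 8, 8))
        mask[2:4, 2:4, 2:4] = 1.0
        assert binarity_loss(mask, brain) == 0.0

    def test_half_valued_mask_scores_half(self, brain):
        mask = np.full((8, 8, 8), 0.5) * brain.mask
        assert binarity_loss(mask, brain) == pytest.approx(0.5)

    def test_hand_computed_mixture(self, brain):
        # half the brain voxels at 0.25 (penalty 0.25 each), half at 1 (penalty 0)
        mask = np.zeros((8, 8, 8))
        mask[2:6, 2:6, 2:4] = 0.25
        mask[2:6, 2:6, 4:6] = 1.0
        assert binarity_loss(mask, brain) == pytest.approx(0.125)

    def test_out_of_range_rejected(self, brain):
        with pytest.raises(ValueError):
            binarity_loss(np.full((8, 8, 8), 1.2), brain)


class TestDice:
    def test_identical_masks(self, rng):
        m = (rng.random((6, 6, 6)) > 0.5).astype(float)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6))
        b = np.zeros((6, 6, 6))
        a[0], b[5] = 1, 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10))
        b = np.zeros((10, 10, 10))
        a.ravel()[:100] = 1
        b.ravel()[50:150] = 1
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))


class TestRecalibrate:
    def test_identity(self, rng):
        s = rng.normal(1.5, 0.3, 10)
        lines = recalibrate({"PIB": s}, {"PIB": s.copy()})
        slope, intercept = lines["PIB"]
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_inverts_generating_line(self, rng):
        corrected = rng.normal(1.5, 0.3, 30)
        mask_suvrs = 0.5 * corrected + 0.1
        lines = recalibrate({"PIB": mask_suvrs}, {"PIB": corrected})
        slope, intercept = lines["PIB"]
        assert slope == pytest.approx(2.0, rel=1e-6)
        assert intercept == pytest.approx(-0.2, abs=1e-6)

    def test_r2_unchanged_by_recalibration(self, rng):
        """An affine map cannot change the squared correlation."""
        from deepsuvr.metrics import r_squared
        from deepsuvr.mask_optim import apply_recalibration

        s = rng.normal(1.5, 0.3, 30)
        y = s + rng.normal(0, 0.05, 30)
        lines = recalibrate({"PIB": s}, {"PIB": y})
        mapped = np.array([apply_recalibration(v, "PIB", lines) for v in s])
        assert r_squared(mapped, y) == pytest.approx(r_squared(s, y))


@pytest.fixture(scope="module")
def mask_cohort():
    """Noise-free, single-scanner phantom study for mask derivation."""
    return make_cohort(
        SimConfig(
            n_participants=40,
            seed=11,
            noise_sd=0.0,
            wm_level_sd=0.08,
            psf_range_mm=(6.0, 6.0),
            psf_change_prob=0.0,
            negative_fraction=0.10,
            sigmoid=SigmoidParams(slope_years=3.0, onset_age_mean=72, onset_age_sd=5),
            baseline_age_sd=5,
            visit_schedule=VisitSchedule(n_visits=2),
        )
    )


class TestOptimizeMasks:
    def test_fixed_point(self, mask_cohort):
        """Targets computed from the init masks themselves: the
        optimisation terminates with a vanishing Pearson loss and the
        masks stay where they started."""
        init = mask_cohort.layout.standard_masks()
        scans = mask_cohort.records
        suvrs = np.array([compute_suvr(s.volume, init) for s in scans])
        config = MaskOptConfig(level_factors=(1,), min_iterations=(120,))
        result = optimize_masks(scans, suvrs, init, mask_cohort.layout.brain_mask(),
                                mask_cohort.grid, config)
        assert result.history["lp"].iloc[-1] < 1e-6
        assert dice(result.masks.reference, init.reference) > 0.95
        assert dice(result.masks.target, init.target) > 0.95
        # monotone improvement at the level scale
        assert result.history["lp"].iloc[-1] <= result.history["lp"].iloc[0] + 1e-12

    def test_output_masks_bounded_and_symmetric(self, mask_cohort):
        init = mask_cohort.layout.standard_masks()
        scans = mask_cohort.records[:30]
        suvrs = np.array([compute_suvr(s.volume, init) for s in scans])
        config = MaskOptConfig(level_factors=(2, 1), min_iterations=(20, 30))
        result = optimize_masks(scans, suvrs, init, mask_cohort.layout.brain_mask(),
                                mask_cohort.grid, config)
        axis = mask_cohort.grid.left_right_axis
        for m in (result.masks.reference, result.masks.target):
            assert m.min() >= 0.0 and m.max() <= 1.0
            assert np.array_equal(m, np.flip(m, axis=axis))

    def test_delta_schedule_boosts_after_epoch(self, mask_cohort):
        init = mask_cohort.layout.standard_masks()
        scans = mask_cohort.records[:20]
        suvrs = np.array([compute_suvr(s.volume, init) for s in scans])
        config = MaskOptConfig(level_factors=(1,), min_iterations=(40,),
                               delta=5e-4, delta_boost_epoch=20, delta_boost_factor=100.0)
        result = optimize_masks(scans, suvrs, init, mask_cohort.layout.brain_mask(),
                                mask_cohort.grid, config)
        h = result.history
        assert np.all(h.loc[h["iteration"] <= 20, "delta"] == 5e-4)
        assert np.all(h.loc[h["iteration"] > 20, "delta"] == 5e-2)

    def test_too_few_scans_per_tracer_rejected(self, mask_cohort):
        init = mask_cohort.layout.standard_masks()
        scans = [r for r in mask_cohort.records if r.tracer == "PIB"][:4]
        scans += [r for r in mask_cohort.records if r.tracer == "FBB"][:1]
        suvrs = np.ones(len(scans))
        with pytest.raises(ValueError, match="at least 3"):
            optimize_masks(scans, suvrs, init, mask_cohort.layout.brain_mask(),
                           mask_cohort.grid, MaskOptConfig())
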