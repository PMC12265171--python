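"""Data-driven derivation of new Centiloid reference and target masks.

The corrections the network learns are reformulated as a mask problem:
find continuous reference/target masks whose SUVRs correlate maximally
(per tracer) with the network-corrected SUVRs.  Gradient descent on the
mask voxels with a Pearson loss ``Lp = 1 - R^2`` (averaged over
tracers) and a binarity loss ``Lb = sum(0.5 - |M - 0.5|) / B`` pushing
voxels towards 0/1, with per-iteration 4 mm smoothing, left-right
mirroring and a 3-level multiresolution schedule.  Gradients of the
SUVR ratio and of the Pearson statistic w.r.t. mask voxels are
analytic, so each iteration is two matrix-vector products per mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FWHM_PER_SIGMA, TRACERS, BrainMask, ScanRecord, VolumeGrid
from .quantify import MaskPair


@dataclasses.dataclass
class MaskOptConfig:
    delta: float = 5e-4                 # binarity weight before the boost
    delta_boost_epoch: int = 20         # full-batch passes before boosting
    delta_boost_factor: float = 100.0
    smooth_fwhm_mm: float = 4.0
    level_factors: tuple[int, ...] = (4, 2, 1)
    min_iterations: tuple[int, ...] = (1000, 3000, 8000)
    convergence_tol: float = 1e-8       # minimum Lp improvement
    convergence_window: int = 50        # moving-average window for the Lp trend
    learning_rate: float = 10.0         # plain gradient step on mask values
    #: random PSF-style smoothing of the input images each iteration
    augment_smoothing: bool = False

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.convergence_tol <= 0:
            raise ValueError("delta and convergence_tol must be positive")
        if len(self.level_factors) != len(self.min_iterations):
            raise ValueError("one minimum-iteration count per level required")


def pearson_loss(mask_suvrs: dict[str, np.ndarray], target_suvrs: dict[str, np.ndarray]) -> float:
    """Mean over tracers of 1 - (Pearson r)^2 between matched SUVR lists."""
    losses = []
    for tracer, s in mask_suvrs.items():
        s = np.asarray(s, dtype=np.float64)
        t = np.asarray(target_suvrs[tracer], dtype=np.float64)
        if s.size < 3 or s.shape != t.shape:
            raise ValueError(f"tracer {tracer}: need >= 3 matched scans")
        if np.std(s) == 0 or np.std(t) == 0:
            raise ValueError(f"tracer {tracer}: zero variance")
        r = np.corrcoef(s, t)[0, 1]
        losses.append(1.0 - r**2)
    if not losses:
        raise ValueError("no tracers present")
    return float(np.mean(losses))


def binarity_loss(mask: np.ndarray, brain_mask: BrainMask) -> float:
    """sum over brain voxels of (0.5 - |M - 0.5|), normalised by B."""
    if mask.min() < 0 or mask.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    contrib = (0.5 - np.abs(mask - 0.5)) * brain_mask.mask
    return float(contrib.sum() / brain_mask.n_voxels)


def dice(mask_a: np.ndarray, mask_b: np.ndarray, threshold: float = 0.5) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) after thresholding at 0.5."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a grid")
    a = mask_a >= threshold
    b = mask_b >= threshold
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks empty after thresholding")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# --------------------------------------------------------------------- #
# Multiresolution helpers


def _downsample(volume: np.ndarray, factor: int) -> np.ndarray:
    """Mean pooling by an integer factor (trailing voxels cropped)."""
    if factor == 1:
        return volume
    s = [d // factor for d in volume.shape]
    v = volume[: s[0] * factor, : s[1] * factor, : s[2] * factor]
    return v.reshape(s[0], factor, s[1], factor, s[2], factor).mean(axis=(1, 3, 5))


def _upsample(volume: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Trilinear interpolation to an arbitrary target shape."""
    zoom = [t / s for t, s in zip(shape, volume.shape)]
    out = ndimage.zoom(volume, zoom, order=1, mode="nearest", grid_mode=True)
    assert out.shape == tuple(shape)
    return np.clip(out, 0.0, 1.0)


def _project(mask: np.ndarray, brain: np.ndarray, axis: int, sigma_vox: float = 0.0) -> np.ndarray:
    """Optionally smooth, then clamp -> mirror-average -> restrict to brain.

    Smoothing is applied to gradient updates rather than to the evolving
    mask each iteration: per-iteration mask smoothing compounds (the
    effective kernel width grows with the square root of the iteration
    count) and erases any mask long before the minimum iteration counts
    are reached, which no loss term can counteract.  Smoothing the
    update preserves the spatial-consistency intent while keeping
    converged masks stationary.
    """
    m = mask
    if sigma_vox > 0:
        m = ndimage.gaussian_filter(m, sigma_vox)
    m = np.clip(m, 0.0, 1.0)
    m = 0.5 * (m + np.flip(m, axis=axis))
    m = np.clip(m * brain, 0.0, 1.0)
    return m


# --------------------------------------------------------------------- #
# Optimisation


@dataclasses.dataclass
class MaskOptResult:
    masks: MaskPair
    history: pd.DataFrame
    recalibration: dict | None = None


def _suvr_and_grads(V: np.ndarray, t: np.ndarray, r: np.ndarray):
    """SUVRs of all scans for masks t (target) and r (reference), plus the
    per-scan quantities needed for the analytic chain rule."""
    Td, Rd = t.sum(), r.sum()
    Tn = V @ t
    Rn = V @ r
    s = (Tn / Td) / (Rn / Rd)
    return s, Tn, Td, Rn, Rd


def optimize_masks(
    scans: list[ScanRecord],
    corrected_suvrs: np.ndarray,
    init_masks: MaskPair,
    brain_mask: BrainMask,
    grid: VolumeGrid,
    config: MaskOptConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MaskOptResult:
    """Optimise reference/target masks against corrected SUVRs.

    Total loss = mean_tracer Lp + delta * (Lb(ref) + Lb(target)); delta
    is boosted 100-fold after ``delta_boost_epoch`` full-batch passes.
    Masks stay in [0,1], are smoothed with a 4 mm FWHM kernel and
    mirrored to exact left-right symmetry after every step; a 3-level
    multiresolution schedule (x4, x2, x1 downsampled images) runs until
    the windowed Lp improvement falls below ``convergence_tol`` and the
    per-level minimum iteration count is reached.
    """
    config = config or MaskOptConfig()
    rng = rng or np.random.default_rng(0)
    corrected_suvrs = np.asarray(corrected_suvrs, dtype=np.float64)
    if len(scans) != corrected_suvrs.size:
        raise ValueError("one corrected SUVR per scan required")

    tracer_groups: dict[str, np.ndarray] = {}
    for tracer in TRACERS:
        idx = np.array([i for i, s in enumerate(scans) if s.tracer == tracer], dtype=int)
        if idx.size:
            if idx.size < 3:
                raise ValueError(f"tracer {tracer}: need at least 3 scans")
            tracer_groups[tracer] = idx
    if not tracer_groups:
        raise ValueError("no scans")

    volumes_full = np.stack([s.volume for s in scans]).astype(np.float64)
    ref = init_masks.reference.astype(np.float64).copy()
    tgt = init_masks.target.astype(np.float64).copy()
    axis = grid.left_right_axis

    rows = []
    epoch = 0  # one full-batch pass == one epoch at full batch
    for level, factor in enumerate(config.level_factors):
        vox_mm = grid.voxel_size_mm * factor
        sigma_vox = config.smooth_fwhm_mm / FWHM_PER_SIGMA / vox_mm
        brain_lvl = (_downsample(brain_mask.mask, factor) > 0.5).astype(np.float64)
        shape_lvl = brain_lvl.shape
        b_count = max(1.0, brain_lvl.sum())
        V = np.stack([_downsample(v, factor) for v in volumes_full]).reshape(len(scans), -1)

        # the initial masks are smoothed once with the 4 mm kernel
        ref_l = _project(_downsample(ref, factor), brain_lvl, axis, sigma_vox if level == 0 else 0.0).ravel()
        tgt_l = _project(_downsample(tgt, factor), brain_lvl, axis, sigma_vox if level == 0 else 0.0).ravel()
        brain_flat = brain_lvl.ravel()

        lp_window: list[float] = []
        iteration = 0
        while True:
            iteration += 1
            epoch += 1
            Vit = V
            if config.augment_smoothing:
                add_fwhm = rng.uniform(0.0, 4.0, size=len(scans))
                Vit = np.stack(
                    [
                        ndimage.gaussian_filter(
                            v.reshape(shape_lvl), f / FWHM_PER_SIGMA / vox_mm
                        ).ravel()
                        for v, f in zip(V, add_fwhm)
                    ]
                )
            s, Tn, Td, Rn, Rd = _suvr_and_grads(Vit, tgt_l, ref_l)

            g = np.zeros(len(scans))
            lp_terms = []
            for tracer, idx in tracer_groups.items():
                si = s[idx]
                yi = corrected_suvrs[idx]
                zs = si - si.mean()
                zy = yi - yi.mean()
                sss = float(zs @ zs)
                syy = float(zy @ zy)
                if sss <= 0 or syy <= 0:
                    raise ValueError(f"tracer {tracer}: zero variance during optimisation")
                r_p = float(zs @ zy) / np.sqrt(sss * syy)
                lp_terms.append(1.0 - r_p**2)
                dr_ds = zy / np.sqrt(sss * syy) - r_p * zs / sss
                g[idx] = (-2.0 * r_p * dr_ds) / len(tracer_groups)
            lp = float(np.mean(lp_terms))
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient in mask optimisation")

            # chain rule through the SUVR ratio
            wt = g * s / Tn
            wr = -g * s / Rn
            grad_t = Vit.T @ wt - (g * s).sum() / Td
            grad_r = Vit.T @ wr + (g * s).sum() / Rd

            delta_eff = config.delta * (config.delta_boost_factor if epoch > config.delta_boost_epoch else 1.0)
            grad_t = grad_t + delta_eff * (-np.sign(tgt_l - 0.5)) * brain_flat / b_count
            grad_r = grad_r + delta_eff * (-np.sign(ref_l - 0.5)) * brain_flat / b_count

            # spatial consistency: the update itself carries the 4 mm kernel
            grad_t = ndimage.gaussian_filter(grad_t.reshape(shape_lvl), sigma_vox).ravel()
            grad_r = ndimage.gaussian_filter(grad_r.reshape(shape_lvl), sigma_vox).ravel()

            tgt_l = _project(
                (tgt_l - config.learning_rate * grad_t).reshape(shape_lvl), brain_lvl, axis
            ).ravel()
            ref_l = _project(
                (ref_l - config.learning_rate * grad_r).reshape(shape_lvl), brain_lvl, axis
            ).ravel()

            lb_r = float(((0.5 - np.abs(ref_l - 0.5)) * brain_flat).sum() / b_count)
            lb_t = float(((0.5 - np.abs(tgt_l - 0.5)) * brain_flat).sum() / b_count)
            rows.append(
                {"level": level + 1, "iteration": iteration, "lp": lp,
                 "lb_ref": lb_r, "lb_target": lb_t, "delta": delta_eff}
            )

            lp_window.append(lp)
            if iteration >= config.min_iterations[level]:
                w = config.convergence_window
                if len(lp_window) >= 2 * w:
                    recent = np.mean(lp_window[-w:])
                    previous = np.mean(lp_window[-2 * w : -w])
                    if previous - recent < config.convergence_tol:
                        break
                elif len(lp_window) >= 2 and lp_window[-2] - lp_window[-1] < config.convergence_tol:
                    break

        ref = _upsample(ref_l.reshape(shape_lvl), grid.shape)
        tgt = _upsample(tgt_l.reshape(shape_lvl), grid.shape)

    ref = _project(ref, brain_mask.mask, axis)
    tgt = _project(tgt, brain_mask.mask, axis)
    return MaskOptResult(masks=MaskPair(reference=ref, target=tgt), history=pd.DataFrame(rows))


# --------------------------------------------------------------------- #
# Recalibration


def recalibrate(
    mask_suvrs: dict[str, np.ndarray], corrected_suvrs: dict[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Per-tracer least-squares line mapping mask SUVR to corrected SUVR.

    Composing this line with the standard Centiloid transform yields the
    mask-based corrected Centiloid scale.
    """
    lines: dict[str, tuple[float, float]] = {}
    for tracer, s in mask_suvrs.items():
        s = np.asarray(s, dtype=np.float64)
        y = np.asarray(corrected_suvrs[tracer], dtype=np.float64)
        if s.size < 3:
            raise ValueError(f"tracer {tracer}: need at least 3 scans")
        if np.std(s) == 0:
            raise ValueError(f"tracer {tracer}: zero variance")
        slope, intercept = np.polyfit(s, y, 1)
        lines[tracer] = (float(slope), float(intercept))
    return lines


def apply_recalibration(suvr: float, tracer: str, lines: dict[str, tuple[float, float]]) -> float:
    slope, intercept = lines[tracer]
    return slope * suvr + intercept
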