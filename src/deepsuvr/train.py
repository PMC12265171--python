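"""Longitudinal-pair training of the correction network.

The network never sees a ground-truth correction.  It is trained purely
from longitudinal consistency of corrected Centiloids over visit pairs,
via four losses:

* ``Ld`` — amyloid burden should not decrease over time in an
  observational cohort: Ld = max(0, CL_T0 - CL_T1);
* ``Lc`` — the annual rate of change should match the natural-history
  curve evaluated at the pair's mean level: Lc = |rate - fc(mean)|;
* ``Ls``/``Li`` — the batch-level regression of corrected on
  uncorrected Centiloid should stay near the identity line
  (slope 1, intercept 0), preventing collapse of the correction;

combined as ``L = mean(Ld) + alpha*mean(Lc) + beta*Ls + gamma*Li`` with
default weights alpha=0.2, beta=1, gamma=0.01.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr

from . import nn as _nn
from .io import MAX_PSF_FWHM_MM, FWHM_PER_SIGMA, TRACERS, ScanRecord, VolumeGrid
from .model import CorrectionNet, NetworkSpec
from .natural_history import NaturalHistoryCurve, VisitPair, build_pairs, fit_natural_history, pair_statistics
from .quantify import MaskPair, TransformTable, compute_suvr
from .synthetic import Cohort

# --------------------------------------------------------------------- #
# Losses


@dataclasses.dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.2  # weight of the curve loss Lc
    beta: float = 1.0   # weight of the anchor slope loss Ls
    gamma: float = 0.01  # weight of the anchor intercept loss Li

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")


def loss_decrease(cl_t0, cl_t1):
    """Ld = max(0, CL_T0 - CL_T1): penalise decreasing amyloid burden."""
    return np.maximum(0.0, np.asarray(cl_t0) - np.asarray(cl_t1))


def loss_curve(cl_t0, cl_t1, interval_years, curve: NaturalHistoryCurve):
    """Lc = |rate - fc(mean)|: deviation from the expected rate of change."""
    cl_t0, cl_t1 = np.asarray(cl_t0, dtype=float), np.asarray(cl_t1, dtype=float)
    rate = (cl_t1 - cl_t0) / np.asarray(interval_years, dtype=float)
    return np.abs(rate - curve((cl_t0 + cl_t1) / 2.0))


def anchor_fit(corrected_cls, uncorrected_cls) -> tuple[float, float]:
    """OLS slope and intercept of corrected on uncorrected Centiloids."""
    c = np.asarray(corrected_cls, dtype=float)
    u = np.asarray(uncorrected_cls, dtype=float)
    if c.shape != u.shape or c.size < 3:
        raise ValueError("anchor regression needs matched batches of size >= 3")
    du = u - u.mean()
    suu = float(du @ du)
    if suu <= 0:
        raise ValueError("anchor regression undefined: uncorrected batch has zero variance")
    s = float(du @ (c - c.mean())) / suu
    i = float(c.mean() - s * u.mean())
    return s, i


def loss_anchor(corrected_cls, uncorrected_cls) -> tuple[float, float]:
    """(Ls, Li) = (|s - 1|, |i|) of the batch anchor regression."""
    s, i = anchor_fit(corrected_cls, uncorrected_cls)
    return abs(s - 1.0), abs(i)


@dataclasses.dataclass
class CentiloidBatch:
    """Corrected and uncorrected Centiloids over a batch of visit pairs."""

    cl_t0: np.ndarray
    cl_t1: np.ndarray
    uncorrected_t0: np.ndarray
    uncorrected_t1: np.ndarray
    interval_years: np.ndarray

    @property
    def corrected_all(self) -> np.ndarray:
        return np.concatenate([self.cl_t0, self.cl_t1])

    @property
    def uncorrected_all(self) -> np.ndarray:
        return np.concatenate([self.uncorrected_t0, self.uncorrected_t1])


def total_loss(batch: CentiloidBatch, weights: LossWeights, curve: NaturalHistoryCurve) -> float:
    """L = mean(Ld) + alpha*mean(Lc) + beta*Ls + gamma*Li."""
    ld = loss_decrease(batch.cl_t0, batch.cl_t1).mean()
    lc = loss_curve(batch.cl_t0, batch.cl_t1, batch.interval_years, curve).mean()
    ls, li = loss_anchor(batch.corrected_all, batch.uncorrected_all)
    return float(ld + weights.alpha * lc + weights.beta * ls + weights.gamma * li)


def _loss_and_grads(
    batch: CentiloidBatch, weights: LossWeights, curve: NaturalHistoryCurve
) -> tuple[float, dict, np.ndarray, np.ndarray]:
    """Total loss plus analytic dL/dCL for each corrected Centiloid.

    Subgradients are used at the kinks of Ld, Lc, Ls and Li (sign(0)=0).
    """
    cl0, cl1 = batch.cl_t0, batch.cl_t1
    n_pairs = cl0.size
    dt = batch.interval_years

    ld_terms = np.maximum(0.0, cl0 - cl1)
    d_ld0 = (cl0 > cl1).astype(float) / n_pairs
    d_ld1 = -d_ld0

    mean_cl = (cl0 + cl1) / 2.0
    err = (cl1 - cl0) / dt - curve(mean_cl)
    sgn = np.sign(err)
    fprime = curve.derivative(mean_cl)
    d_lc0 = sgn * (-1.0 / dt - fprime / 2.0) / n_pairs
    d_lc1 = sgn * (1.0 / dt - fprime / 2.0) / n_pairs

    c = batch.corrected_all
    u = batch.uncorrected_all
    s, i = anchor_fit(c, u)
    du = u - u.mean()
    suu = float(du @ du)
    n = c.size
    d_ls = np.sign(s - 1.0) * du / suu
    d_li = np.sign(i) * (1.0 / n - u.mean() * du / suu)
    d_anchor = weights.beta * d_ls + weights.gamma * d_li

    loss = float(
        ld_terms.mean()
        + weights.alpha * np.abs(err).mean()
        + weights.beta * abs(s - 1.0)
        + weights.gamma * abs(i)
    )
    comps = {
        "Ld": float(ld_terms.mean()),
        "Lc": float(np.abs(err).mean()),
        "Ls": abs(s - 1.0),
        "Li": abs(i),
    }
    d_cl0 = d_ld0 + weights.alpha * d_lc0 + d_anchor[:n_pairs]
    d_cl1 = d_ld1 + weights.alpha * d_lc1 + d_anchor[n_pairs:]
    return loss, comps, d_cl0, d_cl1


# --------------------------------------------------------------------- #
# Augmentation


def augment(
    volume: np.ndarray,
    scanner_psf_fwhm_mm: float,
    rng: np.random.Generator,
    grid: VolumeGrid,
    max_rotation_deg: float = 5.0,
    deform_sigma: float = 20.0,
    deform_magnitude: float = 50.0,
) -> np.ndarray:
    """Random rotation, coarse non-rigid warp and PSF-aware smoothing.

    The added smoothing FWHM is drawn uniformly in
    [0, sqrt(8^2 - psf^2)] so the combined (quadrature) image PSF never
    exceeds 8 mm.  Deformation sigma and magnitude are given in voxels
    of the full-scale 2 mm grid and scaled proportionally to ``grid``.
    """
    if scanner_psf_fwhm_mm > MAX_PSF_FWHM_MM:
        raise ValueError(f"scanner PSF {scanner_psf_fwhm_mm} mm exceeds {MAX_PSF_FWHM_MM} mm")
    out = volume

    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    axes_choice = [(0, 1), (0, 2), (1, 2)][rng.integers(0, 3)]
    out = ndimage.rotate(out, angle, axes=axes_choice, reshape=False, order=1, mode="constant")

    vox_scale = 2.0 / grid.voxel_size_mm
    sigma_vox = deform_sigma * vox_scale
    mag_vox = deform_magnitude * vox_scale
    coords = np.indices(out.shape).astype(float)
    for ax in range(3):
        field = ndimage.gaussian_filter(rng.uniform(-1, 1, out.shape), sigma_vox)
        coords[ax] += field * mag_vox
    out = ndimage.map_coordinates(out, coords, order=1, mode="constant")

    headroom = MAX_PSF_FWHM_MM**2 - scanner_psf_fwhm_mm**2
    added_fwhm = rng.uniform(0.0, np.sqrt(max(0.0, headroom)))
    if added_fwhm > 0:
        out = ndimage.gaussian_filter(out, added_fwhm / FWHM_PER_SIGMA / grid.voxel_size_mm)
    return out


# --------------------------------------------------------------------- #
# Pair datasets


@dataclasses.dataclass
class PairDataset:
    """Visit pairs flattened into arrays over unique scans for training."""

    volumes: np.ndarray       # (n_scans, X, Y, Z)
    suvr: np.ndarray          # standard SUVR per scan
    tracer_idx: np.ndarray    # index into TRACERS per scan
    psf_fwhm_mm: np.ndarray   # per scan
    participants: list[str]   # per scan
    i0: np.ndarray            # per pair: scan index at T0
    i1: np.ndarray            # per pair: scan index at T1
    interval_years: np.ndarray
    slopes: np.ndarray        # per scan: Centiloid slope of its tracer
    intercepts: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.i0.size)

    @property
    def uncorrected_cl(self) -> np.ndarray:
        return self.slopes * self.suvr + self.intercepts

    def corrected_cl(self, cf: np.ndarray) -> np.ndarray:
        return self.slopes * (cf * self.suvr) + self.intercepts

    @classmethod
    def from_pairs(
        cls, pairs: list[VisitPair], masks: MaskPair, transforms: TransformTable
    ) -> "PairDataset":
        scans: list[ScanRecord] = []
        index: dict[int, int] = {}
        for pair in pairs:
            for scan in (pair.scan_t0, pair.scan_t1):
                if id(scan) not in index:
                    index[id(scan)] = len(scans)
                    scans.append(scan)
        if not scans:
            raise ValueError("empty pair list")
        return cls(
            volumes=np.stack([s.volume for s in scans]).astype(np.float32),
            suvr=np.array([compute_suvr(s.volume, masks) for s in scans]),
            tracer_idx=np.array([TRACERS.index(s.tracer) for s in scans]),
            psf_fwhm_mm=np.array([s.scanner_psf_fwhm_mm for s in scans]),
            participants=[s.participant_id for s in scans],
            i0=np.array([index[id(p.scan_t0)] for p in pairs], dtype=int),
            i1=np.array([index[id(p.scan_t1)] for p in pairs], dtype=int),
            interval_years=np.array([p.interval_years for p in pairs]),
            slopes=np.array([transforms[s.tracer].slope for s in scans]),
            intercepts=np.array([transforms[s.tracer].intercept for s in scans]),
        )


def fit_curve_from_pairs(
    pairs: list[VisitPair],
    masks: MaskPair,
    transforms: TransformTable,
    tracer: str = "PIB",
    smoothing_fraction: float = 0.2,
) -> NaturalHistoryCurve:
    """Fit the natural-history curve from standard quantification.

    Restricted to a single tracer (PIB, the unbiased tracer of the
    synthetic pipeline) to avoid tracer-bias contamination; the curve is
    then frozen for the whole training run.
    """
    means, rates = [], []
    for pair in pairs:
        if pair.scan_t0.tracer != tracer or pair.scan_t1.tracer != tracer:
            continue
        cl0 = transforms[tracer].slope * compute_suvr(pair.scan_t0.volume, masks) + transforms[tracer].intercept
        cl1 = transforms[tracer].slope * compute_suvr(pair.scan_t1.volume, masks) + transforms[tracer].intercept
        mean_cl, rate = pair_statistics(pair, cl0, cl1)
        means.append(mean_cl)
        rates.append(rate)
    return fit_natural_history(np.array(means), np.array(rates), smoothing_fraction)


# --------------------------------------------------------------------- #
# Fold assignment


def assign_folds(records: list[ScanRecord], suvrs: dict | None, n_folds: int = 5, seed: int = 0) -> dict[str, int]:
    """Greedy balanced fold assignment at the participant level.

    Participants are grouped by tracer, sorted by (visit count, mean
    SUVR) and snake-dealt across folds, which balances tracer mix,
    visit counts and amyloid level simultaneously.  Each participant
    lands in exactly one fold.
    """
    by_pid: dict[str, list[ScanRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for tracer in TRACERS:
        pids = [p for p, recs in by_pid.items() if recs[0].tracer == tracer]
        if not pids:
            continue

        def sort_key(pid):
            recs = by_pid[pid]
            level = np.mean([suvrs[id(r)] for r in recs]) if suvrs else 0.0
            return (len(recs), level)

        rng.shuffle(pids)  # seed only breaks ties among equivalent participants
        pids.sort(key=sort_key)
        for rank, pid in enumerate(pids):
            k = rank % (2 * n_folds)
            fold = k if k < n_folds else 2 * n_folds - 1 - k
            assignment[pid] = (fold + offset) % n_folds
        offset += 1
    return assignment


# --------------------------------------------------------------------- #
# Training


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-4
    #: learning-rate decay: multiply by ``lr_decay_factor`` at these
    #: fractions of ``max_epochs`` (settles the stochastic optimisation
    #: into its minimum once the systematic corrections are found)
    lr_milestones: tuple[float, ...] = (0.6, 0.85)
    lr_decay_factor: float = 0.3
    max_epochs: int = 500
    patience: int = 20
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    #: full geometric + smoothing augmentation (rotation, non-rigid warp,
    #: PSF-aware smoothing); expensive, and it teaches resolution invariance.
    augment: bool = False
    #: fresh additive Gaussian voxel noise per iteration; defeats
    #: memorisation of a scan's noise pattern while preserving the
    #: resolution and uptake-pattern cues the correction relies on.
    augment_noise_sd: float = 0.02
    #: random extra smoothing drawn per iteration from precomputed
    #: variants (0 disables); randomising apparent resolution blocks the
    #: network from sculpting per-scan corrections out of fine image
    #: detail, at the cost of resolution-correction ability.
    augment_smooth_variants: int = 0
    augment_smooth_max_fwhm: float = 0.0
    network: NetworkSpec = dataclasses.field(default_factory=NetworkSpec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class TrainResult:
    model: CorrectionNet
    history: pd.DataFrame
    best_val_loss: float
    best_epoch: int
    val_spearman: float
    seed: int


def predict_cf_dataset(model: CorrectionNet, data: PairDataset, chunk: int = 256) -> np.ndarray:
    """Evaluation-mode CF for every scan of a dataset."""
    onehots = np.eye(len(TRACERS))[data.tracer_idx]
    out = np.empty(data.volumes.shape[0])
    for start in range(0, out.size, chunk):
        sl = slice(start, start + chunk)
        out[sl] = model.forward(data.volumes[sl], onehots[sl], train=False)
    return out


def _dataset_loss(model, data: PairDataset, weights, curve) -> tuple[float, float]:
    """(total loss, Spearman rho of mean corrected CL vs corrected CL/yr)."""
    cf = predict_cf_dataset(model, data)
    ccl = data.corrected_cl(cf)
    batch = CentiloidBatch(
        cl_t0=ccl[data.i0],
        cl_t1=ccl[data.i1],
        uncorrected_t0=data.uncorrected_cl[data.i0],
        uncorrected_t1=data.uncorrected_cl[data.i1],
        interval_years=data.interval_years,
    )
    loss = total_loss(batch, weights, curve)
    mean_cl = (batch.cl_t0 + batch.cl_t1) / 2.0
    rate = (batch.cl_t1 - batch.cl_t0) / batch.interval_years
    rho = spearmanr(mean_cl, rate).statistic if mean_cl.size >= 3 else 0.0
    return loss, float(rho)


def train_fold(
    train_data: PairDataset,
    val_data: PairDataset,
    curve: NaturalHistoryCurve,
    grid: VolumeGrid,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> TrainResult:
    """Train one model with early stopping on the validation loss.

    Both images of a pair pass through the network in the same
    iteration, in randomised feed order; the time order (not the feed
    order) defines T0/T1 in the losses.  Returns the checkpoint with the
    best validation loss.
    """
    config = config or TrainConfig()
    if train_data.n_pairs == 0:
        raise ValueError("empty training set")
    if set(train_data.participants) & set(val_data.participants):
        raise ValueError("training and validation participants overlap")

    model = CorrectionNet(grid, config.network, seed=seed)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1_000_003)
    onehots = np.eye(len(TRACERS))

    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = 0
    bad_epochs = 0
    variants = None
    if config.augment_smooth_variants > 1 and config.augment_smooth_max_fwhm > 0:
        fwhms = np.linspace(0.0, config.augment_smooth_max_fwhm, config.augment_smooth_variants)
        variants = np.stack(
            [
                np.stack(
                    [
                        ndimage.gaussian_filter(v, f / FWHM_PER_SIGMA / grid.voxel_size_mm)
                        if f > 0
                        else v
                        for v in train_data.volumes
                    ]
                )
                for f in fwhms
            ]
        ).astype(np.float32)

    rows = []
    milestones = {int(round(m * config.max_epochs)) for m in config.lr_milestones}
    for epoch in range(1, config.max_epochs + 1):
        if epoch in milestones:
            opt.lr *= config.lr_decay_factor
        order = rng.permutation(train_data.n_pairs)
        epoch_loss, comps_acc, n_batches = 0.0, None, 0
        for start in range(0, train_data.n_pairs, config.batch_size):
            pb = order[start : start + config.batch_size]
            if pb.size < 2:
                continue
            scan_idx = np.concatenate([train_data.i0[pb], train_data.i1[pb]])
            if variants is not None:
                vidx = rng.integers(0, variants.shape[0], size=scan_idx.size)
                imgs = variants[vidx, scan_idx]
            else:
                imgs = train_data.volumes[scan_idx]
            if config.augment:
                imgs = np.stack(
                    [
                        augment(img, train_data.psf_fwhm_mm[si], rng, grid)
                        for img, si in zip(imgs, scan_idx)
                    ]
                )
            if config.augment_noise_sd > 0:
                imgs = imgs + rng.normal(0.0, config.augment_noise_sd, size=imgs.shape).astype(np.float32)
            perm = rng.permutation(scan_idx.size)  # randomised feed order
            cf_perm = model.forward(imgs[perm], onehots[train_data.tracer_idx[scan_idx[perm]]], train=True)
            cf = np.empty_like(cf_perm)
            cf[perm] = cf_perm

            suvr = train_data.suvr[scan_idx]
            slopes = train_data.slopes[scan_idx]
            ccl = slopes * cf * suvr + train_data.intercepts[scan_idx]
            ucl = train_data.uncorrected_cl[scan_idx]
            nb = pb.size
            batch = CentiloidBatch(
                cl_t0=ccl[:nb],
                cl_t1=ccl[nb:],
                uncorrected_t0=ucl[:nb],
                uncorrected_t1=ucl[nb:],
                interval_years=train_data.interval_years[pb],
            )
            loss, comps, d0, d1 = _loss_and_grads(batch, config.weights, curve)
            dcf = np.concatenate([d0, d1]) * slopes * suvr
            opt.zero_grad()
            model.backward(dcf[perm])
            opt.step()
            epoch_loss += loss
            n_batches += 1
            comps_acc = comps if comps_acc is None else {k: comps_acc[k] + v for k, v in comps.items()}

        val_loss, val_rho = _dataset_loss(model, val_data, config.weights, curve)
        row = {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches), "val_loss": val_loss,
               "val_spearman": val_rho}
        if comps_acc:
            row.update({k: v / n_batches for k, v in comps_acc.items()})
        rows.append(row)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    model.load_state_dict(best_state)
    _, val_rho = _dataset_loss(model, val_data, config.weights, curve)
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_val_loss=best_val,
        best_epoch=best_epoch,
        val_spearman=val_rho,
        seed=seed,
    )


def select_best_restart(results: list[TrainResult]) -> TrainResult:
    """Highest validation Spearman rho between mean corrected CL and
    corrected CL/year; ties broken by lowest validation loss, then by
    seed order."""
    if not results:
        raise ValueError("no candidate models")
    best = results[0]
    for cand in results[1:]:
        if cand.val_spearman > best.val_spearman or (
            cand.val_spearman == best.val_spearman and cand.best_val_loss < best.best_val_loss
        ):
            best = cand
    return best


def train_restarts(
    train_data: PairDataset,
    val_data: PairDataset,
    curve: NaturalHistoryCurve,
    grid: VolumeGrid,
    config: TrainConfig | None = None,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> tuple[TrainResult, list[TrainResult]]:
    """Best-of-N restart training (the reference protocol uses N=5)."""
    results = [train_fold(train_data, val_data, curve, grid, config, seed=s) for s in seeds]
    return select_best_restart(results), results


@dataclasses.dataclass
class CohortTrainResult:
    best: TrainResult
    results: list[TrainResult]
    curve: NaturalHistoryCurve
    train_data: PairDataset
    val_data: PairDataset
    full_data: PairDataset


def train_on_cohort(
    cohort: Cohort,
    masks: MaskPair | None = None,
    config: TrainConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.3,
    restarts: int = 1,
    curve: NaturalHistoryCurve | None = None,
) -> CohortTrainResult:
    """End-to-end desk training on a phantom cohort.

    Builds visit pairs, holds out a participant-level validation split,
    freezes the natural-history curve (fitted from standard PIB
    quantification of the training pairs unless a curve estimated on a
    larger dedicated cohort is supplied), trains ``restarts`` models and
    returns the one with the best validation Spearman.
    """
    masks = masks or cohort.layout.standard_masks()
    pairs = build_pairs(cohort.records)
    pids = sorted({r.participant_id for r in cohort.records})
    rng = np.random.default_rng(seed + 77)
    val_pids = set(rng.choice(pids, size=max(1, int(round(val_fraction * len(pids)))), replace=False))
    train_pairs = [p for p in pairs if p.scan_t0.participant_id not in val_pids]
    val_pairs = [p for p in pairs if p.scan_t0.participant_id in val_pids]
    if curve is None:
        curve = fit_curve_from_pairs(train_pairs, masks, cohort.transforms)
    train_data = PairDataset.from_pairs(train_pairs, masks, cohort.transforms)
    val_data = PairDataset.from_pairs(val_pairs, masks, cohort.transforms)
    best, results = train_restarts(
        train_data, val_data, curve, cohort.grid, config,
        seeds=tuple(seed + i for i in range(restarts)),
    )
    full_data = PairDataset.from_pairs(pairs, masks, cohort.transforms)
    return CohortTrainResult(best, results, curve, train_data, val_data, full_data)


#: Training configuration used by the desk-scale recovery experiments:
#: a capacity-matched network for the 32x40x32 grid and an optimisation
#: schedule sized for cohorts of a few hundred pairs.
DESK_TRAIN_CONFIG = TrainConfig(
    learning_rate=1e-2,
    batch_size=128,
    max_epochs=500,
    patience=200,
    augment_noise_sd=0.05,
    network=NetworkSpec(channels=(8, 16), fc_widths=(32, 16), dropout_rate=0.0),
)


# --------------------------------------------------------------------- #
# Bias-preservation (overfitting-risk) experiment


@dataclasses.dataclass
class BiasPreservationReport:
    """Subgroup comparison after the accelerated-accumulator retraining.

    The rate ratios are level-matched: each accelerated pair's rate is
    divided by the normal subgroup's fitted rate-vs-level curve at the
    same mean CL, and the median of those per-pair ratios is reported.
    Comparing raw median rates between subgroups instead would be
    dominated by which levels the few accelerated participants happen
    to occupy.
    """

    accelerated_participants: list[str]
    corrected_rates_accel: np.ndarray
    corrected_rates_normal: np.ndarray
    uncorrected_rates_accel: np.ndarray
    uncorrected_rates_normal: np.ndarray
    normal_curve_uncorrected: NaturalHistoryCurve
    normal_curve_corrected: NaturalHistoryCurve
    corrected_rate_ratio: float
    uncorrected_rate_ratio: float


def _halve_intervals(records: list[ScanRecord], flagged: set[str]) -> list[ScanRecord]:
    by_pid: dict[str, list[ScanRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    out: list[ScanRecord] = []
    for pid, recs in by_pid.items():
        recs = sorted(recs, key=lambda r: r.acquisition_date)
        if pid in flagged:
            t0 = recs[0].acquisition_date
            for rec in recs:
                half_days = (rec.acquisition_date - t0).days // 2
                new_date = t0 + _dt.timedelta(days=half_days)
                out.append(dataclasses.replace(rec, acquisition_date=new_date))
        else:
            out.extend(recs)
    return out


def run_bias_preservation_experiment(
    cohort: Cohort,
    masks: MaskPair,
    fraction: float = 0.10,
    config: TrainConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.4,
    evaluate_on: str = "validation",
) -> BiasPreservationReport:
    """Retrain on a cohort where a random subset accumulates twice as fast.

    A fraction of participants has the time interval between their scans
    halved, which exactly doubles their uncorrected annual rate.  After
    retraining (curve refitted on the modified data, then frozen), the
    corrected rates of the accelerated subgroup must remain clearly
    separated from the normal subgroup — the correction should not
    collapse a genuinely distinct trajectory onto the population curve.
    Rate medians are compared within accumulating participants, where a
    trajectory difference is expressible.
    """
    rng = np.random.default_rng(seed)
    pids = sorted({r.participant_id for r in cohort.records})
    n_flag = max(1, int(round(fraction * len(pids)))) if fraction > 0 else 0
    flagged = set(rng.choice(pids, size=n_flag, replace=False)) if n_flag else set()

    records = _halve_intervals([dataclasses.replace(r) for r in cohort.records], flagged)
    pairs = build_pairs(records)
    curve = fit_curve_from_pairs(pairs, masks, cohort.transforms)

    val_pids = set(rng.choice(pids, size=int(round(val_fraction * len(pids))), replace=False))
    train_pairs = [p for p in pairs if p.scan_t0.participant_id not in val_pids]
    val_pairs = [p for p in pairs if p.scan_t0.participant_id in val_pids]
    train_data = PairDataset.from_pairs(train_pairs, masks, cohort.transforms)
    val_data = PairDataset.from_pairs(val_pairs, masks, cohort.transforms)
    result = train_fold(train_data, val_data, curve, cohort.grid, config, seed=seed)

    # trajectory preservation is judged out of sample, on held-out
    # participants, mirroring out-of-fold evaluation
    eval_pairs = val_pairs if evaluate_on == "validation" else pairs
    full_data = PairDataset.from_pairs(eval_pairs, masks, cohort.transforms)
    cf = predict_cf_dataset(result.model, full_data)
    ccl = full_data.corrected_cl(cf)
    ucl = full_data.uncorrected_cl
    rate_c = (ccl[full_data.i1] - ccl[full_data.i0]) / full_data.interval_years
    rate_u = (ucl[full_data.i1] - ucl[full_data.i0]) / full_data.interval_years
    pair_pid = np.array([full_data.participants[i] for i in full_data.i0])
    is_flag = np.array([p in flagged for p in pair_pid])

    # Compare medians over pairs with non-trivial true dynamics: flat
    # (negative or saturated) trajectories have near-zero rates in both
    # subgroups and only dilute the comparison with selection noise.
    # Visit order is preserved by the interval halving, so true CLs are
    # matched to scans by (participant, visit rank).
    truth_sorted = cohort.truth.sort_values(["participant_id", "date"])
    true_by_rank = {
        (pid, rank): cl
        for pid, grp in truth_sorted.groupby("participant_id")
        for rank, cl in enumerate(grp["true_cl"])
    }
    scan_rank: dict[tuple, int] = {}
    by_pid: dict[str, list[ScanRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    for pid, recs in by_pid.items():
        for rank, rec in enumerate(sorted(recs, key=lambda r: r.acquisition_date)):
            scan_rank[(pid, rec.acquisition_date)] = rank

    true_scan_cl = np.empty(len(full_data.participants))
    order_index: dict[int, int] = {}
    for p in eval_pairs:  # PairDataset assigns scan indices in this order
        for s in (p.scan_t0, p.scan_t1):
            if id(s) not in order_index:
                i = len(order_index)
                order_index[id(s)] = i
                rank = scan_rank[(s.participant_id, s.acquisition_date)]
                true_scan_cl[i] = true_by_rank[(s.participant_id, rank)]
    true_rate = (true_scan_cl[full_data.i1] - true_scan_cl[full_data.i0]) / full_data.interval_years
    is_acc = np.abs(true_rate) > 0.5

    mean_c = (ccl[full_data.i1] + ccl[full_data.i0]) / 2.0
    mean_u = (ucl[full_data.i1] + ucl[full_data.i0]) / 2.0

    def matched_ratio(rates, means):
        """Median of accelerated rates over the normal subgroup's fitted
        rate-vs-level curve at matched mean CL, normalised by the same
        statistic over the normal subgroup itself (which equals 1 up to
        curve-estimation bias, so the normalisation removes that bias)."""
        sel_norm = ~is_flag
        curve = fit_natural_history(means[sel_norm], rates[sel_norm])

        def group_ratio(sel):
            expected = np.asarray(curve(means[sel]))
            usable = expected > 0.5  # avoid near-zero denominators
            if not np.any(sel) or not np.any(usable):
                return float("nan")
            return float(np.median(rates[sel][usable] / expected[usable]))

        self_check = group_ratio(sel_norm & is_acc)
        accel = group_ratio(is_flag & is_acc)
        return curve, accel / self_check if self_check else float("nan")

    curve_u, ratio_u = matched_ratio(rate_u, mean_u)
    curve_c, ratio_c = matched_ratio(rate_c, mean_c)
    return BiasPreservationReport(
        accelerated_participants=sorted(flagged),
        corrected_rates_accel=rate_c[is_acc & is_flag],
        corrected_rates_normal=rate_c[is_acc & ~is_flag],
        uncorrected_rates_accel=rate_u[is_acc & is_flag],
        uncorrected_rates_normal=rate_u[is_acc & ~is_flag],
        normal_curve_uncorrected=curve_u,
        normal_curve_corrected=curve_c,
        corrected_rate_ratio=ratio_c,
        uncorrected_rate_ratio=ratio_u,
    )
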