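"""Phantom longitudinal amyloid-PET cohorts on the template grid.

The generator renders a geometric brain phantom — a cortical target
shell and an inferior cerebellar-analogue reference (grey + white
blobs) inside an ellipsoidal brain — and drives it with sigmoid
natural-history trajectories.  Tracer-specific multiplicative bias on
the reference region, per-scan Gaussian PSF blurring (<= 8 mm FWHM) and
voxel noise reproduce, in miniature, the variability between tracers
and scanners that motivates the correction model.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import (
    DESK_GRID,
    FWHM_PER_SIGMA,
    TRACERS,
    BrainMask,
    ScanRecord,
    VolumeGrid,
    save_volume,
    suvr_normalise,
    write_manifest,
)
from .quantify import CentiloidTransform, MaskPair, TransformTable, compute_suvr


@dataclasses.dataclass(frozen=True)
class SigmoidParams:
    """Logistic accumulation CL(age) = cl_max / (1 + exp(-(age-onset)/slope)).

    ``slope_years`` is the logistic time constant; the peak accumulation
    rate is cl_max / (4 * slope_years), reached at CL = cl_max/2.
    """

    cl_max: float = 100.0
    onset_age_mean: float = 72.0
    onset_age_sd: float = 5.0
    slope_years: float = 3.0


@dataclasses.dataclass(frozen=True)
class VisitSchedule:
    """Two visits ~1.5 years apart by default: a homogeneous interval
    distribution keeps the mean-level -> secant-rate relation consistent
    across pairs, which is what the curve prior assumes."""

    n_visits: int = 2
    spacing_mean_years: float = 1.5
    spacing_sd_years: float = 0.15


@dataclasses.dataclass
class SimConfig:
    n_participants: int = 100
    tracers: dict | None = None  # tracer -> sampling weight
    visit_schedule: VisitSchedule = dataclasses.field(default_factory=VisitSchedule)
    sigmoid: SigmoidParams = dataclasses.field(default_factory=SigmoidParams)
    #: accumulator-enriched, as longitudinal amyloid training sets are
    negative_fraction: float = 0.10
    tracer_ref_bias: dict | None = None  # tracer -> multiplicative reference bias
    noise_sd: float = 0.02  # voxel noise, as a fraction of the reference mean
    psf_range_mm: tuple[float, float] = (5.0, 7.0)
    #: probability that a follow-up visit happens on a different scanner
    #: (i.e. redraws its PSF); visits otherwise keep the previous PSF.
    psf_change_prob: float = 0.2
    seed: int = 0
    baseline_age_mean: float = 72.0
    baseline_age_sd: float = 5.0
    specific_amplitude: float = 2.0  # upper-shell uptake spans [1, 1+amplitude]
    #: fraction of the specific signal expressed in the lower shell — the
    #: standard target mask covers the whole shell, so its SUVR is a
    #: diluted version of the 'clean' upper-shell SUVR.
    lower_shell_fraction: float = 0.3
    background_level: float = 0.6
    #: white-matter reference level: mean 1 (matching grey), but variable
    #: across scans — non-specific white-matter binding differs between
    #: individuals and drifts between visits, making the white blob a
    #: noisy reference subregion.
    wm_level_sd: float = 0.05
    grid: VolumeGrid = dataclasses.field(default_factory=lambda: DESK_GRID)

    def __post_init__(self) -> None:
        if self.tracers is None:
            # the unbiased anchor tracer dominates; any biased tracer is
            # a minority, as in the pooled multi-study training regime
            self.tracers = {"PIB": 0.75, "FBB": 0.25}
        if self.tracer_ref_bias is None:
            self.tracer_ref_bias = {}
        for t in list(self.tracers) + list(self.tracer_ref_bias):
            if t not in TRACERS:
                raise ValueError(f"unknown tracer {t!r}")
        if any(b <= 0 for b in self.tracer_ref_bias.values()):
            raise ValueError("reference biases must be positive")
        if self.sigmoid.cl_max <= 0:
            raise ValueError("cl_max must be positive")
        lo, hi = self.psf_range_mm
        if not (0 <= lo <= hi <= 8.0):
            raise ValueError("psf_range_mm must lie within [0, 8]")
        if not (0 <= self.negative_fraction <= 1):
            raise ValueError("negative_fraction must be in [0, 1]")

    def bias(self, tracer: str) -> float:
        return float(self.tracer_ref_bias.get(tracer, 1.0))


@dataclasses.dataclass
class PhantomLayout:
    """Disjoint voxel regions of the phantom, all inside the brain.

    The cortical shell is split into an upper part, which carries the
    full amyloid-specific signal, and a lower part expressing only a
    fraction of it; the standard target mask covers the whole shell.
    """

    target_region: np.ndarray
    target_upper: np.ndarray
    target_lower: np.ndarray
    reference_gm: np.ndarray
    reference_wm: np.ndarray
    brain: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        overlap = self.target_region * self.reference_gm + self.target_region * self.reference_wm
        overlap = overlap + self.reference_gm * self.reference_wm
        if overlap.sum() > 0:
            raise ValueError("phantom regions must be disjoint")
        for region in (self.target_region, self.reference_gm, self.reference_wm):
            if np.any(region * (1 - self.brain)):
                raise ValueError("phantom regions must lie within the brain")

    @property
    def reference(self) -> np.ndarray:
        """Whole reference region (cerebellar analogue): grey + white."""
        return self.reference_gm + self.reference_wm

    def standard_masks(self) -> MaskPair:
        return MaskPair(reference=self.reference.copy(), target=self.target_region.copy())

    def brain_mask(self) -> BrainMask:
        return BrainMask(self.brain.copy())


def make_layout(grid: VolumeGrid = DESK_GRID) -> PhantomLayout:
    """Concentric-shell phantom scaled to the grid, symmetric about the
    left-right axis so mask mirroring is well-posed."""
    shape = np.asarray(grid.shape, dtype=float)
    cx, cy, cz = (shape - 1) / 2.0
    idx = np.indices(grid.shape).astype(float)
    sx, sy, sz = idx

    scale = min(grid.shape) / 32.0  # voxel radii below are for the 32-voxel axis
    brain = (
        ((sx - cx) / (0.46 * shape[0])) ** 2
        + ((sy - cy) / (0.46 * shape[1])) ** 2
        + ((sz - cz) / (0.46 * shape[2])) ** 2
    ) <= 1.0

    # Cortical target: a spherical shell in the superior half.
    tz = cz + 3.0 * scale
    r_t = np.sqrt((sx - cx) ** 2 + (sy - cy) ** 2 + (sz - tz) ** 2)
    target = (r_t >= 6.0 * scale) & (r_t <= 8.5 * scale) & (sz >= tz - 2.0 * scale)

    # Cerebellar analogue, inferior: grey blob and adjacent white blob.
    gz, gy = cz - 9.0 * scale, cy - 4.0 * scale
    gm = ((sx - cx) ** 2 + (sy - gy) ** 2 + (sz - gz) ** 2) <= (4.0 * scale) ** 2
    wy = cy + 6.0 * scale
    wm = ((sx - cx) ** 2 + (sy - wy) ** 2 + (sz - gz) ** 2) <= (3.0 * scale) ** 2

    brain = brain | target | gm | wm
    target = target & ~(gm | wm)
    upper = target & (sz >= tz)
    layout = PhantomLayout(
        target_region=target.astype(np.float64),
        target_upper=upper.astype(np.float64),
        target_lower=(target & ~upper).astype(np.float64),
        reference_gm=(gm & ~target).astype(np.float64),
        reference_wm=(wm & ~gm & ~target).astype(np.float64),
        brain=brain.astype(np.float64),
        grid=grid,
    )
    return layout


def hidden_mask_pair(layout: PhantomLayout) -> MaskPair:
    """The 'clean' quantification mask pair used as a recovery oracle:
    only the fully-expressing upper shell as target, and only the stable
    grey blob (excluding the noisy white blob) as reference."""
    return MaskPair(
        reference=layout.reference_gm.copy(),
        target=layout.target_upper.copy(),
    )


# --------------------------------------------------------------------- #
# Trajectories


@dataclasses.dataclass
class ParticipantTruth:
    participant_id: str
    tracer: str
    is_accumulator: bool
    visit_years: np.ndarray  # years from baseline
    true_cls: np.ndarray


def _sigmoid_cl(age: np.ndarray, onset: float, params: SigmoidParams) -> np.ndarray:
    return params.cl_max / (1.0 + np.exp(-(age - onset) / params.slope_years))


def analytic_rate(cl: np.ndarray, params: SigmoidParams) -> np.ndarray:
    """dCL/dt of the logistic trajectory as a function of the level."""
    cl = np.asarray(cl, dtype=np.float64)
    return cl * (1.0 - cl / params.cl_max) / params.slope_years


def simulate_trajectories(config: SimConfig, rng: np.random.Generator | None = None) -> list[ParticipantTruth]:
    """Sample per-participant visit times and true Centiloid burdens.

    Accumulators follow the logistic natural history; non-accumulators
    sit flat at a small positive baseline.  All trajectories are
    non-decreasing in true CL.
    """
    rng = rng or np.random.default_rng(config.seed)
    tracers = list(config.tracers)
    weights = np.asarray([config.tracers[t] for t in tracers], dtype=float)
    weights = weights / weights.sum()
    out: list[ParticipantTruth] = []
    for i in range(config.n_participants):
        pid = f"sub-{i:04d}"
        tracer = tracers[rng.choice(len(tracers), p=weights)]
        sched = config.visit_schedule
        gaps = np.clip(
            rng.normal(sched.spacing_mean_years, sched.spacing_sd_years, size=sched.n_visits - 1),
            0.3,
            3.4,
        )
        years = np.concatenate([[0.0], np.cumsum(gaps)])
        is_acc = rng.random() >= config.negative_fraction
        if is_acc:
            baseline_age = rng.normal(config.baseline_age_mean, config.baseline_age_sd)
            onset = rng.normal(config.sigmoid.onset_age_mean, config.sigmoid.onset_age_sd)
            cls = _sigmoid_cl(baseline_age + years, onset, config.sigmoid)
        else:
            base = abs(rng.normal(0.0, 2.0))
            cls = np.full_like(years, base)
        out.append(ParticipantTruth(pid, tracer, bool(is_acc), years, cls))
    return out


# --------------------------------------------------------------------- #
# Rendering


def render_volume(
    true_cl: float,
    tracer: str,
    layout: PhantomLayout,
    config: SimConfig,
    psf_fwhm_mm: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one SUVR-normalised phantom volume.

    Piecewise-constant uptake (target 1 + amplitude * CL/cl_max, whole
    reference at the tracer bias, brain background) is blurred with the
    scanner PSF, perturbed with Gaussian voxel noise, brain-masked, and
    normalised by the whole-reference mean.  A reference bias k
    therefore deflates the standard SUVR by a factor of ~k.
    """
    bias = config.bias(tracer)
    vol = layout.brain * config.background_level
    level = true_cl / config.sigmoid.cl_max
    upper_level = 1.0 + config.specific_amplitude * level
    lower_level = 1.0 + config.specific_amplitude * config.lower_shell_fraction * level
    vol = vol * (1 - layout.target_region)
    vol = vol + layout.target_upper * upper_level + layout.target_lower * lower_level
    wm_level = 1.0
    if config.wm_level_sd > 0:
        if rng is None:
            raise ValueError("white-matter level variability requires an rng")
        wm_level = max(0.1, 1.0 + rng.normal(0.0, config.wm_level_sd))
    vol = vol * (1 - layout.reference_gm) + layout.reference_gm * bias
    vol = vol * (1 - layout.reference_wm) + layout.reference_wm * bias * wm_level

    if psf_fwhm_mm > 0:
        sigma_vox = psf_fwhm_mm / FWHM_PER_SIGMA / layout.grid.voxel_size_mm
        vol = gaussian_filter(vol, sigma_vox)
    if config.noise_sd > 0:
        if rng is None:
            raise ValueError("voxel noise requires an rng")
        vol = vol + rng.normal(0.0, config.noise_sd * bias, size=vol.shape)
        vol = np.clip(vol, 0.0, None)
    vol = vol * layout.brain
    return suvr_normalise(vol, layout.reference)


def render_scan(
    true_cl: float,
    tracer: str,
    layout: PhantomLayout,
    config: SimConfig,
    rng: np.random.Generator,
    participant_id: str = "sub-0000",
    acquisition_date: _dt.date = _dt.date(2020, 1, 1),
    psf_fwhm_mm: float | None = None,
) -> ScanRecord:
    if psf_fwhm_mm is None:
        psf_fwhm_mm = float(rng.uniform(*config.psf_range_mm))
    volume = render_volume(true_cl, tracer, layout, config, psf_fwhm_mm, rng)
    return ScanRecord(
        participant_id=participant_id,
        acquisition_date=acquisition_date,
        tracer=tracer,
        scanner_psf_fwhm_mm=psf_fwhm_mm,
        volume=volume,
        is_suvr_normalised=True,
    )


def calibrate_transforms(layout: PhantomLayout, config: SimConfig) -> TransformTable:
    """Anchor per-tracer Centiloid transforms under calibration conditions.

    Mirrors the published-calibration setting: noise-free, unbiased
    renderings at a representative scanner PSF, with the young-control
    (CL 0) anchor mapped to 0 and the typical-AD (CL cl_max) anchor to
    100.  Study-specific reference bias is deliberately absent here, so
    it survives as a residual quantification bias — exactly the effect
    the correction model must learn to remove.
    """
    calib = dataclasses.replace(config, tracer_ref_bias={}, noise_sd=0.0, wm_level_sd=0.0)
    psf = float(np.mean(config.psf_range_mm))
    masks = layout.standard_masks()
    transforms = {}
    for tracer in config.tracers:
        s0 = compute_suvr(render_volume(0.0, tracer, layout, calib, psf), masks)
        s1 = compute_suvr(render_volume(config.sigmoid.cl_max, tracer, layout, calib, psf), masks)
        slope = 100.0 / (s1 - s0)
        transforms[tracer] = CentiloidTransform(tracer, slope, -slope * s0)
    return TransformTable(transforms)


# --------------------------------------------------------------------- #
# Cohort assembly


@dataclasses.dataclass
class Cohort:
    records: list[ScanRecord]
    truth: pd.DataFrame
    layout: PhantomLayout
    transforms: TransformTable
    config: SimConfig

    @property
    def grid(self) -> VolumeGrid:
        return self.config.grid


def make_cohort(config: SimConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a complete phantom cohort.

    Returns in-memory scan records plus a ground-truth table (true CL,
    injected bias, PSF per scan) for oracle-based tests, and per-tracer
    Centiloid transforms anchored under unbiased calibration conditions.
    With ``out_dir`` set, also writes NIfTI volumes, the manifest CSV,
    ``ground_truth.csv``, ``transforms.json`` and the layout masks.
    """
    rng = np.random.default_rng(config.seed)
    layout = make_layout(config.grid)
    participants = simulate_trajectories(config, rng)
    transforms = calibrate_transforms(layout, config)

    base_date = _dt.date(2020, 1, 1)
    records: list[ScanRecord] = []
    truth_rows = []
    for part in participants:
        psf = float(rng.uniform(*config.psf_range_mm))
        for visit, (years, cl) in enumerate(zip(part.visit_years, part.true_cls)):
            if visit > 0 and rng.random() < config.psf_change_prob:
                psf = float(rng.uniform(*config.psf_range_mm))
            date = base_date + _dt.timedelta(days=round(years * 365.25))
            rec = render_scan(
                float(cl), part.tracer, layout, config, rng,
                participant_id=part.participant_id, acquisition_date=date,
                psf_fwhm_mm=psf,
            )
            records.append(rec)
            truth_rows.append(
                {
                    "participant_id": part.participant_id,
                    "date": date.isoformat(),
                    "tracer": part.tracer,
                    "psf_fwhm_mm": rec.scanner_psf_fwhm_mm,
                    "true_cl": float(cl),
                    "ref_bias": config.bias(part.tracer),
                    "is_accumulator": part.is_accumulator,
                }
            )
    truth = pd.DataFrame(truth_rows)
    cohort = Cohort(records, truth, layout, transforms, config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vol_dir = out_dir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for rec in records:
            name = f"{rec.participant_id}_{rec.acquisition_date.isoformat()}.nii.gz"
            save_volume(rec.volume, vol_dir / name, grid=config.grid)
            rec.volume_path = str(Path("volumes") / name)
        write_manifest(records, out_dir / "manifest.csv")
        for rec in records:  # restore absolute paths for in-session use
            rec.volume_path = str(vol_dir / Path(rec.volume_path).name)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        transforms.to_json(out_dir / "transforms.json")
        masks = layout.standard_masks()
        save_volume(masks.reference, out_dir / "reference_mask.nii.gz", grid=config.grid)
        save_volume(masks.target, out_dir / "target_mask.nii.gz", grid=config.grid)
        save_volume(layout.brain, out_dir / "brain_mask.nii.gz", grid=config.grid)
    return cohort
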