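"""Template-space volume I/O, cohort manifests, and voxel-grid conventions.

All volumes handled by the package live on a single :class:`VolumeGrid` —
a regular, isotropic voxel lattice standing in for the MNI template grid
PET scans are spatially normalised to.  The full-resolution grid is
91x109x91 at 2 mm; the default desk-scale grid is 32x40x32 at 4 mm so the
whole pipeline runs on a laptop CPU.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: The five amyloid tracers the model knows about.
TRACERS = ("PIB", "NAV", "FBB", "FBP", "FMM")

#: Hard ceiling on scanner point-spread function, in mm FWHM.
MAX_PSF_FWHM_MM = 8.0

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

MANIFEST_COLUMNS = ["participant_id", "date", "tracer", "psf_fwhm_mm", "volume_path"]


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """Isotropic voxel lattice in template space.

    Parameters
    ----------
    shape
        Voxels per axis; every entry must be >= 4.
    voxel_size_mm
        Isotropic voxel edge length in mm.
    left_right_axis
        Axis index flipped when mirroring a volume about the template
        mid-sagittal plane (axis 0 in the usual template orientation).
    """

    shape: tuple[int, int, int] = (32, 40, 32)
    voxel_size_mm: float = 4.0
    left_right_axis: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 4 for s in self.shape):
            raise ValueError(f"grid shape must be a triple with entries >= 4, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.left_right_axis not in (0, 1, 2):
            raise ValueError("left_right_axis must be 0, 1 or 2")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.shape) - 1) / 2.0
        return aff

    def mirror(self, volume: np.ndarray) -> np.ndarray:
        """Reflect a volume about the left-right axis."""
        return np.flip(volume, axis=self.left_right_axis)

    def new_volume(self, fill: float = 0.0, dtype=np.float64) -> np.ndarray:
        return np.full(self.shape, fill, dtype=dtype)


#: Full-resolution template grid (2 mm MNI-like).
FULL_SCALE_GRID = VolumeGrid(shape=(91, 109, 91), voxel_size_mm=2.0)

#: Default desk-scale grid used throughout the tests and examples.
DESK_GRID = VolumeGrid(shape=(32, 40, 32), voxel_size_mm=4.0)


@dataclasses.dataclass
class ScanRecord:
    """One spatially normalised PET volume plus acquisition metadata."""

    participant_id: str
    acquisition_date: _dt.date
    tracer: str
    scanner_psf_fwhm_mm: float
    volume: np.ndarray
    is_suvr_normalised: bool = False
    volume_path: str | None = None

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}; expected one of {TRACERS}")
        if not (0.0 <= self.scanner_psf_fwhm_mm <= MAX_PSF_FWHM_MM):
            raise ValueError(
                f"scanner_psf_fwhm_mm must be in [0, {MAX_PSF_FWHM_MM}], "
                f"got {self.scanner_psf_fwhm_mm}"
            )
        if self.volume is not None and not np.all(np.isfinite(self.volume)):
            raise ValueError("scan volume contains non-finite values")


@dataclasses.dataclass
class BrainMask:
    """Binary brain mask; ``n_voxels`` (B) is the non-zero voxel count."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("brain mask must be binary")
        self.mask = self.mask.astype(np.float64)
        if self.n_voxels == 0:
            raise ValueError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def load_volume(path: str | Path, grid: VolumeGrid | None = None) -> np.ndarray:
    """Load a NIfTI-1 volume, optionally checking it matches ``grid``."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if grid is not None and tuple(data.shape) != grid.shape:
        raise ValueError(f"volume shape {tuple(data.shape)} does not match grid shape {grid.shape}")
    return data


def save_volume(volume: np.ndarray, path: str | Path, grid: VolumeGrid | None = None) -> None:
    """Write a volume as NIfTI-1 on the grid's affine."""
    if grid is not None and tuple(volume.shape) != grid.shape:
        raise ValueError(f"volume shape {tuple(volume.shape)} does not match grid shape {grid.shape}")
    affine = grid.affine if grid is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_manifest(
    path: str | Path,
    grid: VolumeGrid | None = None,
    load_volumes: bool = True,
) -> list[ScanRecord]:
    """Parse a cohort manifest CSV into sorted :class:`ScanRecord` objects.

    The CSV must carry the header ``participant_id,date,tracer,psf_fwhm_mm,
    volume_path``; dates are ISO-8601.  Records come back sorted by
    (participant_id, date) — the order every downstream module relies on.
    Two scans of one participant on the same day are rejected: visit
    pairing needs a strict time order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")

    records: list[ScanRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        tracer = str(row.tracer)
        if tracer not in TRACERS:
            raise ValueError(f"unknown tracer {tracer!r} in manifest row {row_number}")
        try:
            date = _dt.date.fromisoformat(str(row.date))
        except ValueError as exc:
            raise ValueError(f"bad date {row.date!r} in manifest row {row_number}") from exc
        vol_path = Path(str(row.volume_path))
        if not vol_path.is_absolute():
            vol_path = path.parent / vol_path
        volume = None
        if load_volumes:
            if not vol_path.exists():
                raise FileNotFoundError(f"volume file not found: {vol_path}")
            volume = load_volume(vol_path, grid=grid)
        records.append(
            ScanRecord(
                participant_id=str(row.participant_id),
                acquisition_date=date,
                tracer=tracer,
                scanner_psf_fwhm_mm=float(row.psf_fwhm_mm),
                volume=volume,
                volume_path=str(vol_path),
            )
        )

    records.sort(key=lambda r: (r.participant_id, r.acquisition_date))
    seen: set[tuple[str, _dt.date]] = set()
    for rec in records:
        key = (rec.participant_id, rec.acquisition_date)
        if key in seen:
            raise ValueError(
                f"duplicate acquisition date {rec.acquisition_date} for participant "
                f"{rec.participant_id}"
            )
        seen.add(key)
    return records


def write_manifest(records: list[ScanRecord], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "date": r.acquisition_date.isoformat(),
            "tracer": r.tracer,
            "psf_fwhm_mm": r.scanner_psf_fwhm_mm,
            "volume_path": r.volume_path,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def suvr_normalise(volume: np.ndarray, whole_cerebellum_mask: np.ndarray) -> np.ndarray:
    """Divide a volume by its mean uptake over the whole-cerebellum mask.

    After normalisation the mask-weighted mean is exactly 1, which makes
    the operation idempotent and invariant to global intensity scaling.
    """
    mask = np.asarray(whole_cerebellum_mask, dtype=np.float64)
    mass = mask.sum()
    if mass <= 0:
        raise ValueError("whole-cerebellum mask has no mass")
    ref_mean = float((volume * mask).sum() / mass)
    if ref_mean <= 0:
        raise ValueError(f"whole-cerebellum mean must be positive, got {ref_mean}")
    return volume / ref_mean
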