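"""SUVR computation and per-tracer SUVR <-> Centiloid linear transforms.

SUVR is the target-region mean uptake divided by the reference-region
mean.  Masks may be continuous (values in [0,1]); voxel values then act
as weights, which is what the mask optimiser needs before thresholding.
The Centiloid scale is a per-tracer affine rescaling of SUVR anchored at
0 (young-control mean) and 100 (typical-AD mean).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import TRACERS


@dataclasses.dataclass(frozen=True)
class CentiloidTransform:
    tracer: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("Centiloid transform slope must be non-zero")


class TransformTable:
    """One Centiloid transform per tracer."""

    def __init__(self, transforms: dict[str, CentiloidTransform]):
        for tracer, tf in transforms.items():
            if tf.tracer != tracer:
                raise ValueError(f"transform keyed {tracer!r} labelled {tf.tracer!r}")
        self._transforms = dict(transforms)

    def __contains__(self, tracer: str) -> bool:
        return tracer in self._transforms

    def __getitem__(self, tracer: str) -> CentiloidTransform:
        if tracer not in self._transforms:
            raise KeyError(f"no Centiloid transform for tracer {tracer!r}")
        return self._transforms[tracer]

    def to_json(self, path: str | Path) -> None:
        payload = {
            t: {"slope": tf.slope, "intercept": tf.intercept} for t, tf in self._transforms.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                t: CentiloidTransform(t, float(v["slope"]), float(v["intercept"]))
                for t, v in payload.items()
                if t in TRACERS
            }
        )


@dataclasses.dataclass
class MaskPair:
    """Continuous reference and target masks on the scan grid."""

    reference: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        if self.reference.shape != self.target.shape:
            raise ValueError("reference and target masks must share a grid")
        for name, m in (("reference", self.reference), ("target", self.target)):
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} mask values must lie in [0,1]")
            if m.sum() <= 0:
                raise ValueError(f"{name} mask has no mass")


def compute_suvr(volume: np.ndarray, masks: MaskPair) -> float:
    """Weighted target mean over weighted reference mean."""
    ref_mass = masks.reference.sum()
    tgt_mass = masks.target.sum()
    if ref_mass <= 0 or tgt_mass <= 0:
        raise ValueError("masks must have positive mass")
    ref_mean = float((volume * masks.reference).sum() / ref_mass)
    tgt_mean = float((volume * masks.target).sum() / tgt_mass)
    if ref_mean <= 0:
        raise ValueError(f"reference-weighted mean must be positive, got {ref_mean}")
    return tgt_mean / ref_mean


def suvr_to_centiloid(suvr: float, tracer: str, transforms: TransformTable) -> float:
    tf = transforms[tracer]
    return tf.slope * suvr + tf.intercept


def centiloid_to_suvr(cl: float, tracer: str, transforms: TransformTable) -> float:
    tf = transforms[tracer]
    return (cl - tf.intercept) / tf.slope


def apply_correction(suvr: float, cf: float) -> float:
    """Corrected SUVR = CF * SUVR, with CF constrained to [0, 2] upstream."""
    if not (0.0 <= cf <= 2.0):
        raise ValueError(f"correction factor must lie in [0,2], got {cf}")
    if suvr < 0:
        raise ValueError("SUVR must be non-negative")
    return cf * suvr
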