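"""Longitudinal visit pairs and the amyloid natural-history curve.

Amyloid accumulation follows a stereotyped sigmoid trajectory, so the
current Centiloid level of a participant is predictive of their expected
annual rate of change.  The curve ``fc`` capturing that relation is a
LOWESS smooth of (mean CL, CL/year) points over all eligible visit pairs
and serves as the temporal prior in the correction losses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import ScanRecord

#: Eligible inter-scan window in years: at least 3 months, at most 3.5 years.
MIN_INTERVAL_YEARS = 0.25
MAX_INTERVAL_YEARS = 3.5

_DAYS_PER_YEAR = 365.25


@dataclasses.dataclass
class VisitPair:
    """Two scans of one participant ordered by acquisition time."""

    scan_t0: ScanRecord
    scan_t1: ScanRecord

    def __post_init__(self) -> None:
        if self.scan_t0.participant_id != self.scan_t1.participant_id:
            raise ValueError("visit pair must come from a single participant")
        if self.scan_t1.acquisition_date <= self.scan_t0.acquisition_date:
            raise ValueError("scan_t1 must be strictly after scan_t0")
        if not (MIN_INTERVAL_YEARS <= self.interval_years <= MAX_INTERVAL_YEARS):
            raise ValueError(
                f"interval {self.interval_years:.3f} y outside "
                f"[{MIN_INTERVAL_YEARS}, {MAX_INTERVAL_YEARS}]"
            )

    @property
    def interval_years(self) -> float:
        delta = self.scan_t1.acquisition_date - self.scan_t0.acquisition_date
        return delta.days / _DAYS_PER_YEAR


def build_pairs(scans: list[ScanRecord]) -> list[VisitPair]:
    """All ordered within-participant pairs inside the interval window.

    Every permutation is used: three eligible visits yield the pairs
    [1-2], [2-3] and [1-3].  Pairs never cross participants.
    """
    by_participant: dict[str, list[ScanRecord]] = {}
    for scan in scans:
        by_participant.setdefault(scan.participant_id, []).append(scan)

    pairs: list[VisitPair] = []
    for pid in sorted(by_participant):
        visits = sorted(by_participant[pid], key=lambda s: s.acquisition_date)
        for i in range(len(visits)):
            for j in range(i + 1, len(visits)):
                delta = (visits[j].acquisition_date - visits[i].acquisition_date).days
                years = delta / _DAYS_PER_YEAR
                if MIN_INTERVAL_YEARS <= years <= MAX_INTERVAL_YEARS:
                    pairs.append(VisitPair(visits[i], visits[j]))
    return pairs


def pair_statistics(pair: VisitPair, cl_t0: float, cl_t1: float) -> tuple[float, float]:
    """Mean Centiloid and annual rate of change for one pair."""
    mean_cl = (cl_t0 + cl_t1) / 2.0
    rate = (cl_t1 - cl_t0) / pair.interval_years
    return mean_cl, rate


@dataclasses.dataclass
class NaturalHistoryCurve:
    """Piecewise-linear map from mean Centiloid to expected CL/year.

    Inside the observed support the curve equals the LOWESS smooth
    evaluated on a fixed grid; outside, it clamps to the boundary value
    so extreme corrected Centiloids never see an unbounded prior.
    """

    grid: np.ndarray
    values: np.ndarray
    smoothing_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be matching 1-D arrays")
        if not (0 < self.smoothing_fraction <= 1):
            raise ValueError("smoothing_fraction must be in (0, 1]")

    @property
    def support_range(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def __call__(self, mean_cl) -> np.ndarray | float:
        x = np.asarray(mean_cl, dtype=np.float64)
        out = np.interp(x, self.grid, self.values)  # np.interp clamps outside
        return float(out) if np.isscalar(mean_cl) else out

    def derivative(self, mean_cl) -> np.ndarray | float:
        """Slope of the piecewise-linear curve; zero outside the support."""
        x = np.atleast_1d(np.asarray(mean_cl, dtype=np.float64))
        seg = np.clip(np.searchsorted(self.grid, x, side="right") - 1, 0, len(self.grid) - 2)
        dx = self.grid[seg + 1] - self.grid[seg]
        slope = np.where(dx > 0, (self.values[seg + 1] - self.values[seg]) / np.where(dx > 0, dx, 1.0), 0.0)
        slope = np.where((x < self.grid[0]) | (x > self.grid[-1]), 0.0, slope)
        return float(slope[0]) if np.isscalar(mean_cl) else slope

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "grid": self.grid.tolist(),
                    "values": self.values.tolist(),
                    "smoothing_fraction": self.smoothing_fraction,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NaturalHistoryCurve":
        payload = json.loads(Path(path).read_text())
        return cls(
            grid=np.asarray(payload["grid"]),
            values=np.asarray(payload["values"]),
            smoothing_fraction=float(payload["smoothing_fraction"]),
        )


def fit_natural_history(
    mean_cls: np.ndarray,
    rates: np.ndarray,
    smoothing_fraction: float = 0.2,
    n_grid: int = 256,
    robustness_iterations: int = 1,
) -> NaturalHistoryCurve:
    """LOWESS fit of CL/year against mean CL.

    Tricube-weighted local linear regression (span ``smoothing_fraction``,
    one robustness iteration) evaluated on a uniform grid over the
    observed mean-CL support, then linearly interpolated.
    """
    mean_cls = np.asarray(mean_cls, dtype=np.float64)
    rates = np.asarray(rates, dtype=np.float64)
    if mean_cls.shape != rates.shape or mean_cls.ndim != 1:
        raise ValueError("mean_cls and rates must be matching 1-D arrays")
    if mean_cls.size < 20:
        raise ValueError(f"insufficient pairs for curve fitting: {mean_cls.size} < 20")
    if not (np.all(np.isfinite(mean_cls)) and np.all(np.isfinite(rates))):
        raise ValueError("curve fitting requires finite values")

    grid = np.linspace(mean_cls.min(), mean_cls.max(), n_grid)
    if grid[0] == grid[-1]:
        values = np.full(n_grid, rates.mean())
        grid = grid + np.arange(n_grid) * 1e-9  # keep the knots strictly increasing
    else:
        values = _sm_lowess(
            rates,
            mean_cls,
            frac=smoothing_fraction,
            it=robustness_iterations,
            xvals=grid,
        )
        bad = ~np.isfinite(values)
        if bad.all():
            raise ValueError("lowess failed on all evaluation points")
        if bad.any():  # small samples: fill isolated failures from neighbours
            values[bad] = np.interp(grid[bad], grid[~bad], values[~bad])
    return NaturalHistoryCurve(grid=grid, values=values, smoothing_fraction=smoothing_fraction)
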