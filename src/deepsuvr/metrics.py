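"""Evaluation statistics for amyloid quantification methods.

Cross-sectional probes (two-component Gaussian-mixture peak analysis,
R-squared, effect sizes, AUC against visual reads, paired bootstrap
significance) and longitudinal probes (outlier-band fractions, HSIC and
Spearman dependence between amyloid level and rate of change, emergent
amyloid-positivity classification).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture

# --------------------------------------------------------------------- #
# Gaussian-mixture peak analysis


@dataclasses.dataclass(frozen=True)
class GMM2Fit:
    """Two-component Gaussian mixture; the lower-mean component is the
    'first peak', a proxy for the amyloid-negative distribution."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]

    @property
    def first_peak(self) -> int:
        return int(np.argmin(self.means))

    @property
    def first_peak_mean(self) -> float:
        return self.means[self.first_peak]

    @property
    def first_peak_sd(self) -> float:
        return self.sds[self.first_peak]


def fit_gmm2(values: np.ndarray, seed: int = 0, n_restarts: int = 10) -> GMM2Fit:
    """EM fit of a 2-Gaussian mixture, best of seeded k-means++ restarts."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 20:
        raise ValueError(f"need at least 20 values for a 2-component mixture, got {values.size}")
    if np.std(values) == 0:
        raise ValueError("degenerate input: all values identical")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-6,
    ).fit(values[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    return GMM2Fit(means=tuple(means), sds=tuple(sds), weights=tuple(weights))


# --------------------------------------------------------------------- #
# Longitudinal outlier band


@dataclasses.dataclass(frozen=True)
class OutlierBand:
    """Reference range for plausible annual Centiloid change (CL/year)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate band [{self.lower}, {self.upper}]")


def derive_outlier_band(reference_rates: np.ndarray, percentile: float = 90.0) -> OutlierBand:
    """Central interval holding ``percentile`` % of reference rates.

    For the default 90, the band spans the 5th-95th percentiles, i.e.
    5% of the reference mass is excluded in each tail — which is how an
    asymmetric band such as [-5.8, 11.2] CL/yr arises from skewed
    accumulation rates.
    """
    rates = np.asarray(reference_rates, dtype=np.float64)
    if rates.size < 50:
        raise ValueError(f"need at least 50 reference rates, got {rates.size}")
    tail = (100.0 - percentile) / 2.0
    lo, hi = np.percentile(rates, [tail, 100.0 - tail])
    return OutlierBand(lower=float(lo), upper=float(hi))


def outlier_fraction(rates: np.ndarray, band: OutlierBand) -> tuple[float, float]:
    """Percentage of rates below / above the band (negative, positive)."""
    rates = np.asarray(rates, dtype=np.float64)
    if rates.size == 0:
        return 0.0, 0.0
    neg = 100.0 * np.mean(rates < band.lower)
    pos = 100.0 * np.mean(rates > band.upper)
    return float(neg), float(pos)


# --------------------------------------------------------------------- #
# Dependence measures


def _gaussian_gram(x: np.ndarray) -> np.ndarray:
    d2 = (x[:, None] - x[None, :]) ** 2
    off = d2[~np.eye(len(x), dtype=bool)]
    positive = off[off > 0]
    bw2 = np.median(positive) if positive.size else 1.0  # median heuristic
    return np.exp(-d2 / (2.0 * bw2))


def hsic(x: np.ndarray, y: np.ndarray) -> float:
    """Biased empirical Hilbert-Schmidt Independence Criterion.

    Gaussian kernels with median-heuristic bandwidths;
    HSIC = trace(K H L H) / n^2 with H the centring operator.  Zero for
    (empirically) independent inputs, strictly positive under (possibly
    non-monotone) dependence.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("hsic expects matching 1-D samples")
    n = x.size
    if n < 10:
        raise ValueError("hsic needs at least 10 observations")
    K = _gaussian_gram(x)
    L = _gaussian_gram(y)
    H = np.eye(n) - np.ones((n, n)) / n
    return float(np.trace(K @ H @ L @ H) / n**2)


def hsic_permutation_test(
    x: np.ndarray, y: np.ndarray, n_permutations: int = 1000, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """(HSIC, permutation p-value, null distribution) for dependence."""
    rng = np.random.default_rng(seed)
    observed = hsic(x, y)
    y = np.asarray(y, dtype=np.float64)
    null = np.array([hsic(x, rng.permutation(y)) for _ in range(n_permutations)])
    p = float((1 + np.sum(null >= observed)) / (1 + n_permutations))
    return observed, p, null


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    res = stats.spearmanr(x, y)
    return float(res.statistic)


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination as squared Pearson correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("r_squared undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Effect size with pooled standard deviation."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("cohens_d needs at least two observations per group")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("cohens_d undefined: zero pooled variance")
    return float((a.mean() - b.mean()) / pooled)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic, ties counted half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("auc needs both classes present")
    return float(roc_auc_score(labels, scores))


# --------------------------------------------------------------------- #
# Paired bootstrap


@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    mean_diff: float
    ci95: tuple[float, float]
    p_value: float
    n_boot: int


def paired_bootstrap(
    metric_fn,
    method_a_values: np.ndarray,
    method_b_values: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    extra: np.ndarray | None = None,
) -> BootstrapResult:
    """Paired bootstrap comparison of one metric between two methods.

    Units (rows) are resampled with replacement; for each resample the
    metric difference A - B is computed.  The non-parametric p-value is
    the proportion of bootstrap differences whose sign opposes the mean
    difference; the comparison is significant when the 95% CI excludes
    zero.  ``extra`` (e.g. shared labels) is resampled alongside and
    passed as a second argument to ``metric_fn``.
    """
    a = np.asarray(method_a_values, dtype=np.float64)
    b = np.asarray(method_b_values, dtype=np.float64)
    if a.shape[0] != b.shape[0]:
        raise ValueError("paired bootstrap needs matched samples")
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if extra is None:
            diffs[i] = metric_fn(a[idx]) - metric_fn(b[idx])
        else:
            diffs[i] = metric_fn(a[idx], extra[idx]) - metric_fn(b[idx], extra[idx])
    mean_diff = float(diffs.mean())
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    if mean_diff == 0:
        p = 1.0
    else:
        p = float(np.mean(np.sign(diffs) == -np.sign(mean_diff)))
    return BootstrapResult(mean_diff=mean_diff, ci95=(float(lo), float(hi)), p_value=p, n_boot=n_boot)


def peak_stability(
    fits_a: list[GMM2Fit],
    fits_b: list[GMM2Fit],
    statistic: str = "mean",
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Cross-study stability of the amyloid-negative peak.

    Compares, by paired bootstrap over studies, the standard deviation
    across studies of the first-peak means (or SDs) between two
    methods; a negative difference means method A is more stable.
    """
    if len(fits_a) != len(fits_b) or len(fits_a) < 3:
        raise ValueError("need matched per-study fits for at least 3 studies")
    attr = {"mean": "first_peak_mean", "sd": "first_peak_sd"}[statistic]
    a = np.array([getattr(f, attr) for f in fits_a])
    b = np.array([getattr(f, attr) for f in fits_b])
    return paired_bootstrap(lambda v: np.std(v), a, b, n_boot=n_boot, seed=seed)


# --------------------------------------------------------------------- #
# Emergent amyloid positivity


def emergent_classification(
    times_years: np.ndarray,
    cls: np.ndarray,
    threshold: float = 30.0,
    min_followup_years: float = 4.5,
) -> dict:
    """Classify one participant's Centiloid series.

    Requires a baseline below ``threshold`` and at least
    ``min_followup_years`` of follow-up; the participant is 'emergent'
    if any follow-up scan crosses the positivity threshold.  The
    baseline 5-CL bracket within [5, 30) is reported alongside.
    """
    t = np.asarray(times_years, dtype=np.float64)
    c = np.asarray(cls, dtype=np.float64)
    if t.shape != c.shape or t.size < 1:
        raise ValueError("times and Centiloids must match and be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("series must be sorted by time")
    baseline = c[0]
    span = t[-1] - t[0]
    if baseline >= threshold:
        return {"label": "ineligible", "reason": "baseline amyloid-positive", "baseline_cl": float(baseline)}
    if span < min_followup_years:
        return {"label": "ineligible", "reason": "insufficient follow-up", "baseline_cl": float(baseline)}
    emergent = bool(np.any(c[1:] >= threshold))
    bracket = None
    if 5.0 <= baseline < 30.0:
        lo = 5.0 * np.floor(baseline / 5.0)
        bracket = (float(lo), float(lo + 5.0))
    return {
        "label": "emergent" if emergent else "stable_negative",
        "baseline_cl": float(baseline),
        "baseline_bracket": bracket,
        "followup_years": float(span),
    }
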