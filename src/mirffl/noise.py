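"""Flow-cytometry noise statistics.

The coefficient of variation (CV = 100 x SD/mean, sample SD with the n-1
denominator) is the working measure of cell-to-cell variability: unlike
the SD it is expected to *fall* as mean expression rises, so a joint rise
of mean and CV unambiguously signals increased variability.  This module
provides the CV itself, the ratio-based technical-noise bound for
co-regulated channel pairs, peak-channel skew, the analytic (law of total
variance) CV of a mixture, histogram-subtraction unmixing, and a Welch
t-test comparison of replicate CVs between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CVSummary",
    "UnmixCurve",
    "CVComparison",
    "cv",
    "technical_noise_bound",
    "peak_channel_skew",
    "mixture_cv_analytic",
    "unmix_cv_curve",
    "compare_cv",
]


@dataclass(frozen=True)
class CVSummary:
    """Mean, SD and percent CV of a set of per-cell intensities."""

    mean: float
    sd: float
    cv: float  # percent, 100 x sd / mean
    n: int


def cv(values) -> CVSummary:
    """Percent CV of intensities: 100 x sample SD (n-1) / sample mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV requires at least two values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    sd = values.std(ddof=1)
    return CVSummary(float(mean), float(sd), float(100.0 * sd / mean), int(values.size))


def technical_noise_bound(channel_a, channel_b) -> CVSummary:
    """CV of the per-cell ratio of two channels paired per cell.

    For channels reporting an obligate heterodimer (CD8a/CD8b), the shared
    biological signal cancels in the ratio a/b, so its CV is an upper bound
    on the technical noise of the measurement.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must be paired per cell (equal lengths)")
    if np.any(b <= 0):
        raise ValueError("denominator channel must be strictly positive")
    return cv(a / b)


def _log_bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if lo <= 0:
        raise ValueError("log binning requires strictly positive intensities")
    if lo == hi:  # degenerate but non-empty: one point mass
        lo, hi = lo * 0.999, hi * 1.001
    return np.geomspace(lo, hi, n_bins + 1)


def peak_channel_skew(values, n_bins: int = 256, log_binning: bool = True) -> tuple[float, float]:
    """Fractions of events strictly below / above the modal histogram bin.

    The histogram is computed on log-spaced bins by default (cytometer
    channels are log-spaced); events falling in the peak bin itself are
    counted in neither tail.  A right-skewed distribution yields
    fraction_above > fraction_below.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("peak-channel skew requires at least 100 events")
    edges = _log_bin_edges(values, n_bins) if log_binning else np.histogram_bin_edges(values, n_bins)
    counts, _ = np.histogram(values, bins=edges)
    peak = int(np.argmax(counts))
    n = values.size
    return float(counts[:peak].sum() / n), float(counts[peak + 1 :].sum() / n)


def mixture_cv_analytic(components: Sequence[tuple[float, float, float]]) -> float:
    """Percent CV of a mixture from the law of total variance.

    ``components`` is a sequence of (fraction, mean, cv_percent).  With
    grand mean mu = sum f_i mu_i, the mixture variance is
    sum f_i (sigma_i^2 + (mu_i - mu)^2); mixing components of equal CV but
    different means therefore always raises the composite CV above the
    common component CV.
    """
    f = np.array([c[0] for c in components], dtype=float)
    mu = np.array([c[1] for c in components], dtype=float)
    sig = mu * np.array([c[2] for c in components], dtype=float) / 100.0
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    if np.any(mu <= 0):
        raise ValueError("component means must be positive")
    grand = float(f @ mu)
    var = float(f @ (sig**2 + (mu - grand) ** 2))
    return 100.0 * np.sqrt(var) / grand


@dataclass
class UnmixCurve:
    """CV of the remainder after removing a growing reference fraction."""

    fractions: np.ndarray     # fraction of the mixture removed (0-1)
    cv_remainder: np.ndarray  # percent CV at each fraction
    bin_edges: np.ndarray
    n_bins: int

    def fraction_for_reduction(self, delta_cv: float) -> float:
        """Smallest removal fraction lowering the CV by ``delta_cv`` points
        (linear interpolation along the curve; NaN if never reached)."""
        target = self.cv_remainder[0] - delta_cv
        below = np.nonzero(self.cv_remainder <= target)[0]
        if below.size == 0:
            return float("nan")
        j = below[0]
        if j == 0:
            return float(self.fractions[0])
        f0, f1 = self.fractions[j - 1], self.fractions[j]
        c0, c1 = self.cv_remainder[j - 1], self.cv_remainder[j]
        return float(f0 + (c0 - target) / (c0 - c1) * (f1 - f0))


def unmix_cv_curve(
    mixture,
    retaining_reference,
    fraction_grid=None,
    n_bins: int = 256,
) -> UnmixCurve:
    """Computational unmixing: CV after removing a scaled reference density.

    Both samples are histogrammed on shared log-spaced bins spanning the
    pooled range.  For a removal fraction f, the remainder histogram is
    max(H_mix - f N_mix H_ref / N_ref, 0); its CV is computed from the
    mixture's per-bin first and second moments weighted by the remainder
    mass, so at f = 0 the curve reproduces the exact sample CV of the
    mixture.  The curve is truncated with a warning if the remainder mass
    vanishes.
    """
    mixture = np.asarray(mixture, dtype=float)
    reference = np.asarray(retaining_reference, dtype=float)
    if mixture.size == 0 or reference.size == 0:
        raise ValueError("mixture and reference must be non-empty")
    if fraction_grid is None:
        fraction_grid = np.linspace(0.0, 0.3, 31)
    fraction_grid = np.asarray(fraction_grid, dtype=float)
    if np.any(fraction_grid < 0) or np.any(fraction_grid >= 1):
        raise ValueError("removal fractions must lie in [0, 1)")

    pooled = np.concatenate([mixture, reference])
    edges = _log_bin_edges(pooled, n_bins)
    which = np.clip(np.searchsorted(edges, mixture, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=mixture, minlength=n_bins)
    sumsq = np.bincount(which, weights=mixture**2, minlength=n_bins)
    ref_counts, _ = np.histogram(reference, bins=edges)
    ref_density = ref_counts / reference.size

    # per-bin moments of the observed mixture events
    with np.errstate(invalid="ignore"):
        bin_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        bin_m2 = np.where(counts > 0, sumsq / np.maximum(counts, 1), 0.0)

    n_mix = mixture.size
    cvs = []
    kept = []
    for f in fraction_grid:
        if f == 0.0:  # nothing removed: report the exact sample CV
            cvs.append(cv(mixture).cv)
            kept.append(0.0)
            continue
        w = np.maximum(counts - f * n_mix * ref_density, 0.0)
        total = w.sum()
        if total <= 1.0:
            warnings.warn(
                f"unmixing curve truncated at removal fraction {f:.3g}: remainder mass exhausted",
                stacklevel=2,
            )
            break
        m1 = float(w @ bin_mean) / total
        m2 = float(w @ bin_m2) / total
        var = max(m2 - m1**2, 0.0) * total / (total - 1.0)
        cvs.append(100.0 * np.sqrt(var) / m1)
        kept.append(f)
    return UnmixCurve(np.array(kept), np.array(cvs), edges, n_bins)


@dataclass(frozen=True)
class CVComparison:
    """Welch t-test comparison of replicate CVs between two groups."""

    difference: float  # mean CV(a) - mean CV(b), percentage points
    t: float
    p: float
    n_a: int
    n_b: int


def _as_cv_values(group) -> np.ndarray:
    return np.array([g.cv if isinstance(g, CVSummary) else float(g) for g in group])


def compare_cv(group_a, group_b) -> CVComparison:
    """Two-sided Welch (unequal-variance) t-test on per-replicate CVs.

    Groups are sequences of :class:`CVSummary` or bare percent-CV values,
    one entry per biological replicate; at least two replicates per group.
    """
    a, b = _as_cv_values(group_a), _as_cv_values(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two replicate CVs")
    res = stats.ttest_ind(a, b, equal_var=False)
    return CVComparison(float(a.mean() - b.mean()), float(res.statistic), float(res.pvalue), a.size, b.size)
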