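"""Dual-fluorescence (eGFP/mCherry) reporter quantification.

A retroviral construct expresses eGFP upstream of a candidate 3'UTR and
mCherry as an internal control; microRNA activity against the 3'UTR lowers
eGFP relative to mCherry.  Double-positive events are gated, the relative
eGFP level is the slope of an orthogonal (total-least-squares) line fitted
to (mCherry, eGFP), the slope is normalized to the empty vector, and the
control vs microRNA-deficient comparison yields the de-repression ratio.

The orthogonal fit is the principal axis of the 2x2 covariance of
(mCherry, eGFP) through the centroid, minimizing perpendicular distances.
It is performed on linear intensities by default (both channels share
fluorescence-intensity units, so no variance standardization is applied —
note the TLS slope is standardization-dependent); a log-space option fits
the principal axis of the log-intensities instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import EventTable

__all__ = [
    "RegressionFit",
    "NormalizedExpression",
    "gate_double_positive",
    "orthogonal_fit",
    "normalize_to_empty",
    "derepression_ratio",
]


@dataclass(frozen=True)
class RegressionFit:
    """Orthogonal-regression line for eGFP vs mCherry."""

    slope: float            # eGFP change per mCherry (in fit space)
    intercept: float
    n_events: int
    fit_space: str          # "linear" or "log"
    residual_variance: float  # variance perpendicular to the fitted line


@dataclass(frozen=True)
class NormalizedExpression:
    """Relative eGFP expression of a construct: fit slope / empty-vector slope."""

    construct: str
    value: float
    genotype: str = ""


def gate_double_positive(events: EventTable, threshold_gfp: float, threshold_mcherry: float) -> EventTable:
    """Events with both channels strictly above their thresholds (the
    upper-right quadrant of the eGFP/mCherry dot plot)."""
    if threshold_gfp <= 0 or threshold_mcherry <= 0:
        raise ValueError("gate thresholds must be positive")
    mask = (events.data["egfp"] > threshold_gfp) & (events.data["mcherry"] > threshold_mcherry)
    if not mask.any():
        raise ValueError(
            f"empty gate: no events with eGFP > {threshold_gfp} and mCherry > {threshold_mcherry}"
        )
    return EventTable(events.data.loc[mask].reset_index(drop=True), events.channels)


def orthogonal_fit(gfp, mcherry, log_space: bool = False) -> RegressionFit:
    """Total-least-squares line of eGFP on mCherry.

    The slope is the direction of the principal eigenvector of the sample
    covariance of (mCherry, eGFP); swapping the channels inverts the slope
    exactly.  Raises on fewer than 10 events or a channel with (near-)zero
    variance, where the principal axis is degenerate.
    """
    y = np.asarray(gfp, dtype=float)
    x = np.asarray(mcherry, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels must be paired per cell")
    if x.size < 10:
        raise ValueError("orthogonal fit requires at least 10 gated events")
    if log_space:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-space fit requires strictly positive intensities")
        x, y = np.log(x), np.log(y)
    cov = np.cov(x, y)
    scale = max(cov[0, 0], cov[1, 1])
    if scale <= 0 or min(cov[0, 0], cov[1, 1]) < 1e-12 * scale:
        raise ValueError("degenerate covariance: a channel has no variance")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, -1]  # principal axis
    if v[0] == 0:
        raise ValueError("degenerate fit: principal axis is vertical")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return RegressionFit(slope, intercept, int(x.size), "log" if log_space else "linear", float(eigvals[0]))


def normalize_to_empty(fit_construct: RegressionFit, fit_empty: RegressionFit, construct: str = "", genotype: str = "") -> NormalizedExpression:
    """Relative eGFP expression: construct slope over empty-vector slope.

    The empty vector normalizes to exactly 1 against itself, and the ratio
    is invariant to rescaling both channels' units by a common factor.
    """
    if fit_empty.slope <= 0:
        raise ValueError("empty-vector slope must be positive")
    return NormalizedExpression(construct, fit_construct.slope / fit_empty.slope, genotype)


def derepression_ratio(norm_control: NormalizedExpression, norm_deficient: NormalizedExpression) -> float:
    """microRNA-deficient over control normalized expression.

    A ratio > 1 indicates microRNA-dependent repression of the construct in
    control cells (expression rises when microRNAs are removed).
    """
    if norm_control.value <= 0:
        raise ValueError("control normalized expression must be positive")
    return norm_deficient.value / norm_control.value
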