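"""Per-cell copy-number estimation arithmetic and qPCR normalization.

Transcript abundances reported relative to a reference gene (copies per
10^6 copies of the reference) are converted to absolute copies per cell by
anchoring on the reference's known per-cell copy number; microRNA cloning
frequencies are converted the same way by first sizing the total microRNA
pool from an anchor microRNA of known abundance.  qPCR cycle thresholds
are normalized to the geometric average of two housekeeping genes by the
delta-CT method (arithmetic mean of the two reference CTs, which is
exactly the geometric mean of their expression levels).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CopyNumberEstimate",
    "copies_from_reference_ratio",
    "copies_from_cloning_frequency",
    "delta_ct_normalize",
]


@dataclass(frozen=True)
class CopyNumberEstimate:
    """An absolute copies-per-cell estimate (point value or low/high range)."""

    species: str
    copies_low: float
    copies_high: float
    anchor: str = ""

    def __post_init__(self):
        if self.copies_low < 0 or self.copies_high < self.copies_low:
            raise ValueError("copy-number range must satisfy 0 <= low <= high")

    @property
    def copies(self) -> float:
        """Midpoint of the range (equals the point value when low == high)."""
        return 0.5 * (self.copies_low + self.copies_high)


def copies_from_reference_ratio(
    target_per_1e6_ref: float, ref_copies_per_cell: float, round_to_int: bool = False
) -> float:
    """Copies per cell of a target given its abundance per 10^6 reference copies.

    E.g. ~25,000 Cd69 mRNAs per 10^6 B2M at ~215 B2M copies per cell gives
    5.375, i.e. ~6 copies per activated cell when rounded.
    """
    if target_per_1e6_ref < 0 or ref_copies_per_cell < 0:
        raise ValueError("abundance and reference copies must be non-negative")
    copies = target_per_1e6_ref * 1e-6 * ref_copies_per_cell
    return float(round(copies)) if round_to_int else copies


def copies_from_cloning_frequency(
    target_freq_per_1e6: float,
    anchor_freq_per_1e6: float,
    anchor_copies: tuple[float, float],
) -> tuple[float, float]:
    """Copies-per-cell range of a microRNA from cloning frequencies.

    The total microRNA pool per cell is anchor_copies / (anchor frequency
    x 10^-6); the target's copies are that pool times its own frequency
    x 10^-6.  ``anchor_copies`` is a (low, high) range, e.g. 400-800 copies
    of miR-181a per DP thymocyte; the result is the corresponding range.
    """
    if anchor_freq_per_1e6 <= 0:
        raise ValueError("anchor frequency must be positive")
    if target_freq_per_1e6 < 0:
        raise ValueError("target frequency must be non-negative")
    low, high = anchor_copies
    if low < 0 or high < low:
        raise ValueError("anchor copies must satisfy 0 <= low <= high")
    factor = target_freq_per_1e6 / anchor_freq_per_1e6
    return (low * factor, high * factor)


def delta_ct_normalize(ct_target: float, ct_ref_1: float, ct_ref_2: float) -> float:
    """Relative expression 2^-(CT_target - mean(CT_ref1, CT_ref2)).

    Averaging the two reference CTs arithmetically normalizes to the
    geometric mean of the two housekeeping genes' expression (one CT unit
    is one doubling).
    """
    import math

    for ct in (ct_target, ct_ref_1, ct_ref_2):
        if not math.isfinite(ct):
            raise ValueError("CT values must be finite")
    return 2.0 ** -(ct_target - 0.5 * (ct_ref_1 + ct_ref_2))
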