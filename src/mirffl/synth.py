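"""Synthetic flow-cytometry event tables with known ground truth.

Fluorescence intensities are modelled as log-normal (flow distributions
are right-skewed and conventionally displayed on log axes).  A log-normal
with target mean m and percent CV c is parameterized by

    sigma^2 = ln(1 + (c/100)^2),    mu = ln(m) - sigma^2 / 2,

so the distribution's *true* mean and CV equal the specification, not just
the moments of the underlying normal.  Generators cover the inputs the
analysis stages need: single populations, channel pairs sharing a latent
biological signal plus channel-specific technical noise (the CD8a/CD8b
obligate-heterodimer control), labelled mixtures, and dual-fluorescence
(eGFP/mCherry) reporter events with a known underlying slope.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "EventTable",
    "lognormal_params",
    "generate_population",
    "generate_paired_channels",
    "generate_mixture",
    "generate_dual_reporter",
]


@dataclass(frozen=True)
class PopulationSpec:
    """A log-normal single-channel population: n events, target mean and % CV."""

    n: int
    mean: float
    cv: float  # percent

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class EventTable:
    """Per-cell fluorescence intensities over one or more channels.

    ``data`` holds one row per event; ``channels`` names the intensity
    columns (all finite and > 0).  Any further columns are metadata such as
    the generating component label or gate flags.
    """

    data: pd.DataFrame
    channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.channels:
            self.channels = list(self.data.columns)
        for ch in self.channels:
            if ch not in self.data.columns:
                raise ValueError(f"channel {ch!r} missing from data")
            col = self.data[ch].to_numpy()
            if not np.all(np.isfinite(col)) or np.any(col <= 0):
                raise ValueError(f"channel {ch!r} must be finite and > 0")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def values(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, channels: Sequence[str] | None = None) -> "EventTable":
        data = pd.read_csv(path)
        if channels is None:
            channels = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c]) and (data[c] > 0).all()]
        return cls(data, list(channels))

    def write_fcs(self, path: str | Path) -> None:
        """Export to FCS 3.x; requires an optional FCS library (flowkit)."""
        try:
            import flowkit  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("FCS export requires the optional 'flowkit' package") from exc
        sample = flowkit.Sample(self.data[self.channels], sample_id=str(path))  # pragma: no cover
        sample.export(str(path), source="raw")  # pragma: no cover


def lognormal_params(mean: float, cv_percent: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given true mean and percent CV."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv_percent < 0:
        raise ValueError("cv must be non-negative")
    sigma2 = np.log1p((cv_percent / 100.0) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def _lognormal(rng: np.random.Generator, mean: float, cv_percent: float, n: int) -> np.ndarray:
    if cv_percent == 0:
        return np.full(n, mean, dtype=float)
    mu, sigma = lognormal_params(mean, cv_percent)
    return rng.lognormal(mu, sigma, size=n)


def generate_population(spec: PopulationSpec, seed: int) -> EventTable:
    """One log-normal population in channel ``intensity``."""
    rng = np.random.default_rng(seed)
    return EventTable(pd.DataFrame({"intensity": _lognormal(rng, spec.mean, spec.cv, spec.n)}), ["intensity"])


def generate_paired_channels(
    n: int,
    mean_a: float,
    mean_b: float,
    biological_cv: float,
    technical_cv: float,
    seed: int,
) -> EventTable:
    """Two channels reporting one biological signal with independent technical noise.

    Per cell, a shared unit-mean log-normal biological factor (percent CV
    ``biological_cv``) scales both channels; each channel is then multiplied
    by its own unit-mean log-normal technical factor (``technical_cv``).
    Because the factors have mean 1 and are independent, the channel means
    are ``mean_a`` and ``mean_b``.  The per-cell ratio a/b cancels the
    biological factor, leaving purely technical variation — the emulated
    CD8a/CD8b heterodimer control.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("channel means must be positive")
    rng = np.random.default_rng(seed)
    biology = _lognormal(rng, 1.0, biological_cv, n)
    tech_a = _lognormal(rng, 1.0, technical_cv, n)
    tech_b = _lognormal(rng, 1.0, technical_cv, n)
    data = pd.DataFrame({"channel_a": mean_a * biology * tech_a, "channel_b": mean_b * biology * tech_b})
    return EventTable(data, ["channel_a", "channel_b"])


def generate_mixture(
    components: Sequence[tuple[float, PopulationSpec]], n: int, seed: int
) -> EventTable:
    """A labelled mixture of log-normal components.

    ``components`` is a sequence of (fraction, spec) pairs with fractions
    summing to 1; events are allocated multinomially and shuffled, and each
    event keeps its generating ``component`` index.
    """
    fractions = np.array([f for f, _ in components], dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("component fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, fractions)
    values = np.concatenate(
        [_lognormal(rng, spec.mean, spec.cv, k) for k, (_, spec) in zip(counts, components)]
    )
    labels = np.repeat(np.arange(len(components)), counts)
    perm = rng.permutation(n)
    data = pd.DataFrame({"intensity": values[perm], "component": labels[perm]})
    return EventTable(data, ["intensity"])


def generate_dual_reporter(
    n: int,
    true_slope: float,
    mcherry_spec: PopulationSpec,
    residual_cv: float,
    untransduced_fraction: float = 0.0,
    seed: int = 0,
    autofluorescence_mean: float = 5.0,
    autofluorescence_cv: float = 40.0,
) -> EventTable:
    """Dual-fluorescence (eGFP/mCherry) reporter events with known slope.

    Transduced events draw mCherry from ``mcherry_spec`` and set
    eGFP = true_slope x mCherry x (unit-mean log-normal residual with
    percent CV ``residual_cv``).  A Binomial(n, untransduced_fraction)
    number of events instead sit near a low autofluorescence floor in both
    channels, to exercise double-positive gating.  The ``transduced``
    column records the ground truth.
    """
    if true_slope <= 0:
        raise ValueError("true_slope must be positive")
    if not 0 <= untransduced_fraction <= 1:
        raise ValueError("untransduced_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_floor = int(rng.binomial(n, untransduced_fraction))
    n_pos = n - n_floor
    mcherry = _lognormal(rng, mcherry_spec.mean, mcherry_spec.cv, n_pos)
    gfp = true_slope * mcherry * _lognormal(rng, 1.0, residual_cv, n_pos)
    floor_m = _lognormal(rng, autofluorescence_mean, autofluorescence_cv, n_floor)
    floor_g = _lognormal(rng, autofluorescence_mean, autofluorescence_cv, n_floor)
    data = pd.DataFrame(
        {
            "egfp": np.concatenate([gfp, floor_g]),
            "mcherry": np.concatenate([mcherry, floor_m]),
            "transduced": np.concatenate([np.ones(n_pos, bool), np.zeros(n_floor, bool)]),
        }
    )
    data = data.iloc[rng.permutation(n)].reset_index(drop=True)
    return EventTable(data, ["egfp", "mcherry"])
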