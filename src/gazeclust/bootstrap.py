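"""Percentile bootstrap confidence bands by resampling units.

The band decorates a mean curve (log-ratio or proportion-of-gaze) per
condition: units (subjects by default, items by flag) are resampled with
replacement, the per-condition, per-frame mean is recomputed for each
replicate, and the band is the pointwise percentile interval of the
replicate means.  The point estimate is the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import LogRatioSeries
from .design import CONDITIONS


@dataclass
class ConfidenceBand:
    """Pointwise percentile-bootstrap band around a per-condition mean curve."""

    estimate: np.ndarray        # (n_conditions, n_frames)
    lower: np.ndarray
    upper: np.ndarray
    frame_starts_ms: np.ndarray
    level: float
    n_boot: int
    seed: int | None
    unit_kind: str

    def to_frame(self) -> pd.DataFrame:
        C, F = self.estimate.shape
        return pd.DataFrame(
            {
                "condition": pd.Categorical.from_codes(
                    np.repeat(np.arange(C), F), categories=list(CONDITIONS)
                ),
                "frame_index": np.tile(np.arange(F), C),
                "frame_start_ms": np.tile(self.frame_starts_ms, C),
                "estimate": self.estimate.ravel(),
                "lower": self.lower.ravel(),
                "upper": self.upper.ravel(),
            }
        )


def bootstrap_band(unit_series, n_boot: int = 1000, level: float = 0.95,
                   seed=None) -> ConfidenceBand:
    """Percentile bootstrap band from per-unit curves.

    Parameters
    ----------
    unit_series
        A :class:`~gazeclust.aggregate.LogRatioSeries`, or any array of shape
        (n_units, n_conditions, n_frames) of per-unit curves (e.g. per-unit
        gaze proportions).  NaN cells are ignored in means.
    n_boot, level, seed
        Number of replicates (>= 1), coverage level in (0, 1), RNG seed.

    Resampling draws units with replacement; per replicate the per-condition,
    per-frame mean over the drawn units is recorded, and the band is the
    (1 - level)/2 and (1 + level)/2 percentiles of those replicate means.
    Requires at least two units.  Deterministic for a fixed seed.
    """
    if isinstance(unit_series, LogRatioSeries):
        values = unit_series.eta
        frame_starts = unit_series.frame_starts_ms
        unit_kind = unit_series.unit_kind
    else:
        values = np.asarray(unit_series, dtype=float)
        if values.ndim != 3:
            raise ValueError("unit_series array must have shape (n_units, n_conditions, n_frames)")
        frame_starts = np.arange(values.shape[2], dtype=float)
        unit_kind = "unit"
    U = values.shape[0]
    if U < 2:
        raise ValueError("bootstrap requires at least two units")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1); got {level}")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, U, size=(n_boot, U))
    with np.errstate(invalid="ignore"):
        reps = np.nanmean(values[idx], axis=1)      # (n_boot, C, F)
        estimate = np.nanmean(values, axis=0)
        lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        lower = np.nanpercentile(reps, lo_q, axis=0)
        upper = np.nanpercentile(reps, hi_q, axis=0)
    return ConfidenceBand(
        estimate=estimate,
        lower=lower,
        upper=upper,
        frame_starts_ms=np.asarray(frame_starts, dtype=float).copy(),
        level=level,
        n_boot=int(n_boot),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        unit_kind=unit_kind,
    )
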