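"""Synthetic gaze and selection generators.

Gaze is generated as a renewal process of fixations: per trial, fixation
durations are drawn i.i.d. from a gamma law (default mean 250 ms, shape 4)
until the analysis window is covered; at each fixation onset the fixated AOI
is drawn from the condition's preference curve evaluated at that onset, with
the trial's subject and item midpoint shifts applied.  Fixations are then
expanded to the eye-tracker sampling grid, so consecutive samples within a
fixation share an AOI — the run-length autocorrelation real gaze data shows.
Saccade gaps are not modelled; every sample lies in a fixation.

Selections are one multinomial draw per trial from the condition's choice
probabilities.  Both generators are fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import preference_at
from .design import AOI_LABELS, CHOICE_LABELS, CONDITIONS, condition_codes
from .params import SyntheticParams

_N_AOI = len(AOI_LABELS)


def _draw_fixation_durations(rng: np.random.Generator, n_trials: int, window_len: float,
                             mean_ms: float, shape: float) -> np.ndarray:
    """Gamma fixation durations per trial, guaranteed to cover the window.

    Returns an (n_trials, n_fix) array; trailing zero-duration entries may
    pad rows that covered the window early (they never receive samples).
    """
    scale = mean_ms / shape
    n_fix = int(np.ceil(window_len / mean_ms * 2)) + 15
    dur = rng.gamma(shape, scale, size=(n_trials, n_fix))
    while True:
        short = dur.sum(axis=1) < window_len
        if not short.any():
            return dur
        extra = np.where(short[:, None], rng.gamma(shape, scale, size=(n_trials, 8)), 0.0)
        dur = np.concatenate([dur, extra], axis=1)


def generate_gaze(design: pd.DataFrame, params: SyntheticParams, seed=None) -> pd.DataFrame:
    """Simulate a tidy gaze-sample table for every trial in ``design``.

    Parameters
    ----------
    design
        Trial table with columns ``subject``, ``item``, ``condition``
        (see :func:`gazeclust.design.generate_design`).
    params
        Generative specification; ``params.curves`` must cover all three
        conditions.
    seed
        Overrides ``params.seed`` when given.  The same seed yields a
        byte-identical dataset.

    Returns
    -------
    pandas.DataFrame
        One row per gaze sample with columns ``subject``, ``item``,
        ``condition``, ``t_ms`` (time relative to expression offset) and
        ``aoi``; categorical columns use the canonical label orders.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    a, b = params.window_ms
    period = 1000.0 / params.sample_rate_hz
    n_samp = int(round((b - a) / period))
    if n_samp < 1:
        raise ValueError(f"analysis window {params.window_ms} holds no samples at "
                         f"{params.sample_rate_hz} Hz")
    t_rel = np.arange(n_samp) * period

    subj = np.asarray(design["subject"], dtype=np.int64)
    item = np.asarray(design["item"], dtype=np.int64)
    cond = condition_codes(design["condition"])
    n_trials = len(design)
    if n_trials == 0:
        raise ValueError("design is empty")

    # Random effects: rigid time shifts of the curve midpoints.
    subj_ids = np.unique(subj)
    item_ids = np.unique(item)
    s_off = rng.normal(0.0, params.subject_sd_ms, size=subj_ids.size)
    i_off = rng.normal(0.0, params.item_sd_ms, size=item_ids.size)
    shift = (s_off[np.searchsorted(subj_ids, subj)]
             + i_off[np.searchsorted(item_ids, item)])

    dur = _draw_fixation_durations(rng, n_trials, b - a,
                                   params.fixation_mean_ms, params.fixation_shape)
    cum = dur.cumsum(axis=1)
    onset = cum - dur  # fixation onsets, first at window start

    # AOI preference at each fixation onset, per condition curve.
    probs = np.empty(onset.shape + (_N_AOI,), dtype=float)
    for c, label in enumerate(CONDITIONS):
        rows = cond == c
        if rows.any():
            probs[rows] = preference_at(a + onset[rows], params.curves[label],
                                        midpoint_shift_ms=shift[rows, None])
    cdf = probs.cumsum(axis=-1)
    u = rng.random(onset.shape)
    aoi_fix = np.minimum((u[..., None] > cdf).sum(axis=-1), _N_AOI - 1)

    # Expand fixations to the sampling grid.
    aoi_samples = np.empty((n_trials, n_samp), dtype=np.int8)
    for i in range(n_trials):
        idx = np.searchsorted(cum[i], t_rel, side="right")
        aoi_samples[i] = aoi_fix[i, idx]

    return pd.DataFrame(
        {
            "subject": np.repeat(subj, n_samp),
            "item": np.repeat(item, n_samp),
            "condition": pd.Categorical.from_codes(
                np.repeat(cond, n_samp), categories=list(CONDITIONS)
            ),
            "t_ms": np.tile(a + t_rel, n_trials),
            "aoi": pd.Categorical.from_codes(
                aoi_samples.ravel(), categories=list(AOI_LABELS)
            ),
        }
    )


def generate_selections(design: pd.DataFrame, params: SyntheticParams, seed=None) -> pd.DataFrame:
    """Simulate one object selection per test trial.

    Each trial draws once from the condition's selection probabilities over
    (unmentioned, critical, negated).  Deterministic given a seed.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cond = condition_codes(design["condition"])
    p = np.array(
        [[params.selection_probs[c][k] for k in CHOICE_LABELS] for c in CONDITIONS]
    )
    cdf = p.cumsum(axis=1)
    u = rng.random(len(design))
    codes = np.minimum((u[:, None] > cdf[cond]).sum(axis=1), len(CHOICE_LABELS) - 1)
    return pd.DataFrame(
        {
            "subject": np.asarray(design["subject"], dtype=np.int64),
            "item": np.asarray(design["item"], dtype=np.int64),
            "condition": pd.Categorical.from_codes(cond, categories=list(CONDITIONS)),
            "chosen": pd.Categorical.from_codes(codes, categories=list(CHOICE_LABELS)),
        }
    )
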