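"""Per-frame aggregation of gaze samples.

Raw gaze samples are binned into fixed-width frames per trial
(:func:`bin_samples`), pooled into condition-level proportion-of-gaze curves
(:func:`proportion_series`), and reduced to the analysis variable proper:
the per-unit (subject or item) baseline-category log ratio of looks to the
unmentioned versus the critical alternative (:func:`unit_log_ratio`),

    eta = log((c_u + 0.5) / (c_c + 0.5)),

the empirical-logit form of the baseline-category multinomial contrast.  The
+0.5 continuity correction keeps eta finite at zero counts; eta is zero at
equal preference, increasingly positive as looks favour the unmentioned
alternative, negative as they favour the critical one.  Counts are pooled
within unit x condition x frame before the ratio (ratio of sums, not mean of
ratios), which stabilizes sparse frames; ``elsewhere`` samples never enter
eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AOI_LABELS, CONDITIONS, N_CONDITIONS, condition_codes

_N_AOI = len(AOI_LABELS)
_IDX_UNMENTIONED = AOI_LABELS.index("unmentioned")
_IDX_CRITICAL = AOI_LABELS.index("critical")


def empirical_log_ratio(c_u, c_c) -> np.ndarray:
    """log((c_u + 0.5) / (c_c + 0.5)), elementwise."""
    c_u = np.asarray(c_u, dtype=float)
    c_c = np.asarray(c_c, dtype=float)
    if (c_u < 0).any() or (c_c < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log((c_u + 0.5) / (c_c + 0.5))


@dataclass
class BinnedGaze:
    """Per-trial, per-frame AOI sample counts on a shared frame grid."""

    counts: np.ndarray          # (n_trials, n_frames, n_aoi)
    subject: np.ndarray         # (n_trials,)
    item: np.ndarray            # (n_trials,)
    condition: np.ndarray       # (n_trials,) canonical condition codes
    frame_starts_ms: np.ndarray  # (n_frames,)
    bin_width_ms: float

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per trial x frame with per-AOI counts."""
        T, F, _ = self.counts.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(self.subject, F),
                "item": np.repeat(self.item, F),
                "condition": pd.Categorical.from_codes(
                    np.repeat(self.condition, F), categories=list(CONDITIONS)
                ),
                "frame_index": np.tile(np.arange(F), T),
                "frame_start_ms": np.tile(self.frame_starts_ms, T),
            }
        )
        flat = self.counts.reshape(T * F, _N_AOI)
        for j, label in enumerate(AOI_LABELS):
            df[f"n_{label}"] = flat[:, j]
        df["n_samples"] = flat.sum(axis=1)
        return df


def bin_samples(gaze: pd.DataFrame, bin_width_ms: float = 50.0,
                window_ms: tuple[float, float] | None = None) -> BinnedGaze:
    """Bin gaze samples into half-open frames [a + k*w, a + (k+1)*w).

    ``bin_width_ms`` must divide the window length.  When ``window_ms`` is
    omitted it is inferred from the data: start at the earliest sample, end
    one sampling period after the latest.  Every (subject, item) trial must
    appear in exactly one condition.
    """
    if len(gaze) == 0:
        raise ValueError("gaze dataset is empty")
    if not bin_width_ms > 0:
        raise ValueError("bin_width_ms must be positive")
    t = np.asarray(gaze["t_ms"], dtype=float)
    if window_ms is None:
        uniq_t = np.unique(t)
        period = np.diff(uniq_t).min() if uniq_t.size > 1 else bin_width_ms
        window_ms = (float(uniq_t[0]), float(uniq_t[-1] + period))
    a, b = window_ms
    n_frames_f = (b - a) / bin_width_ms
    n_frames = int(round(n_frames_f))
    if n_frames < 1 or abs(n_frames_f - n_frames) > 1e-6:
        raise ValueError(
            f"bin_width_ms={bin_width_ms} does not divide the window length {b - a}"
        )
    frame = np.floor((t - a) / bin_width_ms).astype(np.int64)
    if (frame < 0).any() or (frame >= n_frames).any():
        raise ValueError("gaze samples fall outside the analysis window")

    subj = np.asarray(gaze["subject"], dtype=np.int64)
    item = np.asarray(gaze["item"], dtype=np.int64)
    cond = condition_codes(gaze["condition"])
    aoi = pd.Categorical(gaze["aoi"], categories=list(AOI_LABELS)).codes.astype(np.int64)
    if (aoi < 0).any():
        bad = sorted(set(np.asarray(gaze["aoi"])[aoi < 0]))
        raise ValueError(f"unknown AOI label(s): {bad}; expected one of {AOI_LABELS}")

    key = subj * (item.max() + 1) + item
    trials, first_idx, trial_inv = np.unique(key, return_index=True, return_inverse=True)
    trial_cond = cond[first_idx]
    if (trial_cond[trial_inv] != cond).any():
        raise ValueError("a (subject, item) pair appears in more than one condition")

    T = trials.size
    flat = trial_inv * (n_frames * _N_AOI) + frame * _N_AOI + aoi
    counts = np.bincount(flat, minlength=T * n_frames * _N_AOI).reshape(T, n_frames, _N_AOI)
    return BinnedGaze(
        counts=counts,
        subject=subj[first_idx],
        item=item[first_idx],
        condition=trial_cond,
        frame_starts_ms=a + np.arange(n_frames) * bin_width_ms,
        bin_width_ms=float(bin_width_ms),
    )


def proportion_series(binned: BinnedGaze) -> pd.DataFrame:
    """Condition-level proportion-of-gaze curves, pooled over trials.

    Per condition x frame, counts are pooled across trials and divided by the
    pooled sample total, so the four AOI proportions sum to one.  Returns a
    long table with columns ``condition``, ``aoi``, ``frame_index``,
    ``frame_start_ms``, ``proportion``, ``n_samples``.
    """
    F = binned.n_frames
    pooled = np.zeros((N_CONDITIONS, F, _N_AOI))
    np.add.at(pooled, binned.condition, binned.counts)
    totals = pooled.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(totals > 0, pooled / np.maximum(totals, 1), np.nan)
    rows = []
    for c, cond in enumerate(CONDITIONS):
        for j, label in enumerate(AOI_LABELS):
            rows.append(pd.DataFrame({
                "condition": cond,
                "aoi": label,
                "frame_index": np.arange(F),
                "frame_start_ms": binned.frame_starts_ms,
                "proportion": prop[c, :, j],
                "n_samples": totals[c, :, 0].astype(np.int64),
            }))
    out = pd.concat(rows, ignore_index=True)
    out["condition"] = pd.Categorical(out["condition"], categories=list(CONDITIONS))
    out["aoi"] = pd.Categorical(out["aoi"], categories=list(AOI_LABELS))
    return out


@dataclass
class LogRatioSeries:
    """Per-unit, per-condition, per-frame unmentioned-vs-critical log ratio.

    ``eta`` has shape (n_units, 3, n_frames); cells for which the unit has no
    trials in a condition are NaN (flagged missing, never fabricated).  The
    pooled counts behind each eta are kept alongside.
    """

    eta: np.ndarray                 # (n_units, 3, n_frames)
    count_unmentioned: np.ndarray   # (n_units, 3, n_frames)
    count_critical: np.ndarray      # (n_units, 3, n_frames)
    unit_ids: np.ndarray            # (n_units,)
    unit_kind: str                  # "subject" or "item"
    frame_starts_ms: np.ndarray     # (n_frames,)
    bin_width_ms: float

    @property
    def n_units(self) -> int:
        return self.eta.shape[0]

    @property
    def n_frames(self) -> int:
        return self.eta.shape[2]

    def to_frame(self) -> pd.DataFrame:
        U, _, F = self.eta.shape
        return pd.DataFrame(
            {
                "unit_kind": self.unit_kind,
                "unit": np.repeat(self.unit_ids, N_CONDITIONS * F),
                "condition": pd.Categorical.from_codes(
                    np.tile(np.repeat(np.arange(N_CONDITIONS), F), U),
                    categories=list(CONDITIONS),
                ),
                "frame_index": np.tile(np.arange(F), U * N_CONDITIONS),
                "frame_start_ms": np.tile(self.frame_starts_ms, U * N_CONDITIONS),
                "log_ratio": self.eta.ravel(),
                "n_unmentioned": self.count_unmentioned.ravel(),
                "n_critical": self.count_critical.ravel(),
            }
        )


def unit_log_ratio(binned: BinnedGaze, unit_kind: str = "subject") -> LogRatioSeries:
    """Pool counts per unit x condition x frame and take the empirical logit.

    ``unit_kind`` selects subjects or items as the analysis unit.  Counts of
    looks to the unmentioned and critical alternatives are pooled over the
    unit's trials in each condition before the ratio is taken.
    """
    if unit_kind not in ("subject", "item"):
        raise ValueError(f"unit_kind must be 'subject' or 'item'; got {unit_kind!r}")
    ids = binned.subject if unit_kind == "subject" else binned.item
    unit_ids, uinv = np.unique(ids, return_inverse=True)
    U, F = unit_ids.size, binned.n_frames
    cell = uinv * N_CONDITIONS + binned.condition
    pooled = np.zeros((U * N_CONDITIONS, F, _N_AOI))
    np.add.at(pooled, cell, binned.counts)
    n_trials = np.bincount(cell, minlength=U * N_CONDITIONS).reshape(U, N_CONDITIONS)
    c_u = pooled[:, :, _IDX_UNMENTIONED].reshape(U, N_CONDITIONS, F)
    c_c = pooled[:, :, _IDX_CRITICAL].reshape(U, N_CONDITIONS, F)
    eta = empirical_log_ratio(c_u, c_c)
    eta[n_trials == 0] = np.nan
    return LogRatioSeries(
        eta=eta,
        count_unmentioned=c_u,
        count_critical=c_c,
        unit_ids=unit_ids,
        unit_kind=unit_kind,
        frame_starts_ms=binned.frame_starts_ms.copy(),
        bin_width_ms=binned.bin_width_ms,
    )


def unit_proportion_matrix(binned: BinnedGaze, aoi: str, unit_kind: str = "subject") -> np.ndarray:
    """Per-unit proportion of samples on one AOI, shape (n_units, 3, n_frames).

    Convenience input for bootstrap bands on proportion-of-gaze curves.
    Cells without trials are NaN.
    """
    if aoi not in AOI_LABELS:
        raise ValueError(f"unknown AOI {aoi!r}")
    j = AOI_LABELS.index(aoi)
    ids = binned.subject if unit_kind == "subject" else binned.item
    unit_ids, uinv = np.unique(ids, return_inverse=True)
    U, F = unit_ids.size, binned.n_frames
    cell = uinv * N_CONDITIONS + binned.condition
    pooled = np.zeros((U * N_CONDITIONS, F, _N_AOI))
    np.add.at(pooled, cell, binned.counts)
    totals = pooled.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(totals > 0, pooled[:, :, j] / np.maximum(totals, 1), np.nan)
    return prop.reshape(U, N_CONDITIONS, F)
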