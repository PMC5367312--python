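"""Time-varying gaze-preference curves over areas of interest.

A :class:`PreferenceCurve` gives, for every time point in the analysis
window, a probability vector over the four areas of interest (AOIs) from
which a newly started fixation draws its target.  The curve is a baseline
vector plus an ordered sequence of logistic transitions ("ramps"):

    p(t) = v0 + sum_k sigma((t - m_k) / s_k) * (v_k - v_{k-1})

where v0 is the baseline, v_k the asymptote of ramp k, m_k its midpoint and
s_k its logistic scale.  Because every anchor vector lies on the simplex and
the blend coefficients cancel componentwise, p(t) sums to one at every t;
non-negativity is checked numerically at construction.

A single-ramp curve reduces to the familiar componentwise logistic
interpolation ``base + (asym - base) / (1 + exp(-(t - midpoint)/slope))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import AOI_LABELS, CONDITIONS

_N_AOI = len(AOI_LABELS)


def _as_simplex(v, name: str) -> tuple[float, ...]:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (_N_AOI,):
        raise ValueError(f"{name} must have {_N_AOI} components (one per AOI); got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError(f"{name} must be non-negative; got {arr.tolist()}")
    total = arr.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"{name} must sum to 1; got sum {total}")
    if abs(total - 1.0) > 1e-12:  # keep exact values stable under round-trips
        arr = arr / total
    return tuple(float(x) for x in arr)


@dataclass(frozen=True)
class Ramp:
    """One logistic transition of the AOI preference vector.

    Parameters
    ----------
    asymptote
        Probability vector over AOIs reached after the transition.
    midpoint_ms
        Time of half-transition, in ms relative to expression offset.
    slope_ms
        Logistic scale parameter (ms); larger means a slower transition.
    """

    asymptote: tuple[float, ...]
    midpoint_ms: float
    slope_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "asymptote", _as_simplex(self.asymptote, "asymptote"))
        if not self.slope_ms > 0:
            raise ValueError(f"slope_ms must be positive; got {self.slope_ms}")


@dataclass(frozen=True)
class PreferenceCurve:
    """Baseline AOI preference plus an ordered sequence of logistic ramps."""

    baseline: tuple[float, ...]
    ramps: tuple[Ramp, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline", _as_simplex(self.baseline, "baseline"))
        ramps = tuple(self.ramps)
        object.__setattr__(self, "ramps", ramps)
        mids = [r.midpoint_ms for r in ramps]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError(f"ramp midpoints must be strictly increasing; got {mids}")
        if ramps:
            # Overlapping ramps can drive a component negative; probe a grid.
            lo = min(mids) - 10 * max(r.slope_ms for r in ramps)
            hi = max(mids) + 10 * max(r.slope_ms for r in ramps)
            grid = np.linspace(lo, hi, 201)
            vals = preference_at(grid, self)
            if (vals < -1e-9).any():
                raise ValueError("ramp sequence drives an AOI probability negative")

    def to_dict(self) -> dict:
        return {
            "baseline": list(self.baseline),
            "ramps": [
                {"asymptote": list(r.asymptote), "midpoint_ms": r.midpoint_ms, "slope_ms": r.slope_ms}
                for r in self.ramps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreferenceCurve":
        ramps = tuple(
            Ramp(tuple(r["asymptote"]), float(r["midpoint_ms"]), float(r["slope_ms"]))
            for r in d.get("ramps", ())
        )
        return cls(tuple(d["baseline"]), ramps)


def preference_at(t_ms, curve: PreferenceCurve, midpoint_shift_ms=0.0) -> np.ndarray:
    """Evaluate the AOI preference vector at time(s) ``t_ms``.

    ``midpoint_shift_ms`` shifts every ramp midpoint rigidly in time and may
    be an array broadcastable against ``t_ms`` (used for subject/item random
    effects).  Returns an array with a trailing axis of length 4 (the AOIs);
    each vector is a valid probability vector.
    """
    t = np.asarray(t_ms, dtype=float)
    shift = np.asarray(midpoint_shift_ms, dtype=float)
    shape = np.broadcast_shapes(t.shape, shift.shape)
    out = np.empty(shape + (_N_AOI,), dtype=float)
    out[...] = np.asarray(curve.baseline)
    prev = np.asarray(curve.baseline)
    for ramp in curve.ramps:
        asym = np.asarray(ramp.asymptote)
        z = (t - (ramp.midpoint_ms + shift)) / ramp.slope_ms
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        out += sig[..., None] * (asym - prev)
        prev = asym
    np.clip(out, 0.0, None, out=out)
    return out


# Default condition curves.  Anchors are (negated, unmentioned, critical,
# elsewhere).  All conditions share the baseline; in the two-precedent
# conditions the unmentioned-over-critical preference ramps up with midpoint
# 900 ms ("linguistic" effect), and only OS2P carries a second ramp at
# 1600 ms ("common ground" effect).  OS1P keeps unmentioned = critical
# throughout, so its log ratio stays at zero.  `elsewhere` holds a constant
# 0.1 share.
_BASE = (0.30, 0.30, 0.30, 0.10)
_EQUAL_END = (0.12, 0.39, 0.39, 0.10)
_LING_END = (0.12, 0.52, 0.26, 0.10)
_CG_END = (0.08, 0.72, 0.10, 0.10)

LINGUISTIC_ONSET_MS = 900.0
COMMON_GROUND_ONSET_MS = 1600.0
_SLOPE_MS = 150.0


def default_curves() -> dict[str, PreferenceCurve]:
    """Condition curves encoding the target qualitative pattern.

    An early preference for the unmentioned over the critical alternative in
    both two-precedent conditions (midpoint 900 ms), and a later extra boost
    only when the precedent is in common ground with the live speaker
    (OS2P, midpoint 1600 ms).
    """
    return {
        "OS1P": PreferenceCurve(_BASE, (Ramp(_EQUAL_END, LINGUISTIC_ONSET_MS, _SLOPE_MS),)),
        "OS2P": PreferenceCurve(
            _BASE,
            (
                Ramp(_LING_END, LINGUISTIC_ONSET_MS, _SLOPE_MS),
                Ramp(_CG_END, COMMON_GROUND_ONSET_MS, _SLOPE_MS),
            ),
        ),
        "TS2P": PreferenceCurve(_BASE, (Ramp(_LING_END, LINGUISTIC_ONSET_MS, _SLOPE_MS),)),
    }


def null_curves() -> dict[str, PreferenceCurve]:
    """Identical curves in all conditions: no condition effect anywhere."""
    c = PreferenceCurve(_BASE, (Ramp(_EQUAL_END, LINGUISTIC_ONSET_MS, _SLOPE_MS),))
    return {k: c for k in CONDITIONS}


def constant_curve(p) -> PreferenceCurve:
    """A time-constant preference curve (no ramps)."""
    return PreferenceCurve(tuple(p))
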