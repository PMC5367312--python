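"""Full generative specification for the synthetic experiment.

:class:`SyntheticParams` bundles every knob of the generator: design sizes,
sampling rate and analysis window, the gamma fixation-duration law, the
per-condition AOI preference curves, random-effect spreads, and the
per-condition selection probabilities.  It round-trips to YAML/JSON so a
simulation is fully reproducible from its config block plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .curves import PreferenceCurve, default_curves
from .design import CHOICE_LABELS, CONDITIONS


def default_selection_probs() -> dict[str, dict[str, float]]:
    """Per-condition choice probabilities over the three alternatives.

    Values are the integer choice counts out of 144 trials per condition
    implied by the reference selection rates (their one-decimal percentages
    are 50.0/49.3/0.7, 80.6/16.0/3.5 and 56.2/43.1/0.7).
    """
    return {
        "OS1P": {"unmentioned": 72 / 144, "critical": 71 / 144, "negated": 1 / 144},
        "OS2P": {"unmentioned": 116 / 144, "critical": 23 / 144, "negated": 5 / 144},
        "TS2P": {"unmentioned": 81 / 144, "critical": 62 / 144, "negated": 1 / 144},
    }


@dataclass
class SyntheticParams:
    """Generative specification of the simulated experiment.

    Defaults emulate the study design: 24 subjects, 18 items rotated through
    3 conditions via 3 lists, gaze sampled at 500 Hz over a 0–2500 ms window
    after the offset of the negated expression, gamma fixation durations
    (mean 250 ms, shape 4), normal random shifts of the curve midpoints per
    subject (sd 100 ms) and item (sd 50 ms).
    """

    n_subjects: int = 24
    n_items: int = 18
    n_lists: int = 3
    sample_rate_hz: float = 500.0
    window_ms: tuple[float, float] = (0.0, 2500.0)
    fixation_mean_ms: float = 250.0
    fixation_shape: float = 4.0
    subject_sd_ms: float = 100.0
    item_sd_ms: float = 50.0
    curves: dict[str, PreferenceCurve] = field(default_factory=default_curves)
    selection_probs: dict[str, dict[str, float]] = field(default_factory=default_selection_probs)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_items", "n_lists"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_items % self.n_lists:
            raise ValueError("n_items must be divisible by n_lists")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        a, b = self.window_ms
        if not a < b:
            raise ValueError(f"window_ms start must precede end; got {self.window_ms}")
        self.window_ms = (float(a), float(b))
        if not (self.fixation_mean_ms > 0 and self.fixation_shape > 0):
            raise ValueError("fixation_mean_ms and fixation_shape must be positive")
        if self.subject_sd_ms < 0 or self.item_sd_ms < 0:
            raise ValueError("random-effect sds must be non-negative")
        missing = set(CONDITIONS) - set(self.curves)
        if missing:
            raise ValueError(f"curves missing for condition(s): {sorted(missing)}")
        missing = set(CONDITIONS) - set(self.selection_probs)
        if missing:
            raise ValueError(f"selection_probs missing for condition(s): {sorted(missing)}")
        probs = {}
        for cond in CONDITIONS:
            vec = self.selection_probs[cond]
            if set(vec) != set(CHOICE_LABELS):
                raise ValueError(
                    f"selection_probs[{cond!r}] must have keys {CHOICE_LABELS}; got {sorted(vec)}"
                )
            arr = np.array([vec[k] for k in CHOICE_LABELS], dtype=float)
            if (arr < 0).any():
                raise ValueError(f"selection_probs[{cond!r}] must be non-negative")
            total = arr.sum()
            if not np.isclose(total, 1.0, atol=1e-3):
                raise ValueError(f"selection_probs[{cond!r}] must sum to 1; got {total}")
            arr /= total
            probs[cond] = dict(zip(CHOICE_LABELS, arr.tolist()))
        self.selection_probs = probs

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_items": self.n_items,
            "n_lists": self.n_lists,
            "sample_rate_hz": self.sample_rate_hz,
            "window_ms": list(self.window_ms),
            "fixation_mean_ms": self.fixation_mean_ms,
            "fixation_shape": self.fixation_shape,
            "subject_sd_ms": self.subject_sd_ms,
            "item_sd_ms": self.item_sd_ms,
            "curves": {k: self.curves[k].to_dict() for k in CONDITIONS},
            "selection_probs": {k: dict(self.selection_probs[k]) for k in CONDITIONS},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        if "window_ms" in d:
            d["window_ms"] = tuple(d["window_ms"])
        if "curves" in d:
            d["curves"] = {
                k: v if isinstance(v, PreferenceCurve) else PreferenceCurve.from_dict(v)
                for k, v in d["curves"].items()
            }
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticParams":
        return cls.from_dict(yaml.safe_load(text))

    def with_(self, **kwargs) -> "SyntheticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
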