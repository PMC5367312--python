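"""Experimental design: condition codes, areas of interest, list rotation.

The design emulated throughout the package is a one-factor, three-condition
referential-communication experiment: on each test trial the listener hears a
negated referring expression ("not the jellyfish") and views three
alternatives — the *negated* object, an *unmentioned* object, and a
*critical* object whose naming history defines the condition.  Conditions
differ in who (if anyone) previously named the critical object:

* ``OS1P`` — one speaker, one precedent: the critical object was never named;
* ``OS2P`` — one speaker, two precedents: the live speaker named it;
* ``TS2P`` — two speakers, two precedents: a remote speaker named it.

Items rotate through conditions across three stimulus lists (a Latin square),
so every subject sees every item exactly once and every item occurs in every
condition across lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical condition order.  Contrast weight vectors follow this order.
CONDITIONS = ("OS1P", "OS2P", "TS2P")

#: Areas of interest on the test display.  ``elsewhere`` covers off-object
#: gaze and track loss, so the three object shares need not sum to one.
AOI_LABELS = ("negated", "unmentioned", "critical", "elsewhere")

#: Alternatives a listener can click on in a test trial.
CHOICE_LABELS = ("unmentioned", "critical", "negated")

N_CONDITIONS = len(CONDITIONS)


def condition_codes(values) -> np.ndarray:
    """Map condition labels to canonical integer codes, rejecting unknowns."""
    codes = pd.Categorical(values, categories=list(CONDITIONS)).codes
    if (codes < 0).any():
        bad = sorted(set(np.asarray(values)[codes < 0]))
        raise ValueError(f"unknown condition label(s): {bad}; expected one of {CONDITIONS}")
    return codes.astype(np.int64)


def generate_design(n_subjects: int = 24, n_items: int = 18, n_lists: int = 3) -> pd.DataFrame:
    """Latin-square rotation of items through conditions across lists.

    Subjects are assigned to lists round-robin.  Each subject sees every item
    exactly once; within a subject, items split equally across the three
    conditions; across the three lists, each item appears in all three
    conditions.

    Parameters
    ----------
    n_subjects, n_items, n_lists
        Design sizes.  ``n_items`` must be divisible by ``n_lists`` and
        ``n_lists`` must equal the number of conditions (3).

    Returns
    -------
    pandas.DataFrame
        Tidy trial table with columns ``subject``, ``item``, ``condition``
        (categorical over the canonical condition order) and ``list``.
    """
    if n_lists != N_CONDITIONS:
        raise ValueError(
            f"n_lists must equal the number of conditions ({N_CONDITIONS}); got {n_lists}"
        )
    if n_subjects < 1 or n_items < 1:
        raise ValueError("n_subjects and n_items must be positive")
    if n_items % n_lists:
        raise ValueError(
            f"n_items must be divisible by n_lists so each subject sees an equal number "
            f"of items per condition; got n_items={n_items}, n_lists={n_lists}"
        )
    subjects = np.repeat(np.arange(n_subjects, dtype=np.int64), n_items)
    items = np.tile(np.arange(n_items, dtype=np.int64), n_subjects)
    lists = subjects % n_lists
    cond = (items + lists) % N_CONDITIONS
    return pd.DataFrame(
        {
            "subject": subjects,
            "item": items,
            "condition": pd.Categorical.from_codes(cond, categories=list(CONDITIONS)),
            "list": lists,
        }
    )
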