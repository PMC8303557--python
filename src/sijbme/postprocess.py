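"""Contextual correction of slice predictions and subject-level diagnosis.

Slices of one exam are spatially ordered (lower -> upper pelvis), so isolated
positive or negative slice decisions inside an otherwise consistent run are
likely classifier errors.  A 1-D median filter over the per-subject decision
vector removes them; the filtered vector is then reduced to a single
active-sacroiliitis diagnosis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import median_filter

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclasses.dataclass
class PredictionSequence:
    """Ordered per-slice results for one subject."""

    subject_id: str
    decisions: np.ndarray  # binary, slice order lower -> upper pelvis
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.decisions = np.asarray(self.decisions, dtype=int)
        if self.decisions.ndim != 1 or self.decisions.size == 0:
            raise ValueError("decisions must be a non-empty 1-D vector")
        if not np.isin(self.decisions, (0, 1)).all():
            raise ValueError("decisions must be binary")


def median_filter_1d(seq, size: int = 3) -> np.ndarray:
    """Sliding-window median with replicate padding at both ends.

    Replicate (edge) padding is used so that a genuine run of positives
    touching either end of the stack is never eroded by the boundary.
    """
    seq = np.asarray(seq)
    if seq.ndim != 1 or seq.size == 0:
        raise ValueError("sequence must be non-empty and 1-D")
    if size < 1 or size % 2 == 0:
        raise ValueError("filter size must be an odd integer >= 1")
    return median_filter(seq, size=size, mode="nearest")


def asas_label(lesion_counts) -> str:
    """Subject ground truth from per-slice lesion counts.

    Positive iff some slice carries >=2 lesions, or two consecutive slices
    each carry >=1 lesion (the ASAS active-sacroiliitis positivity rule).
    """
    counts = np.asarray(lesion_counts, dtype=int)
    if counts.size and counts.min() < 0:
        raise ValueError("lesion counts must be non-negative")
    if counts.size == 0:
        return NEGATIVE
    if counts.max() >= 2:
        return POSITIVE
    if counts.size >= 2 and np.any((counts[:-1] >= 1) & (counts[1:] >= 1)):
        return POSITIVE
    return NEGATIVE


def subject_decision(filtered_seq, rule: str = "any_positive", tau: float = 0.0) -> str:
    """Final per-subject diagnosis from the (median-filtered) decision vector.

    ``any_positive`` flags the subject if any filtered slice decision is 1;
    under a size-3 filter this is equivalent to requiring two adjacent raw
    positives (a boundary slice counts as its own neighbour under replicate
    padding), mirroring the consecutive-slice clause of the ASAS rule.
    ``mean_threshold`` flags the subject if the mean decision exceeds ``tau``.
    """
    seq = np.asarray(filtered_seq)
    if seq.size == 0:
        raise ValueError("empty prediction sequence")
    if rule == "any_positive":
        return POSITIVE if seq.any() else NEGATIVE
    if rule == "mean_threshold":
        return POSITIVE if seq.mean() > tau else NEGATIVE
    raise ValueError(f"unknown rule {rule!r}")
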