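"""Splicing dynamics over differentiation or embryogenesis time courses.

For an ordered PSI series (stem-cell differentiation days, or zebrafish
hours post fertilisation) the module reports:

* ``net_shift`` — psi(last) - psi(first), in percentage points.  The switch
  statistic is the *net* first-to-last change (shifts occur in one
  direction), not the range; the range is reported alongside as a
  diagnostic.
* ``pivot_interval`` — the pair of consecutive time points maximising the
  absolute PSI change, i.e. where splicing pivots from one isoform to the
  other.
* ``onset_time`` — first time the (brain-isoform-oriented) PSI exceeds a
  detection threshold, mirroring the first appearance of the brain-specific
  transcript in a gel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .screen import DEFAULT_SWITCH_THRESHOLD

__all__ = ["TimeCourse", "DynamicsResult", "timecourse_stats", "onset_time"]

logger = logging.getLogger(__name__)

DEFAULT_ONSET_THRESHOLD = 10.0


@dataclass(frozen=True)
class TimeCourse:
    """An ordered PSI series for one splice event."""

    ase_id: str
    times: tuple[float, ...]
    psi: tuple[Optional[float], ...]  # percent; None = missing/QC-failed

    def __post_init__(self) -> None:
        if len(self.times) != len(self.psi):
            raise ValueError(f"{self.ase_id}: times and psi lengths differ")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError(f"{self.ase_id}: times must be strictly increasing")
        for v in self.psi:
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{self.ase_id}: PSI {v} outside [0, 100]")

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.psi)


@dataclass(frozen=True)
class DynamicsResult:
    ase_id: str
    net_shift: float  # psi(last) - psi(first), percentage points
    range: float  # max - min over the series
    is_switch: bool
    direction: int
    pivot_interval: tuple[float, float]  # consecutive observed times


def timecourse_stats(
    tc: TimeCourse, threshold: float = DEFAULT_SWITCH_THRESHOLD
) -> DynamicsResult:
    """Net shift, range, switch verdict and pivot interval for one series.

    ``is_switch`` iff |net_shift| strictly exceeds the threshold (default 50
    points) — the event pivots from predominantly one isoform to the other
    over the course.  The pivot interval is the consecutive-time pair with
    the largest |delta psi| (earliest such pair on exact ties).  Incomplete
    series are rejected; callers exclude them with a logged reason.
    """
    if not tc.complete:
        logger.info("dynamics: %s excluded (missing PSI at some time points)", tc.ase_id)
        raise ValueError(f"{tc.ase_id}: incomplete time course")
    if len(tc.times) < 2:
        raise ValueError(f"{tc.ase_id}: need at least 2 time points")
    psi = np.asarray(tc.psi, dtype=float)
    net = float(psi[-1] - psi[0])
    rng = float(psi.max() - psi.min())
    deltas = np.abs(np.diff(psi))
    i = int(np.argmax(deltas))  # argmax takes the first maximum: earliest pivot
    return DynamicsResult(
        ase_id=tc.ase_id,
        net_shift=net,
        range=rng,
        is_switch=abs(net) > threshold,
        direction=int(np.sign(net)),
        pivot_interval=(tc.times[i], tc.times[i + 1]),
    )


def onset_time(
    tc: TimeCourse,
    detect: float = DEFAULT_ONSET_THRESHOLD,
    brain_form_is_long: Optional[bool] = True,
) -> Optional[float]:
    """Earliest time the brain-specific isoform's PSI exceeds ``detect``.

    PSI must be oriented so the brain-specific form is the long product
    (``brain_form_is_long=True``); pass ``False`` to flip (100 - psi), or
    ``None`` if the orientation is unknown — which is an error, because the
    onset of the wrong isoform is meaningless.
    """
    if brain_form_is_long is None:
        raise ValueError(
            "isoform orientation unknown: set brain_form_is_long=True/False "
            "so onset tracks the brain-specific product"
        )
    if not tc.complete:
        raise ValueError(f"{tc.ase_id}: incomplete time course")
    for t, v in zip(tc.times, tc.psi):
        oriented = v if brain_form_is_long else 100.0 - v
        if oriented > detect:
            return t
    return None
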