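"""Quantification of splice-isoform ratios from capillary-electrophoresis peak tables.

A high-throughput RT-PCR splicing assay amplifies across an alternative
region, producing two products: a *long* form (alternative region included)
and a *short* form (region skipped).  Capillary electrophoresis reports each
PCR product as a peak with a fragment size (nt) and a mass signal.  Because
mass scales with fragment length, isoforms are compared on the *molar* scale:

    molarity = mass concentration / fragment length (nt)

    PSI (percent spliced in) = 100 * molar(long) / (molar(long) + molar(short))

Lane quality is gated on *purity*: the fraction of total peak molarity found
at the two expected product sizes.  Lanes with purity <= 0.75 are discarded
(strictly greater than 75% is required to pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

__all__ = [
    "AseAssay",
    "PeakRecord",
    "QuantResult",
    "PeakAssignment",
    "peak_molarity",
    "match_peaks",
    "compute_purity",
    "compute_psi",
    "quantify_assay",
    "DEFAULT_PURITY_THRESHOLD",
]

DEFAULT_PURITY_THRESHOLD = 0.75

EVENT_TYPES = ("cassette", "alt5", "alt3", "complex")


@dataclass(frozen=True)
class AseAssay:
    """One alternative splicing event's PCR assay definition."""

    ase_id: str
    gene: str
    species: str
    event_type: str
    size_short_nt: int
    size_long_nt: int
    primers: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.size_short_nt <= 0 or self.size_long_nt <= 0:
            raise ValueError(
                f"{self.ase_id}: amplicon sizes must be positive, got "
                f"short={self.size_short_nt}, long={self.size_long_nt}"
            )
        if self.size_long_nt <= self.size_short_nt:
            raise ValueError(
                f"{self.ase_id}: long product ({self.size_long_nt} nt) must exceed "
                f"short product ({self.size_short_nt} nt)"
            )
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"{self.ase_id}: unknown event type {self.event_type!r}; "
                f"expected one of {EVENT_TYPES}"
            )

    @property
    def alt_region_nt(self) -> int:
        """Length of the alternative region (long minus short product)."""
        return self.size_long_nt - self.size_short_nt


@dataclass(frozen=True)
class PeakRecord:
    """A sized, quantified electropherogram peak (fragment size in nt, mass conc)."""

    size_nt: float
    conc: float

    def __post_init__(self) -> None:
        if self.size_nt <= 0:
            raise ValueError(f"peak size must be positive, got {self.size_nt}")
        if self.conc < 0:
            raise ValueError(f"peak concentration must be >= 0, got {self.conc}")


@dataclass
class PeakAssignment:
    """Result of matching observed peaks to the two expected product sizes.

    ``short`` / ``long`` hold the index (into the input peak list) of the peak
    matched to each expected size, or ``None`` when no peak fell inside the
    size-tolerance window.  Every other peak index is in ``unmatched``.
    """

    short: Optional[int]
    long: Optional[int]
    unmatched: list[int] = field(default_factory=list)

    @property
    def matched(self) -> list[int]:
        return [i for i in (self.short, self.long) if i is not None]


def peak_molarity(peak: PeakRecord) -> float:
    """Molar amount of a peak: mass concentration divided by fragment length.

    dsDNA mass per molecule is proportional to length, so conc/size is
    proportional to the molar amount; instrument constants cancel in the
    PSI and purity ratios.
    """
    if peak.size_nt <= 0:
        raise ValueError(f"peak size must be positive, got {peak.size_nt}")
    return peak.conc / peak.size_nt


def size_tolerance(expected_nt: float, abs_nt: float = 2.0, rel: float = 0.03) -> float:
    """Matching window for an expected product size: max(2 nt, 3% of expected)."""
    return max(abs_nt, rel * expected_nt)


def match_peaks(
    peaks: Sequence[PeakRecord],
    assay: AseAssay,
    tol_abs_nt: float = 2.0,
    tol_rel: float = 0.03,
) -> PeakAssignment:
    """Assign observed peaks to the expected short/long product sizes.

    A peak matches an expected size when |size - expected| <= max(2 nt, 3% of
    expected).  Each expected size takes at most one peak — the nearest, with
    ties broken toward the smaller observed size — and a peak can serve only
    one expected size (short is matched first).  All remaining peaks are
    unmatched; their molarity counts against purity.
    """
    assignment = PeakAssignment(short=None, long=None)
    taken: set[int] = set()
    for attr, expected in (("short", assay.size_short_nt), ("long", assay.size_long_nt)):
        tol = size_tolerance(expected, tol_abs_nt, tol_rel)
        best: Optional[int] = None
        for i, p in enumerate(peaks):
            if i in taken:
                continue
            if abs(p.size_nt - expected) > tol:
                continue
            if best is None:
                best = i
                continue
            d_new, d_best = abs(p.size_nt - expected), abs(peaks[best].size_nt - expected)
            if d_new < d_best or (d_new == d_best and p.size_nt < peaks[best].size_nt):
                best = i
        if best is not None:
            setattr(assignment, attr, best)
            taken.add(best)
    assignment.unmatched = [i for i in range(len(peaks)) if i not in taken]
    return assignment


def compute_purity(
    assignment: PeakAssignment, peaks: Sequence[PeakRecord]
) -> Optional[float]:
    """Fraction of total peak molarity found at the expected product sizes.

    Returns ``None`` (QC failure) when the lane's total molarity is zero.
    """
    total = sum(peak_molarity(p) for p in peaks)
    if total <= 0:
        return None
    matched = sum(peak_molarity(peaks[i]) for i in assignment.matched)
    return matched / total


def compute_psi(molarity_long: float, molarity_short: float) -> Optional[float]:
    """PSI percent: 100 * long / (long + short); ``None`` when both are zero.

    An undefined PSI (no product at either expected size) is distinct from
    PSI = 0 (only the short form present).
    """
    if molarity_long < 0 or molarity_short < 0:
        raise ValueError("molarities must be >= 0")
    total = molarity_long + molarity_short
    if total == 0:
        return None
    return 100.0 * molarity_long / total


@dataclass
class QuantResult:
    """Per-lane quantification: molarities, purity, PSI, and the QC verdict."""

    ase_id: str
    sample_id: str
    molarity_long: float
    molarity_short: float
    purity: Optional[float]
    psi: Optional[float]
    qc_pass: bool

    def __post_init__(self) -> None:
        defined = self.molarity_long + self.molarity_short > 0
        if defined != (self.psi is not None):
            raise ValueError("psi must be defined iff long+short molarity > 0")


def quantify_assay(
    peaks: Sequence[PeakRecord],
    assay: AseAssay,
    sample_id: str = "",
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    tol_abs_nt: float = 2.0,
    tol_rel: float = 0.03,
) -> QuantResult:
    """Match peaks, convert to molarity, and derive purity, PSI and QC status.

    ``qc_pass`` requires purity strictly greater than ``purity_threshold``
    (default 0.75) *and* a defined PSI.  A lane where only one expected
    product is found still yields PSI 0 or 100 — a fully switched lane is
    valid data provided purity passes.
    """
    if not peaks:
        return QuantResult(assay.ase_id, sample_id, 0.0, 0.0, None, None, False)
    assignment = match_peaks(peaks, assay, tol_abs_nt=tol_abs_nt, tol_rel=tol_rel)
    mol_short = peak_molarity(peaks[assignment.short]) if assignment.short is not None else 0.0
    mol_long = peak_molarity(peaks[assignment.long]) if assignment.long is not None else 0.0
    purity = compute_purity(assignment, peaks)
    psi = compute_psi(mol_long, mol_short)
    qc = purity is not None and purity > purity_threshold and psi is not None
    return QuantResult(assay.ase_id, sample_id, mol_long, mol_short, purity, psi, qc)
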