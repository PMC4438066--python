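"""Switch-like tissue-specific splice event detection and event-type enrichment.

The screen takes an ASE x sample PSI matrix (percent scale), restricts to
events with QC-passing data in every sample, and computes per event the
*shift*: the minimum absolute PSI difference between the reference tissue
(brain) and every comparator tissue.  An event is switch-like when its shift
strictly exceeds the threshold (default 50 percentage points), i.e. the
splicing pattern flips from predominantly one isoform to the other between
brain and *all* other tissues.

Enrichment of an event type (cassette exons) among switch-like hits is
tested with a two-sided Fisher exact test on the 2x2 table
(switch / non-switch) x (cassette / other), with the two-sided p-value
computed by hypergeometric enumeration under the point-probability rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom

__all__ = [
    "PsiMatrix",
    "SwitchCall",
    "EnrichmentResult",
    "qc_filter",
    "compute_shift",
    "classify_switch",
    "screen_matrix",
    "enrichment_test",
    "fisher_exact_2x2",
    "cluster_order",
    "DEFAULT_SWITCH_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_SWITCH_THRESHOLD = 50.0


@dataclass
class PsiMatrix:
    """ASE x sample PSI values (percent) with per-cell QC flags.

    ``values`` is a float DataFrame (rows = ASE ids, columns = sample ids)
    with NaN for missing measurements; ``qc`` is a boolean DataFrame of the
    same shape marking cells that passed the purity gate.  A missing value
    never passes QC.
    """

    values: pd.DataFrame
    qc: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        present = self.values.notna()
        out_of_range = ((self.values < 0) | (self.values > 100)) & present
        if out_of_range.to_numpy().any():
            raise ValueError("PSI values must lie in [0, 100]")
        if self.qc is None:
            self.qc = present
        else:
            self.qc = self.qc.astype(bool) & present
        if not self.qc.index.equals(self.values.index) or not self.qc.columns.equals(
            self.values.columns
        ):
            raise ValueError("qc flags must share the values matrix's index/columns")

    @property
    def ase_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def complete_mask(self) -> pd.Series:
        """True for rows with QC-passing values in every sample."""
        return self.qc.all(axis=1)


@dataclass(frozen=True)
class SwitchCall:
    """Per-event shift statistic and switch verdict against a reference tissue."""

    ase_id: str
    reference_sample: str
    shift: Optional[float]  # percentage points; None when not evaluable
    direction: int  # sign of (psi_ref - mean(others)); 0 when undefined
    is_switch: bool
    complete: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 event-type enrichment among switch hits (Fisher exact)."""

    table: tuple[tuple[int, int], tuple[int, int]]  # [[a, b], [c, d]]
    odds_ratio: Optional[float]
    p_value: float

    @property
    def counts(self) -> dict[str, int]:
        (a, b), (c, d) = self.table
        return {"switch_cassette": a, "switch_other": b,
                "nonswitch_cassette": c, "nonswitch_other": d}


def qc_filter(matrix: PsiMatrix) -> PsiMatrix:
    """Restrict to ASEs whose PSI passed QC in every sample.

    Mirrors the screen's completeness rule: only events with robust data for
    all samples enter any count (numerator or denominator).
    """
    if matrix.values.empty:
        raise ValueError("empty PSI matrix")
    keep = matrix.complete_mask()
    out = PsiMatrix(matrix.values.loc[keep].copy(), matrix.qc.loc[keep].copy())
    logger.info("qc_filter: %d of %d ASEs complete in all %d samples",
                keep.sum(), len(keep), matrix.values.shape[1])
    return out


def compute_shift(
    row: pd.Series, reference: str, others: Sequence[str]
) -> Optional[float]:
    """Shift statistic: min over comparator tissues of |psi_ref - psi_other|.

    The *nearest* comparator governs, so a large shift means the reference
    tissue differs from every other tissue.  Returns ``None`` when the
    reference or any comparator value is missing.
    """
    if not others:
        raise ValueError("need at least one comparator sample")
    ref = row.get(reference)
    vals = [row.get(t) for t in others]
    if ref is None or pd.isna(ref) or any(v is None or pd.isna(v) for v in vals):
        return None
    return float(min(abs(ref - v) for v in vals))


def classify_switch(shift: float, threshold: float = DEFAULT_SWITCH_THRESHOLD) -> bool:
    """Switch-like iff the shift strictly exceeds the threshold (default 50)."""
    if shift is None or pd.isna(shift):
        raise ValueError("shift undefined; exclude the event rather than classify it")
    return shift > threshold


def screen_matrix(
    matrix: PsiMatrix,
    reference: str = "brain",
    threshold: float = DEFAULT_SWITCH_THRESHOLD,
    others: Optional[Sequence[str]] = None,
) -> list[SwitchCall]:
    """Run the switch screen over every row of a PSI matrix.

    Events that are incomplete (any sample missing or QC-failed) get
    ``complete=False``, an undefined shift, and never count as switch —
    they are excluded from both numerator and denominator downstream.
    """
    if reference not in matrix.values.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix columns")
    if others is None:
        others = [c for c in matrix.values.columns if c != reference]
    complete = matrix.complete_mask()
    calls: list[SwitchCall] = []
    for ase_id, row in matrix.values.iterrows():
        if not complete.loc[ase_id]:
            calls.append(SwitchCall(ase_id, reference, None, 0, False, False))
            continue
        shift = compute_shift(row, reference, others)
        diff = row[reference] - np.mean([row[t] for t in others])
        direction = int(np.sign(diff))
        calls.append(
            SwitchCall(ase_id, reference, shift, direction,
                       classify_switch(shift, threshold), True)
        )
    n_switch = sum(c.is_switch for c in calls)
    logger.info("screen: %d switch-like of %d complete ASEs (threshold %g)",
                n_switch, int(complete.sum()), threshold)
    return calls


def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> tuple[Optional[float], float]:
    """Fisher exact test on a 2x2 table by hypergeometric enumeration.

    Conditioning on the margins, the count ``a`` in the top-left cell follows
    a hypergeometric distribution.  The two-sided p-value is the sum of
    probabilities of all tables (with the same margins) whose point
    probability does not exceed the observed table's (point-probability
    rule); one-sided alternatives sum the corresponding tail.

    Returns ``(odds_ratio, p_value)``; the odds ratio ``ad/bc`` is ``None``
    when ``b*c == 0``.  A degenerate margin (an all-zero row or column)
    yields p = 1 and an undefined odds ratio.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return None, 1.0
    odds = (a * d) / (b * c) if b * c > 0 else None

    # conditioned on the margins, a ~ Hypergeom(N=n, K=col1, n=row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - support[0]]
    if alternative == "two-sided":
        # relative slack absorbs floating-point noise in pmf comparisons
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return odds, min(p, 1.0)


def enrichment_test(
    calls: Iterable[SwitchCall],
    assays: pd.DataFrame,
    focal_type: str = "cassette",
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> EnrichmentResult:
    """Test whether switch-like events are enriched in one event type.

    Builds the 2x2 table (switch / non-switch) x (focal type / other) over
    *complete* events only and applies the Fisher exact test.  ``assays``
    must carry ``ase_id`` and ``event_type`` columns.
    """
    types = assays.set_index("ase_id")["event_type"]
    a = b = c = d = 0
    for call in calls:
        if not call.complete:
            continue
        is_focal = types.loc[call.ase_id] == focal_type
        if call.is_switch:
            a, b = a + is_focal, b + (not is_focal)
        else:
            c, d = c + is_focal, d + (not is_focal)
    if a + b == 0 or c + d == 0:
        raise ValueError("need at least one switch and one non-switch event")
    odds, p = fisher_exact_2x2([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(((a, b), (c, d)), odds, p)


def cluster_order(matrix: PsiMatrix, axis: Literal["rows", "columns"] = "rows") -> list[int]:
    """Dendrogram leaf order from average-linkage clustering on PSI vectors.

    Euclidean distance, agglomerative average linkage; the returned list of
    integer positions reorders rows (or columns) for heat-map display.
    Deterministic given the input order (ties resolved by original index).
    Rows with missing values are rejected — run :func:`qc_filter` first.
    """
    data = matrix.values.to_numpy()
    if axis == "columns":
        data = data.T
    if np.isnan(data).any():
        raise ValueError("matrix contains missing values; qc_filter it first")
    if data.shape[0] == 1:
        return [0]
    z = linkage(data, method="average", metric="euclidean")
    return [int(i) for i in leaves_list(z)]
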