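"""Cross-species conservation calls for switch-like splice events.

Per-species switch calls are joined through a one-to-one ortholog map.  An
ortholog group is conserved when every required species contributes a
complete (QC-passing in all tissues) call, every one of those calls is
switch-like, and the direction of the brain shift (which isoform the brain
favours) is identical across species.

``staged_screen`` reproduces the screen's funnel: switch hits in the primary
species -> orthologs found -> complete data in the second species -> switch
vs all of its tissues -> confirmed in the third species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .screen import SwitchCall

__all__ = [
    "OrthologGroup",
    "ConservationCall",
    "validate_ortholog_map",
    "join_orthologs",
    "staged_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologGroup:
    """One ortholog group: species -> ASE id, at most one member per species."""

    group_id: str
    members: Mapping[str, str]  # species -> ase_id


@dataclass(frozen=True)
class ConservationCall:
    """Cross-species consensus for one ortholog group.

    ``all_switch`` and ``direction_consistent`` are ``None`` when the group
    is not evaluable (some required species lacks a complete call).
    """

    group_id: str
    species_evaluated: tuple[str, ...]
    all_switch: Optional[bool]
    direction_consistent: Optional[bool]
    is_conserved: bool


def validate_ortholog_map(
    groups: Sequence[OrthologGroup],
    calls_by_species: Mapping[str, Mapping[str, SwitchCall]],
) -> None:
    """Reject maps where an ASE id appears under two species or twice in one.

    ``calls_by_species`` maps species -> {ase_id -> SwitchCall}; the species
    call tables themselves are keyed, so within-species duplicates are
    checked across the ortholog groups.
    """
    owner: dict[str, str] = {}
    seen_in_species: dict[str, set[str]] = {}
    for g in groups:
        for sp, ase in g.members.items():
            if ase in owner and owner[ase] != sp:
                raise ValueError(
                    f"ase_id {ase!r} listed under both {owner[ase]!r} and {sp!r}"
                )
            owner[ase] = sp
            bucket = seen_in_species.setdefault(sp, set())
            if ase in bucket:
                raise ValueError(f"duplicate ase_id {ase!r} within species {sp!r}")
            bucket.add(ase)
    for ase, sp in owner.items():
        hits = [s for s, tbl in calls_by_species.items() if ase in tbl]
        if len(hits) > 1:
            raise ValueError(
                f"ase_id {ase!r} present in call tables of multiple species: {hits}"
            )


def join_orthologs(
    calls_by_species: Mapping[str, Mapping[str, SwitchCall]],
    groups: Sequence[OrthologGroup],
    required_species: Sequence[str],
) -> list[ConservationCall]:
    """Call conservation per ortholog group.

    A group is evaluable only when every required species contributes a
    *complete* switch call; conservation then requires ``is_switch`` in every
    required species and the same shift direction in all of them.
    """
    validate_ortholog_map(groups, calls_by_species)
    out: list[ConservationCall] = []
    for g in groups:
        evaluated: list[str] = []
        member_calls: list[SwitchCall] = []
        evaluable = True
        for sp in required_species:
            ase = g.members.get(sp)
            call = calls_by_species.get(sp, {}).get(ase) if ase is not None else None
            if call is None or not call.complete:
                evaluable = False
                continue
            evaluated.append(sp)
            member_calls.append(call)
        if not evaluable:
            out.append(ConservationCall(g.group_id, tuple(evaluated), None, None, False))
            continue
        all_switch = all(c.is_switch for c in member_calls)
        directions = {c.direction for c in member_calls}
        direction_consistent = len(directions) == 1 and 0 not in directions
        out.append(
            ConservationCall(
                g.group_id,
                tuple(evaluated),
                all_switch,
                direction_consistent,
                all_switch and direction_consistent,
            )
        )
    logger.info("conservation: %d of %d groups conserved across %s",
                sum(c.is_conserved for c in out), len(groups), list(required_species))
    return out


def staged_screen(
    primary_calls: Mapping[str, SwitchCall],
    secondary_calls: Optional[Mapping[str, SwitchCall]],
    tertiary_calls: Optional[Mapping[str, SwitchCall]],
    groups: Sequence[OrthologGroup],
    species_order: Sequence[str] = ("mouse", "human", "zebrafish"),
) -> dict[str, Optional[int]]:
    """Funnel report across the three screening stages.

    Stages (each count restricted to survivors of the previous stage):

    1. ``primary_switch``    — switch-like hits in the primary species.
    2. ``orthologs_found``   — hits with an ortholog in the secondary species.
    3. ``secondary_complete``— orthologs with complete data in the secondary
                               species' tissues.
    4. ``secondary_switch``  — of those, switch-like vs *all* its tissues.
    5. ``conserved``         — of those, confirmed (switch, same direction)
                               in the tertiary species.

    A missing stage input leaves that stage and everything downstream ``None``
    ("not run").  Counts are monotonically non-increasing along the funnel.
    """
    sp1, sp2, sp3 = species_order
    calls_by_species: dict[str, Mapping[str, SwitchCall]] = {sp1: primary_calls}
    if secondary_calls is not None:
        calls_by_species[sp2] = secondary_calls
    if tertiary_calls is not None:
        calls_by_species[sp3] = tertiary_calls
    validate_ortholog_map(groups, calls_by_species)

    funnel: dict[str, Optional[int]] = {
        "primary_switch": None, "orthologs_found": None,
        "secondary_complete": None, "secondary_switch": None, "conserved": None,
    }
    hits = [g for g in groups
            if sp1 in g.members
            and g.members[sp1] in primary_calls
            and primary_calls[g.members[sp1]].is_switch]
    funnel["primary_switch"] = len(hits)
    if secondary_calls is None:
        return funnel

    with_orth = [g for g in hits if sp2 in g.members]
    funnel["orthologs_found"] = len(with_orth)
    complete2 = [g for g in with_orth
                 if g.members[sp2] in secondary_calls
                 and secondary_calls[g.members[sp2]].complete]
    funnel["secondary_complete"] = len(complete2)
    switch2 = [g for g in complete2 if secondary_calls[g.members[sp2]].is_switch]
    funnel["secondary_switch"] = len(switch2)
    if tertiary_calls is None:
        return funnel

    conserved_calls = join_orthologs(
        calls_by_species, switch2, required_species=list(species_order)
    )
    funnel["conserved"] = sum(c.is_conserved for c in conserved_calls)
    return funnel
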