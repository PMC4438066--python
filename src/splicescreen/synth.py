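"""Synthetic splicing panels with planted ground truth.

Every downstream stage (quantification, switch screen, conservation,
dynamics) is testable without external data by simulating what the study
design produces:

* a multi-species assay panel (expected short/long amplicon sizes, event
  types) with a planted fraction of brain-switch events, a planted subset of
  which is conserved (same switch direction) across all species;
* per-lane capillary-electrophoresis peak tables realising each true PSI as
  two peaks at the expected sizes (mass = molarity x length), optionally
  contaminated by an off-target peak that degrades purity;
* sigmoidal differentiation time courses whose midpoint is planted inside a
  chosen pivot interval.

Planted switch events separate brain from every other tissue by more than 60
PSI points; non-switch events stay within 40 points.  The 10-point guard
bands either side of the 50-point switch threshold make zero-noise recovery
exact and unambiguous.
Observed PSI is the truth plus Gaussian noise, clamped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .quant import AseAssay, PeakRecord
from .screen import PsiMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimPanel",
    "simulate_panel",
    "simulate_peak_tables",
    "simulate_timecourse",
]

# Event-type frequencies of the screened panel: 560 cassette, 100 alt 5',
# 102 alt 3' and 47 complex events of 809, and 78/93 cassette among switch
# hits (cassette exons are enriched among brain switches).
DEFAULT_EVENT_TYPE_PROBS = {
    "cassette": 560 / 809, "alt5": 100 / 809, "alt3": 102 / 809, "complex": 47 / 809,
}
DEFAULT_SWITCH_EVENT_TYPE_PROBS = {
    "cassette": 78 / 93, "alt5": 5 / 93, "alt3": 6 / 93, "complex": 4 / 93,
}

DEFAULT_TISSUES = {
    "mouse": ("brain", "kidney", "liver"),
    "human": ("brain", "kidney", "liver", "lung", "muscle", "heart"),
    "zebrafish": ("brain", "kidney", "liver"),
}

# Guard bands around the 50-point switch threshold: planted switch events
# separate brain from every other tissue by >60 points and non-switch events
# stay within 40, so planted truth is unambiguous under replicate noise.
SWITCH_GAP_MIN = 60.0
NONSWITCH_GAP_MAX = 40.0


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic panel.

    Defaults emulate the screen's design: a three-species panel (mouse and
    zebrafish assayed in brain/kidney/liver, human in six tissues), roughly
    one event in ten switch-like for brain, one switch in ten conserved
    across all species, 5-point replicate PSI noise, and a five-point
    differentiation course (days 0-14) pivoting between days 6 and 10.
    """

    n_ases: int = 500
    species: tuple[str, ...] = ("mouse", "human", "zebrafish")
    tissues_per_species: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    fraction_switch: float = 0.1
    fraction_conserved: float = 0.1
    psi_noise_sd: float = 5.0
    spurious_peak_rate: float = 0.15
    spurious_mass_fraction: float = 0.3
    event_type_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_TYPE_PROBS)
    )
    switch_event_type_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SWITCH_EVENT_TYPE_PROBS)
    )
    size_range_nt: tuple[int, int] = (80, 600)
    timepoints: tuple[float, ...] = (0.0, 2.0, 6.0, 10.0, 14.0)
    pivot_interval: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ases <= 0:
            raise ValueError("n_ases must be positive")
        if not self.species:
            raise ValueError("need at least one species")
        for frac, name in (
            (self.fraction_switch, "fraction_switch"),
            (self.fraction_conserved, "fraction_conserved"),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.psi_noise_sd < 0:
            raise ValueError("psi_noise_sd must be >= 0")
        if not 0 <= self.spurious_peak_rate < 1:
            raise ValueError("spurious_peak_rate must be in [0, 1)")
        if not 0 <= self.spurious_mass_fraction < 1:
            raise ValueError("spurious_mass_fraction must be in [0, 1)")
        for probs, name in (
            (self.event_type_probs, "event_type_probs"),
            (self.switch_event_type_probs, "switch_event_type_probs"),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        lo, hi = self.size_range_nt
        if lo >= hi or lo <= 0:
            raise ValueError("size_range_nt must satisfy 0 < min < max")
        for sp in self.species:
            tissues = self.tissues_per_species.get(sp)
            if not tissues:
                raise ValueError(f"no tissues configured for species {sp!r}")
        if len(self.timepoints) >= 2:
            t_lo, t_hi = self.pivot_interval
            if not (self.timepoints[0] <= t_lo < t_hi <= self.timepoints[-1]):
                raise ValueError("pivot_interval must lie within the timepoint span")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("species", "timepoints", "pivot_interval", "size_range_nt"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "tissues_per_species" in raw:
            raw["tissues_per_species"] = {
                k: tuple(v) for k, v in raw["tissues_per_species"].items()
            }
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted truth for a simulated panel.

    ``psi_true`` maps species -> DataFrame of true PSI percent (ASE x tissue);
    ``is_switch``/``is_conserved``/``switch_direction`` are indexed by ortholog
    group id; per-species switch status lives in ``is_switch_by_species``.
    ``lane_contamination`` (filled by :func:`simulate_peak_tables`) records the
    planted molar contamination fraction per (species, ase_id, sample).
    """

    group_ids: list[str]
    psi_true: dict[str, pd.DataFrame]
    is_switch: pd.Series
    is_conserved: pd.Series
    switch_direction: pd.Series
    is_switch_by_species: pd.DataFrame  # group x species
    lane_contamination: dict[tuple[str, str, str], float] = field(default_factory=dict)
    pivot_time: Optional[pd.Series] = None  # planted logistic midpoints


@dataclass
class SimPanel:
    """Bundle returned by :func:`simulate_panel`."""

    assays: pd.DataFrame  # one row per (species, ase)
    psi: dict[str, PsiMatrix]  # observed (noisy) PSI per species
    orthologs: pd.DataFrame  # group_id, species, ase_id
    truth: GroundTruth
    config: SimConfig


def _draw_event_types(rng: np.random.Generator, probs: Mapping[str, float], n: int):
    names = list(probs)
    return rng.choice(names, size=n, p=[probs[k] for k in names])


def _plant_switch_row(
    rng: np.random.Generator, n_tissues: int, direction: int
) -> np.ndarray:
    """True PSI for a switch event: brain separated >50 points from all others."""
    if direction > 0:  # brain favours the long form
        brain = rng.uniform(70, 100)
        others = rng.uniform(0, brain - SWITCH_GAP_MIN, size=n_tissues - 1)
    else:
        brain = rng.uniform(0, 30)
        others = rng.uniform(brain + SWITCH_GAP_MIN, 100, size=n_tissues - 1)
    return np.concatenate([[brain], others])


def _plant_nonswitch_row(rng: np.random.Generator, n_tissues: int) -> np.ndarray:
    """True PSI for a non-switch event: every tissue within 40 points of brain."""
    brain = rng.uniform(0, 100)
    offsets = rng.uniform(-NONSWITCH_GAP_MAX, NONSWITCH_GAP_MAX, size=n_tissues - 1)
    others = np.clip(brain + offsets, 0, 100)  # clipping only shrinks the gap
    return np.concatenate([[brain], others])


def simulate_panel(config: SimConfig) -> SimPanel:
    """Generate a multi-species assay panel, noisy PSI matrices and truth.

    Exactly ``round(n_ases * fraction_switch)`` ortholog groups are planted
    switch-like in the primary species; ``round(n_switch *
    fraction_conserved)`` of those are switch-like with the same direction in
    *every* species.  Non-conserved switch events are switch only in the
    primary species.  Observed PSI = clamp(true + N(0, psi_noise_sd), 0, 100).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ases
    n_switch = round(n * config.fraction_switch)
    n_conserved = round(n_switch * config.fraction_conserved)

    group_ids = [f"OG{i:05d}" for i in range(n)]
    switch_idx = rng.choice(n, size=n_switch, replace=False)
    is_switch = np.zeros(n, dtype=bool)
    is_switch[switch_idx] = True
    conserved_idx = rng.choice(switch_idx, size=n_conserved, replace=False)
    is_conserved = np.zeros(n, dtype=bool)
    is_conserved[conserved_idx] = True
    direction = np.where(rng.random(n) < 0.5, 1, -1)

    event_types = np.empty(n, dtype=object)
    event_types[~is_switch] = _draw_event_types(
        rng, config.event_type_probs, int((~is_switch).sum())
    )
    event_types[is_switch] = _draw_event_types(
        rng, config.switch_event_type_probs, int(is_switch.sum())
    )

    lo, hi = config.size_range_nt
    short_sizes = rng.integers(lo, max(lo + 1, hi - 30), size=n)
    alt_lens = rng.integers(24, 251, size=n)
    long_sizes = np.minimum(short_sizes + alt_lens, hi + 250)

    assay_rows = []
    ortholog_rows = []
    psi_true: dict[str, pd.DataFrame] = {}
    psi_obs: dict[str, PsiMatrix] = {}
    switch_by_species = pd.DataFrame(
        False, index=group_ids, columns=list(config.species)
    )
    primary = config.species[0]

    for sp in config.species:
        tissues = tuple(config.tissues_per_species[sp])
        ase_ids = [f"{gid}.{sp}" for gid in group_ids]
        truth = np.empty((n, len(tissues)))
        for i in range(n):
            sp_is_switch = is_switch[i] if sp == primary else is_conserved[i]
            if sp_is_switch:
                truth[i] = _plant_switch_row(rng, len(tissues), direction[i])
                switch_by_species.iloc[i, switch_by_species.columns.get_loc(sp)] = True
            else:
                truth[i] = _plant_nonswitch_row(rng, len(tissues))
        true_df = pd.DataFrame(truth, index=ase_ids, columns=list(tissues))
        noise = rng.normal(0.0, config.psi_noise_sd, size=truth.shape) \
            if config.psi_noise_sd > 0 else 0.0
        obs = np.clip(truth + noise, 0.0, 100.0)
        psi_true[sp] = true_df
        psi_obs[sp] = PsiMatrix(pd.DataFrame(obs, index=ase_ids, columns=list(tissues)))

        for i, (gid, ase) in enumerate(zip(group_ids, ase_ids)):
            assay_rows.append({
                "ase_id": ase, "gene": f"GENE{i:05d}", "species": sp,
                "event_type": event_types[i],
                "size_short_nt": int(short_sizes[i]),
                "size_long_nt": int(long_sizes[i]),
            })
            ortholog_rows.append({"group_id": gid, "species": sp, "ase_id": ase})

    truth_obj = GroundTruth(
        group_ids=group_ids,
        psi_true=psi_true,
        is_switch=pd.Series(is_switch, index=group_ids),
        is_conserved=pd.Series(is_conserved, index=group_ids),
        switch_direction=pd.Series(direction, index=group_ids),
        is_switch_by_species=switch_by_species,
    )
    return SimPanel(
        assays=pd.DataFrame(assay_rows),
        psi=psi_obs,
        orthologs=pd.DataFrame(ortholog_rows),
        truth=truth_obj,
        config=config,
    )


LANE_MOLARITY = 10.0  # arbitrary total molar units split between the two products


def _spurious_size(
    rng: np.random.Generator, assay_short: int, assay_long: int, size_range
) -> float:
    """Off-target peak size, kept >= max(2 nt, 5%) away from both products."""
    lo, hi = size_range
    hi = max(hi, assay_long + 60)
    for _ in range(1000):
        s = round(rng.uniform(lo * 0.5, hi * 1.2), 2)
        if all(abs(s - e) > max(2.0, 0.05 * e) for e in (assay_short, assay_long)):
            return s
    raise RuntimeError("could not place a spurious peak away from expected sizes")


def simulate_peak_tables(
    psi_truth: pd.DataFrame,
    assays: pd.DataFrame,
    config: SimConfig,
    species: str,
    truth: Optional[GroundTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Emit per-lane electropherogram peak tables realising true PSI values.

    For PSI fraction p the two products get molar amounts (p, 1-p) times a
    common lane scale, and each peak's mass is molarity x size.  With
    probability ``spurious_peak_rate`` a lane also receives one off-target
    peak carrying ``spurious_mass_fraction`` of the total lane mass, at a
    size guaranteed not to match either product.  When ``truth`` is given,
    each contaminated lane's molar contamination fraction is recorded so the
    purity gate can be validated against planted truth.

    Returns a long-format DataFrame (ase_id, sample_id, size_nt, conc).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sizes = assays.loc[assays["species"] == species].set_index("ase_id")
    rows = []
    for ase_id, psi_row in psi_truth.iterrows():
        if ase_id not in sizes.index:
            raise ValueError(f"no assay sizes for {ase_id!r}")
        s_short = float(sizes.at[ase_id, "size_short_nt"])
        s_long = float(sizes.at[ase_id, "size_long_nt"])
        for sample, psi in psi_row.items():
            if pd.isna(psi) or not 0 <= psi <= 100:
                raise ValueError(
                    f"{ase_id}/{sample}: PSI {psi} outside [0, 100]"
                )
            p = psi / 100.0
            mol_long, mol_short = p * LANE_MOLARITY, (1 - p) * LANE_MOLARITY
            peaks = []
            if mol_short > 0:
                peaks.append((s_short, mol_short * s_short, mol_short))
            if mol_long > 0:
                peaks.append((s_long, mol_long * s_long, mol_long))
            contamination = 0.0
            if config.spurious_peak_rate > 0 and rng.random() < config.spurious_peak_rate:
                lane_mass = sum(m for _, m, _ in peaks)
                f = config.spurious_mass_fraction
                spur_mass = lane_mass * f / (1 - f)  # = f of the final total mass
                spur_size = _spurious_size(
                    rng, int(s_short), int(s_long), config.size_range_nt
                )
                spur_mol = spur_mass / spur_size
                peaks.append((spur_size, spur_mass, spur_mol))
                total_mol = sum(m for *_, m in peaks)
                contamination = spur_mol / total_mol
            if truth is not None:
                truth.lane_contamination[(species, ase_id, sample)] = contamination
            for size_nt, mass, _ in peaks:
                rows.append({
                    "ase_id": ase_id, "sample_id": sample,
                    "size_nt": size_nt, "conc": mass,
                })
    return pd.DataFrame(rows, columns=["ase_id", "sample_id", "size_nt", "conc"])


def simulate_timecourse(
    config: SimConfig,
    n_switch: int,
    n_flat: int = 0,
    amplitude_range: tuple[float, float] = (60.0, 90.0),
    steepness: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list["TimeCourse"], pd.DataFrame]:
    """Sigmoidal differentiation time courses with planted pivots.

    Switch series follow a logistic curve rescaled so the net first-to-last
    change equals the planted amplitude exactly, with midpoint drawn
    uniformly inside ``config.pivot_interval``; flat series sit at a constant
    baseline.  Gaussian noise (``psi_noise_sd``) is added and clamped to
    [0, 100].  Returns the series plus a truth table (ase_id, is_switch,
    amplitude, pivot_time).  Deterministic given the seed.
    """
    from .dynamics import TimeCourse

    if len(config.timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    t = np.asarray(config.timepoints, dtype=float)
    t_lo, t_hi = config.pivot_interval
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    courses: list[TimeCourse] = []
    truth_rows = []
    for i in range(n_switch + n_flat):
        ase_id = f"TC{i:05d}"
        planted_switch = i < n_switch
        if planted_switch:
            amp = rng.uniform(*amplitude_range) * (1 if rng.random() < 0.5 else -1)
            t0 = rng.uniform(t_lo, t_hi)
            s = 1.0 / (1.0 + np.exp(-steepness * (t - t0)))
            if abs(amp) > 0 and s[-1] > s[0]:
                s = (s - s[0]) / (s[-1] - s[0])  # net change == amp exactly
            base = rng.uniform(5, 95 - abs(amp)) if amp > 0 else rng.uniform(5 + abs(amp), 95)
            series = base + amp * s
        else:
            amp, t0 = 0.0, np.nan
            series = np.full_like(t, rng.uniform(5, 95))
        if config.psi_noise_sd > 0:
            series = series + rng.normal(0, config.psi_noise_sd, size=series.shape)
        series = np.clip(series, 0.0, 100.0)
        courses.append(TimeCourse(ase_id, tuple(t), tuple(float(v) for v in series)))
        truth_rows.append({
            "ase_id": ase_id, "is_switch": planted_switch,
            "amplitude": amp, "pivot_time": t0,
        })
    return courses, pd.DataFrame(truth_rows)
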