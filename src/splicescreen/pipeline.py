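"""End-to-end pipeline: simulate -> quantify -> screen -> conserve -> dynamics.

``run_pipeline`` wires the stages together on a synthetic panel, writing
every stage's table plus a JSON run manifest (seed, thresholds, stage
counts) to the output directory.  It is deterministic: re-running with the
same configuration and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .conservation import staged_screen
from .dynamics import timecourse_stats
from .quant import DEFAULT_PURITY_THRESHOLD, AseAssay, PeakRecord, quantify_assay
from .screen import DEFAULT_SWITCH_THRESHOLD, PsiMatrix, enrichment_test, screen_matrix
from .synth import SimConfig, simulate_panel, simulate_peak_tables, simulate_timecourse

__all__ = ["RunConfig", "run_pipeline", "quantify_peak_table"]

logger = logging.getLogger(__name__)

# Stem-cell panel composition: 13 switch-like of 56 complete courses.
DEFAULT_TC_SWITCH = 13
DEFAULT_TC_FLAT = 43


@dataclass
class RunConfig:
    """Thresholds and bookkeeping shared by all pipeline stages."""

    purity_threshold: float = DEFAULT_PURITY_THRESHOLD
    switch_threshold: float = DEFAULT_SWITCH_THRESHOLD
    match_tol_abs_nt: float = 2.0
    match_tol_rel: float = 0.03
    reference_sample: str = "brain"
    required_species: tuple[str, ...] = ("mouse", "human", "zebrafish")
    time_unit: str = "days"
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.purity_threshold <= 1:
            raise ValueError("purity_threshold must be in [0, 1]")
        if not 0 <= self.switch_threshold <= 100:
            raise ValueError("switch_threshold must be in [0, 100]")


def quantify_peak_table(
    peaks: pd.DataFrame,
    assays: pd.DataFrame,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    tol_abs_nt: float = 2.0,
    tol_rel: float = 0.03,
):
    """Quantify every (ase, sample) lane of a long-format peak table."""
    assay_objs = {
        row.ase_id: AseAssay(
            ase_id=row.ase_id, gene=row.gene, species=row.species,
            event_type=row.event_type,
            size_short_nt=int(row.size_short_nt), size_long_nt=int(row.size_long_nt),
        )
        for row in assays.itertuples()
    }
    results = []
    for (ase_id, sample_id), lane in peaks.groupby(["ase_id", "sample_id"], sort=True):
        if ase_id not in assay_objs:
            raise ValueError(f"peak table references unknown assay {ase_id!r}")
        records = [PeakRecord(r.size_nt, r.conc) for r in lane.itertuples()]
        results.append(
            quantify_assay(records, assay_objs[ase_id], sample_id=str(sample_id),
                           purity_threshold=purity_threshold,
                           tol_abs_nt=tol_abs_nt, tol_rel=tol_rel)
        )
    return results


def run_pipeline(
    sim_config: SimConfig,
    run_config: Optional[RunConfig] = None,
    out_dir: Optional[str] = None,
) -> dict:
    """Run the full synthetic screen and write all stage outputs.

    Stages: simulate the panel; emit and quantify peak tables per species;
    screen each species for brain-switch events; report cassette-exon
    enrichment among the primary species' hits; run the conservation funnel;
    simulate and characterise differentiation time courses.  Returns the run
    manifest (also written as ``manifest.json``).
    """
    rc = run_config or RunConfig(seed=sim_config.seed)
    out = Path(out_dir or rc.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, rc.log_level.upper(), logging.INFO))

    panel = simulate_panel(sim_config)
    sio.write_assays(panel.assays, out / "assays.tsv")
    sio.write_orthologs(panel.orthologs, out / "orthologs.tsv")
    for sp, true_df in panel.truth.psi_true.items():
        sio.write_psi_matrix(PsiMatrix(true_df), out / f"psi_true.{sp}.tsv")

    calls_by_species = {}
    stage_counts: dict[str, int] = {}
    rng = np.random.default_rng(sim_config.seed + 1)
    for sp in sim_config.species:
        observed = panel.psi[sp].values
        peaks = simulate_peak_tables(observed, panel.assays, sim_config,
                                     species=sp, truth=panel.truth, rng=rng)
        sio.write_peaks(peaks, out / f"peaks.{sp}.csv")
        quant = quantify_peak_table(peaks, panel.assays,
                                    purity_threshold=rc.purity_threshold,
                                    tol_abs_nt=rc.match_tol_abs_nt,
                                    tol_rel=rc.match_tol_rel)
        sio.write_quant(quant, out / f"quant.{sp}.tsv")
        matrix = sio.quant_to_psi_matrix(
            quant, samples=list(sim_config.tissues_per_species[sp])
        )
        sio.write_psi_matrix(matrix, out / f"psi.{sp}.tsv")
        calls = screen_matrix(matrix, reference=rc.reference_sample,
                              threshold=rc.switch_threshold)
        sio.write_screen(calls, out / f"screen.{sp}.tsv")
        calls_by_species[sp] = {c.ase_id: c for c in calls}
        stage_counts[f"{sp}_complete"] = sum(c.complete for c in calls)
        stage_counts[f"{sp}_switch"] = sum(c.is_switch for c in calls)

    primary = sim_config.species[0]
    species_assays = panel.assays[panel.assays["species"] == primary]
    enrich = enrichment_test(calls_by_species[primary].values(), species_assays)
    with open(out / "enrich.json", "w") as fh:
        json.dump({"counts": enrich.counts,
                   "odds_ratio": enrich.odds_ratio,
                   "p_value": enrich.p_value}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    groups = sio.read_orthologs(out / "orthologs.tsv")
    order = list(sim_config.species[:3])
    funnel = staged_screen(
        calls_by_species[order[0]],
        calls_by_species.get(order[1]) if len(order) > 1 else None,
        calls_by_species.get(order[2]) if len(order) > 2 else None,
        groups, species_order=tuple(order),
    )
    sio.write_funnel(funnel, out / "funnel.json")

    courses, tc_truth = simulate_timecourse(sim_config, n_switch=DEFAULT_TC_SWITCH,
                                            n_flat=DEFAULT_TC_FLAT)
    sio.write_timecourses(courses, out / "timecourse_psi.tsv")
    dyn = [timecourse_stats(tc, threshold=rc.switch_threshold)
           for tc in courses if tc.complete]
    sio.write_dynamics(dyn, out / "dynamics.tsv")
    stage_counts["timecourse_complete"] = len(dyn)
    stage_counts["timecourse_switch"] = sum(r.is_switch for r in dyn)

    manifest = {
        "seed": sim_config.seed,
        "n_ases": sim_config.n_ases,
        "species": list(sim_config.species),
        "purity_threshold": rc.purity_threshold,
        "switch_threshold": rc.switch_threshold,
        "match_tol_abs_nt": rc.match_tol_abs_nt,
        "match_tol_rel": rc.match_tol_rel,
        "reference_sample": rc.reference_sample,
        "psi_noise_sd": sim_config.psi_noise_sd,
        "spurious_peak_rate": sim_config.spurious_peak_rate,
        "stage_counts": stage_counts,
        "funnel": funnel,
        "enrichment": {"odds_ratio": enrich.odds_ratio, "p_value": enrich.p_value},
        "planted": {
            "n_switch": int(panel.truth.is_switch.sum()),
            "n_conserved": int(panel.truth.is_conserved.sum()),
            "timecourse_switch": int(tc_truth["is_switch"].sum()),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", json.dumps(stage_counts))
    return manifest
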