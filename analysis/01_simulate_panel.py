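#!/usr/bin/env python
"""Simulate the cross-species splicing panel and its raw peak tables.

Generates a 500-event assay panel across mouse (brain/kidney/liver), human
(six tissues) and zebrafish (brain/kidney/liver) with 10% planted
brain-switch events, writes the assay definitions, ortholog map, true and
observed PSI matrices, and the per-lane capillary-electrophoresis peak
tables that stage 02 will quantify.
"""

import argparse
from pathlib import Path

import numpy as np

from splicescreen import io as sio
from splicescreen.screen import PsiMatrix
from splicescreen.synth import SimConfig, simulate_panel, simulate_peak_tables

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    OUT.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(cfg)
    sio.write_assays(panel.assays, OUT / "assays.tsv")
    sio.write_orthologs(panel.orthologs, OUT / "orthologs.tsv")
    truth = panel.truth
    truth_frame = truth.is_switch.to_frame("is_switch")
    truth_frame["is_conserved"] = truth.is_conserved
    truth_frame["switch_direction"] = truth.switch_direction
    truth_frame.index.name = "group_id"
    truth_frame.to_csv(OUT / "truth.tsv", sep="\t")

    rng = np.random.default_rng(cfg.seed + 1)
    for sp in cfg.species:
        sio.write_psi_matrix(PsiMatrix(truth.psi_true[sp]), OUT / f"psi_true.{sp}.tsv")
        peaks = simulate_peak_tables(panel.psi[sp].values, panel.assays, cfg,
                                     species=sp, truth=truth, rng=rng)
        sio.write_peaks(peaks, OUT / f"peaks.{sp}.csv")
        print(f"{sp}: {cfg.n_ases} assays x {len(cfg.tissues_per_species[sp])} "
              f"tissues -> {len(peaks)} peaks")
    print(f"planted: {int(truth.is_switch.sum())} switch events, "
          f"{int(truth.is_conserved.sum())} conserved across all species "
          f"(seed {cfg.seed})")
    print(f"wrote panel to {OUT}")


if __name__ == "__main__":
    main()
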