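#!/usr/bin/env python
"""Join the three species' screens through the ortholog map.

Builds the staged conservation funnel (mouse switch hits -> orthologs ->
human-complete -> human switch vs all five other tissues -> confirmed in
zebrafish with the same direction) and compares the final count with the
planted truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from splicescreen import io as sio
from splicescreen.conservation import staged_screen

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    calls = {
        sp: sio.calls_from_frame(sio.read_screen(OUT / f"screen.{sp}.tsv"))
        for sp in ("mouse", "human", "zebrafish")
    }
    groups = sio.read_orthologs(OUT / "orthologs.tsv")
    funnel = staged_screen(calls["mouse"], calls["human"], calls["zebrafish"],
                           groups, species_order=("mouse", "human", "zebrafish"))
    sio.write_funnel(funnel, OUT / "funnel.json")
    truth = pd.read_csv(OUT / "truth.tsv", sep="\t")
    planted = int(truth["is_conserved"].sum())
    print("conservation funnel:", json.dumps(funnel))
    print(f"final conserved count {funnel['conserved']} "
          f"(planted {planted}; attrition is the purity gate plus PSI noise)")


if __name__ == "__main__":
    main()
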