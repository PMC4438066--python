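# splicescreen

A pipeline for finding **switch-like, brain-specific alternative splicing
events (ASEs)** that are conserved across vertebrates, from high-throughput
RT-PCR capillary-electrophoresis data.  It is written for splicing labs
running panel-scale isoform PCR assays (and for anyone auditing such
screens): it turns raw peak tables into percent-spliced-in values, applies
the molar purity quality gate, screens for tissue-switching exons, joins
screens across species through an ortholog map, and characterises splicing
dynamics over differentiation and embryogenesis time courses.

## The quantities

For one lane (one assay × one sample), with peaks matched to the expected
short/long PCR product sizes and mass converted to molarity
(`molarity = conc / size_nt`):

* **PSI** — `psi = 100 · M_long / (M_long + M_short)`, the percent of
  transcripts including the alternative region.
* **Purity** — matched molarity over total peak molarity; a lane passes QC
  only when purity > 0.75 (strict).
* **Shift** — `min_t |psi_brain − psi_t|` over comparator tissues; an event
  is **switch-like** when shift > 50 points, i.e. splicing flips from
  predominantly one isoform to the other between brain and *every* other
  tissue.
* **Conserved** — switch-like with the same direction in every species of
  an ortholog group.
* **Net shift / pivot** — for a time course, `psi(last) − psi(first)` and
  the consecutive-timepoint interval of largest |Δpsi|.

Cassette-exon enrichment among switch hits is tested with a two-sided
Fisher exact test (hypergeometric enumeration, point-probability rule).

See `docs/methods.md` for the full model, parameter table and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole screen on a synthetic
panel with planted ground truth (500 events × three species, 10 % planted
brain switches, 5-point PSI noise, 15 % of lanes contaminated):

```sh
python analysis/01_simulate_panel.py --seed 1
python analysis/02_quantify_psi.py
python analysis/03_screen_switch_events.py
python analysis/04_conservation_funnel.py
python analysis/05_differentiation_dynamics.py
```

which prints (seed 1):

```
planted: 50 switch events, 5 conserved across all species (seed 1)
mouse: 1366/1500 lanes passed the purity gate; 379/500 ASEs complete in all tissues
human: 2727/3000 lanes passed the purity gate; 279/500 ASEs complete in all tissues
mouse: 379 complete ASEs, 34 switch-like vs brain
cassette enrichment among mouse switch hits: table ((28, 6), (231, 114)),
  odds ratio 2.30, two-sided exact p = 0.081
conservation funnel: {"primary_switch": 34, "orthologs_found": 34,
  "secondary_complete": 22, "secondary_switch": 2, "conserved": 1}
56 complete courses, 13 switch-like (planted 13)
  pivot in days 6-10: 13 events
```

Reading it: the purity gate removes ~9 % of lanes, which compounds to
~25 % of events per three-tissue species (and more in six-tissue human) —
of 50 planted switch events, 34 survive QC and are all correctly called in
mouse; demanding complete, switch-like, direction-consistent data in *all
twelve* lanes of three species funnels 5 planted conserved events down to 1
at these noise settings.  The differentiation panel recovers all 13 planted
switch courses and localises every pivot to the planted day 6–10 window.
Each stage writes its tables under `results/analysis/`.

The same stages are available as a CLI
(`splicescreen simulate|quantify|screen|enrich|conserve|dynamics|run`) and
as library functions (`splicescreen.quantify_assay`,
`splicescreen.screen_matrix`, `splicescreen.staged_screen`, ...).

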