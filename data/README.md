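# data/

Drop-in location for external inputs that cannot be redistributed with the
package.

* `cross_species_splicing_s1.xlsx` — the published supplementary workbook
  of the vertebrate brain-splicing screen (Tab1, the cross-evolutionary
  comparison: assay annotations, mouse brain/kidney/liver PSI, human
  six-tissue PSI, neural stem-cell differentiation PSI, zebrafish product
  sizes).  The original is distributed as a legacy `.xls`; convert it
  (e.g. `libreoffice --convert-to xlsx`) and save it under this name.
  When present, the acceptance test
  `test_published_supplementary_funnel_counts` re-derives the published
  screen funnel from it; when absent that test fails with a pointer to
  this file.

Everything else the pipeline consumes is generated synthetically at run
time (see `analysis/01_simulate_panel.py` and `splicescreen.synth`).
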