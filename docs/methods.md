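# Methods

## The measurement model

High-throughput RT-PCR splicing assays amplify across an alternative region
of a transcript, yielding two products per event: a *long* form containing
the alternative region and a *short* form skipping it.  Capillary
electrophoresis reports each product as a peak with a fragment size (nt) and
a mass signal.  Because a dsDNA fragment's mass is proportional to its
length, isoforms are compared per molecule by converting mass to molarity:

    molarity = conc / size_nt

The instrument's proportionality constants cancel in every ratio the
pipeline reports, so molarity is kept in arbitrary units.

**PSI (percent spliced in)** for one lane is

    psi = 100 · M_long / (M_long + M_short)

where `M_long`, `M_short` are the molarities of the peaks matched to the
expected long and short product sizes.  PSI is undefined (reported `NA`,
never 0) when neither product is found.  A lane showing only one product is
valid, fully switched data (PSI 0 or 100), not a failure.

**Peak matching.**  A peak matches an expected size when
`|size − expected| ≤ max(2 nt, 3 % of expected)`, reflecting typical
capillary sizing accuracy (both constants are configurable).  Each expected
size takes at most one peak — the nearest, ties broken toward the smaller
observed size — and a peak can serve only one expected size (the short
product is matched first).  Everything else is off-target.

**Purity gate.**  Lane purity is the matched fraction of total peak
molarity; a lane passes QC only when purity is *strictly* greater than 0.75.
Zero total molarity makes purity undefined and the lane fails.  Events
missing a QC-passing PSI in any tissue are excluded from every downstream
count, numerator and denominator alike.

## The switch screen

For each event with complete data, the **shift** is the minimum over
comparator tissues of `|psi_brain − psi_tissue|`: the *nearest* tissue
governs, so a large shift means brain differs from every other tissue.  An
event is **switch-like** when its shift strictly exceeds 50 percentage
points.  The strict inequality is applied uniformly (screen, conservation,
dynamics); a shift of exactly 50.0 is not a switch.  The shift's direction
is the sign of `psi_brain − mean(psi_others)`.

**Event-type enrichment** among switch hits uses a two-sided Fisher exact
test on the 2×2 table (switch / non-switch) × (cassette / other), restricted
to complete events.  Conditioned on the margins the top-left count is
hypergeometric; the two-sided p-value sums all fixed-margin tables whose
point probability does not exceed the observed table's (point-probability
rule, with 1e-9 relative slack for floating-point pmf ties).  One-sided
alternatives are available behind a flag.  A degenerate margin returns
p = 1 with an undefined odds ratio; the odds ratio is the sample `ad/bc`,
undefined when `bc = 0`.  No multiple-testing correction is applied across
events — the screen reports a single enrichment test, not per-event
significance.

**Heat-map ordering** is agglomerative clustering (Euclidean distance,
average linkage) on PSI vectors; only the dendrogram leaf order is part of
the tested contract, rendering is optional.  The order is deterministic
given the input row order; rows with missing values must be filtered first.

## Conservation across species

Species are joined through a one-to-one ortholog map (group → at most one
event per species; paralog fan-outs are out of scope).  A group is
*evaluable* only when every required species has a complete call, and
*conserved* when every such call is switch-like **and** the shift direction
agrees across species — the same isoform must be the brain-specific one
everywhere.  Direction consistency is required even though a shift-only rule
would be weaker; conservation of a switch with opposite orientation would
not be the same regulatory event.  The tertiary (zebrafish) stage applies
the same strict 50-point rule as the other species; this is configurable via
the screen threshold.

The staged funnel reports, in order: primary-species switch hits → hits with
an ortholog → orthologs complete in the secondary species → of those,
switch-like vs all its tissues → confirmed in the tertiary species.  Each
count is computed within the survivors of the previous stage, so the funnel
is non-increasing by construction.

## Time-course dynamics

For an ordered PSI series the **net shift** is `psi(last) − psi(first)`.
The switch statistic is deliberately the *net* change, not the range,
because switch-like differentiation shifts proceed in one direction; the
range (`max − min`) is reported alongside as a diagnostic, and
`|net_shift| ≤ range` always.  The **pivot interval** is the pair of
consecutive observed times with the largest `|Δpsi|` (earliest pair on
ties).  **Onset** is the first time the brain-isoform-oriented PSI strictly
exceeds a detection threshold (default 10 points — a proxy for the first
visible gel band; there is no instrument-derived value for this).  The
caller must state the isoform orientation (`brain_form_is_long`); onset of
an unknown isoform is refused rather than guessed.

## The synthetic panel

The generator emulates the study design so every stage can be tested against
planted truth:

| parameter | default | meaning |
|---|---|---|
| `n_ases` | 500 | ortholog groups in the panel |
| `species` / tissues | mouse, human, zebrafish; brain+2 (6 for human) | brain is always the reference (first) tissue |
| `fraction_switch` | 0.10 | planted brain-switch fraction in the primary species (≈ 93/809 in the real screen) |
| `fraction_conserved` | 0.10 | fraction of switch events planted switch-like in *all* species (≈ 9/93) |
| `psi_noise_sd` | 5 points | replicate PSI noise; a free parameter — the replicate error of the assay is not published |
| `spurious_peak_rate` | 0.15 | per-lane probability of one off-target peak |
| `spurious_mass_fraction` | 0.30 | the off-target peak's share of total lane mass |
| `event_type_probs` | 560/100/102/47 of 809 | cassette / alt5 / alt3 / complex frequencies |
| `switch_event_type_probs` | 78/93 cassette | event types among planted switches, so panels exhibit the cassette enrichment the screen detects |
| `timepoints`, `pivot_interval` | days 0,2,6,10,14; (6,10) | differentiation design |

Planted switch events separate brain from every comparator by **more than 60
points**, and non-switch events stay **within 40 points** — symmetric
10-point guard bands around the 50-point threshold.  The bands make
zero-noise recovery exact (no planted event sits on the boundary) and keep
5-point replicate noise from flipping calls in either direction; real panels
have no such gap, which is exactly why the zero-noise recovery tests
certify the *machinery*, not field performance.  Observed PSI is
`clamp(truth + N(0, sd), 0, 100)`; clamping can only shrink a planted gap,
never create one.

Peak tables realise a lane's PSI fraction `p` as molar amounts `(p, 1−p)`
times a common scale, with emitted mass = molarity × size, so
quantification at zero noise and zero contamination round-trips PSI to
1e-9.  Contamination is applied per lane (the purity gate is per-lane):
one off-target peak carrying a fixed fraction of total lane *mass*, placed
at least `max(2 nt, 5 %)` from both expected sizes so it can never be
matched.  Because molarity divides mass by size, the resulting *molar*
contamination varies with the drawn off-target size; the generator records
each lane's molar contamination so tests can verify the gate excludes
exactly the lanes above 25 %.

Time courses use a logistic curve rescaled so the realised net first-to-last
change equals the planted amplitude exactly (amplitude drawn from 60–90
points, either direction; steepness 2 /day), with midpoint uniform in the
pivot interval; flat series are constant baselines.  With the default
five-point grid the consecutive interval containing the planted midpoint
always carries the largest Δpsi at zero noise.

What the generator does **not** emulate: raw fluorescence traces and peak
calling, PCR amplification bias, primer failure modes, correlated noise
between tissues from shared cDNA preparations, and paralog cross-priming.
Passing tests therefore demonstrate correctness of the quantification and
screening logic under the stated noise model, not robustness to these
instrument- and biology-level artefacts.

## Determinism and problem sizes

All randomness flows from one integer seed through
`numpy.random.default_rng`; derived stage seeds are small fixed offsets.
Re-running any stage with the same configuration reproduces byte-identical
tables (PSI is written as percent with one decimal, `NA` for missing, which
defines the format's precision).  The standard analysis uses a 500-event
panel, 20 replicate seeds for noise-degradation summaries, a 200-course
zero-noise panel for pivot validation, and exhaustive Fisher validation over
all 2×2 tables with total ≤ 30 — sizes chosen so the whole analysis runs in
seconds while keeping Monte-Carlo summaries stable to well under the
tolerances asserted.

## Known limitations

* The published two-tissue-comparator (mouse/zebrafish) versus
  five-comparator (human) asymmetry is captured simply by each species'
  tissue list; there is no modelling of tissue-specific assay failure rates.
* The supplementary-workbook reader maps columns by position for the
  cross-evolutionary layout (a–am) only; the legacy binary `.xls` container
  must be converted to `.xlsx` or CSV first.
* The enrichment test treats event types as fixed labels; it does not model
  uncertainty in event-type annotation.
* Onset detection is a threshold crossing on the measured grid; it does not
  interpolate between time points.
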