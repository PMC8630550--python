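# Methods

## The analysis model

A dual-luciferase reporter assay reads two luminescence channels per well
of a 96-well plate: firefly luciferase, whose expression is driven by the
regulatory DNA sequence under study, and renilla luciferase, a
co-transfected internal control on a constitutive promoter. Per-well
technical variation — cell density, transfection efficiency, lysate
volume — multiplies both channels by the same unknown factor, so the
first processing step forms the per-well ratio

    r_w = firefly_w / renilla_w

which cancels that factor exactly. The second step expresses each well
relative to a reference condition (typically an empty-vector control):

    fold_change_w = r_w / mean({ r_v : v in reference wells })

The denominator is the **arithmetic mean of the reference group's
per-well ratios**, matching the convention of averaging the ratio within
each condition group before comparing. Because ratios of log-normal
signals are themselves roughly log-normal, a geometric-mean denominator
is available behind a flag (`geometric=True` / `--geometric-mean`), but
the arithmetic mean is the default and the documented behaviour.

Fold change is computed per well and only then summarized — never on
pre-averaged ratios. Both give identical condition means, but the
per-well form preserves the spread of individual observations, which is
what the dot plots are for. By construction the reference group's mean
fold change is exactly 1 (self-normalization), and rescaling both
channels of every well by any common gain leaves all fold changes
unchanged; both properties are asserted in the test suite at 1e-12
relative tolerance.

### Global versus stratified referencing

With a single factor, one denominator serves the whole table (*global*
mode). With several factors — say vector x drug x cell type — the
natural reading of a faceted fold-change plot is that each drug x cell
stratum is normalized to its *own* control wells. The default is
therefore: stratified whenever the experiment has more than one factor
and the reference is given as a single `factor=level` pair; global
otherwise. Both modes can be forced (`--stratified` / `--global`). A
stratum that contains no reference wells is a hard error naming the
stratum, since silently borrowing another stratum's denominator would be
wrong in exactly the situations where it matters.

### Summary statistics

Per condition: n, mean, sample standard deviation (n-1 denominator),
sem = sd/sqrt(n), median, and a 95% confidence interval of the mean from
the t distribution with n-1 degrees of freedom. The t-interval is a
choice (the underlying convention is unstated in the field's informal
practice); for the typical n = 3 it is deliberately wide. With n = 1 the
dispersion statistics are left unset rather than reported as 0.

## File dialects

* **Plate workbook (XLSX).** Two 8x12 tables — firefly first in
  top-to-bottom reading order, then renilla — each flanked by row labels
  A-H on the left and column headers 1-12 above. Blocks are auto-located
  by scanning for exactly two such labelled numeric regions, so
  instrument metadata rows (protocol names, timestamps) anywhere else on
  the sheet are ignored; detection failure is a hard error and an
  explicit `WorkbookLayout` (sheet + anchor cells) overrides it. Wells
  blank in both channels are skipped with a log entry; a well blank in
  only one channel is an error, because an unpaired reading cannot be
  normalized.
* **Design CSV.** A case-insensitive `well` column plus one column per
  experimental factor, in file order. Comma or semicolon delimited
  (sniffed from the header), UTF-8, `.` decimal mark.
* **Tidy CSV.** One observation per row: well, condition column(s), a
  firefly signal column and optionally the renilla control. Column roles
  resolve as explicit configuration > case-insensitive header match
  (`firefly`; `renilla`/`control`/`reference`; `ratio`/`fold_change`) >
  first-numeric-column fallback for the signal. When no control column
  exists the ratio is the firefly signal itself (identity
  normalization) and outputs are unnormalized ratios.

Merging readings with a design is an inner join on well identity: plate
wells without a design entry are dropped with a logged count (`strict`
policy turns this into an error); design wells without a reading always
error, since a designed-but-unmeasured well signals a wrong file
pairing. All writers are deterministic — identical inputs give
byte-identical files (workbook timestamps are pinned for this).

Condition labels from several factor columns are joined into one
condition key in declared column order with `_` (configurable). A label
containing the separator raises a collision warning rather than an
error.

Negative luminescence values (possible after instrument background
subtraction) are rejected by default and accepted with
`allow_negative`/`--allow-negative`.

## The synthetic-data generator

`simulate.generate_experiment` realizes the noise structure the internal
control exists to fix. For well *w* in condition *c*:

    t_w       ~ LogNormal(0, sigma_t)                      (transfection)
    renilla_w = R * t_w * LogNormal(0, sigma_m)            (control channel)
    firefly_w = R * F(c) * t_w * LogNormal(0, sigma_m)     (reporter channel)

with R the control-channel scale (default 1e5 counts, a typical
luminometer mid-range), F(c) the condition's true fold change,
sigma_t = 0.3 the log-scale transfection spread (30-40% well-to-well
variation, realistic for lipofection), and sigma_m = 0.05 the per-channel
measurement noise (a few percent, instrument-level). Noise is
multiplicative log-normal so counts stay positive. Wells fill the plate
in row-major order, replicates adjacent, one plate per experiment (a
design needing more than 96 wells is an error, not a second plate).

The default experiment mirrors a full-plate promoter screen: three
vectors (empty control, geneA, geneB) x four drug treatments x two cell
types, three replicates each = 72 wells (rows A-F; G-H stay blank, which
also exercises the blank-well path of the workbook parser). True effects
vary per stratum, geneA activating and geneB repressing.

What the generator does *not* emulate: plate-edge and position effects,
luminescence decay over read order, substrate kinetics, channel
cross-talk, or counts discretization. Passing tests therefore show the
arithmetic and plumbing are right under the stated noise model, not that
real instrument quirks are handled beyond the parsing behaviours listed
above.

`write_fixture_bundle` emits the matched workbook / design CSV / tidy
CSV trio plus the ground truth as JSON, so every parser is testable
offline against known answers.

## Numerical and design choices

* Zero renilla would give an infinite ratio: error naming the wells by
  default, droppable with a warning (`drop_zero_control`).
* A zero reference mean ratio is an error (fold change undefined).
* Estimator note: with few reference wells the ratio-to-reference-mean
  estimator has a small positive bias of order var(reference mean); at
  the default noise levels this is ~0.2% and sits well inside the
  Monte-Carlo tolerance the recovery tests use.
* Dot-plot jitter is drawn from a seeded generator (default seed 0,
  `--seed`), so exported figures are reproducible byte-for-byte; jitter
  width is 0.2 of the group spacing. Points use the Okabe-Ito
  colour-blind-safe palette; a dashed guide marks fold change 1 whenever
  a reference was applied. The y axis is labelled "Fold Change" after
  normalization and "firefly/renilla ratio" otherwise.
* Figures export as PNG (raster, at the requested dpi) or PDF (vector,
  with creation dates suppressed for reproducibility).

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 50 seeded 72-well fixtures for the file round-trips, 1000
simulations of a 4-condition x 3-replicate design (truths 0.5/1/2/5,
sigma_t = 0.3, sigma_m = 0.05) for parameter recovery, 500 paired
simulations for the transfection-noise-cancellation property, and one
noiseless 72-well bundle pushed through the CLI end to end. One optional
test validates parsing of the archived example dataset
(Zenodo record 5554885) when it has been downloaded into
`data/external/`; it is the only check that touches external data.

## Known limitations

Single-plate experiments only; no batch modelling across plates, no
edge-effect correction, no hypothesis testing between conditions (the
summaries are descriptive), and no import of plate-reader dialects other
than the two-block 96-well workbook described above.
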