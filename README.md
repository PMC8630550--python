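# dualluc

Scriptable analysis of dual-luciferase reporter assays: parse plate-reader
workbooks, merge experimental designs, normalize firefly signal by the
renilla internal control, compute fold change against a reference
condition, and produce summary tables and publication-grade dot plots that
keep every individual data point visible.

## Who this is for

Molecular and cell biologists running reporter gene assays: a DNA sequence
of interest (a promoter, an enhancer, a transcription-factor binding site)
is cloned upstream of firefly luciferase, transfected into cells together
with a constitutively expressed renilla luciferase, and luminescence is
read per well of a 96-well plate. `dualluc` turns the raw plate export
into normalized, plotted, reproducible results from the command line or
from Python — no spreadsheet wrangling, no copy-paste normalization.

## The model

Per well *w*, the renilla internal control cancels well-to-well variation
in cell density and transfection efficiency:

    r_w = firefly_w / renilla_w

and each well is expressed relative to a reference condition (e.g. the
empty-vector control), using the **mean ratio of the reference group** as
the denominator:

    fold_change_w = r_w / mean( r over reference wells )

so the reference group's mean fold change is 1 by construction. With
multi-factor designs (vector x drug x cell type) each drug x cell stratum
is normalized to its own reference wells by default; a single global
denominator is available with `--global`. Per-condition summaries report
n, mean, sd, sem, median and a 95% t-interval of the mean. See
[docs/methods.md](docs/methods.md) for the full model, the file dialects,
and the simulation noise model.

## Worked example

Generate a synthetic 72-well experiment (3 vectors x 4 drug treatments x
2 cell types, 3 replicates, known ground truth), then analyze it:

```sh
dualluc simulate --out-dir demo --seed 42
# wrote 72-well bundle: demo/plate.xlsx, demo/design.csv, demo/tidy.csv, demo/truth.json

dualluc convert --workbook demo/plate.xlsx --design demo/design.csv --out demo/converted.csv
# wrote 72 rows to demo/converted.csv

dualluc analyze --tidy demo/tidy.csv --reference condition=control --out-dir results
# analyzed 72 wells (fold_change); outputs in results
```

`results/` now contains the processed tidy table (`tidy.csv`, with
`ratio` and `fold_change` columns), the per-condition summary
(`summary.csv` / `summary.txt`) and a faceted dot plot (`dotplot.png`,
one panel per drug x cell combination, one point per well, a median bar
per group and a guide line at fold change 1). The first summary row:

```
condition,n,mean,sd,sem,median,ci95_low,ci95_high
control_none_Hek,3,1.0000000000000002,0.0393...,0.0227...,0.9863...,0.9023...,1.0976...
```

— the control condition self-normalizes to a mean fold change of 1, with
its three replicate wells spread by the simulated transfection and
measurement noise. The estimated effects track the generator's truth
(`demo/truth.json`): for seed 42, `geneA_none_Hek` is estimated at 2.43
(truth 2.5), `geneA_drug1_neuron` at 6.33 (truth 6.3) and
`geneB_drug2_Hek` at 0.42 (truth 0.42).

The same pipeline accepts real data: point `--workbook` at a plate-reader
export containing the two 8x12 firefly/renilla tables and `--design` at a
CSV mapping wells to conditions — or pass a single combined table with
`--tidy`. Wells and whole conditions can be excluded
(`--exclude-well A01`, `--exclude-condition drug=drug2`), the reference
hidden (`--hide-reference`), panels rotated (`--rotate`) and figures
exported as PNG or PDF (`--format pdf`).

From Python the same steps are:

```python
from dualluc import (read_glomax, read_design, merge_design, compute_ratios,
                     fold_change, summarize, NormalizationConfig, dot_plot)

exp = merge_design(read_glomax("demo/plate.xlsx"), read_design("demo/design.csv"))
exp = fold_change(compute_ratios(exp), NormalizationConfig("condition=control"))
print(summarize(exp).to_text())
fig = dot_plot(exp, x="condition", facets=["drug", "cell"])
```

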