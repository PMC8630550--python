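"""Publication-grade figures: plate heatmaps and faceted dot plots.

The dot plot shows every observation as a point — never only a bar and an
error whisker — grouped by one factor on the x axis and faceted into one
panel per combination of the remaining factors, with an optional summary
overlay (median or mean line, plus sd / sem / 95% CI / IQR whiskers).
Horizontal jitter is drawn from a fixed seed so exports are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")  # noqa: E402  (headless backend before pyplot)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core_model import (
    N_COLUMNS,
    PlateReadings,
    ROW_LETTERS,
    TidyExperiment,
    ValidationError,
)
from .normalize import _selector_mask

#: Okabe-Ito colour-blind-safe palette (black last, used for overlays).
OKABE_ITO = (
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#000000",
)


@dataclass
class PlotOptions:
    """Geometry and style of the dot plot, mirroring the interactive knobs.

    ``summary_stat`` draws a horizontal line per group at its median or
    mean; ``error_overlay`` adds whiskers (sd, sem, 95% t-CI of the mean,
    or the interquartile range).  ``rotate`` flips the panel 90 degrees so
    conditions read down the y axis.  ``show_reference`` controls whether
    the reference group's points are drawn at all.
    """

    point_size: float = 36.0
    alpha: float = 0.8
    gridlines: bool = True
    summary_stat: str = "median"      # median | mean | none
    error_overlay: str = "none"       # none | sd | sem | ci95 | iqr
    font_size: float = 11.0
    width: float = 8.0                # inches
    height: float = 5.0
    rotate: bool = False
    show_reference: bool = True
    y_scale: str = "linear"           # linear | log10
    jitter_width: float = 0.2         # fraction of group spacing
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError(f"alpha {self.alpha} outside (0, 1]")
        for name in ("point_size", "font_size", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.summary_stat not in {"median", "mean", "none"}:
            raise ValidationError(f"unknown summary_stat {self.summary_stat!r}")
        if self.error_overlay not in {"none", "sd", "sem", "ci95", "iqr"}:
            raise ValidationError(
                f"unknown error_overlay {self.error_overlay!r}"
            )
        if self.y_scale not in {"linear", "log10"}:
            raise ValidationError(f"unknown y_scale {self.y_scale!r}")


def plate_heatmap(readings: PlateReadings, channel: str = "firefly"):
    """False-colour overview of one channel in 96-well layout.

    Rows A-H run top to bottom, columns 1-12 left to right, matching how a
    plate sits on the bench.  Blank (unmeasured) wells render in a distinct
    grey, not as zero signal.  Returns the matplotlib figure; the plotted
    8 x 12 array is recoverable from the image artist for testing.
    """
    if channel not in {"firefly", "renilla"}:
        raise ValidationError(f"unknown channel {channel!r}")
    grid = np.full((len(ROW_LETTERS), N_COLUMNS), np.nan)
    for _, rec in readings.data.iterrows():
        r = ROW_LETTERS.index(rec["well"][0])
        c = int(rec["well"][1:]) - 1
        grid[r, c] = rec[channel]
    fig, ax = plt.subplots(figsize=(7.5, 5))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(np.ma.masked_invalid(grid), cmap=cmap, aspect="equal")
    ax.set_xticks(range(N_COLUMNS), [str(i + 1) for i in range(N_COLUMNS)])
    ax.set_yticks(range(len(ROW_LETTERS)), list(ROW_LETTERS))
    ax.set_title(f"{readings.plate_id}: {channel} luminescence")
    fig.colorbar(im, ax=ax, shrink=0.8, label=f"{channel} (counts)")
    return fig


def _group_summary(values: np.ndarray, options: PlotOptions):
    """(centre, err_low, err_high) per the configured overlay, or Nones."""
    centre = None
    if options.summary_stat == "median":
        centre = float(np.median(values))
    elif options.summary_stat == "mean":
        centre = float(values.mean())
    lo = hi = None
    n = len(values)
    if options.error_overlay != "none" and n > 1:
        mean = values.mean()
        sd = values.std(ddof=1)
        if options.error_overlay == "sd":
            lo, hi = mean - sd, mean + sd
        elif options.error_overlay == "sem":
            sem = sd / np.sqrt(n)
            lo, hi = mean - sem, mean + sem
        elif options.error_overlay == "ci95":
            from scipy import stats
            sem = sd / np.sqrt(n)
            t = stats.t.ppf(0.975, n - 1)
            lo, hi = mean - t * sem, mean + t * sem
        elif options.error_overlay == "iqr":
            lo, hi = np.percentile(values, [25, 75])
    return centre, lo, hi


def dot_plot(
    exp: TidyExperiment,
    x: str,
    facets: list[str] | None = None,
    options: PlotOptions | None = None,
):
    """Faceted dot plot of fold change (or the raw ratio) per condition.

    One point per observation; groups along the axis given by factor ``x``;
    one panel per distinct combination of the ``facets`` factors.  The value
    plotted is the fold change when computed, otherwise the firefly/renilla
    ratio, and the axis is labelled accordingly.  A guide line marks fold
    change 1 when a reference was applied.  Returns the figure; each axes
    carries the plotted subset in ``ax._dualluc_panel`` for introspection.
    """
    options = options or PlotOptions()
    facets = list(facets or [])
    for name in [x, *facets]:
        if name not in exp.factor_names:
            raise ValidationError(
                f"{name!r} is not a factor column; factors are "
                f"{exp.factor_names}"
            )
    if exp.has_fold_change:
        value, label = "fold_change", "Fold Change"
    elif exp.has_ratio:
        value, label = "ratio", "firefly/renilla ratio"
    else:
        raise ValidationError(
            "nothing to plot: compute ratios (and optionally fold change) "
            "first"
        )
    df = exp.data
    if df[value].isna().any():
        bad = df.loc[df[value].isna(), "well"].tolist()
        raise ValidationError(f"NaN {value} in wells {bad}")
    if not options.show_reference and exp.reference is not None:
        df = df[~_selector_mask(exp, exp.reference)]
    if df.empty:
        raise ValidationError("no rows left to plot")

    x_levels = list(dict.fromkeys(df[x]))
    colours = {
        lev: OKABE_ITO[i % (len(OKABE_ITO) - 1)]
        for i, lev in enumerate(x_levels)
    }
    if facets:
        combos = list(
            df[facets].drop_duplicates().itertuples(index=False, name=None)
        )
    else:
        combos = [()]
    ncols = min(4, len(combos))
    nrows = -(-len(combos) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols,
        figsize=(options.width, options.height),
        squeeze=False, sharey=not options.rotate, sharex=options.rotate,
    )
    rng = np.random.default_rng(options.jitter_seed)
    for k, combo in enumerate(combos):
        ax = axes[k // ncols][k % ncols]
        sub = df
        for name, lev in zip(facets, combo):
            sub = sub[sub[name] == lev]
        ax._dualluc_panel = sub  # introspection hook for tests
        for i, lev in enumerate(x_levels):
            vals = sub.loc[sub[x] == lev, value].to_numpy()
            if len(vals) == 0:
                continue
            jitter = rng.uniform(
                -options.jitter_width / 2, options.jitter_width / 2,
                size=len(vals),
            )
            pos = np.full(len(vals), float(i)) + jitter
            xy = (vals, pos) if options.rotate else (pos, vals)
            ax.scatter(
                *xy,
                s=options.point_size,
                alpha=options.alpha,
                color=colours[lev],
                edgecolors="none",
                zorder=3,
            )
            centre, lo, hi = _group_summary(vals, options)
            if centre is not None:
                if options.rotate:
                    ax.plot([centre] * 2, [i - 0.3, i + 0.3],
                            color="black", lw=1.8, zorder=4)
                else:
                    ax.plot([i - 0.3, i + 0.3], [centre] * 2,
                            color="black", lw=1.8, zorder=4)
            if lo is not None:
                if options.rotate:
                    ax.plot([lo, hi], [i] * 2, color="black", lw=1.0,
                            zorder=4)
                else:
                    ax.plot([i] * 2, [lo, hi], color="black", lw=1.0,
                            zorder=4)
        ticks = range(len(x_levels))
        if options.rotate:
            ax.set_yticks(ticks, x_levels, fontsize=options.font_size)
            ax.set_xlabel(label, fontsize=options.font_size)
            if options.y_scale == "log10":
                ax.set_xscale("log")
            if exp.reference is not None and value == "fold_change":
                ax.axvline(1.0, color="0.5", lw=0.8, ls="--", zorder=1)
        else:
            ax.set_xticks(ticks, x_levels, fontsize=options.font_size)
            ax.set_ylabel(label, fontsize=options.font_size)
            if options.y_scale == "log10":
                ax.set_yscale("log")
            if exp.reference is not None and value == "fold_change":
                ax.axhline(1.0, color="0.5", lw=0.8, ls="--", zorder=1)
        ax.tick_params(labelsize=options.font_size)
        if facets:
            ax.set_title(
                ", ".join(str(v) for v in combo), fontsize=options.font_size
            )
        ax.grid(options.gridlines, axis="x" if options.rotate else "y",
                color="0.9", zorder=0)
        if not options.gridlines:
            ax.grid(False)
    for k in range(len(combos), nrows * ncols):
        axes[k // ncols][k % ncols].set_visible(False)
    fig.tight_layout()
    return fig


def export_figure(fig, path, format: str | None = None, dpi: int = 300):
    """Write a figure as PNG (raster, at ``dpi``) or PDF (vector).

    The format is inferred from the file suffix when not given; anything
    other than PNG or PDF is an error.  PDF metadata dates are suppressed so
    repeated exports of the same figure are identical.
    """
    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).lower()
    if fmt not in {"png", "pdf"}:
        raise ValidationError(
            f"unsupported export format {fmt!r}; use png or pdf"
        )
    kwargs = {"format": fmt, "dpi": dpi}
    if fmt == "pdf":
        kwargs["metadata"] = {"CreationDate": None}
    fig.savefig(path, **kwargs)
    return path
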