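"""The analysis core: ratios, fold change versus a reference, and summaries.

Per well, the firefly signal is divided by the renilla internal control to
give the firefly/renilla ratio, cancelling well-to-well variation in cell
density and transfection efficiency.  The fold change of each well is then
its ratio divided by the *average* ratio of the reference group:

    fold_change(w) = ratio(w) / mean(ratio over reference wells)

so the reference group's mean fold change is 1 by construction.  Fold change
is computed per well, not on pre-averaged ratios, preserving the individual
observations for dot plots and summary statistics.

Two referencing modes exist.  *Global*: one denominator for the whole table.
*Stratified*: rows are partitioned by every factor other than the reference
factor (e.g. drug x cell type) and each stratum is normalized to the mean
ratio of its own reference wells — the mode that matches a faceted
fold-change plot.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    NormalizationConfig,
    SummaryTable,
    TidyExperiment,
    ValidationError,
    parse_reference,
    parse_well,
)


def compute_ratios(
    exp: TidyExperiment, drop_zero_control: bool = False
) -> TidyExperiment:
    """Set each row's ratio to firefly/renilla.

    When the experiment has no renilla channel the ratio is the firefly
    signal itself (identity normalization; downstream math is unchanged but
    outputs are unnormalized).  A zero renilla reading would produce a
    silent infinity, so it is an error naming the wells; with
    ``drop_zero_control`` such wells are dropped with a warning instead.
    """
    df = exp.data.copy()
    if exp.has_renilla:
        zero = df.loc[df["renilla"] == 0, "well"].tolist()
        if zero and not drop_zero_control:
            raise ValidationError(
                f"renilla signal is 0 in wells {zero}; cannot form the "
                "firefly/renilla ratio (use drop_zero_control to discard)"
            )
        if zero:
            warnings.warn(
                f"dropping {len(zero)} wells with zero renilla: {zero}",
                stacklevel=2,
            )
            df = df[df["renilla"] != 0]
        df["ratio"] = df["firefly"] / df["renilla"]
    else:
        df["ratio"] = df["firefly"]
    return exp.replace_data(df)


def _selector_mask(exp: TidyExperiment, selector: str) -> pd.Series:
    """Boolean row mask for a 'factor=level' pair or a full condition key."""
    factor, level = parse_reference(selector)
    if factor is not None:
        if factor not in exp.factor_names:
            raise ValidationError(
                f"unknown factor {factor!r}; factors are {exp.factor_names}"
            )
        return exp.data[factor] == level
    return exp.condition_keys() == level


def filter_experiment(
    exp: TidyExperiment,
    exclude_wells: Iterable[str] = (),
    exclude_conditions: Iterable[str] = (),
) -> tuple[TidyExperiment, dict[str, int]]:
    """Remove individual wells and/or whole conditions from the analysis.

    Returns the filtered experiment and a removal report mapping each
    exclusion criterion to the number of rows it removed.  Exclusions that
    match nothing raise a warning, not an error, so a shared exclusion list
    can be applied across plates.
    """
    df = exp.data
    keep = pd.Series(True, index=df.index)
    report: dict[str, int] = {}
    for w in exclude_wells:
        name = parse_well(str(w)).text
        hit = df["well"] == name
        if not hit.any():
            warnings.warn(f"excluded well {name} not in the data",
                          stacklevel=2)
        report[f"well:{name}"] = int((hit & keep).sum())
        keep &= ~hit
    for sel in exclude_conditions:
        hit = _selector_mask(exp, str(sel))
        if not hit.any():
            warnings.warn(
                f"excluded condition {sel!r} matches no rows", stacklevel=2
            )
        report[f"condition:{sel}"] = int((hit & keep).sum())
        keep &= ~hit
    return exp.replace_data(df[keep]), report


def _reference_mean(ratios: np.ndarray, geometric: bool) -> float:
    if geometric:
        if (ratios <= 0).any():
            raise ValidationError(
                "geometric reference mean requires strictly positive ratios"
            )
        return float(np.exp(np.log(ratios).mean()))
    return float(ratios.mean())


def fold_change(
    exp: TidyExperiment, config: NormalizationConfig
) -> TidyExperiment:
    """Divide each well's ratio by the mean ratio of the reference group.

    The denominator is the arithmetic mean of the reference wells' ratios
    (geometric mean with ``config.geometric``, since ratios of log-normal
    signals are themselves log-normal-ish).  With ``config.stratified`` the
    table is partitioned by the non-reference factors and each stratum uses
    its own reference mean; ``stratified=None`` selects stratified mode
    automatically when there is more than one factor and the reference names
    a single factor level.
    """
    if not exp.has_ratio:
        raise ValidationError(
            "ratios not computed; call compute_ratios first"
        )
    factor, level = parse_reference(config.reference)
    stratified = config.stratified
    if stratified is None:
        stratified = factor is not None and len(exp.factor_names) > 1
    if stratified and factor is None:
        raise ValidationError(
            "stratified normalization needs a 'factor=level' reference"
        )

    df = exp.data.copy()
    if stratified:
        others = [f for f in exp.factor_names if f != factor]
        fc = pd.Series(np.nan, index=df.index)
        for key, sub in df.groupby(others, sort=False):
            ref = sub.loc[sub[factor] == level, "ratio"]
            stratum = dict(zip(others, key if isinstance(key, tuple) else (key,)))
            if ref.empty:
                raise ValidationError(
                    f"stratum {stratum} has no reference rows "
                    f"({factor}={level})"
                )
            denom = _reference_mean(ref.to_numpy(), config.geometric)
            if denom == 0:
                raise ValidationError(
                    f"reference mean ratio is 0 in stratum {stratum}"
                )
            fc.loc[sub.index] = sub["ratio"] / denom
        df["fold_change"] = fc
    else:
        mask = _selector_mask(exp, config.reference)
        if not mask.any():
            available = sorted(exp.condition_keys().unique())
            raise ValidationError(
                f"reference {config.reference!r} matches no rows; "
                f"available condition keys: {available}"
            )
        denom = _reference_mean(
            df.loc[mask, "ratio"].to_numpy(), config.geometric
        )
        if denom == 0:
            raise ValidationError("reference mean ratio is 0")
        df["fold_change"] = df["ratio"] / denom
    out = exp.replace_data(df)
    out.reference = config.reference
    return out


def summarize(
    exp: TidyExperiment,
    value: str = "auto",
    by: Sequence[str] | None = None,
) -> SummaryTable:
    """Per-condition descriptive statistics of the ratio or fold change.

    ``value`` is ``"ratio"``, ``"fold_change"``, or ``"auto"`` (fold change
    when computed, else ratio).  Statistics per condition: n, mean, sample
    sd (n-1 denominator), sem = sd/sqrt(n), median, and the 95% confidence
    interval of the mean from the t distribution with n-1 df.  Dispersion
    statistics are left unset (NaN) for conditions with a single well.
    ``by`` optionally restricts the grouping to a subset of factors;
    the default groups by the full condition key.
    """
    if value == "auto":
        value = "fold_change" if exp.has_fold_change else "ratio"
    if value not in exp.data.columns:
        raise ValidationError(f"{value!r} not computed for this experiment")
    if by is None:
        keys = exp.condition_keys()
    else:
        unknown = [f for f in by if f not in exp.factor_names]
        if unknown:
            raise ValidationError(f"unknown grouping factors {unknown}")
        keys = exp.data[list(by)].astype(str).agg(exp.separator.join, axis=1)

    rows = []
    for key, vals in exp.data[value].groupby(keys, sort=False):
        x = vals.to_numpy(dtype=float)
        n = len(x)
        mean = float(x.mean())
        if n > 1:
            sd = float(x.std(ddof=1))
            sem = sd / np.sqrt(n)
            tcrit = float(stats.t.ppf(0.975, n - 1))
            ci_low, ci_high = mean - tcrit * sem, mean + tcrit * sem
        else:
            sd = sem = ci_low = ci_high = np.nan
        rows.append(
            {
                "condition": key,
                "n": n,
                "mean": mean,
                "sd": sd,
                "sem": sem,
                "median": float(np.median(x)),
                "ci95_low": ci_low,
                "ci95_high": ci_high,
            }
        )
    return SummaryTable(data=pd.DataFrame(rows), value=value)
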