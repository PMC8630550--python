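"""Synthetic dual-luciferase experiments with known ground truth.

The generator realizes the noise model that motivates internal-control
normalization: every well has a latent transfection efficiency shared by
both reporters, plus independent measurement noise per channel.  For a well
``w`` in condition ``c``:

    t_w       ~ LogNormal(0, transfection_sigma)
    renilla_w = renilla_mean * t_w * LogNormal(0, measurement_sigma)
    firefly_w = renilla_mean * F(c) * t_w * LogNormal(0, measurement_sigma)

where ``F(c)`` is the condition's true fold change (1 for the reference).
The transfection factor ``t_w`` multiplies both channels and therefore
cancels exactly in the firefly/renilla ratio — which is the entire point of
the renilla control.  Noise is multiplicative log-normal, keeping simulated
luminescence counts positive.

Wells are assigned to plate positions in row-major order (A01, A02, ..) and
everything is deterministic for a given seed, so generated experiments double
as fixtures for parser round-trip tests: :func:`write_fixture_bundle` emits
the matched workbook / design CSV / tidy CSV trio plus a ground-truth JSON.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    DesignTable,
    PLATE_SIZE,
    PlateReadings,
    SeparatorCollisionWarning,
    TidyExperiment,
    ValidationError,
    all_wells,
    condition_key,
)
from .plate_io import write_glomax, write_tidy


@dataclass
class SimulationSpec:
    """Generative parameters for one synthetic plate.

    ``factors`` maps each factor name to its levels; conditions are the full
    cross of all levels, each measured ``replicates`` times.
    ``true_fold_change`` maps condition keys to their true effect relative
    to the reference (conditions not listed default to 1, the reference
    level).  ``renilla_mean`` sets the scale of the control channel in
    luminescence counts; ``transfection_sigma`` and ``measurement_sigma``
    are log-scale standard deviations of the shared per-well transfection
    efficiency and the per-channel measurement noise.
    """

    factors: dict[str, list[str]]
    true_fold_change: dict[str, float] = field(default_factory=dict)
    replicates: int = 3
    renilla_mean: float = 1.0e5
    transfection_sigma: float = 0.3
    measurement_sigma: float = 0.05
    separator: str = "_"
    seed: int = 0
    plate_id: str = "simulated"

    def __post_init__(self) -> None:
        if not self.factors or any(not lv for lv in self.factors.values()):
            raise ValidationError("factors must be non-empty lists of levels")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.transfection_sigma < 0 or self.measurement_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")
        if self.renilla_mean <= 0:
            raise ValidationError("renilla_mean must be > 0")
        if any(v <= 0 for v in self.true_fold_change.values()):
            raise ValidationError("true fold changes must be > 0")
        if self.n_wells > PLATE_SIZE:
            raise ValidationError(
                f"{self.n_wells} wells exceed one 96-well plate; shrink the "
                "design or the replicate count"
            )
        keys = set(self.condition_keys())
        unknown = set(self.true_fold_change) - keys
        if unknown:
            raise ValidationError(
                f"true_fold_change names conditions not in the design: "
                f"{sorted(unknown)}"
            )

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    @property
    def n_conditions(self) -> int:
        return int(np.prod([len(v) for v in self.factors.values()]))

    @property
    def n_wells(self) -> int:
        return self.n_conditions * self.replicates

    def condition_keys(self) -> list[str]:
        keys = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparatorCollisionWarning)
            for combo in itertools.product(*self.factors.values()):
                keys.append(
                    condition_key(
                        dict(zip(self.factor_names, combo)), self.separator
                    )
                )
        return keys

    def truth(self) -> dict[str, float]:
        """True fold change per condition key (1 where unspecified)."""
        return {
            k: float(self.true_fold_change.get(k, 1.0))
            for k in self.condition_keys()
        }


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """A spec emulating a typical full-plate dual-luciferase use case.

    Three transfected vectors (empty control, geneA, geneB) crossed with
    four drug treatments and two cell types, three replicate wells each:
    72 wells.  True effects vary by stratum the way a real enhancer screen
    would — geneA activates (more under drug1), geneB represses.
    """
    factors = {
        "condition": ["control", "geneA", "geneB"],
        "drug": ["none", "drug1", "drug2", "both"],
        "cell": ["Hek", "neuron"],
    }
    fc = {}
    gene_base = {"geneA": 2.5, "geneB": 0.6}
    drug_mod = {"none": 1.0, "drug1": 1.8, "drug2": 0.7, "both": 1.3}
    cell_mod = {"Hek": 1.0, "neuron": 1.4}
    for g, base in gene_base.items():
        for d, dm in drug_mod.items():
            for c, cm in cell_mod.items():
                fc[f"{g}_{d}_{c}"] = round(base * dm * cm, 4)
    spec = dict(
        factors=factors,
        true_fold_change=fc,
        replicates=3,
        renilla_mean=1.0e5,
        transfection_sigma=0.3,
        measurement_sigma=0.05,
        seed=seed,
    )
    spec.update(overrides)
    return SimulationSpec(**spec)


def generate_experiment(
    spec: SimulationSpec,
) -> tuple[TidyExperiment, dict[str, float]]:
    """Draw one synthetic experiment; returns the tidy table and the truth.

    Deterministic for a given ``spec.seed``.  Wells fill the plate in
    row-major order, replicates of each condition adjacent — the layout a
    multichannel pipette produces.
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth()
    wells = all_wells()
    rows = []
    i = 0
    for combo in itertools.product(*spec.factors.values()):
        labels = dict(zip(spec.factor_names, combo))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparatorCollisionWarning)
            key = condition_key(labels, spec.separator)
        f_true = truth[key]
        for _ in range(spec.replicates):
            t = rng.lognormal(0.0, spec.transfection_sigma)
            renilla = (
                spec.renilla_mean * t
                * rng.lognormal(0.0, spec.measurement_sigma)
            )
            firefly = (
                spec.renilla_mean * f_true * t
                * rng.lognormal(0.0, spec.measurement_sigma)
            )
            rows.append(
                {"well": wells[i].text, **labels,
                 "firefly": firefly, "renilla": renilla}
            )
            i += 1
    exp = TidyExperiment(
        data=pd.DataFrame(rows),
        factor_names=spec.factor_names,
        separator=spec.separator,
    )
    return exp, truth


def as_plate_readings(exp: TidyExperiment, plate_id: str) -> PlateReadings:
    """View the experiment's raw channels as one plate of readings."""
    return PlateReadings(
        data=exp.data[["well", "firefly", "renilla"]],
        plate_id=plate_id,
    )


def as_design(exp: TidyExperiment) -> DesignTable:
    """View the experiment's factor assignments as a design table."""
    return DesignTable(
        data=exp.data[["well", *exp.factor_names]],
        factor_names=list(exp.factor_names),
    )


def write_fixture_bundle(spec: SimulationSpec, out_dir) -> dict[str, Path]:
    """Write the matched input trio the tool accepts, plus the ground truth.

    Emits ``plate.xlsx`` (workbook with the two 8x12 blocks), ``design.csv``
    (well-to-condition map), ``tidy.csv`` (the combined single-file upload)
    and ``truth.json`` (true fold change per condition key).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exp, truth = generate_experiment(spec)
    paths = {
        "workbook": out_dir / "plate.xlsx",
        "design": out_dir / "design.csv",
        "tidy": out_dir / "tidy.csv",
        "truth": out_dir / "truth.json",
    }
    write_glomax(as_plate_readings(exp, spec.plate_id), paths["workbook"])
    as_design(exp).data.to_csv(paths["design"], index=False,
                               lineterminator="\n")
    write_tidy(exp, paths["tidy"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "true_fold_change": truth,
                "reference": f"{spec.factor_names[0]}="
                             f"{spec.factors[spec.factor_names[0]][0]}",
                "replicates": spec.replicates,
                "transfection_sigma": spec.transfection_sigma,
                "measurement_sigma": spec.measurement_sigma,
                "seed": spec.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
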