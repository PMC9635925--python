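"""Synthetic screens with known ground truth.

The generator emulates the study design of the MRGPRX2 agonist screen: a
~3,456-compound library laid out on 384-well plates, each compound tested in
triplicate in two genotypes (wild-type receptor and the N62S loss-of-function
mutant), with per-plate vehicle and substance-P control columns.  A well's
ratio value is assembled additively:

    baseline + compound effect (genotype-specific) + row offset
             + column offset + Gaussian noise

A small fraction of compounds are true agonists; in the mutant line their
effect is multiplied by an attenuation factor near zero (the mutation removes
~90-95% of the response).  Row/column offsets are additive positional
artifacts — exactly the structure two-way median polish removes — and an
optional multiplicative edge effect provides a deliberate model violation for
robustness checks.  Everything is reproducible from a single seed.

Dose-response and degranulation fixtures for the pharmacology arm are
generated here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CellLine, PlateGrid, WellRole
from .pharm import DEFAULT_LOG10_CONCENTRATIONS, four_pl

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_dose_response",
    "simulate_degranulation",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Effects are on the ratio scale (dimensionless, baseline ~1).  Agonist
    effects are sized a few-fold above the detection floor so that, as in
    the real screen, hit B-scores sit one to a few times above the 3-SD
    cutoff.  ``mut_attenuation_mean=0.05`` leaves ~5% of the WT effect in
    the mutant line, mirroring the ~90% loss of response reported for
    N62S-attenuated hits.
    """

    n_compounds: int = 3456
    plate_shape: tuple[int, int] = (16, 24)
    n_replicates: int = 3
    frac_agonists: float = 0.03
    agonist_effect_mean: float = 0.4
    agonist_effect_sd: float = 0.15
    mut_attenuation_mean: float = 0.05
    mut_attenuation_sd: float = 0.05
    row_effect_sd: float = 0.03
    col_effect_sd: float = 0.03
    noise_sd: float = 0.05
    baseline_ratio: float = 1.0
    pos_control_effect: float = 1.5
    edge_gain: float = 0.0  # multiplicative rim artifact; 0 disables
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_agonists < 1:
            raise ValueError("frac_agonists must be in [0, 1)")
        for name in ("agonist_effect_sd", "mut_attenuation_sd", "row_effect_sd",
                     "col_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_compounds < 1 or self.n_replicates < 1:
            raise ValueError("n_compounds and n_replicates must be >= 1")
        n_rows, n_cols = self.plate_shape
        if n_rows < 2 or n_cols < 4:
            raise ValueError("plate_shape too small for a library + control layout")

    @property
    def library_wells_per_plate(self) -> int:
        n_rows, n_cols = self.plate_shape
        return n_rows * (n_cols - 2)  # last two columns are NEG / POS controls

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_compounds / self.library_wells_per_plate)


@dataclass
class GroundTruth:
    """Truth ledger of one simulated screen, for recovery tests."""

    compound_ids: list[str]
    is_agonist: np.ndarray
    wt_effect: np.ndarray
    mut_effect: np.ndarray
    row_effects: dict[str, np.ndarray] = field(default_factory=dict)
    col_effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_agonists(self) -> int:
        return int(self.is_agonist.sum())

    def agonist_ids(
        self,
        *,
        min_wt_effect: float = 0.0,
        max_attenuation: float = 1.0,
    ) -> list[str]:
        """Injected agonists, optionally restricted by effect size and by
        the fraction of WT effect remaining in the mutant."""
        ids = []
        for cid, ag, wt, mut in zip(
            self.compound_ids, self.is_agonist, self.wt_effect, self.mut_effect
        ):
            if not ag or wt < min_wt_effect:
                continue
            if wt > 0 and mut / wt > max_attenuation:
                continue
            ids.append(cid)
        return ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "is_agonist": self.is_agonist,
                "wt_effect": self.wt_effect,
                "mut_effect": self.mut_effect,
            }
        ).set_index("compound_id")


def simulate_screen(config: SimulationConfig) -> tuple[list[PlateGrid], GroundTruth]:
    """Generate the full paired screen: WT and MUT plates plus ground truth.

    The compound-to-well layout is sequential and identical across
    genotypes and replicates; each physical plate draws its own row/column
    offsets and noise.  The draw order (truth first, then plates in
    WT-before-MUT, replicate-major, plate-index order) is fixed, so a given
    seed always yields bit-identical output.
    """
    config.validate()
    n_rows, n_cols = config.plate_shape
    lib_cols = n_cols - 2
    per_plate = config.library_wells_per_plate
    if per_plate < 1:
        raise ValueError("plate layout leaves no library wells")
    n_plates = config.n_plates
    if n_plates * per_plate < config.n_compounds:
        raise ValueError("plate capacity insufficient for the library")

    truth_seed, plate_seed = np.random.SeedSequence(config.seed).spawn(2)
    truth_rng = np.random.default_rng(truth_seed)
    plate_rng = np.random.default_rng(plate_seed)

    width = len(str(config.n_compounds))
    compound_ids = [f"C{i + 1:0{width}d}" for i in range(config.n_compounds)]
    is_agonist = truth_rng.random(config.n_compounds) < config.frac_agonists
    raw_effect = truth_rng.normal(
        config.agonist_effect_mean, config.agonist_effect_sd, config.n_compounds
    )
    wt_effect = np.where(is_agonist, np.maximum(raw_effect, 0.0), 0.0)
    attenuation = np.clip(
        truth_rng.normal(
            config.mut_attenuation_mean, config.mut_attenuation_sd, config.n_compounds
        ),
        0.0,
        1.0,
    )
    mut_effect = np.where(is_agonist, wt_effect * attenuation, 0.0)

    # static layout, shared by every plate replicate and genotype
    layout_cid = np.full((n_plates, n_rows, n_cols), None, dtype=object)
    layout_role = np.empty((n_plates, n_rows, n_cols), dtype=object)
    layout_role[...] = WellRole.EMPTY
    layout_role[:, :, lib_cols] = WellRole.NEG_CTRL
    layout_role[:, :, lib_cols + 1] = WellRole.POS_CTRL
    for k, cid in enumerate(compound_ids):
        p, idx = divmod(k, per_plate)
        r, c = divmod(idx, lib_cols)
        layout_cid[p, r, c] = cid
        layout_role[p, r, c] = WellRole.LIBRARY
    effect_by_line = {CellLine.WT: wt_effect, CellLine.MUT: mut_effect}
    layout_effect = {}
    for line, eff in effect_by_line.items():
        mat = np.zeros((n_plates, n_rows, n_cols))
        for k in range(config.n_compounds):
            p, idx = divmod(k, per_plate)
            r, c = divmod(idx, lib_cols)
            mat[p, r, c] = eff[k]
        mat[:, :, lib_cols + 1] = config.pos_control_effect
        layout_effect[line] = mat

    layout_empty = np.array(
        [[[cell is WellRole.EMPTY for cell in row] for row in plane] for plane in layout_role]
    )

    truth = GroundTruth(
        compound_ids=compound_ids,
        is_agonist=is_agonist,
        wt_effect=wt_effect,
        mut_effect=mut_effect,
    )

    edge = np.zeros((n_rows, n_cols), dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True

    plates: list[PlateGrid] = []
    for line in (CellLine.WT, CellLine.MUT):
        for rep in range(1, config.n_replicates + 1):
            for p in range(n_plates):
                plate_id = f"{line.value}-R{rep}-P{p + 1:02d}"
                row_off = plate_rng.normal(0.0, config.row_effect_sd, n_rows)
                col_off = plate_rng.normal(0.0, config.col_effect_sd, n_cols)
                noise = plate_rng.normal(0.0, config.noise_sd, (n_rows, n_cols))
                values = (
                    config.baseline_ratio
                    + layout_effect[line][p]
                    + row_off[:, None]
                    + col_off[None, :]
                    + noise
                )
                if config.edge_gain:
                    values = np.where(edge, values * (1.0 + config.edge_gain), values)
                values = np.where(layout_empty[p], np.nan, values)
                plates.append(
                    PlateGrid(
                        plate_id=plate_id,
                        cell_line=line,
                        values=values,
                        roles=layout_role[p].copy(),
                        compound_ids=layout_cid[p].copy(),
                        n_rows=n_rows,
                        n_cols=n_cols,
                    )
                )
                truth.row_effects[plate_id] = row_off
                truth.col_effects[plate_id] = col_off
    return plates, truth


def simulate_dose_response(
    bottom: float,
    top: float,
    log_ec50: float,
    hill: float,
    *,
    concentrations: Sequence[float] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a dose-response table from the 4PL mean curve plus noise.

    ``concentrations`` are log10 molar; the default is the assay's 8-point
    grid from -6.5 to -3 in half-log steps.  Returns one row per
    concentration x replicate with columns log10_conc_M, response,
    replicate.
    """
    if hill == 0:
        raise ValueError("hill = 0 gives a degenerate (flat) curve")
    if concentrations is None:
        concentrations = DEFAULT_LOG10_CONCENTRATIONS
    x = np.asarray(list(concentrations), dtype=float)
    if x.size == 0:
        raise ValueError("concentrations must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        y = four_pl(x, bottom, top, log_ec50, hill) + rng.normal(0.0, noise_sd, x.size)
        for xi, yi in zip(x, y):
            rows.append({"log10_conc_M": xi, "response": yi, "replicate": rep})
    return pd.DataFrame(rows)


def simulate_degranulation(
    mean_release_by_condition: Mapping,
    *,
    noise_sd: float = 5.0,
    n: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample percent-release measurements around per-condition means.

    Keys of ``mean_release_by_condition`` are either condition labels or
    (condition, genotype) tuples; means must lie in [0, 100].  Samples are
    Gaussian around the mean, clipped to [0, 100].  Returns columns
    condition, [genotype,] replicate, percent_release.
    """
    rng = np.random.default_rng(seed)
    rows = []
    with_genotype = any(isinstance(k, tuple) for k in mean_release_by_condition)
    for key, mean in mean_release_by_condition.items():
        mean = float(mean)
        if not 0 <= mean <= 100:
            raise ValueError(f"mean percent release out of [0, 100]: {key!r} -> {mean}")
        if with_genotype:
            condition, genotype = key
        else:
            condition, genotype = key, None
        draws = np.clip(rng.normal(mean, noise_sd, n), 0.0, 100.0)
        for i, v in enumerate(draws, start=1):
            row = {"condition": condition, "replicate": i, "percent_release": float(v)}
            if with_genotype:
                row["genotype"] = genotype
            rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["condition"] + (["genotype"] if with_genotype else []) + ["replicate", "percent_release"]
    return df[cols]
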