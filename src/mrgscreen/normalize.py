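"""Plate normalization: signal ratios and B-scores via two-way median polish.

A raw well reads out as a peak-over-baseline fluorescence ratio.  Within a
plate, systematic row and column artifacts (dispenser gradients, edge
evaporation) are removed by Tukey's two-way median polish, which decomposes
the plate into an overall level, additive row and column effects, and
residuals.  The B-score of a well is its polish residual divided by the
scaled median absolute deviation (MAD, x 1.4826) of all analyzable residuals
on the plate — a robust, control-free analogue of a Z-score that is exactly
invariant to additive row/column offsets.

Control and empty wells are excluded from the polish and the MAD by default
(so controls cannot distort library statistics); a switch allows including
controls for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CellLine, PlateGrid, RawWellSignal, WellRole

log = logging.getLogger(__name__)

__all__ = [
    "MAD_SCALE",
    "MedianPolishFit",
    "BScorePlate",
    "compute_ratio",
    "median_polish",
    "b_score",
    "b_score_plate",
    "z_score_plate",
    "aggregate_replicates",
    "ReplicateAggregate",
    "screen_b_score_table",
    "aggregate_screen",
]

#: Scale factor making the MAD a consistent estimator of the Gaussian SD.
MAD_SCALE = 1.4826


def compute_ratio(signal: RawWellSignal | tuple[float, float]) -> float:
    """Signal-to-background ratio of one well: peak / baseline.

    ``baseline`` must be strictly positive; a peak below baseline is allowed
    (ratio < 1, i.e. signal below background).
    """
    if isinstance(signal, RawWellSignal):
        baseline, peak = signal.baseline, signal.peak
    else:
        baseline, peak = signal
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline!r}")
    return peak / baseline


@dataclass
class MedianPolishFit:
    """Additive decomposition value = overall + row + col + residual."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iterations: int
    converged: bool
    empty_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    empty_cols: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def median_polish(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MedianPolishFit:
    """Two-way median polish of a plate matrix.

    Alternately sweeps row medians and column medians of the residuals into
    the effect vectors, starting from all-zero effects, until the largest
    absolute change of any effect drops to ``tol`` or ``max_iter`` is
    reached.  After each sweep the median of the effect vector is folded
    into the overall term, so effects have (approximately) zero median at
    convergence.  Cells that are masked out or missing are ignored by every
    median and keep NaN residuals.

    Parameters
    ----------
    values : 2-D array of floats (NaN = missing).
    mask : optional boolean array, True where the cell is analyzable.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    resid = values.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape does not match values")
        resid[~mask] = np.nan
    analyzable = np.isfinite(resid)
    row_has = analyzable.any(axis=1)
    col_has = analyzable.any(axis=0)
    if row_has.sum() < 2 or col_has.sum() < 2:
        raise ValueError("median polish needs at least 2 analyzable rows and columns")
    # structurally expected when control columns are masked out, so debug-level
    if not row_has.all():
        log.debug("median_polish: %d row(s) with no analyzable cells", (~row_has).sum())
    if not col_has.all():
        log.debug("median_polish: %d column(s) with no analyzable cells", (~col_has).sum())

    n_rows, n_cols = resid.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    converged = False
    it = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for it in range(1, max_iter + 1):
            rmed = np.nanmedian(resid, axis=1)
            rmed[~row_has] = 0.0
            resid -= rmed[:, None]
            row_eff += rmed
            shift = float(np.median(row_eff[row_has]))
            row_eff[row_has] -= shift
            overall += shift

            cmed = np.nanmedian(resid, axis=0)
            cmed[~col_has] = 0.0
            resid -= cmed[None, :]
            col_eff += cmed
            shift = float(np.median(col_eff[col_has]))
            col_eff[col_has] -= shift
            overall += shift

            delta = max(np.abs(rmed).max(), np.abs(cmed).max())
            if delta <= tol:
                converged = True
                break
    return MedianPolishFit(
        overall=overall,
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        n_iterations=it,
        converged=converged,
        empty_rows=~row_has,
        empty_cols=~col_has,
    )


@dataclass
class BScorePlate:
    """Per-plate B-scores: polish residuals over the scaled residual MAD."""

    plate_id: str
    b_scores: np.ndarray
    mad: float
    degenerate: bool = False
    cell_line: CellLine | None = None


def b_score(fit: MedianPolishFit, *, plate_id: str = "") -> BScorePlate:
    """Scale polish residuals into B-scores.

    ``mad = 1.4826 x median(|residual|)`` over analyzable wells.  A plate
    whose residuals are all zero (mad = 0) gets all-zero B-scores and a
    degenerate flag rather than an error, so pipelines keep running on
    pathological inputs.
    """
    if not fit.converged:
        log.warning("b_score: median polish did not converge (plate %s)", plate_id)
    resid = fit.residuals
    finite = np.isfinite(resid)
    if not finite.any():
        raise ValueError("b_score: no analyzable residuals")
    mad = MAD_SCALE * float(np.median(np.abs(resid[finite])))
    if mad == 0.0:
        log.warning("b_score: zero residual MAD on plate %s; B-scores set to 0", plate_id)
        b = np.where(finite, 0.0, np.nan)
        return BScorePlate(plate_id=plate_id, b_scores=b, mad=0.0, degenerate=True)
    return BScorePlate(plate_id=plate_id, b_scores=resid / mad, mad=mad)


def b_score_plate(
    plate: PlateGrid,
    *,
    include_controls: bool = False,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BScorePlate:
    """Median polish + MAD scaling for one plate.

    By default only LIBRARY wells enter the polish and the MAD; control and
    empty wells carry missing B-scores.  ``include_controls=True`` adds
    NEG_CTRL/POS_CTRL wells to the polish (sensitivity analysis).
    """
    if include_controls:
        mask = plate.role_mask(WellRole.LIBRARY, WellRole.NEG_CTRL, WellRole.POS_CTRL)
    else:
        mask = plate.library_mask
    fit = median_polish(plate.values, mask, max_iter=max_iter, tol=tol)
    out = b_score(fit, plate_id=plate.plate_id)
    out.cell_line = plate.cell_line
    return out


def z_score_plate(plate: PlateGrid) -> np.ndarray:
    """Plain Z-score of library wells (mean/SD based), for comparison only."""
    vals = np.where(plate.library_mask, plate.values, np.nan)
    mu = np.nanmean(vals)
    sd = np.nanstd(vals, ddof=1)
    if sd == 0:
        return np.where(np.isfinite(vals), 0.0, np.nan)
    return (vals - mu) / sd


class ReplicateAggregate(NamedTuple):
    value: float
    n: int


def aggregate_replicates(values: Iterable[float]) -> ReplicateAggregate:
    """Mean of the finite replicate B-scores, with the replicate count used.

    Zero finite replicates yields a missing aggregate (NaN, n=0).
    """
    arr = np.asarray(list(values), dtype=float)
    finite = np.isfinite(arr)
    n = int(finite.sum())
    if n == 0:
        return ReplicateAggregate(float("nan"), 0)
    return ReplicateAggregate(float(arr[finite].mean()), n)


def screen_b_score_table(
    plates: Sequence[PlateGrid],
    *,
    include_controls: bool = False,
) -> pd.DataFrame:
    """B-score every plate and tabulate library wells.

    Returns one row per library well with columns plate_id, cell_line,
    compound_id, b_score.
    """
    rows = []
    for plate in plates:
        scored = b_score_plate(plate, include_controls=include_controls)
        mask = plate.library_mask
        for r, c in zip(*np.nonzero(mask)):
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "cell_line": plate.cell_line.value,
                    "compound_id": plate.compound_ids[r, c],
                    "b_score": scored.b_scores[r, c],
                }
            )
    return pd.DataFrame(rows, columns=["plate_id", "cell_line", "compound_id", "b_score"])


def aggregate_screen(b_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-well B-scores into per-compound genotype means.

    Input is the table from :func:`screen_b_score_table`.  Output is indexed
    by compound_id with columns ``b_wt``/``b_mut`` (mean over finite
    replicates), ``n_wt``/``n_mut`` (replicate counts) and ``rep_wt``/
    ``rep_mut`` (the raw replicate lists).
    """
    out: dict[str, dict] = {}
    suffixes = {CellLine.WT.value: "wt", CellLine.MUT.value: "mut"}
    for (cid, line), grp in b_table.groupby(["compound_id", "cell_line"], sort=True):
        if line not in suffixes:
            continue  # parental-line counterscreens are tabulated separately
        reps = grp["b_score"].tolist()
        agg = aggregate_replicates(reps)
        rec = out.setdefault(cid, {})
        suffix = suffixes[line]
        rec[f"b_{suffix}"] = agg.value
        rec[f"n_{suffix}"] = agg.n
        rec[f"rep_{suffix}"] = reps
    df = pd.DataFrame.from_dict(out, orient="index")
    for col, default in (
        ("b_wt", np.nan),
        ("b_mut", np.nan),
        ("n_wt", 0),
        ("n_mut", 0),
    ):
        if col not in df.columns:
            df[col] = default
    for col in ("rep_wt", "rep_mut"):
        if col not in df.columns:
            df[col] = [[] for _ in range(len(df))]
        else:
            df[col] = df[col].apply(lambda v: v if isinstance(v, list) else [])
    df.index.name = "compound_id"
    return df
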