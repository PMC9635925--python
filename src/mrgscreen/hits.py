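"""Hit calling, class summaries and paired WT/MUT differential selection.

The screen's hit rule is control-free: a compound is active in wild-type
cells when its aggregated B-score exceeds three times the sample SD of the
B-scores of *all* library compounds (hits included; strict inequality).
Selectivity for the receptor is assessed in a paired fashion against the
N62S loss-of-function line: the per-compound delta = b_wt - b_mut is
compared with a window of mean +/- SD of all deltas, and the percent change
100 x (b_mut - b_wt) / b_wt quantifies how much activity the mutation
removes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CompoundRecord, DifferentialCall, ScreenResult
from .normalize import MAD_SCALE, screen_b_score_table, aggregate_screen

log = logging.getLogger(__name__)

__all__ = [
    "HitThreshold",
    "DifferentialWindow",
    "ClassSummary",
    "call_hits",
    "class_summary",
    "percent_change",
    "differential_select",
    "analyze_screen",
]


@dataclass(frozen=True)
class HitThreshold:
    """Activity cutoff: multiplier x SD of all library B-scores."""

    sd_library: float
    multiplier: float = 3.0

    @property
    def threshold(self) -> float:
        return self.multiplier * self.sd_library

    def is_hit(self, b: float) -> bool:
        """Strict inequality: a B-score exactly at the cutoff is not a hit."""
        return bool(np.isfinite(b) and b > self.threshold)


@dataclass(frozen=True)
class DifferentialWindow:
    """Selection window for paired deltas: mean +/- SD of all deltas."""

    mean_delta: float
    sd_delta: float

    @property
    def upper(self) -> float:
        return self.mean_delta + self.sd_delta

    @property
    def lower(self) -> float:
        return self.mean_delta - self.sd_delta

    def call(self, delta: float) -> DifferentialCall:
        if not np.isfinite(delta):
            return DifferentialCall.NONE
        if delta > self.upper:
            return DifferentialCall.POSITIVE
        if delta < self.lower:
            return DifferentialCall.NEGATIVE
        return DifferentialCall.NONE


@dataclass(frozen=True)
class ClassSummary:
    """Count and WT B-score statistics of one drug class within a hit list."""

    drug_class: str
    n: int
    mean_b: float
    sd_b: float | None  # sample SD (n-1); undefined for n < 2
    pct: float  # share of the summarized subset, in percent


def _as_series(b_scores: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(dict(b_scores)) if not isinstance(b_scores, pd.Series) else b_scores
    return s.astype(float)


def call_hits(
    b_scores: Mapping[str, float] | pd.Series,
    multiplier: float = 3.0,
    *,
    robust: bool = False,
) -> tuple[HitThreshold, set[str]]:
    """Call active compounds from aggregated WT B-scores.

    The spread estimate is the sample SD over all library compounds with a
    finite aggregate (hits are not trimmed out).  ``robust=True`` swaps in
    the scaled MAD instead of the SD.
    """
    s = _as_series(b_scores).dropna()
    if len(s) < 2:
        raise ValueError("call_hits needs at least 2 finite B-scores")
    if robust:
        sd = MAD_SCALE * float(np.median(np.abs(s - s.median())))
    else:
        sd = float(s.std(ddof=1))
    thr = HitThreshold(sd_library=sd, multiplier=multiplier)
    hits = {str(cid) for cid, b in s.items() if thr.is_hit(b)}
    return thr, hits


def class_summary(
    b_scores: Mapping[str, float] | pd.Series,
    library: Mapping[str, CompoundRecord] | Mapping[str, str],
) -> list[ClassSummary]:
    """Per-class count, mean and sample SD of WT B-scores for a hit list.

    ``library`` maps compound_id to a :class:`CompoundRecord` (or directly
    to a drug-class string).  Percentages are relative to the summarized
    subset.  Unknown compound ids are a hard error.
    """
    s = _as_series(b_scores)
    unknown = [cid for cid in s.index if cid not in library]
    if unknown:
        raise KeyError(f"unknown compound ids: {sorted(unknown)}")

    def cls_of(cid: str) -> str:
        entry = library[cid]
        cls = getattr(entry, "drug_class", entry)
        if not cls:
            raise ValueError(f"compound {cid!r} has no drug_class annotation")
        return str(cls)

    total = len(s)
    groups: dict[str, list[float]] = {}
    for cid, b in s.items():
        groups.setdefault(cls_of(str(cid)), []).append(float(b))
    out = []
    for cls in sorted(groups):
        vals = np.asarray(groups[cls])
        sd = float(vals.std(ddof=1)) if len(vals) >= 2 else None
        out.append(
            ClassSummary(
                drug_class=cls,
                n=len(vals),
                mean_b=float(vals.mean()),
                sd_b=sd,
                pct=100.0 * len(vals) / total,
            )
        )
    return out


def percent_change(b_wt: float, b_mut: float) -> float:
    """Percent change of activity from WT to MUT: 100 x (b_mut - b_wt) / b_wt.

    Negative for compounds whose activity the N62S mutation attenuates.
    Undefined (NaN, with a warning) when b_wt is zero.
    """
    if b_wt == 0:
        log.warning("percent_change undefined for b_wt = 0")
        return float("nan")
    return 100.0 * (b_mut - b_wt) / b_wt


def differential_select(
    paired: pd.DataFrame | Mapping[str, tuple[float, float]],
) -> tuple[DifferentialWindow, pd.Series, list[str]]:
    """Select differentially responding compounds from paired aggregates.

    ``paired`` holds one (b_wt, b_mut) pair per compound (DataFrame with
    columns ``b_wt``/``b_mut`` or a mapping).  The window is mean +/- sample
    SD of delta = b_wt - b_mut over all complete pairs; calls are POSITIVE
    above the upper bound, NEGATIVE below the lower bound (strict), NONE
    otherwise.  Compounds missing one genotype are excluded and returned.
    """
    if not isinstance(paired, pd.DataFrame):
        paired = pd.DataFrame.from_dict(dict(paired), orient="index", columns=["b_wt", "b_mut"])
    df = paired[["b_wt", "b_mut"]].astype(float)
    complete = df.dropna()
    excluded = sorted(set(df.index.astype(str)) - set(complete.index.astype(str)))
    if excluded:
        log.info("differential_select: %d compound(s) missing one genotype", len(excluded))
    if len(complete) < 2:
        raise ValueError("differential_select needs at least 2 complete pairs")
    delta = complete["b_wt"] - complete["b_mut"]
    window = DifferentialWindow(
        mean_delta=float(delta.mean()),
        sd_delta=float(delta.std(ddof=1)),
    )
    calls = delta.apply(window.call)
    calls.name = "differential_call"
    return window, calls, excluded


def analyze_screen(
    plates,
    *,
    multiplier: float = 3.0,
    include_controls: bool = False,
) -> tuple[list[ScreenResult], HitThreshold, DifferentialWindow]:
    """End-to-end screen analysis: B-scores, hit calls, differential calls.

    Takes the full plate set (both genotypes, all replicates), normalizes
    each plate, aggregates replicates per compound and genotype, calls WT
    hits at ``multiplier`` x SD, runs the paired delta selection, and scores
    the percent change for every compound with a nonzero WT aggregate.
    """
    table = screen_b_score_table(plates, include_controls=include_controls)
    agg = aggregate_screen(table)
    thr, hit_ids = call_hits(agg["b_wt"], multiplier=multiplier)
    window, calls, _ = differential_select(agg)
    results = []
    for cid, row in agg.iterrows():
        b_wt = float(row["b_wt"])
        b_mut = float(row["b_mut"])
        pct = None
        if np.isfinite(b_wt) and np.isfinite(b_mut) and b_wt != 0:
            pct = percent_change(b_wt, b_mut)
        results.append(
            ScreenResult(
                compound_id=str(cid),
                b_wt=b_wt,
                b_mut=b_mut,
                replicate_b_wt=list(row["rep_wt"]),
                replicate_b_mut=list(row["rep_mut"]),
                is_hit_wt=str(cid) in hit_ids,
                differential_call=calls.get(cid, DifferentialCall.NONE),
                pct_change=pct,
            )
        )
    return results, thr, window
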