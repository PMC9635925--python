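"""Data model and tabular I/O for paired-genotype plate screens.

The screen reads out agonist activity of a compound library against the mast
cell receptor MRGPRX2 in two HEK293-Ga15 cell backgrounds: one expressing the
wild-type receptor (``WT``) and one expressing the loss-of-function N62S
variant (``MUT``).  Each 384-well plate carries library compounds alongside
vehicle (negative) and substance-P (positive) control wells; the well value is
the peak-over-baseline calcium-flux fluorescence ratio.

This module defines the in-memory containers (:class:`PlateGrid`,
:class:`CompoundRecord`, :class:`ScreenResult`) and the plain-text readers and
writers that move them in and out of long-format CSV/TSV files.  A packaged
reference table of 34 published MRGPRX2-selective hit compounds (name, PubChem
CID, indication class, WT/N62S B-scores, percent change) is exposed through
:func:`load_reference_hits`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CellLine",
    "WellRole",
    "DifferentialCall",
    "PlateGrid",
    "RawWellSignal",
    "CompoundRecord",
    "ScreenResult",
    "parse_well_label",
    "format_well_label",
    "read_plate_table",
    "write_plate_table",
    "read_compound_table",
    "write_results",
    "read_results",
    "sort_for_report",
    "load_reference_hits",
    "reference_hit_library",
]


class CellLine(str, Enum):
    """Cell background of a plate: wild-type, N62S mutant, or untransfected."""

    WT = "WT"
    MUT = "MUT"
    PARENTAL = "PARENTAL"


class WellRole(str, Enum):
    LIBRARY = "LIBRARY"
    NEG_CTRL = "NEG_CTRL"
    POS_CTRL = "POS_CTRL"
    EMPTY = "EMPTY"


class DifferentialCall(str, Enum):
    """Outcome of the paired WT-vs-MUT delta selection for one compound."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NONE = "NONE"


_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


def parse_well_label(label: str) -> tuple[int, int]:
    """Map an alphanumeric well label ("A1".."P24") to 0-based (row, col)."""
    m = _WELL_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed well label: {label!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if col < 0:
        raise ValueError(f"malformed well label: {label!r}")
    return row, col


def format_well_label(row: int, col: int) -> str:
    """Inverse of :func:`parse_well_label`; (0, 0) -> "A1"."""
    if not (0 <= row < 26) or col < 0:
        raise ValueError(f"well index out of range: ({row}, {col})")
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass(frozen=True)
class RawWellSignal:
    """Kinetic-trace summary for one well: pre-injection baseline and peak."""

    baseline: float
    peak: float


@dataclass
class PlateGrid:
    """One physical plate: well values, roles and compound assignment.

    ``values`` holds the dimensionless fluorescence ratio per well (NaN for
    missing), ``roles`` the :class:`WellRole` per well, and ``compound_ids``
    the library compound in each LIBRARY well (``None`` elsewhere).
    """

    plate_id: str
    cell_line: CellLine
    values: np.ndarray
    roles: np.ndarray
    compound_ids: np.ndarray
    n_rows: int = 16
    n_cols: int = 24

    def __post_init__(self) -> None:
        self.cell_line = CellLine(self.cell_line)
        self.values = np.asarray(self.values, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.compound_ids = np.asarray(self.compound_ids, dtype=object)
        shape = (self.n_rows, self.n_cols)
        for name, arr in (
            ("values", self.values),
            ("roles", self.roles),
            ("compound_ids", self.compound_ids),
        ):
            if arr.shape != shape:
                raise ValueError(
                    f"plate {self.plate_id}: {name} has shape {arr.shape}, "
                    f"expected {shape}"
                )
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                role = WellRole(self.roles[r, c])
                self.roles[r, c] = role
                cid = self.compound_ids[r, c]
                if cid is not None:
                    # normalize NaN / empty tokens to "no compound"
                    if (isinstance(cid, float) and np.isnan(cid)) or str(cid) == "":
                        cid = None
                    else:
                        cid = str(cid)
                    self.compound_ids[r, c] = cid
                if role is WellRole.LIBRARY and not self.compound_ids[r, c]:
                    raise ValueError(
                        f"plate {self.plate_id}: LIBRARY well "
                        f"{format_well_label(r, c)} has no compound id"
                    )
                if role is not WellRole.LIBRARY and self.compound_ids[r, c]:
                    raise ValueError(
                        f"plate {self.plate_id}: {role.value} well "
                        f"{format_well_label(r, c)} carries a compound id"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def role_mask(self, *roles: WellRole) -> np.ndarray:
        # elementwise `is`; object-array == enum does not broadcast reliably
        wanted = set(roles)
        return np.array(
            [[cell in wanted for cell in row] for row in self.roles], dtype=bool
        )

    @property
    def library_mask(self) -> np.ndarray:
        return self.role_mask(WellRole.LIBRARY)


@dataclass
class CompoundRecord:
    """Library entry: identity, annotation class and optional structure."""

    compound_id: str
    name: str = ""
    pubchem_cid: int | None = None
    drug_class: str | None = None
    approval_status: str | None = None
    smiles: str | None = None


@dataclass
class ScreenResult:
    """Per-compound outcome of the paired WT/MUT screen analysis."""

    compound_id: str
    b_wt: float
    b_mut: float
    replicate_b_wt: list[float] = field(default_factory=list)
    replicate_b_mut: list[float] = field(default_factory=list)
    is_hit_wt: bool = False
    differential_call: DifferentialCall = DifferentialCall.NONE
    pct_change: float | None = None

    @property
    def delta(self) -> float:
        """WT minus MUT aggregated B-score (positive for WT-selective)."""
        return self.b_wt - self.b_mut


# ---------------------------------------------------------------------------
# plate tables


_ROLE_TOKENS = {r.value: r for r in WellRole}
_CELL_TOKENS = {c.value: c for c in CellLine}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _opt_float(token: str) -> float:
    token = token.strip()
    if token == "" or token.upper() in {"NA", "NAN"}:
        return float("nan")
    return float(token)


def read_plate_table(
    path: str | Path,
    *,
    n_rows: int = 16,
    n_cols: int = 24,
) -> list[PlateGrid]:
    """Read a long-format well table into one :class:`PlateGrid` per plate.

    The file must contain columns ``plate_id``, ``cell_line``, ``role``,
    ``compound_id``, a well address (either ``well`` labels like "B3" or
    0-based ``row``/``col`` integers) and either a precomputed ``value``
    (fluorescence ratio) or a ``baseline``/``peak`` pair from which the
    ratio is computed.  Wells absent from the file stay EMPTY with missing
    values; duplicate well assignments are a hard error.
    """
    df = _read_table(path)
    required = {"plate_id", "cell_line", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_well = "well" in df.columns
    if not has_well and not {"row", "col"} <= set(df.columns):
        raise ValueError(f"{path}: need a 'well' column or 'row'/'col' columns")
    has_value = "value" in df.columns
    if not has_value and not {"baseline", "peak"} <= set(df.columns):
        raise ValueError(f"{path}: need a 'value' column or 'baseline'/'peak'")

    plates: dict[tuple[str, CellLine], PlateGrid] = {}
    seen: set[tuple[str, int, int]] = set()
    for rec in df.itertuples(index=False):
        plate_id = str(rec.plate_id).strip()
        tok = str(rec.cell_line).strip().upper()
        if tok not in _CELL_TOKENS:
            raise ValueError(f"{path}: unknown cell_line token {tok!r}")
        cell_line = _CELL_TOKENS[tok]
        tok = str(rec.role).strip().upper()
        if tok not in _ROLE_TOKENS:
            raise ValueError(f"{path}: unknown role token {tok!r}")
        role = _ROLE_TOKENS[tok]
        if has_well:
            row, col = parse_well_label(str(rec.well))
        else:
            row, col = int(rec.row), int(rec.col)
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(
                f"{path}: well ({row}, {col}) outside {n_rows}x{n_cols} plate"
            )
        key = (plate_id, row, col)
        if key in seen:
            raise ValueError(
                f"{path}: duplicate well assignment "
                f"{plate_id}/{format_well_label(row, col)}"
            )
        seen.add(key)
        if has_value:
            value = _opt_float(str(rec.value))
        else:
            baseline = _opt_float(str(rec.baseline))
            peak = _opt_float(str(rec.peak))
            if np.isnan(baseline) or np.isnan(peak):
                value = float("nan")
            else:
                from .normalize import compute_ratio

                value = compute_ratio(RawWellSignal(baseline, peak))
        pkey = (plate_id, cell_line)
        if pkey not in plates:
            empty_roles = np.empty((n_rows, n_cols), dtype=object)
            empty_roles[...] = WellRole.EMPTY
            plates[pkey] = PlateGrid(
                plate_id=plate_id,
                cell_line=cell_line,
                values=np.full((n_rows, n_cols), np.nan),
                roles=empty_roles,
                compound_ids=np.full((n_rows, n_cols), None, dtype=object),
                n_rows=n_rows,
                n_cols=n_cols,
            )
        grid = plates[pkey]
        grid.values[row, col] = value
        grid.roles[row, col] = role
        cid = str(getattr(rec, "compound_id", "")).strip()
        grid.compound_ids[row, col] = cid or None
        if role is WellRole.LIBRARY and not cid:
            raise ValueError(
                f"{path}: LIBRARY well {plate_id}/"
                f"{format_well_label(row, col)} has no compound id"
            )
        if role is not WellRole.LIBRARY and cid:
            raise ValueError(
                f"{path}: {role.value} well {plate_id}/"
                f"{format_well_label(row, col)} carries a compound id"
            )
    return list(plates.values())


def write_plate_table(plates: Sequence[PlateGrid], path: str | Path) -> None:
    """Write plates to a long-format table (inverse of :func:`read_plate_table`)."""
    rows = []
    for plate in plates:
        for r in range(plate.n_rows):
            for c in range(plate.n_cols):
                v = plate.values[r, c]
                rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "cell_line": plate.cell_line.value,
                        "well": format_well_label(r, c),
                        "role": plate.roles[r, c].value,
                        "compound_id": plate.compound_ids[r, c] or "",
                        "value": "" if np.isnan(v) else repr(float(v)),
                    }
                )
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# compound tables


def read_compound_table(path: str | Path) -> dict[str, CompoundRecord]:
    """Read a compound annotation table keyed by compound_id.

    Recognised columns: ``compound_id``, ``name``, ``pubchem_cid``,
    ``drug_class``, ``approval_status``, ``smiles``; anything else is
    ignored.  An unparseable SMILES keeps the record but drops the
    structure with a warning.
    """
    df = _read_table(path)
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing 'compound_id' column")
    library: dict[str, CompoundRecord] = {}
    validate_smiles = "smiles" in df.columns
    if validate_smiles:
        from rdkit import Chem  # deferred: only needed when structures present
    for rec in df.itertuples(index=False):
        cid = str(rec.compound_id).strip()
        if not cid:
            raise ValueError(f"{path}: blank compound_id")
        if cid in library:
            raise ValueError(f"{path}: duplicate compound_id {cid!r}")
        smiles = None
        if validate_smiles:
            raw = str(rec.smiles).strip()
            if raw:
                if Chem.MolFromSmiles(raw) is None:
                    log.warning("compound %s: unparseable SMILES %r dropped", cid, raw)
                else:
                    smiles = raw
        pubchem = str(getattr(rec, "pubchem_cid", "")).strip()
        library[cid] = CompoundRecord(
            compound_id=cid,
            name=str(getattr(rec, "name", "")).strip(),
            pubchem_cid=int(pubchem) if pubchem else None,
            drug_class=str(getattr(rec, "drug_class", "")).strip() or None,
            approval_status=str(getattr(rec, "approval_status", "")).strip() or None,
            smiles=smiles,
        )
    return library


# ---------------------------------------------------------------------------
# screen results


_RESULT_COLUMNS = [
    "compound_id",
    "b_wt",
    "b_mut",
    "delta",
    "pct_change",
    "is_hit_wt",
    "differential_call",
    "replicate_b_wt",
    "replicate_b_mut",
]


def _join_reps(reps: Iterable[float]) -> str:
    return ";".join(repr(float(v)) for v in reps)


def _split_reps(token: str) -> list[float]:
    token = token.strip()
    return [float(t) for t in token.split(";")] if token else []


def write_results(results: Sequence[ScreenResult], path: str | Path) -> None:
    """Write screen results to TSV with a fixed column order.

    Floats are written at full precision so that a read/write round trip
    is lossless.
    """
    if not results:
        raise ValueError("write_results: empty result list")
    rows = []
    for res in results:
        rows.append(
            {
                "compound_id": res.compound_id,
                "b_wt": repr(float(res.b_wt)),
                "b_mut": repr(float(res.b_mut)),
                "delta": repr(float(res.delta)),
                "pct_change": "" if res.pct_change is None else repr(float(res.pct_change)),
                "is_hit_wt": str(res.is_hit_wt),
                "differential_call": res.differential_call.value,
                "replicate_b_wt": _join_reps(res.replicate_b_wt),
                "replicate_b_mut": _join_reps(res.replicate_b_mut),
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[ScreenResult]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    results = []
    for rec in df.itertuples(index=False):
        pct = str(rec.pct_change).strip()
        results.append(
            ScreenResult(
                compound_id=str(rec.compound_id),
                b_wt=float(rec.b_wt),
                b_mut=float(rec.b_mut),
                replicate_b_wt=_split_reps(str(rec.replicate_b_wt)),
                replicate_b_mut=_split_reps(str(rec.replicate_b_mut)),
                is_hit_wt=str(rec.is_hit_wt) == "True",
                differential_call=DifferentialCall(str(rec.differential_call)),
                pct_change=float(pct) if pct else None,
            )
        )
    return results


def sort_for_report(
    results: Sequence[ScreenResult],
    library: Mapping[str, CompoundRecord],
) -> list[ScreenResult]:
    """Order results by drug class, descending WT B-score within class.

    Classes keep their order of first appearance in ``library`` (the
    convention of the published hit table).
    """
    class_order: dict[str, int] = {}
    for rec in library.values():
        cls = rec.drug_class or ""
        class_order.setdefault(cls, len(class_order))

    def key(res: ScreenResult) -> tuple[int, float]:
        rec = library.get(res.compound_id)
        cls = (rec.drug_class if rec else None) or ""
        return (class_order.get(cls, len(class_order)), -res.b_wt)

    return sorted(results, key=key)


# ---------------------------------------------------------------------------
# packaged reference data


def _reference_path():
    return resources.files("mrgscreen.data") / "mrgprx2_hit_table.tsv"


def load_reference_hits() -> pd.DataFrame:
    """Reference table of the 34 published MRGPRX2-selective hit compounds.

    Columns: compound_id, name, pubchem_cid, indication (as printed),
    drug_class (one of five major indication classes), approval_status,
    b_score_wt, b_score_mut, pct_change.
    """
    with resources.as_file(_reference_path()) as p:
        return pd.read_csv(p, sep="\t")


def reference_hit_library() -> dict[str, CompoundRecord]:
    """The reference hit table as a compound library keyed by id."""
    with resources.as_file(_reference_path()) as p:
        return read_compound_table(p)
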