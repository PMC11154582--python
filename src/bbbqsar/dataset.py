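"""Compound data model and CSV I/O.

The central dataset is a table of heterocyclic drug candidates, one row per
compound, carrying six in-silico molecular descriptors (MW, NRB, HBD, HBA,
TPSA, polarizability), the in-silico blood-brain distribution ratio log BB,
and the chromatographically measured lipophilicity index log k_w,IAM.  The
126-compound study table ships with the package as
``bbbqsar/data/table2_compounds.csv`` and is loaded with :func:`load_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CompoundRecord",
    "SchemaError",
    "IntegrityError",
    "REQUIRED_COLUMNS",
    "load_fixture",
    "load_fixture_frame",
    "read_compound_table",
    "write_compound_table",
    "records_to_frame",
    "frame_to_records",
    "descriptor_panel",
    "DESCRIPTOR_NAMES",
]

#: CSV schema shared by every compound table the package reads or writes.
REQUIRED_COLUMNS = (
    "compound_id",
    "class",
    "mw",
    "nrb",
    "hbd",
    "hba",
    "tpsa",
    "alpha",
    "log_bb",
    "log_kw_iam",
)

#: Descriptor block used by the chemometrics stage; ``hb_total`` = HBD + HBA.
DESCRIPTOR_NAMES = ("mw", "alpha", "tpsa", "hb_total", "nrb")

_COUNT_FIELDS = ("nrb", "hbd", "hba")
_FLOAT_FIELDS = ("mw", "tpsa", "alpha", "log_bb", "log_kw_iam")


class SchemaError(ValueError):
    """A compound table violates the documented CSV schema."""


class IntegrityError(ValueError):
    """The packaged fixture failed an internal consistency check."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identity, descriptors, response and lipophilicity index.

    Units: ``mw`` g/mol, ``tpsa`` Å², ``alpha`` Å³; ``log_bb`` and
    ``log_kw_iam`` are base-10 logarithms (dimensionless); ``nrb``, ``hbd``,
    ``hba`` are counts.
    """

    compound_id: int
    class_label: str
    mw: float
    nrb: int
    hbd: int
    hba: int
    tpsa: float
    alpha: float
    log_bb: float
    log_kw_iam: float
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.compound_id <= 0:
            raise SchemaError(f"compound_id must be positive, got {self.compound_id}")
        if self.mw <= 0:
            raise SchemaError(f"compound {self.compound_id}: mw must be > 0")
        if self.alpha <= 0:
            raise SchemaError(f"compound {self.compound_id}: alpha must be > 0")
        if self.tpsa < 0:
            raise SchemaError(f"compound {self.compound_id}: tpsa must be >= 0")
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise SchemaError(
                    f"compound {self.compound_id}: {name} must be a non-negative "
                    f"integer, got {value!r}"
                )
        for name in _FLOAT_FIELDS:
            if not math.isfinite(getattr(self, name)):
                raise SchemaError(f"compound {self.compound_id}: {name} is not finite")

    @property
    def hb_total(self) -> int:
        """Total hydrogen-bonding count HBD + HBA."""
        return self.hbd + self.hba


def _fixture_path() -> Path:
    return Path(resources.files("bbbqsar.data") / "table2_compounds.csv")


def _parse_cell(raw: object, column: str, row: int):
    text = str(raw).strip().replace("−", "-")  # normalise Unicode minus
    try:
        if column in ("compound_id", *_COUNT_FIELDS):
            value = int(text)
        elif column in _FLOAT_FIELDS:
            value = float(text)
        else:
            return text
    except ValueError:
        raise SchemaError(
            f"row {row}, column {column!r}: non-numeric value {raw!r}"
        ) from None
    return value


def read_compound_table(path, *, require_log_bb: bool = True) -> list[CompoundRecord]:
    """Read a compound CSV and return validated :class:`CompoundRecord` rows.

    Parameters
    ----------
    path : str or Path
        CSV with lower-snake-case headers (see :data:`REQUIRED_COLUMNS`); an
        optional ``provenance`` column is carried through as free text.
    require_log_bb : bool
        Query tables for prediction may omit the ``log_bb`` column; set False
        to accept them (missing values are filled with NaN-free 0.0 never —
        the column is then simply absent and records get ``log_bb`` = nan).
    """
    frame = pd.read_csv(path, dtype=str, comment="#")
    required = [c for c in REQUIRED_COLUMNS if require_log_bb or c != "log_bb"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "provenance" in frame.columns:  # free-text footnote column, may be blank
        frame["provenance"] = frame["provenance"].fillna("")
    if frame.isna().any().any():
        cell = frame.isna().stack()
        row, col = cell[cell].index[0]
        raise SchemaError(f"missing value at row {row}, column {col!r}")

    records: list[CompoundRecord] = []
    seen: set[int] = set()
    has_prov = "provenance" in frame.columns
    has_logbb = "log_bb" in frame.columns
    for i in range(len(frame)):
        row = frame.iloc[i]
        data = {c: _parse_cell(row[c], c, i) for c in required}
        cid = data["compound_id"]
        if cid in seen:
            raise SchemaError(f"row {i}: duplicate compound_id {cid}")
        seen.add(cid)
        records.append(
            CompoundRecord(
                compound_id=cid,
                class_label=data["class"],
                mw=data["mw"],
                nrb=data["nrb"],
                hbd=data["hbd"],
                hba=data["hba"],
                tpsa=data["tpsa"],
                alpha=data["alpha"],
                log_bb=data["log_bb"] if has_logbb else float("nan"),
                log_kw_iam=data["log_kw_iam"],
                provenance=str(row["provenance"]) if has_prov else "",
            )
        )
    return records


def write_compound_table(records: Sequence[CompoundRecord], path) -> None:
    """Write records as a CSV that :func:`read_compound_table` inverts exactly.

    Counts are written as integers; floats use :func:`repr` precision so the
    round trip is value-exact.
    """
    if not records:
        raise ValueError("cannot write an empty compound table")
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "class": r.class_label,
                "mw": r.mw,
                "nrb": r.nrb,
                "hbd": r.hbd,
                "hba": r.hba,
                "tpsa": r.tpsa,
                "alpha": r.alpha,
                "log_bb": r.log_bb,
                "log_kw_iam": r.log_kw_iam,
                "provenance": r.provenance,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[CompoundRecord]:
    """Inverse of :func:`records_to_frame` (validates every row)."""
    records = []
    for _, row in frame.iterrows():
        records.append(
            CompoundRecord(
                compound_id=int(row["compound_id"]),
                class_label=str(row["class"]),
                mw=float(row["mw"]),
                nrb=int(row["nrb"]),
                hbd=int(row["hbd"]),
                hba=int(row["hba"]),
                tpsa=float(row["tpsa"]),
                alpha=float(row["alpha"]),
                log_bb=float(row["log_bb"]),
                log_kw_iam=float(row["log_kw_iam"]),
                provenance=str(row.get("provenance", "") or ""),
            )
        )
    return records


# Printed summary statistics used to verify fixture integrity on load.
_FIXTURE_CHECKS = {
    "n": 126,
    "mw": (186.21, 430.11),
    "tpsa": (33.95, 121.85),
    "hbd": (0, 3),
    "hba": (4, 10),
    "log_bb": (-1.315, 0.772),
    "log_kw_iam": (-0.27, 3.40),
}


def load_fixture() -> list[CompoundRecord]:
    """Load the packaged 126-compound study table.

    Raises
    ------
    IntegrityError
        If the packaged file has been corrupted (wrong row count, duplicate
        ids, or descriptor ranges that disagree with the published summaries).
    """
    try:
        records = read_compound_table(_fixture_path())
    except SchemaError as exc:
        raise IntegrityError(f"packaged fixture is corrupted: {exc}") from exc
    if len(records) != _FIXTURE_CHECKS["n"]:
        raise IntegrityError(
            f"fixture must have 126 records, found {len(records)}"
        )
    ids = sorted(r.compound_id for r in records)
    if ids != list(range(1, 127)):
        raise IntegrityError("fixture compound_id values must be exactly 1..126")
    for col in ("mw", "tpsa", "hbd", "hba", "log_bb", "log_kw_iam"):
        lo, hi = _FIXTURE_CHECKS[col]
        values = [getattr(r, col) for r in records]
        if not math.isclose(min(values), lo) or not math.isclose(max(values), hi):
            raise IntegrityError(
                f"fixture range check failed for {col}: "
                f"[{min(values)}, {max(values)}] != [{lo}, {hi}]"
            )
    return records


def load_fixture_frame() -> pd.DataFrame:
    """The packaged study table as a DataFrame (with ``hb_total`` appended)."""
    frame = records_to_frame(load_fixture())
    frame["hb_total"] = frame["hbd"] + frame["hba"]
    return frame


def descriptor_panel(frame: pd.DataFrame, names: Sequence[str] = DESCRIPTOR_NAMES) -> pd.DataFrame:
    """Extract the numeric descriptor block used for chemometrics.

    Adds ``hb_total`` (= hbd + hba) if absent, checks for missing values, and
    returns the columns in ``names`` order.
    """
    panel = frame.copy()
    if "hb_total" not in panel.columns and {"hbd", "hba"} <= set(panel.columns):
        panel["hb_total"] = panel["hbd"] + panel["hba"]
    missing = [n for n in names if n not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing descriptor column(s): {missing}")
    panel = panel[list(names)].astype(float)
    if panel.isna().any().any():
        raise SchemaError("descriptor panel contains missing values")
    return panel
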