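"""Data model and I/O for per-square cremated-bone weight records.

A cremation deposit is recorded as a long-format table of weighed lots of
burnt bone: each row carries the excavation square (a letter row and a
numeric column on a grid of 25 x 25 cm cells), the stratigraphic unit
("US") with an optional cut label, a fragment size class (< 20 mm,
> 20 mm, or tooth), a gross anatomical region for the larger fragments
(cranial, post-cranial, undetermined), and the weight in grams.

The canonical on-disk format is a UTF-8 CSV with header
``us,cut,row,column,size_class,region,weight_g``; an XLSX reader with the
same column contract is provided for spreadsheet supplements.
"""

from __future__ import annotations

import operator
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

#: Default row alphabet: 18 letter rows A..R on the short side of the trench.
#: The exact letters in use are configurable because published grid codings
#: sometimes skip visually ambiguous letters (I, J); here all 18 are kept.
DEFAULT_ROW_ALPHABET = "ABCDEFGHIJKLMNOPQR"

#: Default number of numeric columns on the long side.
DEFAULT_N_COLUMNS = 28

#: Side length of one grid cell, metres.
DEFAULT_CELL_SIZE = 0.25

#: Excavated surface reported for the site, m^2 (used only for a geometry
#: cross-check warning; the declared grid bounding box is larger).
DOCUMENTED_AREA_M2 = 26.0

SIZE_CLASSES = ("lt20", "ge20", "tooth")
REGIONS = ("cranial", "postcranial", "tooth", "undetermined")
CUT_LABELS = ("roof", "I", "II", "III", "IV")

_CUT_RANK = {None: 0, "roof": 1, "I": 2, "II": 3, "III": 4, "IV": 5}


class DepositValidationError(ValueError):
    """A record or input table violates the deposit data contract."""


class GridGeometryWarning(UserWarning):
    """Declared grid bounding box disagrees with the documented surface."""


@dataclass(frozen=True, order=True)
class SquareID:
    """One 25 x 25 cm excavation cell, e.g. row ``'G'``, column ``5`` -> G5."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if not (isinstance(self.row, str) and len(self.row) == 1 and self.row.isalpha()):
            raise DepositValidationError(f"square row must be a single letter, got {self.row!r}")
        object.__setattr__(self, "row", self.row.upper())
        try:
            column = int(operator.index(self.column))
        except TypeError:
            raise DepositValidationError(
                f"square column must be a positive integer, got {self.column!r}"
            ) from None
        if column < 1:
            raise DepositValidationError(f"square column must be a positive integer, got {column}")
        object.__setattr__(self, "column", column)

    @classmethod
    def from_label(cls, label: str) -> "SquareID":
        """Parse a compact label such as ``'G5'`` or ``'A26'``."""
        label = label.strip()
        if len(label) < 2 or not label[0].isalpha() or not label[1:].isdigit():
            raise DepositValidationError(f"cannot parse square label {label!r}")
        return cls(label[0].upper(), int(label[1:]))

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"

    def indices(self, row_alphabet: str = DEFAULT_ROW_ALPHABET) -> tuple[int, int]:
        """0-based (row_index, column_index) within the declared grid."""
        try:
            r = row_alphabet.index(self.row)
        except ValueError:
            raise DepositValidationError(
                f"row letter {self.row!r} is not in the grid alphabet {row_alphabet!r}"
            ) from None
        return r, self.column - 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class StratumID:
    """A stratigraphic unit, optionally subdivided: e.g. US 11, cut II.

    ``cut`` may be a roman numeral I..IV or the literal surface label
    ``'roof'``; blank/unknown cuts are stored as ``None``.
    """

    us: int
    cut: Optional[str] = None

    def __post_init__(self) -> None:
        if not (10 <= self.us <= 20):
            raise DepositValidationError(f"stratigraphic unit must be in 10..20, got {self.us}")
        if self.cut is not None and self.cut not in CUT_LABELS:
            raise DepositValidationError(
                f"cut must be one of {CUT_LABELS} or absent, got {self.cut!r}"
            )

    def __lt__(self, other: "StratumID") -> bool:  # deterministic sort incl. None cuts
        return (self.us, _CUT_RANK[self.cut]) < (other.us, _CUT_RANK[other.cut])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"US{self.us}" + (f"/{self.cut}" if self.cut else "")


@dataclass(frozen=True)
class FragmentRecord:
    """One weighed lot of bone fragments from a single square and stratum."""

    square: SquareID
    stratum: StratumID
    size_class: str
    region: str
    weight: float

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise DepositValidationError(
                f"size_class must be one of {SIZE_CLASSES}, got {self.size_class!r}"
            )
        if self.region not in REGIONS:
            raise DepositValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        # Teeth are weighed apart from the </> 20 mm split, so the tooth
        # region and the tooth size class imply each other.
        if (self.size_class == "tooth") != (self.region == "tooth"):
            raise DepositValidationError(
                f"region='tooth' iff size_class='tooth'; got ({self.size_class!r}, {self.region!r})"
            )
        if not (self.weight >= 0):
            raise DepositValidationError(f"weight must be >= 0 g, got {self.weight!r}")

    def sort_key(self):
        return (
            self.stratum.us,
            _CUT_RANK[self.stratum.cut],
            self.square.row,
            self.square.column,
            SIZE_CLASSES.index(self.size_class),
            REGIONS.index(self.region),
        )


@dataclass
class Deposit:
    """A collection of fragment records over a rectangular grid of cells."""

    records: list[FragmentRecord] = field(default_factory=list)
    row_alphabet: str = DEFAULT_ROW_ALPHABET
    n_columns: int = DEFAULT_N_COLUMNS
    cell_size: float = DEFAULT_CELL_SIZE

    def __post_init__(self) -> None:
        for rec in self.records:
            rec.square.indices(self.row_alphabet)  # raises if outside alphabet
            if rec.square.column > self.n_columns:
                raise DepositValidationError(
                    f"square {rec.square.label} outside the declared grid "
                    f"({len(self.row_alphabet)} rows x {self.n_columns} columns)"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.row_alphabet)

    @property
    def grid_area_m2(self) -> float:
        """Area of the declared grid bounding box (not of the excavated surface)."""
        return self.n_rows * self.n_columns * self.cell_size**2

    # -- aggregation ------------------------------------------------------

    def total_weight(
        self,
        *,
        us: Optional[int] = None,
        cut: Optional[str] = None,
        size_class: Optional[str] = None,
        region: Optional[str] = None,
        predicate: Optional[Callable[[FragmentRecord], bool]] = None,
    ) -> float:
        """Summed weight in grams of records matching all given filters.

        A ``us`` filter alone matches every cut of that unit (including the
        'roof' surface layer); pass ``cut`` to narrow further.  An empty
        selection sums to 0.
        """
        total = 0.0
        for rec in self.records:
            if us is not None and rec.stratum.us != us:
                continue
            if cut is not None and rec.stratum.cut != cut:
                continue
            if size_class is not None and rec.size_class != size_class:
                continue
            if region is not None and rec.region != region:
                continue
            if predicate is not None and not predicate(rec):
                continue
            total += rec.weight
        return total

    def aggregate(self, by: str) -> pd.Series:
        """Group weights by ``'square'``, ``'stratum'``, ``'size_class'`` or ``'region'``.

        Returns a Series of grams indexed by the group label; group sums
        always add up to the deposit total.
        """
        keyfuncs = {
            "square": lambda r: r.square.label,
            "stratum": lambda r: str(r.stratum),
            "size_class": lambda r: r.size_class,
            "region": lambda r: r.region,
            "us": lambda r: r.stratum.us,
        }
        if by not in keyfuncs:
            raise ValueError(f"unknown grouping {by!r}; expected one of {sorted(keyfuncs)}")
        keyf = keyfuncs[by]
        sums: dict = {}
        for rec in self.records:
            k = keyf(rec)
            sums[k] = sums.get(k, 0.0) + rec.weight
        return pd.Series(sums, dtype=float).sort_index()

    # -- tabular form -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, sorted deterministically (us, cut, row, column,
        size_class, region)."""
        recs = sorted(self.records, key=FragmentRecord.sort_key)
        return pd.DataFrame(
            {
                "us": [r.stratum.us for r in recs],
                "cut": [r.stratum.cut if r.stratum.cut is not None else "" for r in recs],
                "row": [r.square.row for r in recs],
                "column": [r.square.column for r in recs],
                "size_class": [r.size_class for r in recs],
                "region": [r.region for r in recs],
                "weight_g": [r.weight for r in recs],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Deposit):
            return NotImplemented
        return (
            sorted(self.records, key=FragmentRecord.sort_key)
            == sorted(other.records, key=FragmentRecord.sort_key)
            and self.row_alphabet == other.row_alphabet
            and self.n_columns == other.n_columns
            and self.cell_size == other.cell_size
        )


_COLUMNS = ["us", "cut", "row", "column", "size_class", "region", "weight_g"]


def _records_from_frame(
    df: pd.DataFrame, *, source: str
) -> list[FragmentRecord]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DepositValidationError(f"{source}: missing required columns {missing}")
    records: list[FragmentRecord] = []
    errors: list[str] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            cut = getattr(row, "cut")
            if cut is None or (not isinstance(cut, str) and pd.isna(cut)) or str(cut).strip() == "":
                cut = None  # blank/unknown cut labels load as absent
            else:
                cut = str(cut).strip()
            rec = FragmentRecord(
                square=SquareID(str(row.row).strip(), int(row.column)),
                stratum=StratumID(int(row.us), cut),
                size_class=str(row.size_class).strip(),
                region=str(row.region).strip(),
                weight=float(row.weight_g),
            )
        except (DepositValidationError, ValueError, TypeError) as exc:
            errors.append(f"{source}:{line}: {exc}")
            continue
        key = (rec.square, rec.stratum, rec.size_class, rec.region)
        if key in seen:
            errors.append(
                f"{source}:{line}: duplicate key (square {rec.square.label}, "
                f"{rec.stratum}, {rec.size_class}, {rec.region}); first seen at line {seen[key]}"
            )
            continue
        seen[key] = line
        records.append(rec)
    if errors:
        raise DepositValidationError(
            f"{len(errors)} malformed row(s):\n" + "\n".join(errors)
        )
    return records


def read_deposit_table(
    source,
    *,
    fmt: Optional[str] = None,
    row_alphabet: str = DEFAULT_ROW_ALPHABET,
    n_columns: int = DEFAULT_N_COLUMNS,
    cell_size: float = DEFAULT_CELL_SIZE,
    warn_geometry: bool = True,
) -> Deposit:
    """Read a long-format weight table (CSV or XLSX) into a validated Deposit.

    Malformed rows are collected and reported together with their line
    numbers.  ``fmt`` is inferred from the file suffix when not given.
    """
    if fmt is None:
        suffix = Path(str(source)).suffix.lower() if isinstance(source, (str, Path)) else ""
        fmt = "xlsx" if suffix in (".xlsx", ".xlsm") else "csv"
    name = str(source) if isinstance(source, (str, Path)) else "<buffer>"
    if fmt == "xlsx":
        df = pd.read_excel(source)
    else:
        df = pd.read_csv(
            source, dtype={"cut": "string", "row": "string"},
            float_precision="round_trip",
        )
    records = _records_from_frame(df, source=name)
    dep = Deposit(records, row_alphabet=row_alphabet, n_columns=n_columns, cell_size=cell_size)
    if warn_geometry and abs(dep.grid_area_m2 - DOCUMENTED_AREA_M2) > 1e-9:
        warnings.warn(
            f"declared grid bounding box is {dep.grid_area_m2:.2f} m^2 "
            f"({dep.n_rows} x {dep.n_columns} cells at {dep.cell_size} m); the documented "
            f"excavated surface is {DOCUMENTED_AREA_M2:.0f} m^2 — the published grid coding "
            "does not fully determine the cell layout",
            GridGeometryWarning,
            stacklevel=2,
        )
    return dep


def write_deposit_table(deposit: Deposit, target, *, fmt: Optional[str] = None) -> None:
    """Write a Deposit to CSV (default) or XLSX in a bit-stable row order."""
    if fmt is None:
        suffix = Path(str(target)).suffix.lower() if isinstance(target, (str, Path)) else ""
        fmt = "xlsx" if suffix in (".xlsx", ".xlsm") else "csv"
    df = deposit.to_frame()
    if fmt == "xlsx":
        df.to_excel(target, index=False)
    else:
        df.to_csv(target, index=False)
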