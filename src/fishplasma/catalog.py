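"""Domain types and loaders for pharmaceutical (API) descriptor tables.

An :class:`APIRecord` carries the physicochemical and pharmacokinetic
descriptors the fish plasma model needs: ionization speciation at plasma
pH, pH-dependent distribution coefficient LogD_ow, the human therapeutic
plasma concentration C_max, and (where available) chronic fish effect
concentrations (NOEC/LOEC).  A :class:`SpeciesContext` records the plasma
pH, assay temperature and assay plasma fraction for each study species.

The package ships a reference screening table of 44 APIs with rainbow
trout worst-case Rf_u values and both original and refined therapeutic
water concentrations, stored at printed precision, plus the four species
contexts.  :func:`load_fixture` returns both as parsed objects.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "APIRecord",
    "SpeciesContext",
    "ScreeningFixture",
    "TableLoadError",
    "SPECIATION_CODES",
    "SPECIATION_MAPPINGS",
    "charge_class_of",
    "read_api_table",
    "write_api_table",
    "load_species_contexts",
    "load_fixture",
]

#: Valid one-letter speciation codes: predominant charge at plasma pH.
#: A anion, a anionic-unionized, N neutral, c cationic-unionized,
#: C cation, Z zwitterion.
SPECIATION_CODES = frozenset("AaNcCZ")

#: Named collapses of the 6 speciation codes onto 4-level factors.
#: ``charge_class`` groups by parent acid/base chemistry ({A,a} acidic,
#: {C,c} basic); ``ionization_group`` groups by actual charge state at
#: plasma pH ({a,N,c} all unionized), the grouping used for proportion
#: summaries of flagged APIs.
SPECIATION_MAPPINGS: dict[str, dict[str, str]] = {
    "charge_class": {
        "A": "anionic", "a": "anionic",
        "C": "cationic", "c": "cationic",
        "N": "neutral", "Z": "zwitterionic",
    },
    "ionization_group": {
        "A": "anionic",
        "C": "cationic",
        "a": "unionized", "N": "unionized", "c": "unionized",
        "Z": "zwitterionic",
    },
}

_FIXTURE_TABLE = "twc_rainbow_trout_44api.csv"
_FIXTURE_SPECIES = "species_contexts.csv"

# en dash, minus sign, hyphen-minus variants seen in typeset tables
_MINUS_RE = re.compile("[‒–—−]")


class TableLoadError(ValueError):
    """Structured load/validation error naming the offending row and column."""

    def __init__(self, message: str, row: int | None = None,
                 column: str | None = None):
        self.row = row
        self.column = column
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column {column!r}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


def charge_class_of(speciation_code: str, mapping: str = "charge_class") -> str:
    """Map a speciation code onto a 4-level charge factor.

    ``mapping`` selects one of :data:`SPECIATION_MAPPINGS`.
    """
    try:
        table = SPECIATION_MAPPINGS[mapping]
    except KeyError:
        raise KeyError(
            f"unknown speciation mapping {mapping!r}; "
            f"choose from {sorted(SPECIATION_MAPPINGS)}"
        ) from None
    if speciation_code not in SPECIATION_CODES:
        raise ValueError(f"unknown speciation code {speciation_code!r}")
    return table[speciation_code]


@dataclass
class APIRecord:
    """One pharmaceutical's descriptors and effect concentrations.

    Concentrations are mg/L.  ``logd_by_ph`` maps pH to LogD_ow at that
    pH; missing optional values are ``None``, never zero.
    """

    name: str
    speciation_code: str
    logd_by_ph: dict[float, float]
    mw: float | None = None
    pka: float | None = None
    cmax: float | None = None
    noec: float | None = None
    loec: float | None = None

    def __post_init__(self):
        if self.speciation_code not in SPECIATION_CODES:
            raise ValueError(
                f"{self.name}: unknown speciation code {self.speciation_code!r}"
            )
        if not self.logd_by_ph:
            raise ValueError(f"{self.name}: logd_by_ph must be non-empty")
        for attr in ("cmax", "noec", "loec"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValueError(
                    f"{self.name}: {attr} must be strictly positive, got {v}"
                )

    @property
    def charge_class(self) -> str:
        return charge_class_of(self.speciation_code)

    def charge_group(self, mapping: str = "charge_class") -> str:
        return charge_class_of(self.speciation_code, mapping)

    def logd(self, ph: float) -> float:
        """LogD_ow at ``ph``; exact key lookup, no interpolation."""
        for key, value in self.logd_by_ph.items():
            if math.isclose(key, ph, abs_tol=1e-9):
                return value
        raise KeyError(f"{self.name}: no LogD tabulated at pH {ph}")


@dataclass(frozen=True)
class SpeciesContext:
    """Plasma pH and dialysis-assay conditions for one study species."""

    species_id: str
    plasma_ph: float
    assay_temperature: float
    assay_plasma_fraction: float = 1.0

    def __post_init__(self):
        if not 6.5 <= self.plasma_ph <= 8.5:
            raise ValueError(
                f"{self.species_id}: plasma_ph {self.plasma_ph} outside [6.5, 8.5]"
            )
        if not 0 < self.assay_plasma_fraction <= 1:
            raise ValueError(
                f"{self.species_id}: assay_plasma_fraction must be in (0, 1]"
            )

    @property
    def dilution_factor(self) -> float:
        """Plasma dilution factor implied by the assay plasma fraction."""
        return 1.0 / self.assay_plasma_fraction


@dataclass
class ScreeningFixture:
    """Packaged 44-API screening table plus species contexts.

    ``table`` holds the parsed numeric columns (printed precision);
    ``raw`` the same cells as strings, preserving the number of decimals
    each value was printed with.
    """

    apis: list[APIRecord]
    species: dict[str, SpeciesContext]
    table: pd.DataFrame
    raw: pd.DataFrame

    def api(self, name: str) -> APIRecord:
        for rec in self.apis:
            if rec.name == name:
                return rec
        raise KeyError(name)


def _normalize_minus(text: str) -> str:
    return _MINUS_RE.sub("-", text)


def _parse_float(cell: str, row: int, column: str) -> float | None:
    cell = _normalize_minus(cell.strip())
    if cell in ("", "-", "NA", "nan"):
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableLoadError(
            f"cannot parse {cell!r} as a number", row=row, column=column
        ) from None


_LOGD_COL_RE = re.compile(r"^logd_ph(\d+(?:\.\d+)?)$")


def read_api_table(path: str | Path) -> list[APIRecord]:
    """Read an API descriptor CSV into :class:`APIRecord` objects.

    Expected header: ``name,speciation,mw,pka,logd_ph7.4,...,cmax_mg_per_L,
    noec_mg_per_L,loec_mg_per_L``; any ``logd_phX.Y`` column is accepted by
    pattern and only ``name``, ``speciation`` and at least one LogD column
    are mandatory.  Unicode minus/en-dash signs are normalized; rows with
    missing C_max are retained (``cmax=None``).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableLoadError(f"{path}: empty file")
        header = [h.strip() for h in reader.fieldnames]
        logd_cols = {h: float(m.group(1))
                     for h in header if (m := _LOGD_COL_RE.match(h))}
        if "name" not in header or "speciation" not in header:
            raise TableLoadError(
                f"{path}: header must contain 'name' and 'speciation'"
            )
        if not logd_cols:
            raise TableLoadError(f"{path}: no logd_phX.Y column found")

        records: list[APIRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            name = (row.get("name") or "").strip()
            if not name:
                raise TableLoadError("missing API name", row=i, column="name")
            if name in seen:
                raise TableLoadError(f"duplicate API name {name!r}", row=i,
                                     column="name")
            seen.add(name)
            code = (row.get("speciation") or "").strip()
            if code not in SPECIATION_CODES:
                raise TableLoadError(
                    f"unknown speciation code {code!r}", row=i,
                    column="speciation",
                )
            logd_by_ph = {}
            for col, ph in logd_cols.items():
                v = _parse_float(row.get(col) or "", i, col)
                if v is not None:
                    logd_by_ph[ph] = v
            if not logd_by_ph:
                raise TableLoadError("no LogD value present", row=i,
                                     column=next(iter(logd_cols)))
            kwargs = {}
            for attr, col in (("mw", "mw"), ("pka", "pka"),
                              ("cmax", "cmax_mg_per_L"),
                              ("noec", "noec_mg_per_L"),
                              ("loec", "loec_mg_per_L")):
                if col in header:
                    kwargs[attr] = _parse_float(row.get(col) or "", i, col)
            try:
                records.append(APIRecord(name, code, logd_by_ph, **kwargs))
            except ValueError as exc:
                raise TableLoadError(str(exc), row=i) from exc
    return records


def write_api_table(records: Iterable[APIRecord], path: str | Path) -> None:
    """Write records in the CSV dialect read by :func:`read_api_table`."""
    records = list(records)
    phs = sorted({ph for r in records for ph in r.logd_by_ph})
    logd_cols = [f"logd_ph{ph:g}" for ph in phs]
    header = (["name", "speciation", "mw", "pka"] + logd_cols
              + ["cmax_mg_per_L", "noec_mg_per_L", "loec_mg_per_L"])

    def fmt(v: float | None) -> str:
        return "" if v is None else repr(v)

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [r.name, r.speciation_code, fmt(r.mw), fmt(r.pka)]
            row += [fmt(r.logd_by_ph.get(ph)) for ph in phs]
            row += [fmt(r.cmax), fmt(r.noec), fmt(r.loec)]
            writer.writerow(row)


def _fixture_path(name: str) -> Path:
    return Path(resources.files("fishplasma.data") / name)


def load_species_contexts(path: str | Path | None = None
                          ) -> dict[str, SpeciesContext]:
    """Load species contexts; defaults to the packaged four-species table."""
    path = _fixture_path(_FIXTURE_SPECIES) if path is None else Path(path)
    out: dict[str, SpeciesContext] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                ctx = SpeciesContext(
                    species_id=row["species_id"].strip(),
                    plasma_ph=float(row["plasma_ph"]),
                    assay_temperature=float(row["assay_temperature_c"]),
                    assay_plasma_fraction=float(row["assay_plasma_fraction"]),
                )
            except (KeyError, ValueError) as exc:
                raise TableLoadError(str(exc), row=i) from exc
            out[ctx.species_id] = ctx
    return out


#: Columns of the packaged screening table that hold printed numbers.
FIXTURE_NUMERIC_COLUMNS = [
    "logd_ph7.4", "pbw_ph7.4", "logd_ph7.9", "pbw_ph7.9",
    "cmax_mg_per_L", "rfu_trout_max",
    "twc_original_mg_per_L", "twc_refined_mg_per_L", "twc_ratio",
    "noec_mg_per_L", "loec_mg_per_L",
    "twc_original_over_loec", "twc_refined_over_loec",
]

_EXPECTED_FIXTURE_ROWS = 44


def load_fixture() -> ScreeningFixture:
    """Load the packaged 44-API screening fixture.

    Returns APIRecords (LogD at pH 7.4 and 7.9, C_max/NOEC/LOEC where
    printed), the parsed screening table including the rainbow-trout
    worst-case Rf_u column, the raw printed strings, and the species
    contexts.  An Rf_u printed as 0 is below quantification: it is kept
    as 0.0 in ``table`` but yields no refined water concentration
    downstream.
    """
    path = _fixture_path(_FIXTURE_TABLE)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ["speciation", "name", *FIXTURE_NUMERIC_COLUMNS]
               if c not in raw.columns]
    if missing:
        raise TableLoadError(
            f"fixture {path.name} is missing columns {missing}",
            column=missing[0],
        )
    if len(raw) != _EXPECTED_FIXTURE_ROWS:
        raise TableLoadError(
            f"fixture {path.name} has {len(raw)} rows, "
            f"expected {_EXPECTED_FIXTURE_ROWS}",
            row=len(raw) + 1,
        )

    table = raw.copy()
    apis: list[APIRecord] = []
    for idx, row in raw.iterrows():
        rownum = int(idx) + 2
        parsed = {col: _parse_float(row[col], rownum, col)
                  for col in FIXTURE_NUMERIC_COLUMNS}
        for col in FIXTURE_NUMERIC_COLUMNS:
            table.loc[idx, col] = parsed[col]
        if parsed["logd_ph7.4"] is None or parsed["logd_ph7.9"] is None:
            raise TableLoadError("missing LogD value", row=rownum,
                                 column="logd_ph7.4")
        try:
            apis.append(APIRecord(
                name=row["name"],
                speciation_code=row["speciation"],
                logd_by_ph={7.4: parsed["logd_ph7.4"],
                            7.9: parsed["logd_ph7.9"]},
                cmax=parsed["cmax_mg_per_L"],
                noec=parsed["noec_mg_per_L"],
                loec=parsed["loec_mg_per_L"],
            ))
        except ValueError as exc:
            raise TableLoadError(str(exc), row=rownum) from exc
    for col in FIXTURE_NUMERIC_COLUMNS:
        table[col] = pd.to_numeric(table[col])
    return ScreeningFixture(
        apis=apis,
        species=load_species_contexts(),
        table=table,
        raw=raw,
    )


def printed_tolerance(raw_value: str, rel: float = 0.05) -> float:
    """Comparison tolerance for a value printed with finite precision.

    Half an ulp at the printed decimal place, or ``rel`` of the magnitude,
    whichever is larger: a table cell printed as ``0.01`` can only be
    reproduced to +-0.005 however exact the arithmetic.
    """
    text = _normalize_minus(raw_value.strip().lower())
    value = float(text)
    mantissa, _, exponent = text.partition("e")
    decimals = len(mantissa.partition(".")[2])
    exp = int(exponent) if exponent else 0
    half_ulp = 0.5 * 10.0 ** (exp - decimals)
    return max(rel * abs(value), half_ulp)
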