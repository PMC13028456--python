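"""File formats: conversion-table CSVs with JSON sidecars, listing CSVs,
and YAML/JSON assessment documents.

Table CSVs follow the published layout — one column of base points
(descending 50..5) and one column per patient category, widest population
first — with comma thousands-separators on values of five digits or more.
A JSON sidecar next to the CSV carries provenance and the anchor row.
"""

from __future__ import annotations

import csv
import json
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .scoring import ValueAssessment, validate_assessment
from .tables import (AnchorRow, CATEGORIES, ConversionTable, DomainError,
                     POINTS_RANGE)
from .update import ListingRecord, PRICE_BASES

__all__ = [
    "ParseError",
    "read_table", "write_table",
    "read_listings", "write_listings",
    "read_assessment", "read_anchor_csv",
    "load_reference_table", "REFERENCE_WINDOWS",
]


class ParseError(ValueError):
    """Malformed input file; message includes the location."""


# columns in file order = categories widest-population first
_FILE_ORDER = tuple(reversed(CATEGORIES))
_HEADER = ("Base Points",) + tuple(c.label for c in _FILE_ORDER)


def _fmt_price(v: int) -> str:
    return f"{v:,d}" if v >= 10_000 else str(v)


def _parse_price(text: str, where: str) -> int:
    t = text.strip().replace(",", "")
    if not t:
        raise ParseError(f"{where}: empty price cell")
    try:
        return int(t)
    except ValueError:
        raise ParseError(f"{where}: non-numeric price {text!r}") from None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_table(table: ConversionTable, path: str | Path) -> None:
    """Write a table CSV plus its JSON sidecar (provenance + anchor row)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for p in sorted(POINTS_RANGE, reverse=True):
            row = [str(p)]
            for cat in _FILE_ORDER:
                row.append(_fmt_price(table.cell(p, cat)))
            w.writerow(row)
    sidecar = {
        "provenance": table.provenance,
        "anchor_points": table.anchor_points,
        "step_rate": str(table.step_rate),
        "anchor": {c.label: v for c, v in zip(CATEGORIES, table.anchor.prices)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2,
                                              ensure_ascii=False) + "\n",
                                   encoding="utf-8")


def read_table(path: str | Path) -> ConversionTable:
    """Read a table CSV (sidecar optional; without it, provenance is empty
    and the anchor row is taken from the 35-point row as printed)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = tuple(h.strip() for h in rows[0])
    if len(header) != len(_HEADER):
        raise ParseError(
            f"{path}, line 1: expected {len(_HEADER)} columns "
            f"(base points + {len(CATEGORIES)} categories), got {len(header)}")
    if header != _HEADER:
        bad = [h for h in header[1:] if h not in {c.label for c in CATEGORIES}]
        raise ParseError(f"{path}, line 1: unexpected header; "
                         f"unknown or misordered columns {bad or list(header)}")

    grid: dict[int, tuple[int, ...]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) != len(_HEADER):
            raise ParseError(f"{path}, line {lineno}: expected {len(_HEADER)} "
                             f"cells, got {len(row)}")
        try:
            points = int(row[0].strip().rstrip("*").strip())
        except ValueError:
            raise ParseError(f"{path}, line {lineno}: bad base-points value "
                             f"{row[0]!r}") from None
        if points not in POINTS_RANGE:
            raise ParseError(f"{path}, line {lineno}: base points {points} "
                             f"outside {POINTS_RANGE}")
        if points in grid:
            raise ParseError(f"{path}, line {lineno}: duplicate row for "
                             f"{points} points")
        vals = [_parse_price(c, f"{path}, line {lineno}") for c in row[1:]]
        # file order is widest-first; store in canonical ascending order
        grid[points] = tuple(reversed(vals))
    missing = [p for p in POINTS_RANGE if p not in grid]
    if missing:
        raise ParseError(f"{path}: missing rows for base points {missing}")

    sidecar = _sidecar_path(path)
    provenance = ""
    anchor_points = 35
    step_rate = Fraction(1, 10)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        provenance = meta.get("provenance", "")
        anchor_points = int(meta.get("anchor_points", anchor_points))
        step_rate = Fraction(meta.get("step_rate", step_rate))
        anchor = AnchorRow.from_mapping(meta["anchor"]) if "anchor" in meta \
            else AnchorRow(grid[anchor_points])
    else:
        anchor = AnchorRow(grid[anchor_points])
    return ConversionTable(anchor=anchor, provenance=provenance,
                           anchor_points=anchor_points, step_rate=step_rate,
                           rows=grid)


def read_anchor_csv(path: str | Path) -> AnchorRow:
    """Read an anchor row from a two-line CSV: category labels, then prices."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if len(rows) != 2:
        raise ParseError(f"{path}: expected 2 lines (labels, prices), got {len(rows)}")
    labels = [c.strip() for c in rows[0]]
    prices = [_parse_price(c, f"{path}, line 2") for c in rows[1]]
    if len(labels) != len(prices):
        raise ParseError(f"{path}: {len(labels)} labels but {len(prices)} prices")
    return AnchorRow.from_mapping(dict(zip(labels, prices)))


_LISTING_FIELDS = ("drug_id", "fiscal_year", "daily_price", "max_patients",
                   "price_basis", "price_derivable")
_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def read_listings(path: str | Path) -> list[ListingRecord]:
    """Read a listing dataset CSV (UTF-8, thousands separators accepted in
    price fields, empty daily_price = not stated)."""
    path = Path(path)
    records: list[ListingRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                tuple(f.strip() for f in reader.fieldnames) != _LISTING_FIELDS:
            raise ParseError(f"{path}, line 1: expected header "
                             f"{','.join(_LISTING_FIELDS)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}, line {lineno}"
            try:
                price_text = (row["daily_price"] or "").strip()
                basis = row["price_basis"].strip()
                if basis not in PRICE_BASES:
                    raise ParseError(f"{where}: price_basis must be one of "
                                     f"{PRICE_BASES}, got {basis!r}")
                deriv_text = row["price_derivable"].strip().lower()
                if deriv_text in _TRUE:
                    derivable = True
                elif deriv_text in _FALSE:
                    derivable = False
                else:
                    raise ParseError(f"{where}: bad price_derivable "
                                     f"{row['price_derivable']!r}")
                records.append(ListingRecord(
                    drug_id=row["drug_id"].strip(),
                    fiscal_year=int(row["fiscal_year"].strip()),
                    daily_price=(float(price_text.replace(",", ""))
                                 if price_text else None),
                    max_patients=int(row["max_patients"].strip().replace(",", "")),
                    price_basis=basis,
                    price_derivable=derivable))
            except ParseError:
                raise
            except (KeyError, ValueError, TypeError, DomainError) as exc:
                raise ParseError(f"{where}: {exc}") from exc
    return records


def write_listings(records: Iterable[ListingRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LISTING_FIELDS)
        for r in records:
            w.writerow([r.drug_id, r.fiscal_year,
                        "" if r.daily_price is None else r.daily_price,
                        r.max_patients, r.price_basis,
                        "true" if r.price_derivable else "false"])


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys (a duplicated element
    would otherwise silently shadow an earlier one)."""


def _strict_map(loader: _StrictLoader, node: yaml.MappingNode):  # noqa: ANN202
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=True)
        if key in seen:
            raise ParseError(f"duplicate element: {key!r}")
        seen.add(key)
    return loader.construct_mapping(node, deep=True)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_map)


def read_assessment(path: str | Path) -> ValueAssessment:
    """Read and validate a YAML or JSON assessment document."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.load(text, Loader=_StrictLoader)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: assessment document must be a mapping")
    return validate_assessment(doc)


#: Fiscal windows of the reference tables shipped with the package.
REFERENCE_WINDOWS = ("FY2012-FY2021", "FY2015-FY2024")

_REFERENCE_FILES = {
    "FY2012-FY2021": "table_fy2012_fy2021.csv",
    "FY2015-FY2024": "table_fy2015_fy2024.csv",
}


def load_reference_table(window: str = "FY2015-FY2024") -> ConversionTable:
    """Load one of the published conversion tables bundled with the package.

    ``window`` is "FY2012-FY2021" (the original table) or "FY2015-FY2024"
    (the updated one).
    """
    key = window.strip().replace(":", "-").upper()
    if key not in _REFERENCE_FILES:
        raise DomainError(f"no reference table for {window!r}; "
                          f"available: {REFERENCE_WINDOWS}")
    data_dir = resources.files("marie") / "data"
    with resources.as_file(data_dir / _REFERENCE_FILES[key]) as p:
        return read_table(p)
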