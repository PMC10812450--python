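"""Study schema, fixture readers, and polyphenol-class aggregation.

The study measures per-compound concentrations (µg/g dry extract) in
sugarcane straw batches harvested under five factors: collection date,
variety, geographic area (Guariba / Valparaiso), borer infection level and
harvest (ratoon) number.  Individual compounds are summed into three
polyphenol classes — hydroxybenzoic acids, hydroxycinnamic acids and
flavones — which, together with ABTS and DPPH IC50s, form the five modeled
responses.
"""

from __future__ import annotations

import datetime as _dt
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AREAS",
    "VARIETIES",
    "CLASSES",
    "RESPONSE_COLUMNS",
    "SampleCondition",
    "CompoundMeasurement",
    "FixtureFormatError",
    "UnknownCompoundError",
    "normalize_name",
    "parse_cell",
    "load_class_map",
    "load_compound_table",
    "load_conditions",
    "map_class",
    "aggregate_classes",
    "summarize_extrema",
    "write_responses_tidy",
    "read_responses_tidy",
    "fixture_path",
]

AREAS = ("Guariba", "Valparaiso")

#: Varieties in the order the sampling plan lists them.
VARIETIES = (
    "SP813250",
    "SP803280",
    "CU0618",
    "RB985476",
    "CTC4",
    "CU7870",
    "CTC15",
    "RB966928",
    "CTC9001",
)

CLASSES = ("hydroxybenzoic_acids", "hydroxycinnamic_acids", "flavones")

#: Columns of a response table, in canonical order.
RESPONSE_COLUMNS = (
    "hydroxybenzoic",
    "hydroxycinnamic",
    "flavones",
    "abts_ic50",
    "dpph_ic50",
)

#: Numeric borer-infection levels (%) used when only the class is known:
#: midpoints of the sampling plan's stated ranges (high 4–11%, low 0–4%).
INFECTION_CLASS_MIDPOINT = {"high": 7.5, "low": 2.0}


class FixtureFormatError(ValueError):
    """A fixture cell or row could not be parsed."""


class UnknownCompoundError(KeyError):
    """A compound name has no entry in the class map."""


@dataclass(frozen=True)
class SampleCondition:
    """Factor values for one harvested straw batch."""

    sample_id: str
    area: str
    collection_date: _dt.date
    variety: str
    infection_level: float
    infection_class: str
    harvest_number: int

    def __post_init__(self):
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}")
        if self.variety not in VARIETIES:
            raise ValueError(f"unknown variety {self.variety!r}")
        if self.infection_class not in ("high", "low"):
            raise ValueError(f"infection_class must be high/low, got {self.infection_class!r}")
        if not 1 <= self.harvest_number <= 7:
            raise ValueError(f"harvest_number must be in [1, 7], got {self.harvest_number}")
        if self.infection_level < 0:
            raise ValueError("infection_level must be >= 0")


@dataclass(frozen=True)
class CompoundMeasurement:
    """One (sample, compound) concentration record."""

    sample_id: str
    compound_name: str
    concentration: float  # µg/g dry extract; 0 when not detected
    sd: float | None
    detected: bool


_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonicalize a compound name: NFKC unicode + whitespace collapse.

    Matching is otherwise exact — no fuzzy matching, so a typo surfaces as
    a lookup error instead of a silent class misassignment.
    """
    return _WS.sub(" ", unicodedata.normalize("NFKC", name)).strip()


_CELL = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*(?:±\s*([0-9]+(?:\.[0-9]+)?))?\s*$")


def parse_cell(text: str) -> tuple[float, float | None, bool]:
    """Parse a ``"value ± sd"`` fixture cell.

    Returns ``(concentration, sd, detected)``.  The tables print ``"-"``
    for compounds below the reporting threshold; those parse as
    ``(0.0, None, False)``.

    Raises
    ------
    FixtureFormatError
        For truncated or otherwise malformed cells (e.g. ``"165.7 ±"``).
    """
    t = text.strip()
    if t in ("-", "", "ND"):
        return 0.0, None, False
    m = _CELL.match(t)
    if m is None:
        raise FixtureFormatError(f"unparseable cell {text!r}")
    value = float(m.group(1))
    sd = float(m.group(2)) if m.group(2) is not None else None
    return value, sd, True


def fixture_path(name: str) -> Path:
    """Path to one of the packaged study tables."""
    return Path(resources.files("strawpoly") / "fixtures" / name)


def load_class_map(path: str | Path | None = None) -> dict[str, str]:
    """Read the compound → polyphenol-class map (packaged table by default)."""
    path = fixture_path("table1_classes.csv") if path is None else path
    df = pd.read_csv(path)
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        name = normalize_name(row["compound"])
        cls = row["class"].strip()
        if cls not in CLASSES:
            raise FixtureFormatError(f"unknown class {cls!r} for {name!r}")
        if name in mapping and mapping[name] != cls:
            raise FixtureFormatError(f"compound {name!r} mapped to two classes")
        mapping[name] = cls
    return mapping


def load_compound_table(
    path: str | Path, class_map: dict[str, str] | None = None
) -> list[CompoundMeasurement]:
    """Read a wide concentration fixture (compounds × samples).

    Cells follow the ``"value ± sd"`` grammar with ``"-"`` marking
    not-detected.  When *class_map* is given, every compound name is
    validated against it.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "compound":
        raise FixtureFormatError(f"{path}: first column must be 'compound'")
    records: list[CompoundMeasurement] = []
    for i, row in df.iterrows():
        name = normalize_name(row["compound"])
        if class_map is not None and name not in class_map:
            raise UnknownCompoundError(name)
        for col in df.columns[1:]:
            cell = row[col] if isinstance(row[col], str) else "-"
            try:
                value, sd, detected = parse_cell(cell)
            except FixtureFormatError as exc:
                raise FixtureFormatError(
                    f"{path}: row {name!r}, column {col!r}: {exc}"
                ) from None
            records.append(CompoundMeasurement(col, name, value, sd, detected))
    return records


def load_conditions(
    path: str | Path | None = None,
) -> tuple[list[SampleCondition], pd.DataFrame]:
    """Read per-sample conditions and antioxidant IC50s (the packaged
    condition/antioxidant table by default).

    Returns the condition list and a frame indexed by sample_id with
    ``abts_ic50`` / ``dpph_ic50`` columns (NaN where the assay printed ND).
    """
    path = fixture_path("table4_antioxidant.csv") if path is None else path
    df = pd.read_csv(path, dtype=str)
    conditions = []
    ic50 = {}
    for _, row in df.iterrows():
        cls = row["infection_class"].strip().lower()
        conditions.append(
            SampleCondition(
                sample_id=row["sample_id"],
                area=row["area"].strip(),
                collection_date=_dt.date.fromisoformat(row["collection_date"]),
                variety=row["variety"].strip(),
                infection_level=INFECTION_CLASS_MIDPOINT[cls],
                infection_class=cls,
                harvest_number=int(row["harvest_number"]),
            )
        )
        vals = {}
        for assay in ("abts", "dpph"):
            v, _sd, det = parse_cell(row[assay])
            vals[f"{assay}_ic50"] = v if det else float("nan")
        ic50[row["sample_id"]] = vals
    frame = pd.DataFrame.from_dict(ic50, orient="index")
    frame.index.name = "sample_id"
    return conditions, frame


def map_class(name: str, class_map: dict[str, str]) -> str:
    """Polyphenol class of a compound; raises UnknownCompoundError if absent."""
    key = normalize_name(name)
    try:
        return class_map[key]
    except KeyError:
        raise UnknownCompoundError(name) from None


_CLASS_TO_COLUMN = {
    "hydroxybenzoic_acids": "hydroxybenzoic",
    "hydroxycinnamic_acids": "hydroxycinnamic",
    "flavones": "flavones",
}


def aggregate_classes(
    measurements: list[CompoundMeasurement],
    class_map: dict[str, str],
    ic50: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sum per-compound concentrations into the three class responses.

    Undetected compounds contribute 0.  Returns a frame indexed by
    sample_id with RESPONSE_COLUMNS; the IC50 columns are NaN unless an
    *ic50* frame is supplied.  An all-zero sample row triggers a warning.
    """
    sample_ids: list[str] = []
    for m in measurements:
        if m.sample_id not in sample_ids:
            sample_ids.append(m.sample_id)
    table = pd.DataFrame(
        0.0, index=pd.Index(sample_ids, name="sample_id"), columns=list(RESPONSE_COLUMNS)
    )
    table[["abts_ic50", "dpph_ic50"]] = float("nan")
    for m in measurements:
        col = _CLASS_TO_COLUMN[map_class(m.compound_name, class_map)]
        table.loc[m.sample_id, col] += m.concentration
    if ic50 is not None:
        for col in ("abts_ic50", "dpph_ic50"):
            table.loc[ic50.index.intersection(table.index), col] = ic50[col]
    empty = table[list(_CLASS_TO_COLUMN.values())].sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"samples with no detected compounds: {list(table.index[empty])}",
            stacklevel=2,
        )
    return table


def summarize_extrema(
    measurements: list[CompoundMeasurement],
    conditions: list[SampleCondition] | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-compound min/max with sample attribution.

    When *group* is an area name, only samples from that area (per
    *conditions*) are summarized.  Raises ValueError for an unknown group
    or an empty selection.
    """
    if group is not None:
        if group not in AREAS:
            raise ValueError(f"unknown group {group!r}")
        if conditions is None:
            raise ValueError("conditions required when grouping by area")
        keep = {c.sample_id for c in conditions if c.area == group}
        measurements = [m for m in measurements if m.sample_id in keep]
    if not measurements:
        raise ValueError("empty group")
    rows = {}
    for m in measurements:
        if not m.detected:
            continue
        r = rows.setdefault(
            m.compound_name,
            {"min": m.concentration, "min_sample": m.sample_id,
             "max": m.concentration, "max_sample": m.sample_id},
        )
        if m.concentration < r["min"]:
            r["min"], r["min_sample"] = m.concentration, m.sample_id
        if m.concentration > r["max"]:
            r["max"], r["max_sample"] = m.concentration, m.sample_id
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "compound"
    return out


def condition_schema() -> dict:
    """JSON-schema description of the sample-condition metadata."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "SampleCondition",
        "type": "object",
        "properties": {
            "sample_id": {"type": "string"},
            "area": {"type": "string", "enum": list(AREAS)},
            "collection_date": {"type": "string", "format": "date"},
            "variety": {"type": "string", "enum": list(VARIETIES)},
            "infection_level": {"type": "number", "minimum": 0,
                                "description": "borer infestation, %"},
            "infection_class": {"type": "string", "enum": ["high", "low"]},
            "harvest_number": {"type": "integer", "minimum": 1, "maximum": 7},
        },
        "required": [
            "sample_id", "area", "collection_date", "variety",
            "infection_level", "infection_class", "harvest_number",
        ],
    }


def write_responses_tidy(table: pd.DataFrame, path: str | Path) -> None:
    """Write a response table as tidy long CSV (sample_id, response, value)."""
    long = table.reset_index().melt(
        id_vars="sample_id", var_name="response", value_name="value"
    )
    long.to_csv(path, index=False, float_format="%.12g")


def read_responses_tidy(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_responses_tidy`."""
    long = pd.read_csv(path)
    wide = long.pivot(index="sample_id", columns="response", values="value")
    cols = [c for c in RESPONSE_COLUMNS if c in wide.columns]
    return wide[cols].rename_axis(columns=None)
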