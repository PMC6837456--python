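"""Packaged survey data and delimited-text I/O.

The packaged fixture is the winter nitrification survey: 13 study-lake
records from two ecozones (11 Saskatchewan prairie water bodies, 2 boreal
shield lakes) plus literature records from Lake St. George, Lake Croche,
Lake Superior and five Wisconsin NTL-LTER lakes — 31 records in all, with
winter and (for the two cross-season lakes) summer rows.

The delimited layout mirrors how such tables are printed: nutrient values
below method detection limits are encoded as ``<86`` / ``<57``,
nitrification rates below their sample-specific LOQ carry a trailing
asterisk (``-1.7*``), sample LOQs may use typeset scientific notation
(``4.9 x 10−3``, unicode minus included), and missing values are empty
fields. Reading parses all of that into numeric columns plus boolean
flags; writing re-encodes it so a read/write cycle round-trips.
"""

from __future__ import annotations

import hashlib
import io
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AMMONIUM_MDL, NITRATE_MDL

__all__ = [
    "SCHEMA_COLUMNS",
    "QUAPPELLE_DOWNSTREAM_LAKES",
    "parse_scientific",
    "load_packaged_survey",
    "read_survey_csv",
    "write_survey_csv",
]

#: Raw file columns, in order.
SCHEMA_COLUMNS = (
    "location",
    "source",
    "season",
    "rate",
    "loq",
    "ammonium",
    "nitrate",
    "oxygen",
    "ph",
    "specific_conductance",
    "n2o_saturation",
    "ch4_saturation",
    "date",
)

#: Qu'Appelle chain lakes downstream of the Regina wastewater outfall,
#: in flow order.
QUAPPELLE_DOWNSTREAM_LAKES = (
    "Pasqua Lake",
    "Echo Lake",
    "Mission Lake",
    "Katepwa Lake",
)

_PACKAGED_NAME = "data/survey_tables.csv"

#: SHA-256 of the packaged fixture; any edit to the data breaks loading.
_PACKAGED_SHA256 = "e22356baf792ac4e8aa59892fb369d463b3c47a67e485036e51a854ca0806cf4"

_MDL_BY_COLUMN = {"ammonium": AMMONIUM_MDL, "nitrate": NITRATE_MDL}

_SCI_RE = re.compile(
    r"^\s*([+\-−]?\d*\.?\d+)\s*[x×*]\s*10\^?\(?([+\-−]?\d+)\)?\s*$"
)


def parse_scientific(text: str) -> float:
    """Parse a numeric string, tolerating typeset scientific notation.

    Accepts plain floats (``0.022``, ``4.9e-3``) and printed forms such as
    ``4.9 x 10−3`` or ``1.1 × 10^−1`` (unicode minus U+2212 included).
    """
    cleaned = text.strip().replace("−", "-")
    match = _SCI_RE.match(cleaned)
    if match:
        mantissa, exponent = match.groups()
        return float(mantissa) * 10.0 ** int(exponent)
    return float(cleaned)


def _parse_cell(raw, column: str, row_number: int):
    """Parse one cell; returns (value, flag) for the markered columns."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        text = ""
    else:
        text = str(raw).strip()
    if text in ("", "NA", "na", "NaN"):
        return np.nan, False
    flagged = False
    if column in _MDL_BY_COLUMN and text.startswith("<"):
        flagged = True
        text = text[1:]
    if column == "rate" and text.endswith("*"):
        flagged = True
        text = text[:-1]
    try:
        value = parse_scientific(text)
    except ValueError as exc:
        raise ValueError(
            f"row {row_number}: malformed numeric {raw!r} in column {column!r}"
        ) from exc
    return value, flagged


_NUMERIC_COLUMNS = (
    "rate",
    "loq",
    "ammonium",
    "nitrate",
    "oxygen",
    "ph",
    "specific_conductance",
    "n2o_saturation",
    "ch4_saturation",
)


def _parse_frame(raw: pd.DataFrame, origin: str) -> pd.DataFrame:
    raw = raw.rename(columns=lambda c: str(c).strip().lower())
    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    out = pd.DataFrame(index=raw.index)
    for column in ("location", "source", "season"):
        out[column] = raw[column].astype(str).str.strip()
    for column in _NUMERIC_COLUMNS:
        parsed = [
            _parse_cell(value, column, i + 2)  # +2: header + 1-based rows
            for i, value in zip(raw.index, raw[column])
        ]
        out[column] = [v for v, _ in parsed]
        if column in _MDL_BY_COLUMN:
            out[f"{column}_below_mdl"] = [f for _, f in parsed]
        elif column == "rate":
            out["rate_below_sample_loq"] = [f for _, f in parsed]
    out["date"] = raw["date"].map(
        lambda v: "" if pd.isna(v) else str(v).strip()
    )
    extra = [c for c in raw.columns if c not in SCHEMA_COLUMNS]
    for column in extra:
        out[column] = raw[column]
    keys = list(zip(out["location"], out["date"]))
    duplicates = {k for k in keys if keys.count(k) > 1}
    if duplicates:
        raise ValueError(f"{origin}: duplicate record keys {sorted(duplicates)}")
    return out


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read a survey table from delimited text into the parsed schema.

    The parsed frame has numeric value columns plus flag columns
    ``rate_below_sample_loq``, ``ammonium_below_mdl`` and
    ``nitrate_below_mdl``; below-detection values are stored at the MDL
    with the flag set. Unknown columns are preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return _parse_frame(raw, str(path))


def write_survey_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a parsed survey table back to the delimited layout.

    Flags are re-encoded as ``<MDL`` markers and trailing asterisks, and
    missing values as empty fields, so ``read(write(t))`` equals ``t``.
    """

    def fmt(value) -> str:
        if pd.isna(value):
            return ""
        as_float = float(value)
        if as_float == int(as_float) and abs(as_float) < 1e15:
            return str(int(as_float))
        return repr(as_float)

    out = pd.DataFrame(index=table.index)
    for column in ("location", "source", "season"):
        out[column] = table[column]
    for column in _NUMERIC_COLUMNS:
        encoded = []
        for idx in table.index:
            value = table.at[idx, column]
            text = fmt(value)
            if column in _MDL_BY_COLUMN and bool(
                table.at[idx, f"{column}_below_mdl"]
            ):
                text = "<" + text
            elif column == "rate" and bool(
                table.at[idx, "rate_below_sample_loq"]
            ):
                text = text + "*"
            encoded.append(text)
        out[column] = encoded
    out["date"] = table["date"]
    known = set(SCHEMA_COLUMNS) | {
        "rate_below_sample_loq",
        "ammonium_below_mdl",
        "nitrate_below_mdl",
    }
    for column in table.columns:
        if column not in known and column not in out.columns:
            out[column] = table[column]
    out.to_csv(path, index=False)


def load_packaged_survey(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the packaged 31-record survey fixture.

    ``verify_checksum`` guards the fixture against accidental edits: the
    file's SHA-256 must match the committed digest.
    """
    resource = resources.files("winternit").joinpath(_PACKAGED_NAME)
    payload = resource.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(payload).hexdigest()
        if digest != _PACKAGED_SHA256:
            raise ValueError(
                "packaged survey checksum mismatch: "
                f"expected {_PACKAGED_SHA256}, got {digest}"
            )
    raw = pd.read_csv(io.BytesIO(payload), dtype=str, keep_default_na=False)
    return _parse_frame(raw, _PACKAGED_NAME)
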