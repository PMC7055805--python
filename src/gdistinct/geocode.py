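"""Surrogate-ZIP geocoding and partition by provincial-level division (PAD).

Address triples (province, city, district) are converted into fixed-width
9-digit surrogate ZIP codes by exact lookup in a :class:`Gazetteer`:
2 digits for the PAD, 3 for the city, 4 for the district, concatenated.
Codes are opaque digit *strings* — never integers — so leading zeros
survive. Lookup is exact after whitespace trimming and Unicode NFC
normalization; there is no fuzzy matching, and triples absent from the
gazetteer are reported as unmapped rather than guessed.

Encoded records can then be partitioned by PAD (the first two ZIP digits),
the grouping the stratified risk analysis operates on.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import ValidationError

TRIPLE_COLUMNS = ("province", "city", "district")
CODE_COLUMNS = ("pad_code", "city_code", "district_code")
CODE_WIDTHS = {"pad_code": 2, "city_code": 3, "district_code": 4}

#: Column added to a record table by encoding; missing where unmapped.
ZIP_COLUMN = "zip"


def normalize_name(value: str) -> str:
    """Canonical form used for gazetteer lookup: NFC + stripped."""
    return unicodedata.normalize("NFC", str(value)).strip()


def _normalize_series(s: pd.Series) -> pd.Series:
    return s.astype("string").map(lambda v: normalize_name(v) if pd.notna(v) else v)


@dataclass(frozen=True)
class Gazetteer:
    """Validated mapping from address triples to (pad, city, district) codes.

    ``table`` has the six columns ``province, city, district, pad_code,
    city_code, district_code`` with name columns already normalized.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_gazetteer(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pad_codes(self) -> list[str]:
        return sorted(self.table["pad_code"].unique())

    def lookup(self, province: str, city: str, district: str) -> str | None:
        """Surrogate ZIP for one triple, or ``None`` if unmapped."""
        key = tuple(normalize_name(v) for v in (province, city, district))
        t = self.table
        hit = t[(t["province"] == key[0]) & (t["city"] == key[1]) & (t["district"] == key[2])]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return row["pad_code"] + row["city_code"] + row["district_code"]


def _validate_gazetteer(table: pd.DataFrame) -> None:
    missing = [c for c in (*TRIPLE_COLUMNS, *CODE_COLUMNS) if c not in table.columns]
    if missing:
        raise ValidationError(f"gazetteer missing column(s): {', '.join(missing)}")
    for col, width in CODE_WIDTHS.items():
        ok = table[col].astype("string").str.fullmatch(rf"\d{{{width}}}")
        bad_rows = table.index[~ok.fillna(False)].tolist()
        if bad_rows:
            raise ValidationError(
                f"gazetteer column {col!r} must be exactly {width} digits; "
                f"bad row(s): {bad_rows[:10]}"
            )
    dup_triple = table.duplicated(subset=list(TRIPLE_COLUMNS))
    if dup_triple.any():
        raise ValidationError(
            f"duplicate address triple(s) at row(s): {table.index[dup_triple].tolist()[:10]}"
        )
    dup_code = table.duplicated(subset=list(CODE_COLUMNS))
    if dup_code.any():
        raise ValidationError(
            f"duplicate code triple(s) at row(s): {table.index[dup_code].tolist()[:10]}"
        )


def load_gazetteer(path, delimiter: str = ",") -> Gazetteer:
    """Read and validate a gazetteer from delimited text.

    Width or uniqueness violations raise :class:`ValidationError` naming
    the offending row numbers (0-based data rows).
    """
    raw = pd.read_csv(path, sep=delimiter, dtype="string", keep_default_na=False, na_values=[""])
    return make_gazetteer(raw)


def make_gazetteer(frame: pd.DataFrame) -> Gazetteer:
    """Build a validated :class:`Gazetteer` from an in-memory frame."""
    table = frame.copy()
    for col in TRIPLE_COLUMNS:
        if col in table.columns:
            table[col] = _normalize_series(table[col])
    for col in CODE_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype("string")
    return Gazetteer(table.reset_index(drop=True))


@dataclass(frozen=True)
class EncodingReport:
    """Counts from one encoding pass over a record table."""

    n_mapped: int
    n_unmapped: int
    per_pad: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_mapped": self.n_mapped,
            "n_unmapped": self.n_unmapped,
            "per_pad": dict(self.per_pad),
        }


def encode_address(record, gazetteer: Gazetteer) -> str | None:
    """Encode one record's address triple; ``None`` when unmapped.

    ``record`` is any mapping with province/city/district entries (e.g. a
    DataFrame row).
    """
    return gazetteer.lookup(record["province"], record["city"], record["district"])


def encode_records(
    records: pd.DataFrame, gazetteer: Gazetteer
) -> tuple[pd.DataFrame, EncodingReport]:
    """Attach surrogate ZIP codes to a record table via exact lookup.

    Returns the table with an added ``zip`` column (missing where the
    triple is not in the gazetteer) and an :class:`EncodingReport`. Row
    order is preserved. Unmapped records stay in the table but are excluded
    from downstream risk analysis by :func:`partition_by_pad`.
    """
    left = records.copy().reset_index(drop=True)
    keys = pd.DataFrame({c: _normalize_series(left[c]) for c in TRIPLE_COLUMNS})
    gaz = gazetteer.table
    merged = keys.merge(gaz, how="left", on=list(TRIPLE_COLUMNS))
    zips = (merged["pad_code"] + merged["city_code"] + merged["district_code"]).astype("string")
    left[ZIP_COLUMN] = zips
    mapped = zips.notna()
    per_pad = zips[mapped].str[:2].value_counts().sort_index()
    report = EncodingReport(
        n_mapped=int(mapped.sum()),
        n_unmapped=int((~mapped).sum()),
        per_pad={str(k): int(v) for k, v in per_pad.items()},
    )
    return left, report


@dataclass(frozen=True)
class PadPartition:
    """Disjoint exhaustive grouping of encoded records by PAD code.

    ``groups`` maps each 2-digit PAD code to the sub-table of records whose
    surrogate ZIP starts with it; every encoded (mapped) record appears in
    exactly one group.
    """

    groups: dict[str, pd.DataFrame]

    @property
    def n_pads(self) -> int:
        """Number of nonempty PAD groups."""
        return sum(1 for g in self.groups.values() if len(g) > 0)

    @property
    def n_records(self) -> int:
        return sum(len(g) for g in self.groups.values())

    def sizes(self) -> dict[str, int]:
        return {pad: len(g) for pad, g in self.groups.items()}


def partition_by_pad(encoded: pd.DataFrame) -> PadPartition:
    """Group encoded records by the first two digits of their surrogate ZIP.

    Records with a missing ``zip`` (unmapped addresses) are excluded; group
    sizes therefore sum to the number of mapped records.
    """
    mapped = encoded[encoded[ZIP_COLUMN].notna()]
    groups = {
        str(pad): grp.reset_index(drop=True)
        for pad, grp in mapped.groupby(mapped[ZIP_COLUMN].str[:2], sort=True)
    }
    return PadPartition(groups=groups)


class GazetteerEncoder(BaseEstimator, TransformerMixin):
    """Transformer attaching surrogate ZIP codes to record tables.

    Parameters
    ----------
    gazetteer : Gazetteer
        The lookup table; validated on construction.

    Attributes
    ----------
    report_ : EncodingReport
        Mapped/unmapped counts from the most recent :meth:`transform`.
    """

    def __init__(self, gazetteer: Gazetteer | None = None):
        self.gazetteer = gazetteer

    def fit(self, X: pd.DataFrame, y=None) -> "GazetteerEncoder":
        if self.gazetteer is None:
            raise ValueError("GazetteerEncoder requires a gazetteer")
        self.n_entries_ = len(self.gazetteer)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.gazetteer is None:
            raise ValueError("GazetteerEncoder requires a gazetteer")
        encoded, report = encode_records(X, self.gazetteer)
        self.report_ = report
        return encoded
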