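"""Reading, validating, filtering and writing patient demographic records.

The pipeline's unit of data is a *record table*: a :class:`pandas.DataFrame`
with one row per patient and the columns

``record_id``
    opaque non-empty identifier, unique within a table;
``dob``
    date of birth as an ISO-8601 string ``"YYYY-MM-DD"``, or missing
    (``pd.NA``);
``gender``
    ``"M"`` / ``"F"``, or missing;
``province``, ``city``, ``district``
    hierarchical residence-address components, each a string or missing.

Dates are accepted only in the ISO dialect; anything else (including
ambiguous ``31/12/1980``-style values) is treated as missing rather than
guessed, since silently reinterpreting a date dialect can corrupt birth
years. Records failing the study's exclusion rules — missing residence
address, or a sentinel ("obviously erroneous") date of birth such as
1900-01-01 — are removed by :func:`filter_records`, which accounts for every
input row in a :class:`FilterReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of a record table.
RECORD_COLUMNS = ("record_id", "dob", "gender", "province", "city", "district")

#: Address component columns; a record with any of these missing is
#: considered to have a missing residence address.
ADDRESS_COLUMNS = ("province", "city", "district")

#: Default sentinel (data-entry placeholder) dates of birth.
DEFAULT_SENTINEL_DOBS = frozenset({"1900-01-01"})

GENDER_VALUES = frozenset({"M", "F"})


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class ValidationError(ValueError):
    """Record contents violate an invariant (e.g. duplicated record_id)."""


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the exclusion rules applied by :func:`filter_records`.

    Each excluded record is attributed to exactly one rule; rules are
    evaluated in order (missing address first, then sentinel DOB), so the
    counts always reconcile::

        n_input == n_missing_address + n_sentinel_dob + n_retained
    """

    n_input: int
    n_missing_address: int
    n_sentinel_dob: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_missing_address + self.n_sentinel_dob + self.n_retained:
            raise ValidationError(
                f"filter report does not reconcile: {self.n_input} != "
                f"{self.n_missing_address} + {self.n_sentinel_dob} + {self.n_retained}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_missing_address": self.n_missing_address,
            "n_sentinel_dob": self.n_sentinel_dob,
            "n_retained": self.n_retained,
        }

    def to_text(self) -> str:
        """Small key-value block suitable for a run log."""
        return "\n".join(f"{k}: {v}" for k, v in self.as_dict().items())


def _normalize_str_column(s: pd.Series) -> pd.Series:
    """Strip whitespace and map empty strings to missing."""
    s = s.astype("string").str.strip()
    return s.mask(s == "", pd.NA)


def validate_records(df: pd.DataFrame, reference_date: str | None = None) -> pd.DataFrame:
    """Coerce a raw frame to the canonical record-table schema.

    Parameters
    ----------
    df
        Frame containing at least the columns in :data:`RECORD_COLUMNS`
        (after any renaming by the caller).
    reference_date
        ISO date; DOBs strictly after it are invalid and become missing
        (with a logged warning). ``None`` disables the check.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        if ``record_id`` values are empty, missing, or duplicated.
    """
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    out = pd.DataFrame(index=pd.RangeIndex(len(df)))
    for col in RECORD_COLUMNS:
        out[col] = _normalize_str_column(df[col].reset_index(drop=True))

    if out["record_id"].isna().any():
        raise ValidationError("record_id must be non-empty for every row")
    dupes = out.loc[out["record_id"].duplicated(), "record_id"].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicated record_id values: {', '.join(map(str, dupes))}")

    # DOB: strict ISO-8601; any other dialect or impossible date -> missing.
    parsed = pd.to_datetime(out["dob"], format="%Y-%m-%d", errors="coerce")
    bad = out["dob"].notna() & parsed.isna()
    if bad.any():
        logger.warning("%d DOB value(s) not valid ISO-8601 dates; treated as missing", int(bad.sum()))
    if reference_date is not None:
        future = parsed > pd.Timestamp(reference_date)
        if future.any():
            logger.warning(
                "%d DOB value(s) after reference date %s; treated as missing",
                int(future.sum()),
                reference_date,
            )
        parsed = parsed.mask(future)
    out["dob"] = parsed.dt.strftime("%Y-%m-%d").astype("string")

    bad_gender = out["gender"].notna() & ~out["gender"].isin(GENDER_VALUES)
    if bad_gender.any():
        logger.warning(
            "%d gender value(s) outside {M, F}; treated as missing", int(bad_gender.sum())
        )
        out["gender"] = out["gender"].mask(bad_gender)

    return out


def read_records(
    path,
    delimiter: str = ",",
    columns: dict[str, str] | None = None,
    reference_date: str | None = None,
) -> pd.DataFrame:
    """Read a delimited record file into a canonical record table.

    Parameters
    ----------
    path
        UTF-8 delimited text file with a header row.
    delimiter
        Field separator (comma default, tab selectable).
    columns
        Optional mapping from canonical column name to the file's column
        name, for files whose headers differ from the canonical schema.
    reference_date
        Passed to :func:`validate_records`.

    Returns
    -------
    pandas.DataFrame
        One row per data row, in file order.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype="string", keep_default_na=False, na_values=[""])
    if columns:
        missing = [src for src in columns.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"mapped column(s) not in file header: {', '.join(missing)}")
        raw = raw.rename(columns={src: dst for dst, src in columns.items()})
    return validate_records(raw, reference_date=reference_date)


def write_records(records: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a record table as delimited text (missing values as empty fields).

    Round-trip contract: ``read_records(write_records(r))`` reproduces ``r``
    field for field, including missingness.
    """
    records.loc[:, list(RECORD_COLUMNS)].to_csv(path, sep=delimiter, index=False, na_rep="")


def filter_records(
    records: pd.DataFrame,
    sentinel_dobs: frozenset[str] | set[str] = DEFAULT_SENTINEL_DOBS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the study's exclusion rules to a record table.

    Rules, in attribution order (a record failing both is counted once,
    under the first):

    1. missing residence address — any of province/city/district missing;
    2. sentinel DOB — date of birth in ``sentinel_dobs``.

    Records with missing gender or missing (non-sentinel) DOB are retained
    here; they drop out later, at quasi-identifier binning, where the drop
    is counted separately.

    Returns
    -------
    (retained, report)
        ``retained`` preserves input row order; ``report`` accounts for
        every input row.
    """
    if not sentinel_dobs:
        raise ValueError("sentinel_dobs must be non-empty")
    missing_addr = records[list(ADDRESS_COLUMNS)].isna().any(axis=1)
    sentinel = ~missing_addr & records["dob"].isin(list(sentinel_dobs))
    retained = records.loc[~missing_addr & ~sentinel].reset_index(drop=True)
    report = FilterReport(
        n_input=len(records),
        n_missing_address=int(missing_addr.sum()),
        n_sentinel_dob=int(sentinel.sum()),
        n_retained=len(retained),
    )
    return retained, report
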