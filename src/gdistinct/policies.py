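"""Generalization policies producing quasi-identifier views.

A *policy* says how much of each quasi-identifier survives into the binning
key: the date of birth is kept at day/month/year/decade granularity, the
9-digit surrogate ZIP is truncated to a prefix, and (optionally) ages above
a threshold are pooled into one top-coded birth component, mirroring the
HIPAA "ages over 89" rule.

Two named policies correspond to the standard HIPAA-style releases:

* ``limited`` — full DOB, gender, full 9-digit surrogate ZIP;
* ``safe_harbor`` — birth year, gender, first 6 ZIP digits.

:func:`coarsens` formalizes when one policy's view is a deterministic
function of another's — the property that guarantees generalization can
only merge equivalence classes, never split them, hence never increases
uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geocode import ZIP_COLUMN

#: Granularities from finest to coarsest; each is a function of any finer one.
DOB_GRANULARITIES = ("day", "month", "year", "decade")

_GRAN_RANK = {g: i for i, g in enumerate(DOB_GRANULARITIES)}
_GRAN_SLICE = {"day": 10, "month": 7, "year": 4}


@dataclass(frozen=True)
class PolicySpec:
    """A quasi-identifier generalization policy.

    Parameters
    ----------
    name
        ``limited``, ``safe_harbor`` or ``custom``.
    dob_granularity
        One of ``day`` ("YYYY-MM-DD"), ``month`` ("YYYY-MM"), ``year``
        ("YYYY"), ``decade`` ("YYY0s", birth year floored to the decade).
    zip_prefix_len
        ZIP digits kept, 0–9; 0 drops geography from the key entirely.
    topcode_age_at
        Optional age (years); patients at least this old at the reference
        date share one pooled birth component (``"90+"`` style). Off by
        default: the two named policies do not top-code.
    """

    name: str = "custom"
    dob_granularity: str = "day"
    zip_prefix_len: int = 9
    topcode_age_at: int | None = None

    def __post_init__(self) -> None:
        if self.dob_granularity not in DOB_GRANULARITIES:
            raise ValueError(f"unknown dob_granularity {self.dob_granularity!r}")
        if not 0 <= self.zip_prefix_len <= 9:
            raise ValueError(f"zip_prefix_len must be in [0, 9], got {self.zip_prefix_len}")
        if self.topcode_age_at is not None and self.topcode_age_at < 0:
            raise ValueError("topcode_age_at must be non-negative")


#: Full DOB + gender + full surrogate ZIP (direct identifiers already removed).
LIMITED = PolicySpec(name="limited", dob_granularity="day", zip_prefix_len=9)

#: Birth year + gender + first 6 of 9 ZIP digits.
SAFE_HARBOR = PolicySpec(name="safe_harbor", dob_granularity="year", zip_prefix_len=6)

NAMED_POLICIES = {"limited": LIMITED, "safe_harbor": SAFE_HARBOR}


def get_policy(spec: PolicySpec | str) -> PolicySpec:
    """Resolve a policy name or pass a spec through."""
    if isinstance(spec, PolicySpec):
        return spec
    try:
        return NAMED_POLICIES[spec]
    except KeyError:
        raise ValueError(
            f"unknown policy {spec!r}; expected one of {sorted(NAMED_POLICIES)}"
        ) from None


#: Key columns of a quasi-identifier view, in binning order.
KEY_COLUMNS = ("dob_key", "gender", "zip_key")


@dataclass(frozen=True)
class QuasiIdentifierView:
    """Policy-transformed binning keys for a set of records.

    ``keys`` has one row per retained patient with columns ``dob_key``,
    ``gender``, ``zip_key`` (all non-missing); ``n_dropped_missing`` counts
    input records dropped because some key component was missing.
    """

    policy: PolicySpec
    keys: pd.DataFrame
    n_dropped_missing: int

    def __len__(self) -> int:
        return len(self.keys)

    def key_tuples(self) -> list[tuple[str, str, str]]:
        """Keys as plain tuples (convenient for oracle comparisons)."""
        return list(map(tuple, self.keys[list(KEY_COLUMNS)].itertuples(index=False)))


def generalize_dob(dob: pd.Series, granularity: str) -> pd.Series:
    """Generalize ISO date strings to the requested granularity."""
    s = dob.astype("string")
    if granularity == "decade":
        return s.str[:3] + "0s"
    return s.str[: _GRAN_SLICE[granularity]]


def _ages_at(dob: pd.Series, reference_date: str) -> pd.Series:
    ref = pd.Timestamp(reference_date)
    born = pd.to_datetime(dob, format="%Y-%m-%d", errors="coerce")
    had_birthday = (born.dt.month < ref.month) | (
        (born.dt.month == ref.month) & (born.dt.day <= ref.day)
    )
    return ref.year - born.dt.year - (~had_birthday).astype(int)


def apply_policy(
    encoded: pd.DataFrame,
    spec: PolicySpec | str,
    reference_date: str | None = None,
) -> QuasiIdentifierView:
    """Transform encoded records into a quasi-identifier view.

    Records with any missing key component (DOB, gender, or — when
    ``zip_prefix_len > 0`` — ZIP) are dropped and counted in
    ``n_dropped_missing``; gender is never altered. When ``topcode_age_at``
    is set, ``reference_date`` (ISO) is required to compute ages.
    """
    spec = get_policy(spec)
    df = encoded.reset_index(drop=True)

    dob_key = generalize_dob(df["dob"], spec.dob_granularity)
    if spec.topcode_age_at is not None:
        if reference_date is None:
            raise ValueError("reference_date is required when topcode_age_at is set")
        pooled = _ages_at(df["dob"], reference_date) >= spec.topcode_age_at
        dob_key = dob_key.mask(pooled.fillna(False), f"{spec.topcode_age_at}+")
    dob_key = dob_key.mask(df["dob"].isna())

    if spec.zip_prefix_len == 0:
        zip_key = pd.Series([""] * len(df), dtype="string")
    else:
        zip_key = df[ZIP_COLUMN].astype("string").str[: spec.zip_prefix_len]

    keys = pd.DataFrame(
        {"dob_key": dob_key, "gender": df["gender"].astype("string"), "zip_key": zip_key}
    )
    complete = keys.notna().all(axis=1)
    return QuasiIdentifierView(
        policy=spec,
        keys=keys.loc[complete].reset_index(drop=True),
        n_dropped_missing=int((~complete).sum()),
    )


def coarsens(spec_a: PolicySpec | str, spec_b: PolicySpec | str) -> bool:
    """True iff ``spec_b``'s view is a deterministic function of ``spec_a``'s.

    Holds when B's DOB granularity is coarser or equal, B's ZIP prefix is
    shorter or equal, and B's top-coding is derivable from A's view: either
    the thresholds agree, or A does not pool and exposes day-level DOB (so
    exact ages are computable) while B pools. A pooled view can never be
    un-pooled, and a non-day DOB component does not determine exact age.
    """
    a, b = get_policy(spec_a), get_policy(spec_b)
    if _GRAN_RANK[b.dob_granularity] < _GRAN_RANK[a.dob_granularity]:
        return False
    if b.zip_prefix_len > a.zip_prefix_len:
        return False
    if b.topcode_age_at == a.topcode_age_at:
        return True
    if a.topcode_age_at is None:
        return b.topcode_age_at is not None and a.dob_granularity == "day"
    # A pools: B must pool at least as much, from day-level detail it no
    # longer has — only an equal threshold (handled above) is derivable.
    return False


class PolicyTransformer(BaseEstimator, TransformerMixin):
    """Transformer from encoded record tables to quasi-identifier key frames.

    Parameters
    ----------
    policy : PolicySpec or str, default "limited"
        Generalization policy (or its name).
    reference_date : str, optional
        ISO date used for age top-coding, when the policy requires it.

    Attributes
    ----------
    view_ : QuasiIdentifierView
        Full view object from the most recent :meth:`transform`.
    n_dropped_missing_ : int
        Records dropped for missing key components in that transform.
    """

    def __init__(self, policy: PolicySpec | str = "limited", reference_date: str | None = None):
        self.policy = policy
        self.reference_date = reference_date

    def fit(self, X: pd.DataFrame, y=None) -> "PolicyTransformer":
        self.policy_ = get_policy(self.policy)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        view = apply_policy(X, self.policy, reference_date=self.reference_date)
        self.view_ = view
        self.n_dropped_missing_ = view.n_dropped_missing
        return view.keys
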