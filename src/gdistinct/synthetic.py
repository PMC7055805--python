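"""Seeded synthetic populations with hierarchical administrative geography.

The study's patient data are private, so every pipeline stage is exercised
on synthetic populations that reproduce the *structure* the analysis
assumes: a three-level residence hierarchy (provincial-level administrative
division → city → district) with a matching gazetteer, heavily skewed PAD
populations (Zipf-weighted by default), dates of birth spread over decades,
binary gender, and the two data-quality defects the preprocessing removes —
missing addresses and sentinel ("1900-01-01") dates of birth.

Generation is fully reproducible from the config's seed. One pseudo-random
stream is consumed in a fixed, documented order: gazetteer structure (only
when city/district counts are given as ranges), then per-record PAD → city
→ district → DOB → gender → defect draws. The number of variates each
per-record stage consumes depends only on the config, never on the values
drawn earlier, so adding fields later cannot silently reshuffle existing
draws.

The bundled *truth* table records each patient's assigned PAD and surrogate
ZIP before any defect is injected, providing an end-to-end oracle for the
geocoding stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geocode import Gazetteer, make_gazetteer
from .records import RECORD_COLUMNS, write_records

SENTINEL_DOB = "1900-01-01"


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of one synthetic population.

    Parameters
    ----------
    n_patients
        Number of records to generate.
    n_pads
        Provincial-level divisions (≤ 99; 2-digit codes). Default 33, the
        number of nonempty PADs in the motivating study.
    cities_per_pad, districts_per_city
        Either a fixed count or an inclusive ``(lo, hi)`` range drawn per
        PAD / per city. Defaults (4 and 20) give 33·4·20 = 2,640 districts —
        a deliberately stylized geography sized so that, at the default
        analysis scale of ~10⁵ patients, the safe-harbor view reaches the
        class-saturation regime the full-scale study exhibits.
    pad_weighting
        ``"zipf"`` (share of PAD at rank r ∝ r^(−zipf_exponent)) or
        ``"uniform"``. Zipf with exponent 1 emulates the order-of-magnitude
        population skew across real PADs.
    dob_range
        Inclusive birth-year span; default (1930, 2010), ~80 years.
    dob_model
        ``"uniform_daily"`` (uniform over all calendar days in range) or
        ``"year_weighted"`` (year drawn from ``year_weights``, then a
        uniform day within it; uniform year weights by default — the hook
        exists for age-pyramid emulation).
    gender_prob
        Probability of gender ``"F"``.
    missing_address_rate
        Probability a record's entire address triple is blanked.
    sentinel_dob_rate
        Probability a record's DOB is replaced by ``"1900-01-01"``.
    seed
        Seed of the single pseudo-random stream.
    """

    n_patients: int
    n_pads: int = 33
    cities_per_pad: int | tuple[int, int] = 4
    districts_per_city: int | tuple[int, int] = 20
    pad_weighting: str = "zipf"
    zipf_exponent: float = 1.0
    dob_range: tuple[int, int] = (1930, 2010)
    dob_model: str = "uniform_daily"
    year_weights: tuple[float, ...] | None = None
    gender_prob: float = 0.5
    missing_address_rate: float = 0.02
    sentinel_dob_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 1 <= self.n_pads <= 99:
            raise ValueError("n_pads must be in [1, 99] (2-digit codes)")
        for name, bound in (("cities_per_pad", 999), ("districts_per_city", 9999)):
            val = getattr(self, name)
            lo, hi = (val, val) if isinstance(val, int) else val
            if not 1 <= lo <= hi <= bound:
                raise ValueError(f"{name} must lie in [1, {bound}]")
        if self.pad_weighting not in ("uniform", "zipf"):
            raise ValueError("pad_weighting must be 'uniform' or 'zipf'")
        if self.dob_model not in ("uniform_daily", "year_weighted"):
            raise ValueError("dob_model must be 'uniform_daily' or 'year_weighted'")
        for rate in ("gender_prob", "missing_address_rate", "sentinel_dob_rate"):
            if not 0 <= getattr(self, rate) <= 1:
                raise ValueError(f"{rate} must be in [0, 1]")
        if self.dob_range[0] > self.dob_range[1]:
            raise ValueError("dob_range must be non-empty")

    def pad_weights(self) -> np.ndarray:
        """Normalized PAD population shares (rank 1 = largest)."""
        ranks = np.arange(1, self.n_pads + 1, dtype=float)
        w = np.ones_like(ranks) if self.pad_weighting == "uniform" else ranks**-self.zipf_exponent
        return w / w.sum()

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated population: records, the matching gazetteer, and truth.

    ``truth`` has columns ``record_id, pad_code, zip`` holding the
    *assigned* geography of every record, including records whose address
    was later blanked — encoding any record whose address survived must
    reproduce its truth ZIP exactly.
    """

    records: pd.DataFrame
    gazetteer: Gazetteer
    truth: pd.DataFrame
    config: PopulationConfig

    def write(self, directory) -> None:
        """Write records/gazetteer/truth as delimited text plus the config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_records(self.records, directory / "records.csv")
        self.gazetteer.table.to_csv(directory / "gazetteer.csv", index=False)
        self.truth.to_csv(directory / "truth.csv", index=False)
        (directory / "config.json").write_text(json.dumps(self.config.as_dict(), indent=2))


def _resolve_counts(spec: int | tuple[int, int], n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, int):
        return np.full(n, spec, dtype=np.int64)
    lo, hi = spec
    return rng.integers(lo, hi + 1, size=n)


def _build_gazetteer(config: PopulationConfig, rng: np.random.Generator):
    """Deterministic hierarchy: PAD codes 01.., city 001.., district 0001..

    Returns the gazetteer plus index arrays used to vectorize record
    assembly.
    """
    n_cities = _resolve_counts(config.cities_per_pad, config.n_pads, rng)
    n_districts = _resolve_counts(config.districts_per_city, int(n_cities.sum()), rng)

    rows = []
    city_global = 0
    for p in range(config.n_pads):
        pad_code = f"{p + 1:02d}"
        for c in range(n_cities[p]):
            city_code = f"{c + 1:03d}"
            for d in range(n_districts[city_global]):
                district_code = f"{d + 1:04d}"
                rows.append(
                    (
                        f"Province{pad_code}",
                        f"City{pad_code}x{city_code}",
                        f"District{pad_code}x{city_code}x{district_code}",
                        pad_code,
                        city_code,
                        district_code,
                    )
                )
            city_global += 1
    table = pd.DataFrame(
        rows, columns=["province", "city", "district", "pad_code", "city_code", "district_code"]
    )
    return make_gazetteer(table), n_cities, n_districts


def generate_population(config: PopulationConfig) -> SyntheticBundle:
    """Generate a reproducible synthetic population bundle.

    Exactly ``config.n_patients`` records are produced. PAD membership
    follows the configured weighting; city and district are uniform within
    their parent; DOBs follow the configured model; the address triple is
    blanked with probability ``missing_address_rate`` and the DOB replaced
    by the sentinel with probability ``sentinel_dob_rate`` (independent
    draws; a record may suffer both).
    """
    rng = np.random.default_rng(config.seed)
    gazetteer, n_cities, n_districts = _build_gazetteer(config, rng)
    n = config.n_patients

    if n == 0:
        empty_records = pd.DataFrame(columns=list(RECORD_COLUMNS)).astype("string")
        empty_truth = pd.DataFrame(columns=["record_id", "pad_code", "zip"]).astype("string")
        return SyntheticBundle(
            records=empty_records, gazetteer=gazetteer, truth=empty_truth, config=config
        )

    city_offset = np.concatenate([[0], np.cumsum(n_cities)])[:-1]  # pad -> first global city

    # Fixed draw order; each stage consumes exactly n variates.
    pad_idx = rng.choice(config.n_pads, size=n, p=config.pad_weights())
    city_local = np.floor(rng.random(n) * n_cities[pad_idx]).astype(np.int64)
    city_global = city_offset[pad_idx] + city_local
    district_local = np.floor(rng.random(n) * n_districts[city_global]).astype(np.int64)
    dob = _draw_dobs(config, rng, n)
    gender = np.where(rng.random(n) < config.gender_prob, "F", "M")
    missing_mask = rng.random(n) < config.missing_address_rate
    sentinel_mask = rng.random(n) < config.sentinel_dob_rate

    pad_code = np.array([f"{i + 1:02d}" for i in range(config.n_pads)])[pad_idx]
    city_code = np.char.zfill((city_local + 1).astype(str), 3)
    district_code = np.char.zfill((district_local + 1).astype(str), 4)
    zips = np.char.add(np.char.add(pad_code, city_code), district_code)

    pad_city = np.char.add(np.char.add(pad_code, "x"), city_code)
    province = np.char.add("Province", pad_code)
    city_name = np.char.add("City", pad_city)
    district_name = np.char.add("District", np.char.add(pad_city, np.char.add("x", district_code)))

    record_id = np.char.add("P", np.char.zfill(np.arange(1, n + 1).astype(str), 7))
    dob = np.where(sentinel_mask, SENTINEL_DOB, dob)

    records = pd.DataFrame(
        {
            "record_id": record_id,
            "dob": dob,
            "gender": gender,
            "province": province,
            "city": city_name,
            "district": district_name,
        },
        columns=list(RECORD_COLUMNS),
    ).astype("string")
    records.loc[missing_mask, ["province", "city", "district"]] = pd.NA

    truth = pd.DataFrame({"record_id": record_id, "pad_code": pad_code, "zip": zips}).astype(
        "string"
    )
    return SyntheticBundle(records=records, gazetteer=gazetteer, truth=truth, config=config)


def _draw_dobs(config: PopulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    y0, y1 = config.dob_range
    start = np.datetime64(f"{y0}-01-01", "D")
    end = np.datetime64(f"{y1 + 1}-01-01", "D")
    if config.dob_model == "uniform_daily":
        span = int((end - start) / np.timedelta64(1, "D"))
        offsets = np.floor(rng.random(n) * span).astype(np.int64)
        dates = start + offsets
    else:
        years = np.arange(y0, y1 + 1)
        w = (
            np.asarray(config.year_weights, dtype=float)
            if config.year_weights is not None
            else np.ones(len(years), dtype=float)
        )
        if len(w) != len(years):
            raise ValueError("year_weights length must match the dob_range span")
        year = years[rng.choice(len(years), size=n, p=w / w.sum())]
        year_start = np.array([np.datetime64(f"{y}-01-01", "D") for y in years])[year - y0]
        year_len = (
            np.array([np.datetime64(f"{y + 1}-01-01", "D") for y in years])[year - y0] - year_start
        ).astype(np.int64)
        dates = year_start + np.floor(rng.random(n) * year_len).astype(np.int64)
    return np.datetime_as_string(dates, unit="D")


def scenario_presets() -> dict[str, PopulationConfig]:
    """Named configurations spanning unit-test to stress scale.

    * ``tiny`` — 1,000 patients; full pipeline in well under a second.
    * ``paper_like`` — 100,000 patients over 33 Zipf-weighted PADs and
      2,640 districts, daily DOBs across ~80 years: the default analysis
      scenario.
    * ``stress`` — 1,000,000 patients, same shape, for throughput checks.
    """
    return {
        "tiny": PopulationConfig(n_patients=1_000),
        "paper_like": PopulationConfig(n_patients=100_000),
        "stress": PopulationConfig(n_patients=1_000_000),
    }
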