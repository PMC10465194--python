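"""Reading, validation and writing of ringing-count and species-trait tables.

Count tables hold daily capture totals (individuals per day) for each species
across one spring season per calendar year.  Two CSV layouts are supported:

* ``long`` — columns ``year, date, species, count``, one row per record;
* ``wide`` — columns ``year, date, <species 1>, <species 2>, ...``, one row
  per sampling day.

Days on which no species has a record (nets closed for weather) are stored as
*missing-effort* days, not as zeros: a closed net says nothing about bird
passage.  In the wide layout a missing day is a row whose species cells are
all empty; in the long layout it is a calendar gap between the first and last
recorded day of the season.
"""

from __future__ import annotations

import datetime as dt
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "SeasonCounts",
    "WINTERING_AREAS",
    "FORAGING_NICHES",
    "normalize_species_name",
    "read_counts",
    "write_counts",
    "read_species_meta",
    "load_ponza_traits",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the format contract."""


#: closed vocabulary for the wintering-area factor
WINTERING_AREAS = ("NorthAfrica", "Sahel", "Tropical")

#: closed vocabulary for the foraging-niche factor
FORAGING_NICHES = (
    "invertivore glean arboreal",
    "invertivore ground",
    "invertivore sally air",
    "invertivore sally ground",
    "granivore ground",
    "omnivorous arboreal",
)

_WS = re.compile(r"\s+")


def normalize_species_name(name: str) -> str:
    """NFC-normalize and collapse internal whitespace of a scientific name."""
    return _WS.sub(" ", unicodedata.normalize("NFC", str(name)).strip())


def _normalize_category(value: str) -> str:
    return _WS.sub(" ", str(value).strip().casefold())


# accepted spellings -> canonical labels
_WINTERING_LOOKUP = {
    "northafrica": "NorthAfrica",
    "north africa": "NorthAfrica",
    "north african": "NorthAfrica",
    "sahel": "Sahel",
    "tropical": "Tropical",
}
_NICHE_LOOKUP = {_normalize_category(n): n for n in FORAGING_NICHES}


@dataclass(frozen=True)
class SeasonCounts:
    """One season's species-by-day matrix of capture counts.

    Parameters
    ----------
    year:
        Calendar year of the season.
    days:
        Complete daily grid of the season (strictly increasing, consecutive
        calendar dates).
    counts:
        Integer matrix of shape ``(n_species, n_days)``; cells on
        missing-effort days are zero placeholders and must be ignored
        downstream (see :attr:`effort_mask`).
    species:
        Ordered, unique scientific names matching the matrix rows.
    missing_days:
        Dates within ``days`` on which no trapping effort took place.
    """

    year: int
    days: tuple[dt.date, ...]
    counts: np.ndarray
    species: tuple[str, ...]
    missing_days: frozenset[dt.date] = frozenset()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "days", tuple(self.days))
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "missing_days", frozenset(self.missing_days))
        if counts.ndim != 2 or counts.shape != (len(self.species), len(self.days)):
            raise DataValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.species)} species x {len(self.days)} days"
            )
        if (counts < 0).any():
            raise DataValidationError("negative counts are not allowed")
        if len(set(self.species)) != len(self.species):
            raise DataValidationError("duplicate species identifiers")
        deltas = [(b - a).days for a, b in zip(self.days, self.days[1:])]
        if any(d <= 0 for d in deltas):
            raise DataValidationError("days must be strictly increasing")
        if any(d != 1 for d in deltas):
            raise DataValidationError(
                "days must form a consecutive daily grid; represent effort "
                "gaps via missing_days"
            )
        if not self.missing_days <= set(self.days):
            raise DataValidationError("missing_days must be a subset of days")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def effort_mask(self) -> np.ndarray:
        """Boolean vector over days; False on missing-effort days."""
        missing = self.missing_days
        return np.array([d not in missing for d in self.days], dtype=bool)

    @property
    def totals(self) -> np.ndarray:
        """Season total per species (effort days only)."""
        return self.counts[:, self.effort_mask].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Species x day DataFrame (dates as columns)."""
        return pd.DataFrame(
            self.counts, index=list(self.species), columns=list(self.days)
        )

    def series(self, species: str) -> np.ndarray:
        return self.counts[self.species.index(species)]


def _parse_dates(raw: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(raw, format="mixed", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        rows = [i + 2 for i in np.flatnonzero(bad.to_numpy())[:5]]  # 1-based + header
        raise DataValidationError(
            f"unparseable date(s) at CSV row(s) {rows}: "
            f"{raw[bad].unique()[:5].tolist()}"
        )
    return parsed.dt.date


def _season_from_records(year: int, recs: pd.DataFrame) -> SeasonCounts:
    """Dense season matrix from long records of one year.

    A calendar day inside the observed span with no record for *any* species
    is flagged as a missing-effort day; a day on which at least one species
    was recorded contributes zeros for the unrecorded species.
    """
    species = sorted({normalize_species_name(s) for s in recs["species"]})
    first, last = recs["date"].min(), recs["date"].max()
    days = [first + dt.timedelta(days=i) for i in range((last - first).days + 1)]
    observed = set(recs["date"])
    missing = frozenset(d for d in days if d not in observed)
    sp_idx = {s: i for i, s in enumerate(species)}
    day_idx = {d: j for j, d in enumerate(days)}
    counts = np.zeros((len(species), len(days)), dtype=np.int64)
    for sp, day, n in zip(recs["species"], recs["date"], recs["count"]):
        counts[sp_idx[normalize_species_name(sp)], day_idx[day]] = n
    return SeasonCounts(int(year), tuple(days), counts, tuple(species), missing)


def _read_counts_long(df: pd.DataFrame) -> list[SeasonCounts]:
    required = {"year", "date", "species", "count"}
    if not required <= set(df.columns):
        raise DataValidationError(
            f"long layout requires columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.copy()
    df["date"] = _parse_dates(df["date"])
    cnt = pd.to_numeric(df["count"], errors="coerce")
    bad = cnt.isna()
    if bad.any():
        rows = [i + 2 for i in np.flatnonzero(bad.to_numpy())[:5]]
        raise DataValidationError(f"non-numeric count(s) at CSV row(s) {rows}")
    if (cnt < 0).any():
        rows = [i + 2 for i in np.flatnonzero((cnt < 0).to_numpy())[:5]]
        raise DataValidationError(f"negative count(s) at CSV row(s) {rows}")
    df["count"] = cnt.round().astype(np.int64)
    df["species"] = df["species"].map(normalize_species_name)
    dup = df.duplicated(subset=["year", "date", "species"])
    if dup.any():
        rows = [i + 2 for i in np.flatnonzero(dup.to_numpy())[:5]]
        raise DataValidationError(
            f"duplicate (year, date, species) record(s) at CSV row(s) {rows}"
        )
    return [
        _season_from_records(year, recs)
        for year, recs in df.groupby("year", sort=True)
    ]


def _read_counts_wide(df: pd.DataFrame) -> list[SeasonCounts]:
    if not {"year", "date"} <= set(df.columns):
        raise DataValidationError(
            "wide layout requires leading 'year' and 'date' columns"
        )
    sp_cols = [c for c in df.columns if c not in ("year", "date")]
    if not sp_cols:
        raise DataValidationError("wide layout has no species columns")
    df = df.copy()
    df["date"] = _parse_dates(df["date"])
    seasons = []
    for year, block in df.groupby("year", sort=True):
        block = block.sort_values("date")
        if block["date"].duplicated().any():
            raise DataValidationError(f"duplicate date rows in year {year}")
        vals = block[sp_cols].apply(pd.to_numeric, errors="coerce")
        if (vals < 0).any().any():
            raise DataValidationError(f"negative count(s) in year {year}")
        first, last = block["date"].min(), block["date"].max()
        days = [first + dt.timedelta(days=i) for i in range((last - first).days + 1)]
        row_of = dict(zip(block["date"], range(len(block))))
        counts = np.zeros((len(sp_cols), len(days)), dtype=np.int64)
        missing = set()
        arr = vals.to_numpy(dtype=float)
        for j, d in enumerate(days):
            if d not in row_of:
                missing.add(d)  # absent row = no effort
                continue
            row = arr[row_of[d]]
            if np.isnan(row).all():
                missing.add(d)  # fully blank row = nets closed
            else:
                counts[:, j] = np.nan_to_num(row, nan=0.0).round().astype(np.int64)
        species = tuple(normalize_species_name(s) for s in sp_cols)
        seasons.append(
            SeasonCounts(int(year), tuple(days), counts, species, frozenset(missing))
        )
    return seasons


def read_counts(path: str | Path, layout: str = "long") -> list[SeasonCounts]:
    """Read a multi-year count CSV into one :class:`SeasonCounts` per year."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise DataValidationError(f"{path}: no count records")
    if layout == "long":
        return _read_counts_long(df)
    if layout == "wide":
        return _read_counts_wide(df)
    raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_counts(
    seasons: list[SeasonCounts], path: str | Path, layout: str = "long"
) -> None:
    """Write seasons to CSV.  Long layout emits one row per effort-day cell
    (zeros included, missing-effort days omitted); wide layout emits one row
    per grid day with blank cells on missing-effort days."""
    path = Path(path)
    if layout == "long":
        rows = []
        for sc in seasons:
            mask = sc.effort_mask
            for i, sp in enumerate(sc.species):
                for j, day in enumerate(sc.days):
                    if mask[j]:
                        rows.append((sc.year, day.isoformat(), sp, int(sc.counts[i, j])))
        pd.DataFrame(rows, columns=["year", "date", "species", "count"]).to_csv(
            path, index=False
        )
    elif layout == "wide":
        all_species = sorted({sp for sc in seasons for sp in sc.species})
        rows = []
        for sc in seasons:
            frame = sc.to_frame()
            for j, day in enumerate(sc.days):
                rec: dict[str, object] = {"year": sc.year, "date": day.isoformat()}
                if day in sc.missing_days:
                    rec.update({sp: np.nan for sp in all_species})
                else:
                    rec.update(
                        {
                            sp: int(frame.loc[sp, day]) if sp in sc.species else 0
                            for sp in all_species
                        }
                    )
                rows.append(rec)
        pd.DataFrame(rows, columns=["year", "date", *all_species]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_species_meta(
    path: str | Path, required_species: list[str] | None = None
) -> pd.DataFrame:
    """Read and validate the species-trait table.

    Returns a DataFrame indexed by species with canonical ``wintering_area``
    and ``foraging_niche`` columns.  Category strings are matched after
    case-folding and whitespace collapsing; unknown values are rejected by
    name, as are species present in the counts but absent here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise DataValidationError(f"{path}: no species records")
    required = {"species", "wintering_area", "foraging_niche"}
    if not required <= set(df.columns):
        raise DataValidationError(
            f"trait table requires columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.copy()
    df["species"] = df["species"].map(normalize_species_name)
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise DataValidationError(f"duplicate species in trait table: {dups}")

    def _wintering(v: str) -> str:
        key = _normalize_category(v)
        if key not in _WINTERING_LOOKUP:
            raise DataValidationError(
                f"unknown wintering_area value {v!r}; "
                f"expected one of {list(WINTERING_AREAS)}"
            )
        return _WINTERING_LOOKUP[key]

    def _niche(v: str) -> str:
        key = _normalize_category(v)
        if key not in _NICHE_LOOKUP:
            raise DataValidationError(
                f"unknown foraging_niche value {v!r}; "
                f"expected one of {list(FORAGING_NICHES)}"
            )
        return _NICHE_LOOKUP[key]

    df["wintering_area"] = df["wintering_area"].map(_wintering)
    df["foraging_niche"] = df["foraging_niche"].map(_niche)
    meta = df.set_index("species")[["wintering_area", "foraging_niche"]]
    if required_species is not None:
        missing = sorted(
            set(map(normalize_species_name, required_species)) - set(meta.index)
        )
        if missing:
            raise DataValidationError(
                f"species present in counts but absent from trait table: {missing}"
            )
    return meta


def load_ponza_traits() -> pd.DataFrame:
    """Trait table for the 31 focal species of the Ponza stopover study."""
    return read_species_meta(Path(__file__).parent / "data" / "ponza_species_traits.csv")
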