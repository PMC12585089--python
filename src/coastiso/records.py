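"""Record schema, I/O, and inclusion/classification rules.

The pipeline's atom is one georeferenced, dated δ¹³C/δ¹⁵N measurement
with a taxonomic identification.  Records are held as rows of a pandas
DataFrame inside a :class:`Dataset`; the Julian day of each record is
always recomputed against the dataset-wide earliest collection date
(the origin), never trusted from the input.

Inclusion rules
---------------
A row is kept only if it carries all six required metadata fields
(collection date, latitude, longitude, depth, both isotope values, and
a taxon name) and its isotope values fall inside a configurable sanity
envelope (δ¹³C in [−60, 0] ‰, δ¹⁵N in [−20, 40] ‰ by default).  Every
exclusion is counted and attributed to the rule that fired.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from coastiso.errors import EmptyDatasetError, UnmappedVocabularyError

#: input schema (CSV header); extra columns are preserved as provenance
REQUIRED_COLUMNS = ("date", "lat", "lon", "depth_m", "taxon", "d13C", "d15N")
SCHEMA_COLUMNS = (
    "date", "lat", "lon", "depth_m", "taxon", "phylum", "genus",
    "group", "habit", "d13C", "d15N", "treatment",
)

#: default isotope sanity envelope, ‰
D13C_ENVELOPE = (-60.0, 0.0)
D15N_ENVELOPE = (-20.0, 40.0)

CATEGORIES = ("end-member", "consumer")
FEEDING_HABITS = (
    "deposit_feeder", "suspension_feeder", "opportunist_scavenger",
    "predator", "none",
)
ENDMEMBER_CLASSES = (
    "pPOM", "sPOM", "iPOM", "macroalgae", "benthic_microalgae", "none",
)
COASTSCAPES = ("fjord", "lagoon", "shelf", "strait")


@dataclass(frozen=True)
class SectorBoundaries:
    """Ordered half-open longitude intervals partitioning [−180, 180].

    Each entry is ``(name, west, east)`` in degrees E; a longitude x is
    assigned to the interval with ``west <= x < east`` (the western
    bound is inclusive), except that the easternmost interval also
    includes its eastern bound so the partition is total on
    [−180, 180].
    """

    intervals: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        ivs = self.intervals
        if not ivs:
            raise ValueError("no sector intervals given")
        if ivs[0][1] != -180.0 or ivs[-1][2] != 180.0:
            raise ValueError("sector intervals must span [-180, 180]")
        for (_, _, e0), (_, w1, _) in zip(ivs, ivs[1:]):
            if e0 != w1:
                raise ValueError("sector intervals must abut with no gaps")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)

    def lookup(self, longitude: float) -> str:
        if not (-180.0 <= longitude <= 180.0) or not np.isfinite(longitude):
            raise ValueError(f"longitude {longitude} outside [-180, 180]")
        for name, west, east in self.intervals:
            if west <= longitude < east:
                return name
        return self.intervals[-1][0]  # longitude == 180


#: a-priori longitudinal sectors of the study region
DEFAULT_SECTORS = SectorBoundaries((
    ("Northern Bering/Chukchi Seas", -180.0, -157.0),
    ("Beaufort Sea", -157.0, -123.0),
    ("Canadian Arctic Archipelago", -123.0, -78.0),
    ("Baffin Bay", -78.0, -45.0),
    ("East Greenland", -45.0, 0.0),
    ("Svalbard", 0.0, 180.0),
))

#: sectors subject to the shallow-shelf depth rule
SHALLOW_SHELF_SECTORS = frozenset(
    {"Northern Bering/Chukchi Seas", "Beaufort Sea"}
)


@dataclass
class ExclusionReport:
    """Accounting of rows removed by a filtering stage."""

    frame: pd.DataFrame  # columns: record_id, rule_violated

    @property
    def n_excluded(self) -> int:
        return len(self.frame)

    def counts(self) -> pd.Series:
        return self.frame["rule_violated"].value_counts()

    def summary(self) -> str:
        if self.frame.empty:
            return "0 excluded"
        parts = [f"{n} excluded: {rule}" for rule, n in self.counts().items()]
        return "; ".join(parts)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class Dataset:
    """An ordered collection of isotope records with a shared origin date.

    ``frame`` carries one row per record, indexed by a unique
    ``record_id``.  ``origin_date`` always equals the minimum collection
    date across records; ``julian_day`` is derived from it on every
    load.
    """

    frame: pd.DataFrame
    origin_date: _dt.date
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.empty:
            raise EmptyDatasetError("dataset has zero records")
        if not self.frame.index.is_unique:
            raise ValueError("record_ids are not unique")
        dates = pd.to_datetime(self.frame["date"]).dt.date
        if dates.min() != self.origin_date:
            raise ValueError(
                "origin_date must equal the earliest collection date"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> pd.DataFrame:
        return self.frame

    def copy_with(self, frame: pd.DataFrame) -> "Dataset":
        """New Dataset from a row-subset, recomputing origin and days."""
        return from_frame(frame, provenance=list(self.provenance))


def _compute_julian_day(frame: pd.DataFrame, origin: _dt.date) -> pd.Series:
    days = (
        pd.to_datetime(frame["date"]) - pd.Timestamp(origin)
    ).dt.days.astype(int)
    return days


def from_frame(
    frame: pd.DataFrame, provenance: Sequence[str] | None = None
) -> Dataset:
    """Build a Dataset from an already-validated frame, setting the
    origin to the earliest collection date and recomputing julian_day."""
    if frame.empty:
        raise EmptyDatasetError("zero surviving records")
    origin = pd.to_datetime(frame["date"]).dt.date.min()
    frame = frame.copy()
    frame["julian_day"] = _compute_julian_day(frame, origin)
    return Dataset(frame=frame, origin_date=origin,
                   provenance=list(provenance or []))


def parse_records(
    source,
    d13c_envelope: tuple[float, float] = D13C_ENVELOPE,
    d15n_envelope: tuple[float, float] = D15N_ENVELOPE,
    provenance: Sequence[str] | None = None,
) -> tuple[Dataset, ExclusionReport]:
    """Read a delimited table of isotope records.

    Rows missing any required field, with an unparseable ISO-8601 date,
    or with isotope values outside the sanity envelope are excluded and
    reported.  Extra columns are carried through untouched.

    Parameters
    ----------
    source
        Path or file-like readable by :func:`pandas.read_csv`.
    d13c_envelope, d15n_envelope
        Inclusive (low, high) bounds in ‰ outside which a value is
        treated as physically implausible.

    Returns
    -------
    (Dataset, ExclusionReport)

    Raises
    ------
    EmptyDatasetError
        If no row survives.
    ValueError
        If a required column is absent from the header entirely.
    """
    raw = pd.read_csv(source, dtype={"date": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"input table lacks required columns: {missing_cols}")

    if "record_id" in raw.columns:
        raw = raw.set_index("record_id")
        if not raw.index.is_unique:
            raise ValueError("record_id column is not unique")
    else:
        raw.index = pd.Index(
            [f"r{i:06d}" for i in range(len(raw))], name="record_id"
        )

    exclusions: list[tuple[str, str]] = []
    keep = pd.Series(True, index=raw.index)

    for col in REQUIRED_COLUMNS:
        bad = raw[col].isna()
        if col in ("lat", "lon", "depth_m", "d13C", "d15N"):
            vals = pd.to_numeric(raw[col], errors="coerce")
            bad = bad | vals.isna()
            raw[col] = vals
        for rid in raw.index[bad & keep]:
            exclusions.append((rid, f"missing {col}"))
        keep &= ~bad

    # ISO-8601 dates only; other dialects must be pre-converted
    parsed_dates = pd.to_datetime(raw["date"], format="ISO8601",
                                  errors="coerce")
    bad = parsed_dates.isna()
    for rid in raw.index[bad & keep]:
        exclusions.append((rid, "unparseable date"))
    keep &= ~bad

    for col, (lo, hi), label in (
        ("d13C", d13c_envelope, "d13C outside sanity envelope"),
        ("d15N", d15n_envelope, "d15N outside sanity envelope"),
    ):
        bad = keep & ((raw[col] < lo) | (raw[col] > hi))
        for rid in raw.index[bad]:
            exclusions.append((rid, label))
        keep &= ~bad

    report = ExclusionReport(
        pd.DataFrame(exclusions, columns=["record_id", "rule_violated"])
    )
    surviving = raw.loc[keep].copy()
    if surviving.empty:
        raise EmptyDatasetError(
            f"zero surviving records ({report.summary()})"
        )
    surviving["date"] = parsed_dates.loc[keep].dt.date
    for col in ("phylum", "genus", "group", "habit", "treatment"):
        if col not in surviving.columns:
            surviving[col] = "none" if col == "treatment" else ""
    if "lipid_corrected" not in surviving.columns:
        surviving["lipid_corrected"] = False
    dataset = from_frame(surviving, provenance=provenance)
    return dataset, report


def write_records(dataset: Dataset, path) -> None:
    """Write a Dataset back to CSV in the input schema (plus derived
    columns), round-trippable through :func:`parse_records`."""
    out = dataset.frame.copy()
    out["date"] = out["date"].astype(str)
    out.to_csv(path, index=True, index_label="record_id")


def assign_sector(
    longitude: float, boundaries: SectorBoundaries = DEFAULT_SECTORS
) -> str:
    """Sector label for one longitude (degrees E, in [−180, 180])."""
    return boundaries.lookup(longitude)


def assign_sectors(
    dataset: Dataset, boundaries: SectorBoundaries = DEFAULT_SECTORS
) -> Dataset:
    """Return a Dataset with a ``sector`` column assigned from ``lon``."""
    frame = dataset.frame.copy()
    frame["sector"] = [boundaries.lookup(x) for x in frame["lon"]]
    return Dataset(frame=frame, origin_date=dataset.origin_date,
                   provenance=list(dataset.provenance))


def depth_filter(
    dataset: Dataset,
    max_shelf_depth: float = 45.0,
    retained_sites: Iterable[str] = (),
) -> tuple[Dataset, ExclusionReport]:
    """Drop deep collections from the shallow western shelf sectors.

    Records from the Northern Bering/Chukchi and Beaufort Sea sectors
    strictly deeper than ``max_shelf_depth`` (45 m by default) are
    removed.  Records whose id appears in ``retained_sites`` are kept
    regardless of depth — the allow-list stands in for the qualitative
    "close proximity to the coastline" exemption applied to some deep
    Svalbard and Canadian Archipelago shelf sites.  Records outside the
    two named sectors are never touched.
    """
    if "sector" not in dataset.frame.columns:
        raise ValueError("sectors must be assigned before depth filtering")
    retained = set(retained_sites)
    frame = dataset.frame
    violates = (
        frame["sector"].isin(SHALLOW_SHELF_SECTORS)
        & (frame["depth_m"] > max_shelf_depth)
        & ~frame.index.isin(retained)
    )
    report = ExclusionReport(pd.DataFrame(
        {"record_id": frame.index[violates],
         "rule_violated": f"depth > {max_shelf_depth} m on shallow shelf"}
    ))
    kept = frame.loc[~violates]
    if kept.empty:
        raise EmptyDatasetError("depth filter removed every record")
    # copy_with recomputes the origin in case the earliest record fell
    return dataset.copy_with(kept), report


def _load_vocab(filename: str, key: str, value: str) -> dict[str, str]:
    path = resources.files("coastiso.data") / filename
    with path.open() as fh:
        table = pd.read_csv(fh)
    return {
        str(k).strip().lower(): str(v)
        for k, v in zip(table[key], table[value])
    }


_FEEDING_MAP: dict[str, str] | None = None
_ENDMEMBER_MAP: dict[str, str] | None = None


def feeding_habit_vocabulary() -> Mapping[str, str]:
    global _FEEDING_MAP
    if _FEEDING_MAP is None:
        _FEEDING_MAP = _load_vocab(
            "feeding_habit_map.csv", "raw_habit", "feeding_habit")
    return _FEEDING_MAP


def endmember_vocabulary() -> Mapping[str, str]:
    global _ENDMEMBER_MAP
    if _ENDMEMBER_MAP is None:
        _ENDMEMBER_MAP = _load_vocab(
            "endmember_map.csv", "raw_label", "endmember_class")
    return _ENDMEMBER_MAP


def classify_feeding_habit(raw_habit: str) -> str:
    """Map a raw feeding-habit term to one of the four functional groups.

    Grazers and surface/subsurface deposit feeders fold into deposit
    feeders; filter feeders into suspension feeders; parasites, fish
    and mammals into predators; scavengers and omnivores into
    opportunist/scavengers.  Unknown terms raise rather than being
    coerced, to keep exclusion accounting exact.
    """
    key = str(raw_habit).strip().lower()
    vocab = feeding_habit_vocabulary()
    if key not in vocab:
        raise UnmappedVocabularyError(
            f"feeding habit {raw_habit!r} not in controlled vocabulary"
        )
    return vocab[key]


def synonymize_endmember(raw_label: str) -> str:
    """Map a raw end-member description to its canonical source pool
    (pPOM, sPOM, iPOM, macroalgae, or benthic_microalgae)."""
    key = str(raw_label).strip().lower()
    vocab = endmember_vocabulary()
    if key not in vocab:
        raise UnmappedVocabularyError(
            f"end-member label {raw_label!r} not in controlled vocabulary"
        )
    return vocab[key]


def harmonize_groups(dataset: Dataset) -> Dataset:
    """Populate ``feeding_habit`` and ``endmember_class`` columns.

    Consumers (``group == 'consumer'``) get a feeding habit from their
    raw ``habit`` term and ``endmember_class == 'none'``; end-members
    get the converse.  Any unmapped term raises.
    """
    frame = dataset.frame.copy()
    habits, classes = [], []
    for _, row in frame.iterrows():
        if str(row.get("group", "")) == "end-member":
            habits.append("none")
            classes.append(synonymize_endmember(row["habit"]))
        else:
            habits.append(classify_feeding_habit(row["habit"]))
            classes.append("none")
    frame["feeding_habit"] = habits
    frame["endmember_class"] = classes
    return Dataset(frame=frame, origin_date=dataset.origin_date,
                   provenance=list(dataset.provenance))
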