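"""Deterministic coastscape classification from physiographic features.

Arctic coastal sites are grouped into four habitat archetypes —
fjord, lagoon, shelf, strait — by eight ordinal physiographic
characteristics (barrier islands, enclosure by land, distance from
shore, glacial and riverine input, salinity regime, macroalgal
end-member availability).  The published characterization grades each
characteristic per archetype on a four-level qualitative scale
(almost always / often / often not / rarely); the original site
assignments were expert judgment, so this module provides a
reproducible additive proxy rather than a reconstruction.

Scoring scheme
--------------
The qualitative grades are encoded symmetrically as ``++ → +2``,
``+ → +1``, ``− → −1``, ``− − → −2``.  A site's feature vector marks
each characteristic present (+1), absent (−1) or unknown (0), and the
score of archetype *c* is the dot product of its weight column with
the site vector.  Unknown features contribute nothing; exact ties at
the top are surfaced as ``ambiguous`` rather than broken silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from coastiso.errors import UnscorableError

FEATURES = (
    "barrier_islands",
    "land_3_sides_sill",
    "two_land_two_outlets",
    "distant_from_land",
    "glacial_input",
    "riverine_input",
    "salinity_fluctuation",
    "macroalgal_endmember",
)
COASTSCAPES = ("fjord", "lagoon", "shelf", "strait")
FEATURE_STATES = ("present", "absent", "unknown")

_WEIGHT_CODE = {"++": 2, "+": 1, "-": -1, "--": -2}
_STATE_SIGN = {"present": 1, "absent": -1, "unknown": 0}


@dataclass(frozen=True)
class CoastscapeCall:
    """Classification outcome: best label, margin over the runner-up,
    and the full score vector."""

    label: str  # one of COASTSCAPES or "ambiguous"
    margin: float
    scores: dict[str, float]


def load_coastscape_profile() -> pd.DataFrame:
    """Packaged 8×4 weight grid (features × coastscapes), numeric."""
    path = resources.files("coastiso.data") / "coastscape_profile.csv"
    with path.open() as fh:
        grid = pd.read_csv(fh).set_index("feature")
    if tuple(grid.index) != FEATURES or tuple(grid.columns) != COASTSCAPES:
        raise ValueError("packaged coastscape profile grid is malformed")
    return grid.apply(lambda col: col.map(_WEIGHT_CODE)).astype(int)


_PROFILE: pd.DataFrame | None = None


def _profile() -> pd.DataFrame:
    global _PROFILE
    if _PROFILE is None:
        _PROFILE = load_coastscape_profile()
    return _PROFILE


def score_coastscape(
    features: dict[str, str], profiles: pd.DataFrame | None = None
) -> dict[str, float]:
    """Additive score of each coastscape for one site's feature vector.

    Parameters
    ----------
    features
        Mapping of feature name to ``present``/``absent``/``unknown``.
        Features not mentioned are treated as unknown.
    profiles
        Alternative weight grid (features × coastscapes); defaults to
        the packaged profile.

    Raises
    ------
    UnscorableError
        If every feature is unknown.
    ValueError
        On unrecognized feature names or states.
    """
    grid = profiles if profiles is not None else _profile()
    unknown_names = set(features) - set(FEATURES)
    if unknown_names:
        raise ValueError(f"unrecognized features: {sorted(unknown_names)}")
    signs = {}
    for f in FEATURES:
        state = features.get(f, "unknown")
        if state not in _STATE_SIGN:
            raise ValueError(f"feature {f!r} has invalid state {state!r}")
        signs[f] = _STATE_SIGN[state]
    if all(s == 0 for s in signs.values()):
        raise UnscorableError("all coastscape features unknown")
    return {
        c: float(sum(signs[f] * int(grid.at[f, c]) for f in FEATURES))
        for c in grid.columns
    }


def classify_coastscape(
    features: dict[str, str], profiles: pd.DataFrame | None = None
) -> CoastscapeCall:
    """Argmax coastscape with the margin (best − second best).

    An exact tie for the top score yields the label ``ambiguous`` with
    margin 0; ties are never broken arbitrarily because the original
    assignments were a-priori expert calls.
    """
    scores = score_coastscape(features, profiles)
    ordered = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
    (best, s1), (_, s2) = ordered[0], ordered[1]
    if s1 == s2:
        return CoastscapeCall("ambiguous", 0.0, scores)
    return CoastscapeCall(best, s1 - s2, scores)


def classify_site_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify a site×feature table (values present/absent/unknown).

    Returns a frame indexed like ``table`` with ``coastscape`` and
    ``margin`` columns plus one score column per archetype.
    """
    rows = []
    for _, row in table.iterrows():
        call = classify_coastscape(
            {f: row[f] for f in FEATURES if f in table.columns})
        rows.append({"coastscape": call.label, "margin": call.margin,
                     **{f"score_{c}": s for c, s in call.scores.items()}})
    return pd.DataFrame(rows, index=table.index)
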