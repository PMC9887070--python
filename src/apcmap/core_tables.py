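"""Domain types, file readers/writers, record filtering, and histology classification.

Registry data arrive as banded tables: one row per (sex, histology, area,
year, 5-year age group) with a case count, and a matching person-years
table. Everything downstream (rates, trends, the age-period-cohort grid,
the maps) consumes these two tables plus a set of area geometries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AgeGroup",
    "make_age_groups",
    "HistologyMap",
    "DEFAULT_HISTOLOGY_MAP",
    "FALLBACK_HISTOLOGY",
    "AreaGeometry",
    "read_incidence",
    "write_incidence",
    "read_person_years",
    "write_person_years",
    "read_geometries",
    "write_geometries",
    "classify_histology",
    "filter_topography",
    "validate_coverage",
]

INCIDENCE_COLUMNS = ["sex", "histology", "area_id", "year", "age_group", "count"]
PERSON_YEARS_COLUMNS = ["sex", "area_id", "year", "age_group", "person_years"]
INCIDENCE_KEY = ["sex", "histology", "area_id", "year", "age_group"]
PERSON_YEARS_KEY = ["sex", "area_id", "year", "age_group"]

FALLBACK_HISTOLOGY = "other specified or unspecified carcinoma"


class ConfigError(ValueError):
    """A required column, file, or configuration field is missing."""


class ValidationError(ValueError):
    """Input records violate a table invariant (e.g. negative counts)."""


@dataclass(frozen=True, order=True)
class AgeGroup:
    """One inclusive 5-year (or other width) age band.

    ``index`` is the 0-based ordinal of the band within its banding scheme;
    ``lower``/``upper`` are inclusive integer years, so a 30-34 band has
    midpoint 32.0.
    """

    index: int
    lower: int
    upper: int

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0

    @property
    def width(self) -> int:
        return self.upper - self.lower + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.lower}-{self.upper}"


def make_age_groups(lower: int, upper: int, width: int = 5) -> list[AgeGroup]:
    """Contiguous inclusive age bands covering [lower, upper].

    ``make_age_groups(30, 84)`` yields the eleven bands 30-34 ... 80-84.
    """
    if (upper - lower + 1) % width != 0:
        raise ConfigError(
            f"age range [{lower}, {upper}] is not divisible into {width}-year bands"
        )
    return [
        AgeGroup(index=i, lower=lo, upper=lo + width - 1)
        for i, lo in enumerate(range(lower, upper + 1, width))
    ]


# ---------------------------------------------------------------------------
# Histology classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistologyMap:
    """Ordered (morphology-code ranges -> label) rules with a fallback.

    Each rule is ``(label, ranges)`` where ``ranges`` is a tuple of
    inclusive ``(lo, hi)`` 4-digit ICD-O-3 morphology code intervals.
    The first matching rule wins; unmatched codes get ``fallback``.
    """

    rules: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    fallback: str = FALLBACK_HISTOLOGY

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for _, ranges in self.rules:
            for lo, hi in ranges:
                if lo > hi:
                    raise ConfigError(f"invalid morphology range ({lo}, {hi})")
                for slo, shi in seen:
                    if lo <= shi and slo <= hi:
                        raise ConfigError(
                            f"overlapping morphology ranges ({lo},{hi}) and ({slo},{shi})"
                        )
                seen.append((lo, hi))

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.rules] + [self.fallback]

    @classmethod
    def from_dict(cls, spec: dict, fallback: str = FALLBACK_HISTOLOGY) -> "HistologyMap":
        """Build from a config mapping label -> list of [lo, hi] ranges."""
        rules = tuple(
            (label, tuple((int(lo), int(hi)) for lo, hi in ranges))
            for label, ranges in spec.items()
        )
        return cls(rules=rules, fallback=fallback)


#: Default grouping of ICD-O-3 morphology codes into the five histological
#: types used for lung cancer. Standard groupings; fully overrideable from
#: config since registry practice varies in the allied-code tails.
DEFAULT_HISTOLOGY_MAP = HistologyMap(
    rules=(
        ("squamous cell carcinoma", ((8050, 8078), (8083, 8084))),
        ("small cell carcinoma", ((8041, 8045),)),
        (
            "adenocarcinoma",
            (
                (8140, 8147),
                (8250, 8260),
                (8310, 8310),
                (8323, 8323),
                (8480, 8490),
                (8550, 8574),
            ),
        ),
        ("large cell carcinoma", ((8012, 8014),)),
    ),
)


def classify_histology(morphology_code: int | str, hist_map: HistologyMap | None = None) -> str:
    """Map a 4-digit ICD-O-3 morphology code to a histology label.

    The first rule whose ranges contain the code wins; anything unmatched
    falls through to the map's fallback label, so the classification is
    total over 4-digit codes.
    """
    if hist_map is None:
        hist_map = DEFAULT_HISTOLOGY_MAP
    try:
        code = int(str(morphology_code).strip().split("/")[0])
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric morphology code: {morphology_code!r}") from exc
    for label, ranges in hist_map.rules:
        for lo, hi in ranges:
            if lo <= code <= hi:
                return label
    return hist_map.fallback


def filter_topography(records: pd.DataFrame, code_set: set[str]) -> pd.DataFrame:
    """Keep records whose topography matches a 3-character ICD-O site prefix.

    ``{"C33", "C34"}`` keeps C33, C34.1, C34.9 and so on; matching is by
    family prefix, mirroring ICD-O site groupings.
    """
    if not code_set:
        raise ConfigError("empty topography filter")
    if "topography" not in records.columns:
        raise ConfigError("records lack a 'topography' column")
    prefixes = tuple(str(c).strip().upper()[:3] for c in code_set)
    topo = records["topography"].astype(str).str.strip().str.upper().str[:3]
    kept = records[topo.isin(prefixes)].reset_index(drop=True)
    return kept


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path, required: list[str], key: list[str], value_col: str,
                nonneg_int: bool) -> pd.DataFrame:
    df = pd.read_csv(path)
    # Accept a raw morphology column in place of a pre-classified histology one.
    if "histology" in required and "histology" not in df.columns and "morphology" in df.columns:
        df = df.copy()
        df["histology"] = df["morphology"].map(classify_histology)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"missing required column(s): {', '.join(missing)}")
    df = df[required].copy()
    df["year"] = df["year"].astype(int)
    df["age_group"] = df["age_group"].astype(int)
    df["area_id"] = df["area_id"].astype(str)
    df["sex"] = df["sex"].astype(str)
    vals = pd.to_numeric(df[value_col], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        raise ValidationError(f"unparseable {value_col} in row(s) {list(bad[:10])}")
    neg = df.index[vals < 0]
    if len(neg):
        raise ValidationError(f"negative {value_col} in row(s) {list(neg[:10])}")
    df[value_col] = vals.astype(int) if nonneg_int else vals.astype(float)
    return df.groupby(key, as_index=False)[value_col].sum().sort_values(key).reset_index(drop=True)


def read_incidence(path) -> pd.DataFrame:
    """Read and aggregate an incidence CSV into a validated table.

    Rows sharing the (sex, histology, area_id, year, age_group) key are
    summed; negative or unparseable counts are a validation error.
    """
    return _read_table(path, INCIDENCE_COLUMNS, INCIDENCE_KEY, "count", nonneg_int=True)


def write_incidence(table: pd.DataFrame, path) -> None:
    table[INCIDENCE_COLUMNS].to_csv(path, index=False)


def read_person_years(path) -> pd.DataFrame:
    return _read_table(path, PERSON_YEARS_COLUMNS, PERSON_YEARS_KEY, "person_years",
                       nonneg_int=False)


def write_person_years(table: pd.DataFrame, path) -> None:
    table[PERSON_YEARS_COLUMNS].to_csv(path, index=False)


def validate_coverage(incidence: pd.DataFrame, person_years: pd.DataFrame) -> None:
    """Require person-years for every key present in the incidence table."""
    inc_keys = incidence[PERSON_YEARS_KEY].drop_duplicates()
    merged = inc_keys.merge(person_years[PERSON_YEARS_KEY].drop_duplicates(),
                            on=PERSON_YEARS_KEY, how="left", indicator=True)
    orphans = merged[merged["_merge"] == "left_only"]
    if len(orphans):
        example = orphans.iloc[0][PERSON_YEARS_KEY].to_dict()
        raise ValidationError(
            f"{len(orphans)} incidence key(s) lack person-years; first: {example}"
        )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class AreaGeometry:
    """One administrative area: id, planar polygon, centroid."""

    area_id: str
    polygon: BaseGeometry
    centroid: Point = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.centroid is None:
            self.centroid = self.polygon.centroid


def read_geometries(path) -> list[AreaGeometry]:
    """Read a GeoJSON FeatureCollection with an ``area_id`` property per feature."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ConfigError(f"{path}: not a GeoJSON FeatureCollection")
    out: list[AreaGeometry] = []
    seen: set[str] = set()
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise ConfigError(f"{path}: feature missing 'area_id' property")
        aid = str(props["area_id"])
        if aid in seen:
            raise ValidationError(f"duplicate geometry for area {aid}")
        seen.add(aid)
        out.append(AreaGeometry(area_id=aid, polygon=shape(feat["geometry"])))
    return out


def write_geometries(geoms: list[AreaGeometry], path, crs: str | None = None) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"area_id": g.area_id},
            "geometry": json.loads(json.dumps(g.polygon.__geo_interface__)),
        }
        for g in geoms
    ]
    gj: dict = {"type": "FeatureCollection", "features": features}
    if crs:
        gj["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(gj, fh)
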