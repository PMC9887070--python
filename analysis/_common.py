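"""Shared paths and loading for the numbered analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"
FIGURES = ROOT / "results" / "figures"

SEED = 1
STRATA = [
    {"sex": "male", "histology": "adenocarcinoma"},
    {"sex": "female", "histology": "adenocarcinoma"},
    {"sex": "male", "histology": "squamous cell carcinoma"},
    {"sex": "female", "histology": "squamous cell carcinoma"},
]


def ensure_dirs() -> None:
    for p in (DATA, TABLES, FIGURES):
        p.mkdir(parents=True, exist_ok=True)


def load_registry():
    from apcmap.core_tables import (read_geometries, read_incidence,
                                    read_person_years)
    inc = read_incidence(DATA / "incidence.csv")
    py = read_person_years(DATA / "person_years.csv")
    geoms = read_geometries(DATA / "areas.geojson")
    return inc, py, geoms
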