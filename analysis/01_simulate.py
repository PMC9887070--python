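"""Draw the default synthetic registry and write its input files.

The scenario emulates a national registry: 306 administrative areas on a
unit grid, years 1997-2017, eleven 5-year age bands (30-84), two sexes,
an adenocarcinoma-like stratum rising ~4-5.5%/yr and a squamous-like
stratum falling ~1-3.5%/yr, each with a spatially correlated log-relative-
risk field. The ground truth (spatial fields, true per-area AAPC and SIR)
is saved alongside so later stages can be scored against it.
"""

import json

from _common import DATA, SEED, ensure_dirs

from apcmap.core_tables import (write_geometries, write_incidence,
                                write_person_years)
from apcmap.synthetic import default_config, generate_registry


def main() -> None:
    ensure_dirs()
    cfg = default_config(seed=SEED)
    incidence, person_years, geoms, truth = generate_registry(cfg)
    write_incidence(incidence, DATA / "incidence.csv")
    write_person_years(person_years, DATA / "person_years.csv")
    write_geometries(geoms, DATA / "areas.geojson")
    slim = {
        "area_ids": truth["area_ids"],
        "strata": {f"{s}|{h}": {
            "u": t["u"].tolist(),
            "true_aapc": t["true_aapc"].tolist(),
            "true_sir": t["true_sir"].tolist(),
        } for (s, h), t in truth["strata"].items()},
    }
    (DATA / "truth.json").write_text(json.dumps(slim))
    print(f"wrote {len(incidence)} incidence rows, "
          f"{len(person_years)} person-year rows, "
          f"{len(geoms)} areas -> {DATA}")
    print(f"total cases: {incidence['count'].sum():,}")


if __name__ == "__main__":
    main()
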