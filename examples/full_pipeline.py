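"""The whole chain under one config: brightness raster -> zonal statistics
-> model selection -> municipal prediction -> large-city filter -> spatial
autocorrelation -> correlation matrix.

Builds a two-level synthetic map (4x4 provinces tiled by 8x8 cities), writes
the three input files, and runs the pipeline, which leaves every artifact as
CSV plus a provenance record in the output directory.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from lightodr import (
    RunConfig,
    generate_dn_raster,
    generate_lattice_zones,
    generate_sigmoid_odr,
    mask_extract,
    run_pipeline,
    write_ascii_grid,
    write_zones_geojson,
    zonal_stats,
)

out = Path(tempfile.mkdtemp(prefix="lightodr_"))
provinces = generate_lattice_zones(4, 4, cell_size=1.0, level="province")
cities = generate_lattice_zones(8, 8, cell_size=0.5, level="city")
rng = np.random.default_rng(1)
intensity = dict(zip(provinces.zone_ids, rng.uniform(10, 60, len(provinces))))
raster = generate_dn_raster(provinces, intensity, pixels_per_zone=6400, seed=1)
write_ascii_grid(raster, out / "raster.asc")
write_zones_geojson(provinces, out / "provinces.geojson")
write_zones_geojson(cities, out / "cities.geojson")

stats = zonal_stats(raster, mask_extract(raster, provinces))
x = np.array([s.sum_dn for s in stats], dtype=float)
rows = []
for i, year in enumerate(("2019", "2020")):
    odr = generate_sigmoid_odr(x, noise_sd=0.05, seed=10 + i)
    rows += [{"zone_id": s.zone_id, "year": year, "odr": o}
             for s, o in zip(stats, odr)]
pd.DataFrame(rows).to_csv(out / "odr.csv", index=False)

config = RunConfig(
    raster_path=str(out / "raster.asc"),
    province_zones_path=str(out / "provinces.geojson"),
    city_zones_path=str(out / "cities.geojson"),
    odr_path=str(out / "odr.csv"),
    out_dir=str(out / "run"),
    odr_min=10.0,        # thresholds scaled to the synthetic brightness
    sum_min=30_000.0,
    seed=1,
)
result = run_pipeline(config)

gm_analytic, gm_perm = result["global_moran"]
print(f"selected model:          {result['selected_model']}")
print(f"cities predicted:        {len(result['predictions'])}")
print(f"pass the filter:         {len(result['filtered'])}")
print(f"global Moran's I:        {gm_analytic.I:.4f} "
      f"(z = {gm_analytic.z:.2f}, permutation p = {gm_perm.pseudo_p:.4f})")
print(f"r(ODR, SUM of DN):       {result['correlations'].r.loc['odr_pred', 'sum_dn']:.3f}")
print(f"artifacts in:            {result['out_dir']}")
# Predictions inherit the provinces' blocky brightness pattern, so the
# municipal ODR shows strong positive spatial autocorrelation — the same
# qualitative structure the method reports on real Chinese cities.
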