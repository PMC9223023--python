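"""End-to-end orchestration: brightness -> model selection -> prediction ->
large-city filter -> spatial autocorrelation -> correlation matrix.

A single :class:`RunConfig` drives the whole chain and every artifact is
written as CSV with fixed headers plus a JSON provenance record, so reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import curves, spatial, zones as zones_mod
from .raster import read_ascii_grid
from .zones import mask_extract, zonal_stats, zonal_stats_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "correlation_matrix", "CorrelationMatrix"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    raster_path: str
    province_zones_path: str
    city_zones_path: str
    odr_path: str                       # CSV zone_id,year,odr (province level)
    out_dir: str = "lightodr_run"
    zone_id_field: str = "zone_id"
    raster_crs: str = "lonlat"
    years: list = None                  # default: all years in the ODR table
    models: list = field(default_factory=lambda: list(curves.MODEL_NAMES))
    odr_min: float = 13.71
    sum_min: float = 115_762.0
    weights_standardization: str = "row"
    n_perm: int = 999
    seed: int = 0
    extra_city_columns: str = None      # optional CSV zone_id,<var>,... to correlate

    def __post_init__(self):
        if self.n_perm < 99:
            raise ValueError("permutation count must be >= 99")
        for name in ("odr_min", "sum_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with 0.01-level two-sided flags."""

    variables: list
    r: pd.DataFrame
    significant_01: pd.DataFrame
    n_used: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.r.round(3).astype(object)
        for a in self.variables:
            for b in self.variables:
                if a != b and bool(self.significant_01.loc[a, b]):
                    out.loc[a, b] = f"{self.r.loc[a, b]:.3f} **"
        return out


def correlation_matrix(columns: dict) -> CorrelationMatrix:
    """Pairwise Pearson r over named per-unit value lists.

    Each pair is correlated on its complete cases (the n used is reported
    per cell). A constant column yields undefined r, reported as NaN.
    Significance flags mark two-sided t-test p <= 0.01.
    """
    names = list(columns.keys())
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    if len(df.dropna()) < 3:
        raise ValueError("need at least 3 complete rows")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    sig = pd.DataFrame(False, index=names, columns=names)
    nn = pd.DataFrame(len(df), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sub = df[[a, b]].dropna()
            nn.loc[a, b] = nn.loc[b, a] = len(sub)
            if len(sub) < 3 or sub[a].nunique() == 1 or sub[b].nunique() == 1:
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rr, p = sps.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rr
            sig.loc[a, b] = sig.loc[b, a] = bool(p <= 0.01)
    return CorrelationMatrix(names, r, sig, nn)


def _load_inputs(config: RunConfig):
    for name in ("raster_path", "province_zones_path", "city_zones_path", "odr_path"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name}: {p}")
    raster = read_ascii_grid(config.raster_path, crs=config.raster_crs)
    provinces = zones_mod.read_zones_geojson(
        config.province_zones_path, config.zone_id_field, level="province")
    cities = zones_mod.read_zones_geojson(
        config.city_zones_path, config.zone_id_field, level="city")
    odr = pd.read_csv(config.odr_path, dtype={"zone_id": str})
    return raster, provinces, cities, odr


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write artifacts under ``config.out_dir``.

    Outputs: zonal_stats.csv, model_comparison.csv, predictions.csv,
    filtered_cities.csv, global_moran.csv, local_moran.csv, gistar.csv,
    correlations.csv, weights.gal and provenance.json. Returns the artifact
    paths plus the in-memory results. On failure, partial outputs from this
    run are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise


def _run(config, out, written):
    raster, provinces, cities, odr = _load_inputs(config)

    def save(df: pd.DataFrame, name: str) -> str:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        return str(path)

    # 1. zonal statistics at both levels
    prov_stats = zonal_stats(raster, mask_extract(raster, provinces))
    city_stats = zonal_stats(raster, mask_extract(raster, cities))
    stats_df = pd.concat([
        zonal_stats_frame(prov_stats, level="province"),
        zonal_stats_frame(city_stats, level="city"),
    ], ignore_index=True)
    save(stats_df, "zonal_stats.csv")

    # 2. provincial model comparison across years
    prov_sum = {s.zone_id: s.sum_dn for s in prov_stats}
    years = config.years or sorted(odr["year"].astype(str).unique())
    series = {}
    for year in years:
        sub = odr[odr["year"].astype(str) == str(year)]
        pts = [(prov_sum[z], o) for z, o in zip(sub["zone_id"], sub["odr"])
               if z in prov_sum]
        if len(pts) >= 4:
            series[str(year)] = pts
    if not series:
        raise ValueError("no year has enough provinces with both ODR and brightness")
    comparison = curves.compare_models(series, config.models)
    comp_df = comparison.table.reset_index(names="model")
    save(comp_df, "model_comparison.csv")
    best = comparison.best_model
    logger.info("selected model by mean R^2: %s", best)

    # 3. fit the selected model on the most recent year; predict cities
    fit_year = sorted(series.keys())[-1]
    fit = curves.fit_curve_model(series[fit_year], best)
    city_x = {s.zone_id: s.sum_dn for s in city_stats}
    pred_rows = [(zid, x, float(curves.predict_curve(fit, x)))
                 for zid, x in city_x.items() if x > 0]
    pred_df = pd.DataFrame(pred_rows, columns=["zone_id", "sum_dn", "odr_pred"])
    save(pred_df, "predictions.csv")

    # 4. large-city filter
    filtered = curves.filter_large_cities(
        list(pred_df.itertuples(index=False, name=None)),
        odr_min=config.odr_min, sum_min=config.sum_min)
    filt_df = pd.DataFrame(filtered, columns=["zone_id", "sum_dn", "odr_pred"])
    save(filt_df, "filtered_cities.csv")

    # 5. spatial autocorrelation of the predicted municipal ODR
    # (restricted to cities that received a prediction; zones without
    # effective pixels were already logged and dropped upstream)
    have = set(pred_df["zone_id"])
    keep = [i for i, z in enumerate(cities.zone_ids) if z in have]
    sub_cities = zones_mod.ZonePolygons(
        [cities.zone_ids[i] for i in keep],
        [cities.geometries[i] for i in keep], level="city")
    w = spatial.build_queen_weights(sub_cities)
    gal_path = out / "weights.gal"
    spatial.write_gal(w, gal_path)
    written.append(gal_path)
    wrow = w.row_standardized() if config.weights_standardization == "row" else w
    x = pred_df.set_index("zone_id").loc[list(sub_cities.zone_ids), "odr_pred"].to_numpy()
    gm_analytic = spatial.global_moran(x, wrow, inference="randomization")
    gm_perm = spatial.global_moran(x, wrow, inference="permutation",
                                   n_perm=config.n_perm, seed=config.seed)
    gm_df = pd.DataFrame([
        {"inference": g.inference, "I": g.I, "expectation": g.expectation,
         "variance": g.variance, "z": g.z, "p": g.pseudo_p,
         "n_perm": g.n_permutations}
        for g in (gm_analytic, gm_perm)
    ])
    save(gm_df, "global_moran.csv")

    lisa = spatial.local_moran(x, wrow, n_perm=config.n_perm, seed=config.seed)
    lisa_df = pd.DataFrame([
        {"unit_id": r.unit_id, "stat": r.Ii, "z": r.zi, "p": r.pseudo_p,
         "label": r.quadrant, "significant": r.significant, "island": r.island}
        for r in lisa
    ])
    save(lisa_df, "local_moran.csv")

    gi = spatial.getis_ord_gistar(x, w)
    gi_df = pd.DataFrame([
        {"unit_id": r.unit_id, "stat": r.gi_star, "z": r.gi_star,
         "p": "", "label": r.cls} for r in gi
    ])
    save(gi_df, "gistar.csv")

    # 6. correlation matrix: predicted ODR vs brightness (+ optional extras)
    pix = pred_df.set_index("zone_id").loc[list(sub_cities.zone_ids)]
    cols = {"odr_pred": pix["odr_pred"], "sum_dn": pix["sum_dn"]}
    if config.extra_city_columns:
        extra = pd.read_csv(config.extra_city_columns, dtype={"zone_id": str})
        extra = extra.set_index("zone_id").reindex(list(sub_cities.zone_ids))
        for c in extra.columns:
            cols[c] = extra[c].to_numpy(dtype=float)
    corr = correlation_matrix({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    corr_df = corr.r.reset_index(names="variable")
    save(corr_df, "correlations.csv")

    # 7. provenance
    import lightodr
    prov = {
        "package_version": lightodr.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": asdict(config),
        "selected_model": best,
        "fit_year": fit_year,
        "n_provinces": len(prov_stats),
        "n_cities": len(city_stats),
        "n_filtered": len(filt_df),
    }
    prov_path = out / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
    written.append(prov_path)

    return {
        "out_dir": str(out),
        "selected_model": best,
        "fit": fit,
        "comparison": comparison,
        "predictions": pred_df,
        "filtered": filt_df,
        "global_moran": (gm_analytic, gm_perm),
        "local_moran": lisa,
        "gistar": gi,
        "correlations": corr,
    }
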