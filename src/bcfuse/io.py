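"""Readers and writers for the artifact's external formats.

Everything round-trips through plain text: drive logs, sensor series and
maps as delimited text, road segments as GeoJSON, factor models and fusion
bundles as directories of delimited matrices with a JSON manifest.
Timestamps are written ISO-8601; tz-aware inputs are converted to a local
zone and made naive, because all downstream time semantics (day/night,
weekday/weekend, bin edges) are local-clock.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from bcfuse.factorization import FactorModel
from bcfuse.fusion import BCField, FusionModel
from bcfuse.kriging import VariogramModel
from bcfuse.mobile import RoadSegment, SegmentConcentrationMap
from bcfuse.sensors import SensorMatrix

__all__ = [
    "read_drive_log", "write_drive_log",
    "read_segments_geojson", "write_segments_geojson",
    "read_sensor_raw", "write_sensor_raw",
    "read_sites", "write_sites",
    "read_segment_map", "write_segment_map",
    "read_sensor_matrix", "write_sensor_matrix",
    "read_factor_model", "write_factor_model",
    "write_bc_field", "read_bc_field",
    "write_fusion_bundle",
    "write_variograms",
]


def _localize(ts: pd.Series, tz: str | None) -> pd.Series:
    out = pd.to_datetime(ts, format="ISO8601")
    if getattr(out.dt, "tz", None) is not None:
        out = out.dt.tz_convert(tz) if tz else out.dt.tz_localize(None)
        if tz:
            out = out.dt.tz_localize(None)
    return out


def read_drive_log(path, tz: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"timestamp", "vehicle_id", "x", "y"}
    if missing := required - set(df.columns):
        raise ValueError(f"drive log {path}: missing columns {sorted(missing)}")
    df["timestamp"] = _localize(df["timestamp"], tz)
    return df


def write_drive_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_segments_geojson(path) -> list[RoadSegment]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    segments = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "segment_id" not in props:
            raise ValueError(f"{path}: feature without a segment_id property")
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: segment {props['segment_id']} is not a LineString")
        segments.append(RoadSegment(segment_id=str(props["segment_id"]), geometry=geom))
    return segments


def write_segments_geojson(segments: list[RoadSegment], path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"segment_id": s.segment_id},
            "geometry": mapping(s.geometry),
        }
        for s in segments
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_sensor_raw(path, tz: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"site_id", "timestamp", "bc_ugm3"}
    if missing := required - set(df.columns):
        raise ValueError(f"sensor series {path}: missing columns {sorted(missing)}")
    df["timestamp"] = _localize(df["timestamp"], tz)
    return df


def write_sensor_raw(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if missing := {"site_id", "x", "y"} - set(df.columns):
        raise ValueError(f"site table {path}: missing columns {sorted(missing)}")
    return df


def write_sites(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_segment_map(seg_map: SegmentConcentrationMap, path) -> None:
    df = pd.DataFrame(seg_map.values.T, columns=seg_map.pollutants)
    df.insert(0, "location_id", seg_map.locations)
    if seg_map.coords is not None:
        df.insert(1, "x", seg_map.coords[:, 0])
        df.insert(2, "y", seg_map.coords[:, 1])
    df["visit_count"] = seg_map.visit_counts
    df.to_csv(path, index=False)


def read_segment_map(path) -> SegmentConcentrationMap:
    df = pd.read_csv(path)
    meta = [c for c in ("location_id", "x", "y", "visit_count") if c in df.columns]
    if "location_id" not in meta or "visit_count" not in meta:
        raise ValueError(f"map {path}: needs location_id and visit_count columns")
    pollutants = [c for c in df.columns if c not in meta]
    coords = df[["x", "y"]].to_numpy() if "x" in df.columns else None
    return SegmentConcentrationMap(
        pollutants=pollutants,
        locations=[str(v) for v in df["location_id"]],
        values=df[pollutants].to_numpy().T,
        visit_counts=df["visit_count"].to_numpy(),
        coords=coords,
    )


def write_sensor_matrix(matrix: SensorMatrix, prefix) -> None:
    prefix = Path(prefix)
    cols = [t.isoformat() for t in matrix.time_bins]
    pd.DataFrame(matrix.values, index=matrix.sites, columns=cols).to_csv(
        prefix.with_name(prefix.name + "_values.csv"), index_label="site_id"
    )
    pd.DataFrame(matrix.observed_mask.astype(int), index=matrix.sites, columns=cols).to_csv(
        prefix.with_name(prefix.name + "_mask.csv"), index_label="site_id"
    )
    meta = {
        "bin_width": matrix.bin_width,
        "imputed_fraction": dict(zip(matrix.sites, matrix.imputed_fraction.tolist())),
    }
    prefix.with_name(prefix.name + "_meta.json").write_text(json.dumps(meta, indent=2))


def read_sensor_matrix(prefix) -> SensorMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_name(prefix.name + "_values.csv"), index_col="site_id")
    mask = pd.read_csv(prefix.with_name(prefix.name + "_mask.csv"), index_col="site_id")
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    sites = [str(s) for s in values.index]
    return SensorMatrix(
        sites=sites,
        time_bins=pd.DatetimeIndex([pd.Timestamp(c) for c in values.columns]),
        bin_width=int(meta["bin_width"]),
        values=values.to_numpy(),
        observed_mask=mask.to_numpy().astype(bool),
        imputed_fraction=np.array([meta["imputed_fraction"][s] for s in sites]),
    )


def write_factor_model(model: FactorModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "left.csv", model.left, delimiter=",")
    np.savetxt(directory / "right.csv", model.right, delimiter=",")
    meta = {
        "rank": model.rank,
        "seed": model.seed,
        "converged": model.converged,
        "objective_trace": model.objective_trace.tolist(),
    }
    (directory / "meta.json").write_text(json.dumps(meta))


def read_factor_model(directory) -> FactorModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    left = np.loadtxt(directory / "left.csv", delimiter=",", ndmin=2)
    right = np.loadtxt(directory / "right.csv", delimiter=",", ndmin=2)
    model = FactorModel(
        left=left,
        right=right,
        rank=int(meta["rank"]),
        objective_trace=np.asarray(meta["objective_trace"]),
        seed=int(meta["seed"]),
        converged=bool(meta["converged"]),
    )
    object.__setattr__(model, "input_norm", float("nan"))
    return model


def write_bc_field(bc_field: BCField, path) -> None:
    cols = [t.isoformat() for t in bc_field.time_bins]
    pd.DataFrame(bc_field.values, index=bc_field.location_order, columns=cols).to_csv(
        path, index_label="location_id"
    )


def read_bc_field(path) -> BCField:
    df = pd.read_csv(path, index_col="location_id")
    return BCField(
        values=df.to_numpy(),
        location_order=[str(i) for i in df.index],
        time_bins=pd.DatetimeIndex([pd.Timestamp(c) for c in df.columns]),
    )


def write_variograms(variograms: dict[str, VariogramModel], path) -> None:
    payload = {
        pol: {"kind": v.kind, "nugget": v.nugget, "partial_sill": v.partial_sill, "range": v.range_}
        for pol, v in variograms.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_fusion_bundle(model: FusionModel, directory) -> None:
    """Serialize a fusion run as a directory with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_segment_map(model.segment_map, directory / "extended_map.csv")
    if model.pollutant_model is not None:
        write_factor_model(model.pollutant_model, directory / "pollutant_factors")
    if model.sensor_model is not None:
        write_factor_model(model.sensor_model, directory / "sensor_factors")
    np.savetxt(directory / "coefficients.csv", model.coefficients.matrix, delimiter=",")
    write_bc_field(model.bc_field, directory / "bc_field.csv")
    if model.variograms:
        write_variograms(model.variograms, directory / "variograms.json")
    manifest = {
        "k": model.k,
        "q": model.q,
        "rcond": model.coefficients.rcond,
        "effective_rank": model.coefficients.effective_rank,
        "reprojection_residual": model.coefficients.residual_norm,
        "sites": model.phi.site_order,
        "n_locations": len(model.phi.location_order),
        "n_clipped_field_values": model.bc_field.n_clipped,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
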