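"""Plain-text I/O: CSV sample tables, nodal map CSVs, JSON sidecars.

Column conventions
------------------
``egm.csv``       x_mm, y_mm, z_mm, bipolar_mV, lat_ms, true_class
``pace.csv``      x_mm, y_mm, z_mm, captured, s_qrs_ms, true_class
``landmarks.csv`` src_x, src_y, src_z, dst_x, dst_y, dst_z
node map CSV      vertex_id, value, known

Missing values (uncaptured S-QRS, absent LAT, unknown truth class) are
empty cells.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .eam import EgmSample, PaceSite
from .mesh import NodeBinaryMap, NodeScalarMap
from .transforms import LandmarkSet, RigidTransform


def write_egm_csv(samples: list[EgmSample], path) -> None:
    rows = [{"x_mm": s.position[0], "y_mm": s.position[1], "z_mm": s.position[2],
             "bipolar_mV": s.bipolar_mV, "lat_ms": s.lat_ms, "true_class": s.true_class}
            for s in samples]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_egm_csv(path) -> list[EgmSample]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        lat = None if ("lat_ms" not in df or pd.isna(r.get("lat_ms"))) else float(r["lat_ms"])
        tc = None if ("true_class" not in df or pd.isna(r.get("true_class"))) else int(r["true_class"])
        out.append(EgmSample(np.array([r["x_mm"], r["y_mm"], r["z_mm"]]),
                             float(r["bipolar_mV"]), lat_ms=lat, true_class=tc))
    return out


def write_pace_csv(sites: list[PaceSite], path) -> None:
    rows = [{"x_mm": s.position[0], "y_mm": s.position[1], "z_mm": s.position[2],
             "captured": int(s.captured), "s_qrs_ms": s.s_qrs_ms, "true_class": s.true_class}
            for s in sites]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pace_csv(path) -> list[PaceSite]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        cap = bool(int(r["captured"]))
        sq = float(r["s_qrs_ms"]) if cap and not pd.isna(r.get("s_qrs_ms")) else None
        tc = None if ("true_class" not in df or pd.isna(r.get("true_class"))) else int(r["true_class"])
        out.append(PaceSite(np.array([r["x_mm"], r["y_mm"], r["z_mm"]]),
                            cap, s_qrs_ms=sq, true_class=tc))
    return out


def write_landmarks_csv(landmarks: LandmarkSet, path) -> None:
    df = pd.DataFrame(np.hstack([landmarks.source, landmarks.destination]),
                      columns=["src_x", "src_y", "src_z", "dst_x", "dst_y", "dst_z"])
    df.to_csv(path, index=False)


def read_landmarks_csv(path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(df[["src_x", "src_y", "src_z"]].to_numpy(),
                       df[["dst_x", "dst_y", "dst_z"]].to_numpy())


def write_node_map_csv(node_map, path) -> None:
    if isinstance(node_map, NodeBinaryMap):
        df = pd.DataFrame({"vertex_id": np.arange(len(node_map)),
                           "value": node_map.labels.astype(int),
                           "known": 1})
    else:
        df = pd.DataFrame({"vertex_id": np.arange(len(node_map.values)),
                           "value": node_map.values,
                           "known": node_map.known.astype(int)})
    df.to_csv(path, index=False, float_format="%.12g")


def read_node_scalar_csv(path) -> NodeScalarMap:
    df = pd.read_csv(path).sort_values("vertex_id")
    return NodeScalarMap(df["value"].to_numpy(float), df["known"].to_numpy(bool))


def read_node_binary_csv(path) -> NodeBinaryMap:
    df = pd.read_csv(path).sort_values("vertex_id")
    return NodeBinaryMap(df["value"].to_numpy(int))


def write_transform_json(transform: RigidTransform, path, extra: dict | None = None) -> None:
    doc = transform.to_dict()
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_transform_json(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
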