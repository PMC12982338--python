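"""File dialects: mesh CSV, displacement HDF5/CSV, embedding and report tables.

Documented dialects
-------------------
nodes.csv        columns ``id,x,y,z`` (mm)
elements.csv     columns ``id,n1..n8,part`` (node ids refer to nodes.csv)
displacements    HDF5 with datasets ``times`` (s) and
                 ``displacements[t, node, 3]`` (mm), or long CSV with
                 columns ``time,node,ux,uy,uz``
embedding table  HDF5/CSV with ``beam_node,element,xi1,xi2,xi3``
marker histories CSV with ``time,marker,ux,uy,uz``
cluster          JSON with ``markers`` (id -> [x,y,z]), ``tets`` (lists of 4
                 marker ids) and optional ``excluded`` tet indices

Times may be given in ms (``time_unit="ms"``); they are normalized to
seconds at ingest.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .cluster import ClusterDefinition
from .embedding import EmbeddedFiberSet
from .mesh import DisplacementHistory, HexMesh

__all__ = [
    "read_mesh_csv",
    "write_mesh_csv",
    "read_displacements_h5",
    "write_displacements_h5",
    "read_displacements_csv",
    "write_embedding",
    "read_embedding_table",
    "write_strain_history_h5",
    "write_peak_summary_csv",
    "read_cluster_json",
    "write_cluster_json",
    "read_marker_histories_csv",
]

_TIME_SCALE = {"s": 1.0, "ms": 1e-3}


def _time_factor(time_unit: str) -> float:
    try:
        return _TIME_SCALE[time_unit]
    except KeyError:
        raise ValueError(f"time_unit must be one of {sorted(_TIME_SCALE)}") from None


# ---------------------------------------------------------------------------
# mesh

def read_mesh_csv(nodes_path, elements_path) -> HexMesh:
    nodes = pd.read_csv(nodes_path)
    elems = pd.read_csv(elements_path)
    need_n = {"id", "x", "y", "z"}
    need_e = {"id", "part"} | {f"n{i}" for i in range(1, 9)}
    if not need_n <= set(nodes.columns):
        raise ValueError(f"nodes file needs columns {sorted(need_n)}")
    if not need_e <= set(elems.columns):
        raise ValueError(f"elements file needs columns {sorted(need_e)}")
    node_ids = nodes["id"].to_numpy(dtype=np.int64)
    index = {nid: i for i, nid in enumerate(node_ids)}
    conn = np.array(
        [[index[v] for v in row]
         for row in elems[[f"n{i}" for i in range(1, 9)]].to_numpy(dtype=np.int64)]
    )
    return HexMesh(
        node_coords=nodes[["x", "y", "z"]].to_numpy(dtype=float),
        elements=conn,
        part_labels=[str(p) for p in elems["part"]],
        node_ids=node_ids,
    )


def write_mesh_csv(mesh: HexMesh, nodes_path, elements_path) -> None:
    pd.DataFrame({
        "id": mesh.node_ids,
        "x": mesh.node_coords[:, 0],
        "y": mesh.node_coords[:, 1],
        "z": mesh.node_coords[:, 2],
    }).to_csv(nodes_path, index=False)
    cols = {"id": np.arange(mesh.n_elements)}
    ext = mesh.node_ids[mesh.elements]
    for i in range(8):
        cols[f"n{i+1}"] = ext[:, i]
    cols["part"] = mesh.part_labels
    pd.DataFrame(cols).to_csv(elements_path, index=False)


# ---------------------------------------------------------------------------
# displacements

def read_displacements_h5(path, time_unit: str = "s") -> DisplacementHistory:
    with h5py.File(path, "r") as f:
        times = np.asarray(f["times"], dtype=float) * _time_factor(time_unit)
        disp = np.asarray(f["displacements"], dtype=float)
    return DisplacementHistory(times=times, displacements=disp)


def write_displacements_h5(path, disp: DisplacementHistory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=disp.times)
        f.create_dataset("displacements", data=disp.displacements)


def read_displacements_csv(path, time_unit: str = "s") -> DisplacementHistory:
    """Long CSV: time,node,ux,uy,uz; node ids must be dense 0..n-1."""
    df = pd.read_csv(path)
    need = {"time", "node", "ux", "uy", "uz"}
    if not need <= set(df.columns):
        raise ValueError(f"displacement CSV needs columns {sorted(need)}")
    times = np.sort(df["time"].unique()) * _time_factor(time_unit)
    nodes = np.sort(df["node"].unique())
    n_nodes = nodes.size
    if not np.array_equal(nodes, np.arange(n_nodes)):
        raise ValueError("node ids must be dense 0..n-1 in displacement CSV")
    disp = np.zeros((times.size, n_nodes, 3))
    t_index = {t: i for i, t in enumerate(np.sort(df["time"].unique()))}
    ti = df["time"].map(t_index).to_numpy()
    ni = df["node"].to_numpy(dtype=np.int64)
    disp[ti, ni, 0] = df["ux"].to_numpy(dtype=float)
    disp[ti, ni, 1] = df["uy"].to_numpy(dtype=float)
    disp[ti, ni, 2] = df["uz"].to_numpy(dtype=float)
    return DisplacementHistory(times=times, displacements=disp)


# ---------------------------------------------------------------------------
# embedding table

def write_embedding(path, emb: EmbeddedFiberSet) -> None:
    """Embedding table as CSV (beam_node,element,xi1..xi3) or HDF5 by suffix."""
    path = str(path)
    if path.endswith(".h5") or path.endswith(".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("node_element", data=emb.node_element)
            f.create_dataset("node_xi", data=emb.node_xi)
            f.create_dataset("node_ref_coords", data=emb.node_ref_coords)
            f.create_dataset("beam_nodes", data=emb.beam_nodes)
            f.create_dataset("ref_lengths", data=emb.ref_lengths)
        return
    pd.DataFrame({
        "beam_node": np.arange(len(emb.node_element)),
        "element": emb.node_element,
        "xi1": emb.node_xi[:, 0],
        "xi2": emb.node_xi[:, 1],
        "xi3": emb.node_xi[:, 2],
    }).to_csv(path, index=False)


def read_embedding_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"beam_node", "element", "xi1", "xi2", "xi3"}
    if not need <= set(df.columns):
        raise ValueError(f"embedding table needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------------------
# strain exports

def write_strain_history_h5(path, history) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=history.times)
        f.create_dataset("strain", data=history.strain)
        f.attrs["measure"] = history.measure


def write_peak_summary_csv(path, history) -> None:
    pd.DataFrame({
        "beam": np.arange(history.strain.shape[1]),
        "tract": history.beam_tract,
        "fiber": history.beam_fiber,
        "peak_strain": history.peaks,
    }).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# cluster / markers

def read_cluster_json(path) -> ClusterDefinition:
    with open(path) as fh:
        data = json.load(fh)
    ids = list(data["markers"])
    coords = np.array([data["markers"][m] for m in ids], dtype=float)
    tets = [tuple(t) for t in data["tets"]]
    return ClusterDefinition(marker_ids=ids, marker_coords=coords, tets=tets,
                             excluded=list(data.get("excluded", [])))


def write_cluster_json(path, cluster: ClusterDefinition) -> None:
    data = {
        "markers": {m: cluster.marker_coords[i].tolist()
                    for i, m in enumerate(cluster.marker_ids)},
        "tets": [list(t) for t in cluster.tets],
        "excluded": list(cluster.excluded),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_marker_histories_csv(path, time_unit: str = "s"):
    """Return (times, {marker: (n_times, 3) displacements}).

    Marker histories are linearly resampled to the coarsest common grid when
    their time bases differ.
    """
    df = pd.read_csv(path)
    need = {"time", "marker", "ux", "uy", "uz"}
    if not need <= set(df.columns):
        raise ValueError(f"marker CSV needs columns {sorted(need)}")
    fac = _time_factor(time_unit)
    markers = list(dict.fromkeys(df["marker"]))
    per = {m: df[df["marker"] == m].sort_values("time") for m in markers}
    # coarsest common grid: fewest samples, clipped to the common span
    t0 = max(g["time"].iloc[0] for g in per.values()) * fac
    t1 = min(g["time"].iloc[-1] for g in per.values()) * fac
    n = min(len(g) for g in per.values())
    times = np.linspace(t0, t1, n)
    out = {}
    for m, g in per.items():
        t = g["time"].to_numpy(dtype=float) * fac
        out[m] = np.column_stack([
            np.interp(times, t, g[c].to_numpy(dtype=float))
            for c in ("ux", "uy", "uz")
        ])
    return times, out
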