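"""Readers and writers for the plain-CSV data contracts.

All inputs are comma-separated UTF-8 text with a header row:

- network edges: ``edge_id,up_node,down_node,length_m``
- barriers: ``edge_id,chainage_m,passable``
- sites: ``site_id,edge_id,chainage_m``
- segments: ``edge_id,start_m,end_m`` plus one column per catalogue code
- fish records: ``site_id,species,year,count``

Schema violations are reported with the offending column (and row numbers
where possible).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .catalog import Catalog
from .network import RiverNetwork

__all__ = [
    "read_network",
    "read_sites",
    "read_segments",
    "read_records",
    "write_segments",
    "write_auc_records",
]


def _require(df: pd.DataFrame, cols, what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path}: missing required column(s) {missing}")


def read_network(edges_path, barriers_path=None) -> RiverNetwork:
    edges = pd.read_csv(edges_path)
    _require(edges, ["edge_id", "up_node", "down_node", "length_m"], "edge list", edges_path)
    barriers = []
    if barriers_path is not None:
        bar = pd.read_csv(barriers_path)
        _require(bar, ["edge_id", "chainage_m", "passable"], "barrier", barriers_path)
        barriers = [
            (r.edge_id, float(r.chainage_m), _as_bool(r.passable)) for r in bar.itertuples()
        ]
    return RiverNetwork(
        [(r.edge_id, r.up_node, r.down_node, float(r.length_m)) for r in edges.itertuples()],
        barriers,
    )


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["site_id", "edge_id", "chainage_m"], "site", path)
    return df


def read_segments(path, catalog: Catalog | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["edge_id", "start_m", "end_m"], "segment", path)
    if catalog is not None:
        unknown = [
            c for c in df.columns
            if c not in ("edge_id", "start_m", "end_m") and c not in catalog
        ]
        if unknown:
            raise ValueError(
                f"segment file {path}: variable code(s) {unknown} not in the catalogue"
            )
    bad = df.index[df["end_m"] <= df["start_m"]].tolist()
    if bad:
        raise ValueError(f"segment file {path}: end_m <= start_m at rows {bad[:10]}")
    return df


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["site_id", "species", "year", "count"], "fish record", path)
    bad = df.index[df["count"] < 0].tolist()
    if bad:
        raise ValueError(f"record file {path}: negative counts at rows {bad[:10]}")
    return df


def write_segments(segments: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    segments.to_csv(path, index=False)


def write_auc_records(records: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        records.to_csv(fh, index=False)


def read_auc_records(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
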