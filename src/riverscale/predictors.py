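"""Assemble predictor datasets: variable aggregation, presence pooling,
and the measured/assessed x distance-class x topology dataset grid.

Raw field mappings often record many narrow subcategories (e.g. %mud, %clay,
%silt).  These are pooled into aggregate variables by summing, and count
variables are standardised to a rate per 100 m of mapped segment length.
Fish records from repeated surveys are pooled to a single presence/absence
per site and species, and only species present at a minimum number of sites
are modelled.  The final predictor datasets cross two variable sets
(measured, assessed) with five focal distance classes and the inclusion or
not of the three topological variables: 2 x 5 x 2 = 20 datasets per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog
from .focal import DISTANCE_CLASSES

log = logging.getLogger(__name__)

__all__ = [
    "aggregate_variables",
    "pool_presence",
    "PresenceMatrix",
    "PredictorDataset",
    "assemble_datasets",
]


def aggregate_variables(
    raw: pd.DataFrame,
    rules: Mapping[str, Sequence[str]],
    count_rate_codes: Iterable[str] = (),
) -> pd.DataFrame:
    """Pool raw subcategory columns into aggregate variables.

    ``rules`` maps an aggregate code to the raw columns summed into it (e.g.
    ``{"SuSo": ["mud", "clay", "silt"]}``).  Columns named in
    ``count_rate_codes`` (raw counts per segment) are rescaled to counts per
    100 m using the segment length implied by ``start_m``/``end_m``.
    Unreferenced raw columns pass through unchanged.
    """
    out = raw.copy()
    for agg, parts in rules.items():
        missing = [p for p in parts if p not in raw.columns]
        if missing:
            raise KeyError(f"aggregation rule {agg!r} references absent columns: {missing}")
        out[agg] = raw[list(parts)].sum(axis=1)
        out = out.drop(columns=[p for p in parts if p != agg])
    length_100m = (out["end_m"] - out["start_m"]) / 100.0
    for code in count_rate_codes:
        if code not in out.columns:
            raise KeyError(f"count variable {code!r} not present after aggregation")
        out[code] = out[code] / length_100m
    return out


@dataclass
class PresenceMatrix:
    """Site x species presence/absence with per-species summaries."""

    matrix: pd.DataFrame  # index site_id, columns species codes, values 0/1
    summary: pd.DataFrame  # per-species presence, absence, frequency

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def sites(self) -> list:
        return list(self.matrix.index)


def pool_presence(records: pd.DataFrame, min_sites: int = 10) -> PresenceMatrix:
    """Pool survey records to presence/absence and filter rare species.

    A species is present at a site if any survey there caught at least one
    specimen; repeated years are pooled.  Species present at fewer than
    ``min_sites`` sites are dropped.  Occurrence frequency is presence
    divided by the number of sampled sites (reported to 2 decimals in the
    summary; the matrix itself is exact).
    """
    if records.empty:
        empty = pd.DataFrame()
        return PresenceMatrix(empty, pd.DataFrame(columns=["presence", "absence", "frequency"]))
    if (records["count"] < 0).any():
        raise ValueError("specimen counts must be non-negative")
    pres = (
        records.assign(present=(records["count"] >= 1).astype(int))
        .groupby(["site_id", "species"])["present"]
        .max()
        .unstack(fill_value=0)
    )
    n_sites = pres.shape[0]
    keep = pres.sum(axis=0) >= min_sites
    dropped = sorted(pres.columns[~keep])
    if dropped:
        log.info("pool_presence: dropped %d species below %d sites: %s", len(dropped), min_sites, dropped)
    pres = pres.loc[:, keep]
    presence = pres.sum(axis=0)
    summary = pd.DataFrame(
        {
            "presence": presence,
            "absence": n_sites - presence,
            "frequency": (presence / n_sites).round(2),
        }
    )
    summary.index.name = "species"
    return PresenceMatrix(pres, summary)


@dataclass
class PredictorDataset:
    """One site x predictor matrix with its binary response."""

    species: str
    varset: str  # "MV" (measured) or "AV" (assessed)
    distance_m: float
    topo_included: bool
    X: pd.DataFrame  # index site_id, columns predictor codes
    y: pd.Series  # index site_id, values 0/1

    @property
    def dataset_id(self) -> str:
        topo = "TV" if self.topo_included else "noTV"
        return f"{self.species}_{self.varset}_{int(self.distance_m)}m_{topo}"


_VARSET_NAME = {"MV": "measured", "AV": "assessed"}


def assemble_datasets(
    focal: pd.DataFrame,
    topo_values: pd.DataFrame,
    presence: PresenceMatrix,
    catalog: Catalog,
    distances: Sequence[float] = DISTANCE_CLASSES,
) -> list[PredictorDataset]:
    """Build the 2 x len(distances) x 2 predictor datasets per species.

    ``focal`` is the long focal-predictor table; ``topo_values`` is indexed
    by site with the topological variable columns.  Row order follows the
    presence matrix's site order.  Every cell of each dataset traces back to
    exactly one focal entry or topological value.
    """
    have = set(focal["distance_m"].unique())
    missing = [d for d in distances if float(d) not in have]
    if missing:
        raise ValueError(f"focal table lacks distance classes: {missing}")

    wide = focal.pivot_table(
        index="site_id", columns=["distance_m", "variable"], values="value", aggfunc="first"
    )
    sites = presence.sites
    datasets: list[PredictorDataset] = []
    for varset in ("MV", "AV"):
        codes = [c for c in catalog.codes(set=_VARSET_NAME[varset]) if c in focal["variable"].unique()]
        for d in distances:
            base = wide[float(d)].reindex(index=sites)
            base = base[[c for c in codes if c in base.columns]]
            for topo in (False, True):
                X = base
                if topo:
                    X = base.join(topo_values.reindex(sites))
                for sp in presence.species:
                    datasets.append(
                        PredictorDataset(
                            species=sp,
                            varset=varset,
                            distance_m=float(d),
                            topo_included=topo,
                            X=X.copy(),
                            y=presence.matrix[sp].reindex(sites),
                        )
                    )
    return datasets
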