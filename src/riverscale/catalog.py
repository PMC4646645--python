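"""Habitat-variable catalogue.

Each variable has a code (e.g. ``ChWi``), a hydromorphological group
(TOPO, PROFILE, BED, BANK, LONG, FLOODPLAIN), a set (measured, assessed or
topological) and a kind that decides the focal statistic: continuous and
count-rate variables are averaged with the mean, ordinal categories and
assessment scores with the median (so the focal value stays on the ordinal
scale).  The packaged catalogue covers the 35 measured, 13 assessed and 3
topological variables of the lowland-river survey this package models,
including the survey's category bounds and catchment-wide mean/SD used by
the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

GROUPS = ("TOPO", "PROFILE", "BED", "BANK", "LONG", "FLOODPLAIN")
SETS = ("measured", "assessed", "topological")
KINDS = ("continuous", "ordinal", "score", "count_rate")

#: kinds summarised by the mean; the rest use the (lower-middle) median
MEAN_KINDS = ("continuous", "count_rate")


@dataclass(frozen=True)
class VariableDef:
    code: str
    group: str
    set: str
    kind: str
    cat_min: float | None = None
    cat_max: float | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.set not in SETS:
            raise ValueError(f"unknown variable set {self.set!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")


class Catalog:
    """Lookup table of :class:`VariableDef` by code."""

    def __init__(self, variables: list[VariableDef]) -> None:
        self._vars = {v.code: v for v in variables}
        if len(self._vars) != len(variables):
            raise ValueError("duplicate variable codes in catalogue")

    def __getitem__(self, code: str) -> VariableDef:
        try:
            return self._vars[code]
        except KeyError:
            raise KeyError(
                f"unknown variable code {code!r}; not in the packaged catalogue"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self._vars

    def __iter__(self):
        return iter(self._vars.values())

    def __len__(self) -> int:
        return len(self._vars)

    def codes(self, set: str | None = None, group: str | None = None) -> list[str]:
        return [
            v.code
            for v in self._vars.values()
            if (set is None or v.set == set) and (group is None or v.group == group)
        ]

    def group_of(self, code: str) -> str:
        return self[code].group

    def subset(self, codes) -> "Catalog":
        return Catalog([self[c] for c in codes])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self._vars.values()])


def load_catalog() -> Catalog:
    """Load the packaged variable catalogue."""
    with resources.files("riverscale.data").joinpath("variable_catalog.csv").open() as fh:
        df = pd.read_csv(fh)
    return catalog_from_frame(df)


def catalog_from_frame(df: pd.DataFrame) -> Catalog:
    variables = []
    for row in df.itertuples(index=False):
        variables.append(
            VariableDef(
                code=row.code,
                group=row.group,
                set=row.set,
                kind=row.kind,
                cat_min=None if pd.isna(row.cat_min) else float(row.cat_min),
                cat_max=None if pd.isna(row.cat_max) else float(row.cat_max),
                mean=None if pd.isna(row.mean) else float(row.mean),
                sd=None if pd.isna(row.sd) else float(row.sd),
            )
        )
    return Catalog(variables)
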