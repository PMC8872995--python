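"""Parcellation metadata: 360 HCP-MMP-style cortical regions plus 16 bilateral
subcortical structures, each affiliated to a resting-state module.

The canonical region order (cortical L, cortical R, subcortical; grouped by
module within each cortical hemisphere) is fixed in the bundled table and
inherited by every matrix and vector in the package, so that region index i
means the same region everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

N_REGIONS = 376
N_CORTICAL = 360
N_SUBCORTICAL = 16
N_PER_HEMISPHERE = 188

MODULES = ("VIS", "MOT", "DA", "VA", "LIM", "FP", "DMN", "SUB")
HEMISPHERES = ("L", "R")
TISSUE_CLASSES = ("cortical", "subcortical")


class ParcellationError(ValueError):
    """Raised when a parcellation table violates the atlas invariants."""


@dataclass(frozen=True)
class ParcellationMeta:
    """Validated parcellation table.

    ``table`` has columns region_id, index, hemisphere, tissue_class, module
    and is sorted by ``index`` (0..375).
    """

    table: pd.DataFrame

    def __post_init__(self):
        _validate(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def index_of(self, region_id: str) -> int:
        hit = self.table.index[self.table["region_id"] == region_id]
        if len(hit) == 0:
            raise KeyError(f"unknown region {region_id!r}")
        return int(self.table.loc[hit[0], "index"])

    def module_members(self, module: str) -> np.ndarray:
        """Integer indices of all regions affiliated to ``module``."""
        if module not in MODULES:
            raise ParcellationError(f"unknown module {module!r}")
        return self.table.loc[self.table["module"] == module, "index"].to_numpy()

    def hemisphere_members(self, hemisphere: str) -> np.ndarray:
        if hemisphere not in HEMISPHERES:
            raise ParcellationError(f"unknown hemisphere {hemisphere!r}")
        return self.table.loc[
            self.table["hemisphere"] == hemisphere, "index"
        ].to_numpy()


def _validate(df: pd.DataFrame) -> None:
    required = {"region_id", "index", "hemisphere", "tissue_class", "module"}
    missing = required - set(df.columns)
    if missing:
        raise ParcellationError(f"missing columns: {sorted(missing)}")
    if len(df) != N_REGIONS:
        raise ParcellationError(f"expected {N_REGIONS} regions, got {len(df)}")
    if df["region_id"].duplicated().any():
        dupes = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        raise ParcellationError(f"duplicate region ids: {dupes}")
    if sorted(df["index"]) != list(range(N_REGIONS)):
        raise ParcellationError("index column is not a permutation of 0..375")
    bad_mod = set(df["module"]) - set(MODULES)
    if bad_mod:
        raise ParcellationError(f"unknown module labels: {sorted(bad_mod)}")
    bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ParcellationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    bad_tc = set(df["tissue_class"]) - set(TISSUE_CLASSES)
    if bad_tc:
        raise ParcellationError(f"unknown tissue classes: {sorted(bad_tc)}")
    if (df["tissue_class"] == "cortical").sum() != N_CORTICAL:
        raise ParcellationError(f"expected {N_CORTICAL} cortical regions")
    for hemi in HEMISPHERES:
        n = (df["hemisphere"] == hemi).sum()
        if n != N_PER_HEMISPHERE:
            raise ParcellationError(
                f"hemisphere {hemi} has {n} regions, expected {N_PER_HEMISPHERE}"
            )
    sub = df[df["tissue_class"] == "subcortical"]
    if not (sub["module"] == "SUB").all():
        raise ParcellationError("all subcortical regions must be module SUB")
    if (df.loc[df["tissue_class"] == "cortical", "module"] == "SUB").any():
        raise ParcellationError("cortical regions may not be module SUB")


def load_parcellation(path) -> ParcellationMeta:
    """Read a parcellation table (TSV) and validate it.

    The table is re-sorted by the ``index`` column so downstream code can rely
    on positional order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    _validate(df)
    df = df.sort_values("index").reset_index(drop=True)
    return ParcellationMeta(df)


def default_parcellation() -> ParcellationMeta:
    """The bundled canonical parcellation."""
    with resources.files("crpconn.data").joinpath("parcellation.tsv").open() as fh:
        return load_parcellation(fh)
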