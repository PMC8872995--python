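"""Readers and writers for on-disk artefacts.

Tabular artefacts (subject tables, qMT vectors, statistics tables) are TSV;
dense arrays (time-series panels, connectivity matrices) use NumPy ``.npz``
containers. Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConnectivityMatrix,
    QMTRegionalVector,
    RegionalTimeSeriesPanel,
    validate_subject_table,
)
from .parcellation import ParcellationMeta

_QMT_PARAMS = ("pd", "f_b", "k_bf", "t2_b", "t2_f", "t1_f")


def _check_regions(n: int, meta: ParcellationMeta | None, what: str) -> None:
    if meta is not None and n != meta.n_regions:
        raise ValueError(
            f"{what} has {n} regions but parcellation has {meta.n_regions}"
        )


# -- subject tables ---------------------------------------------------------

def write_subject_table(df: pd.DataFrame, path) -> None:
    validate_subject_table(df, strict_crp=False)
    df.to_csv(path, sep="\t", index=False)


def read_subject_table(path, strict_crp: bool = False) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str, "centre": str, "sex": str},
        float_precision="round_trip",
    )
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return validate_subject_table(df, strict_crp=strict_crp)


# -- time-series panels -----------------------------------------------------

def write_panel(panel: RegionalTimeSeriesPanel, path) -> None:
    np.savez_compressed(
        path, matrix=panel.matrix, tr=panel.tr, subject_id=panel.subject_id
    )


def read_panel(path, meta: ParcellationMeta | None = None) -> RegionalTimeSeriesPanel:
    with np.load(path, allow_pickle=False) as z:
        panel = RegionalTimeSeriesPanel(
            subject_id=str(z["subject_id"]), matrix=z["matrix"], tr=float(z["tr"])
        )
    _check_regions(panel.n_regions, meta, f"panel {panel.subject_id}")
    return panel


# -- connectivity matrices --------------------------------------------------

def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    np.savez_compressed(path, r=matrix.r, subject_id=matrix.subject_id)


def read_matrix(path, meta: ParcellationMeta | None = None) -> ConnectivityMatrix:
    with np.load(path, allow_pickle=False) as z:
        m = ConnectivityMatrix(subject_id=str(z["subject_id"]), r=z["r"])
    _check_regions(m.n_regions, meta, f"connectivity matrix {m.subject_id}")
    return m


# -- qMT regional vectors ---------------------------------------------------

def write_qmt(vec: QMTRegionalVector, path, meta: ParcellationMeta | None = None) -> None:
    _check_regions(len(vec.pd), meta, f"qMT vector {vec.subject_id}")
    cols = {"region_index": np.arange(len(vec.pd))}
    if meta is not None:
        cols["region_id"] = meta.region_ids
    for name in _QMT_PARAMS:
        v = getattr(vec, name)
        if v is not None:
            cols[name] = v
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={vec.subject_id}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_qmt(path, meta: ParcellationMeta | None = None) -> QMTRegionalVector:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# subject_id="):
            raise ValueError(f"{path}: missing subject_id header line")
        subject_id = header.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    kwargs = {name: df[name].to_numpy() for name in _QMT_PARAMS if name in df}
    vec = QMTRegionalVector(subject_id=subject_id, **kwargs)
    _check_regions(len(vec.pd), meta, f"qMT vector {subject_id}")
    return vec


# -- statistics tables ------------------------------------------------------

def write_stat_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stat_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str}, float_precision="round_trip")
    df["significant"] = df["significant"].astype(bool)
    return df


def subject_paths(directory, subjects, suffix: str) -> dict[str, Path]:
    """Canonical per-subject file layout inside an artefact directory."""
    directory = Path(directory)
    return {sid: directory / f"{sid}{suffix}" for sid in subjects}
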