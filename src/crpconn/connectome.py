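"""Functional-connectivity matrices and weighted graph summaries.

The connectome here is fully weighted and signed: no thresholding or
binarization is applied anywhere, and nodal "hubness" is the signed mean
correlation of a region with all 375 others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConnectivityMatrix, RegionalTimeSeriesPanel
from .parcellation import ParcellationMeta


@dataclass
class DegreeVector:
    """Weighted degree (signed mean off-diagonal correlation) per node."""

    subject_id: str
    k: np.ndarray

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        if self.k.ndim != 1 or not np.isfinite(self.k).all():
            raise ValueError("degree vector must be 1-D and finite")


def functional_connectivity(panel: RegionalTimeSeriesPanel, region_ids=None) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time series."""
    x = panel.matrix
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(region_ids[i]) for i in bad] if region_ids is not None else bad.tolist()
        )
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(subject_id=panel.subject_id, r=r)


def weighted_degree(matrix: ConnectivityMatrix) -> DegreeVector:
    """Signed row mean of the connectivity matrix, excluding the unit
    diagonal (divide by n-1)."""
    r = matrix.r
    n = r.shape[0]
    k = (r.sum(axis=1) - np.diag(r)) / (n - 1)
    return DegreeVector(subject_id=matrix.subject_id, k=k)


def modular_degree(degree: DegreeVector, meta: ParcellationMeta, module: str) -> float:
    """Mean weighted degree over the member nodes of one resting-state
    module (e.g. DMN)."""
    members = meta.module_members(module)
    if len(members) == 0:
        raise ValueError(f"module {module!r} has no member regions")
    return float(degree.k[members].mean())


def seed_connectivity(
    matrix: ConnectivityMatrix,
    seed_region: str,
    meta: ParcellationMeta,
    same_hemisphere: bool = False,
):
    """One node's connectivity profile to target regions.

    Returns ``(target_ids, r_values)``. With ``same_hemisphere`` the targets
    are restricted to the seed's hemisphere (187 targets for a hippocampal
    seed); otherwise all 375 other regions are returned.
    """
    seed = meta.index_of(seed_region)
    hemi = meta.table.loc[meta.table["index"] == seed, "hemisphere"].iloc[0]
    if same_hemisphere:
        targets = meta.hemisphere_members(hemi)
    else:
        targets = np.arange(matrix.n_regions)
    targets = targets[targets != seed]
    ids = meta.region_ids[targets]
    return ids, matrix.r[seed, targets]


def edge_values(matrix: ConnectivityMatrix) -> np.ndarray:
    """Upper-triangle edge weights flattened in :func:`crpconn.core.edge_index`
    order (70,500 values for the full parcellation)."""
    n = matrix.n_regions
    ii, jj = np.triu_indices(n, k=1)
    return matrix.r[ii, jj]


def edges_to_matrix(values: np.ndarray, n_regions: int, subject_id: str = "") -> ConnectivityMatrix:
    """Inverse of :func:`edge_values` (diagonal restored to 1)."""
    values = np.asarray(values, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if values.shape != (expected,):
        raise ValueError(f"expected {expected} edge values, got {values.shape}")
    r = np.eye(n_regions)
    ii, jj = np.triu_indices(n_regions, k=1)
    r[ii, jj] = values
    r[jj, ii] = values
    return ConnectivityMatrix(subject_id=subject_id, r=r)


def group_mean_matrix(matrices, subject_id: str = "group_mean", fisher_z: bool = False) -> ConnectivityMatrix:
    """Entrywise mean of subject matrices, on the r scale by default (a
    Fisher-z average is available via ``fisher_z=True``)."""
    stack = np.stack([m.r for m in matrices])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(subject_id=subject_id, r=mean)
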