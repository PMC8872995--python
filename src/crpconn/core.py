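"""Domain containers shared by every stage of the pipeline.

All arrays follow the canonical region order of the bundled parcellation;
time-series panels are time x region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import N_REGIONS

GROUPS = ("HC", "loCRP", "hiCRP")
CASE_GROUPS = ("loCRP", "hiCRP")
#: CRP stratification threshold between low- and high-inflammation cases, mg/L
CRP_THRESHOLD = 3.0

SUBJECT_COLUMNS = ("subject_id", "group", "crp", "age", "sex", "bmi", "centre", "qc_pass")


def edge_index(n_regions: int) -> list[tuple[int, int]]:
    """All unordered region pairs (i, j), i < j, in lexicographic order.

    For the full 376-region parcellation this enumerates the 70,500 edges of
    the whole-brain connectome. The order is the contract every edge vector
    in the package follows.
    """
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    ii, jj = np.triu_indices(n_regions, k=1)
    return list(zip(ii.tolist(), jj.tolist()))


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def scan_duration(n_volumes: int, tr: float) -> float:
    """Total acquisition time in seconds for ``n_volumes`` at repetition time ``tr``."""
    if n_volumes < 1 or tr <= 0:
        raise ValueError("need n_volumes >= 1 and tr > 0")
    return n_volumes * tr


@dataclass
class RegionalTimeSeriesPanel:
    """One subject's regional BOLD time series, time x region."""

    subject_id: str
    matrix: np.ndarray
    tr: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("panel matrix must be 2-D (time x region)")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"panel {self.subject_id}: non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume and the derived
    framewise-displacement series (mm). Rotations are radians."""

    subject_id: str
    params: np.ndarray
    fd: np.ndarray | None = None

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be T x 6")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (self.params.shape[0],):
                raise ValueError("fd length must match number of volumes")
            if (self.fd < 0).any():
                raise ValueError("fd must be non-negative")


@dataclass
class QMTRegionalVector:
    """Per-subject regional quantitative-MT parameters.

    ``pd`` is proton density normalized to unit subject mean; the companion
    parameters (bound-pool fraction f_b, exchange rate k_bf, relaxation times)
    are optional.
    """

    subject_id: str
    pd: np.ndarray
    f_b: np.ndarray | None = None
    k_bf: np.ndarray | None = None
    t2_b: np.ndarray | None = None
    t2_f: np.ndarray | None = None
    t1_f: np.ndarray | None = None

    def __post_init__(self):
        self.pd = np.asarray(self.pd, dtype=float)
        if self.pd.ndim != 1:
            raise ValueError("pd must be a 1-D regional vector")
        if not np.isfinite(self.pd).all():
            raise ValueError(f"qMT vector {self.subject_id}: non-finite PD")
        for name in ("f_b", "k_bf", "t2_b", "t2_f", "t1_f"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.pd.shape or not np.isfinite(v).all():
                    raise ValueError(f"qMT vector {self.subject_id}: bad {name}")
                setattr(self, name, v)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson functional-connectivity matrix with unit diagonal."""

    subject_id: str
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError(f"connectivity matrix {self.subject_id} not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError(f"connectivity matrix {self.subject_id}: diagonal != 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-10:
            raise ValueError(f"connectivity matrix {self.subject_id}: |r| > 1")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


def validate_subject_table(df: pd.DataFrame, strict_crp: bool = True) -> pd.DataFrame:
    """Validate a subject table (group labels, CRP, covariates, QC flag).

    With ``strict_crp`` (used for generated cohorts) group membership must be
    consistent with the 3 mg/L stratification threshold; for externally loaded
    tables pass ``strict_crp=False`` to only warn.
    """
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if (df["crp"] < 0).any():
        raise ValueError("CRP must be non-negative (mg/L)")
    hi = df["group"] == "hiCRP"
    inconsistent = (hi & (df["crp"] <= CRP_THRESHOLD)) | (
        ~hi & (df["crp"] >= CRP_THRESHOLD)
    )
    if inconsistent.any():
        msg = (
            f"{int(inconsistent.sum())} subjects have CRP inconsistent with the "
            f"{CRP_THRESHOLD} mg/L group stratification"
        )
        if strict_crp:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    return df


def stat_result_table(
    unit_ids, beta, t, p, q, alpha: float = 0.05, degenerate=None
) -> pd.DataFrame:
    """Assemble a per-unit statistics table with an FDR significance mask."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1 + 1e-12)).any():
        raise ValueError("p and q must lie in [0, 1]")
    df = pd.DataFrame(
        {
            "unit_id": list(unit_ids),
            "beta": np.asarray(beta, dtype=float),
            "t": np.asarray(t, dtype=float),
            "p": p,
            "q": np.minimum(q, 1.0),
            "significant": q < alpha,
        }
    )
    if degenerate is not None:
        df["degenerate"] = np.asarray(degenerate, dtype=bool)
    return df
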