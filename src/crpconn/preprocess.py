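"""Subject-level quality control and signal conditioning on parcellated data.

Mirrors the acquisition design of the study cohort: 250 volumes at
TR = 2.57 s, first 6 discarded for magnetization equilibration, wavelet
band-pass to the 0.01-0.1 Hz BOLD band (MODWT detail levels 2-4), and motion /
artefact exclusion with framewise-displacement and global-correlation
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RegionalTimeSeriesPanel
from .modwt import DEFAULT_WAVELET, modwt_mra

#: Power-convention head radius used to convert rotations to arc length, mm
DEFAULT_HEAD_RADIUS = 50.0
DEFAULT_N_DROP = 6
DEFAULT_SCALES = (2, 4)

QC_REASONS = ("FD_MEAN", "FD_MAX", "GLOBAL_CORR")


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; a subject is excluded when a statistic strictly
    exceeds its threshold."""

    fd_mean: float = 0.3  # mm
    fd_max: float = 1.3  # mm
    global_corr: float = 0.7
    fd_statistic: str = "mean"  # or "rms"


@dataclass
class QCReport:
    subject_id: str
    fd_mean: float
    fd_rms: float
    fd_max: float
    global_mean_corr: float
    excluded: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag inconsistent with reasons list")


def compute_fd(params: np.ndarray, head_radius: float = DEFAULT_HEAD_RADIUS) -> np.ndarray:
    """Framewise displacement from six rigid-body parameters.

    ``params`` is T x 6: three translations (mm) then three rotations
    (radians). FD at frame t is the sum of absolute backward differences of
    the six parameters, with rotations converted to arc length on a sphere of
    ``head_radius`` mm. ``fd[0] = 0`` by convention.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion params must be T x 6")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    deltas = np.abs(np.diff(params, axis=0))
    fd = deltas[:, :3].sum(axis=1) + head_radius * deltas[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def global_mean_correlation(panel: RegionalTimeSeriesPanel) -> float:
    """Mean off-diagonal Pearson correlation over all region pairs.

    Values near 1 indicate a systemic artefact driving all regions together.
    """
    r = np.corrcoef(panel.matrix, rowvar=False)
    n = r.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(r[off].mean())


def qc_subject(
    fd: np.ndarray,
    panel: RegionalTimeSeriesPanel | None = None,
    thresholds: QCThresholds = QCThresholds(),
    subject_id: str = "",
) -> QCReport:
    """Apply the motion and global-artefact exclusion rules.

    A subject is excluded when the configured FD statistic (mean by default,
    RMS optionally) exceeds ``fd_mean``, when any single frame exceeds
    ``fd_max``, or when the panel's mean inter-regional correlation exceeds
    ``global_corr``. All comparisons are strict.
    """
    fd = np.asarray(fd, dtype=float)
    fd_mean = float(fd.mean())
    fd_rms = float(np.sqrt(np.mean(fd**2)))
    fd_max = float(fd.max())
    gcorr = global_mean_correlation(panel) if panel is not None else float("nan")

    fd_stat = fd_rms if thresholds.fd_statistic == "rms" else fd_mean
    reasons = []
    if fd_stat > thresholds.fd_mean:
        reasons.append("FD_MEAN")
    if fd_max > thresholds.fd_max:
        reasons.append("FD_MAX")
    if panel is not None and gcorr > thresholds.global_corr:
        reasons.append("GLOBAL_CORR")
    return QCReport(
        subject_id=subject_id,
        fd_mean=fd_mean,
        fd_rms=fd_rms,
        fd_max=fd_max,
        global_mean_corr=gcorr,
        excluded=bool(reasons),
        reasons=reasons,
    )


def drop_initial_volumes(raw: np.ndarray, n_drop: int = DEFAULT_N_DROP) -> np.ndarray:
    """Discard the first ``n_drop`` volumes (magnetization equilibration)."""
    raw = np.asarray(raw, dtype=float)
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if raw.shape[0] <= n_drop:
        raise ValueError(
            f"cannot drop {n_drop} volumes from a series of length {raw.shape[0]}"
        )
    return raw[n_drop:]


def wavelet_bandpass(
    panel: RegionalTimeSeriesPanel,
    scale_lo: int = DEFAULT_SCALES[0],
    scale_hi: int = DEFAULT_SCALES[1],
    wavelet: str = DEFAULT_WAVELET,
) -> RegionalTimeSeriesPanel:
    """Band-pass each regional series by summing MODWT details at levels
    ``scale_lo``..``scale_hi``.

    At the study TR of 2.57 s, levels 2-4 give a nominal passband of
    0.012-0.097 Hz, i.e. the conventional 0.01-0.1 Hz resting-state band.
    Output length equals input length (the MODWT is undecimated).
    """
    if scale_lo < 1 or scale_lo > scale_hi:
        raise ValueError("need 1 <= scale_lo <= scale_hi")
    details, _ = modwt_mra(panel.matrix, level=scale_hi, wavelet=wavelet)
    out = sum(details[scale_lo - 1 : scale_hi])
    return RegionalTimeSeriesPanel(
        subject_id=panel.subject_id, matrix=out, tr=panel.tr
    )


def regress_global_signal(panel: RegionalTimeSeriesPanel) -> RegionalTimeSeriesPanel:
    """Optionally remove the panel-mean series from every region (off by
    default in the pipeline; offered for sensitivity analyses)."""
    x = panel.matrix
    g = x.mean(axis=1, keepdims=True)
    gc = g - g.mean()
    beta = (gc * (x - x.mean(axis=0))).sum(axis=0) / (gc**2).sum()
    out = x - gc * beta
    return RegionalTimeSeriesPanel(subject_id=panel.subject_id, matrix=out, tr=panel.tr)


def normalize_pd(raw_pd: np.ndarray) -> np.ndarray:
    """Divide regional proton-density values by their subject mean so that PD
    is globally normalized to unity (removes overall scanner sensitivity)."""
    raw_pd = np.asarray(raw_pd, dtype=float)
    m = raw_pd.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("PD subject mean must be positive")
    return raw_pd / m
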