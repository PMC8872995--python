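"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design: three groups (46 healthy controls,
50 low-CRP depressed cases, 33 high-CRP depressed cases) with group CRP, age,
sex and BMI marginals matching the cohort summary table; 244-timepoint
regional BOLD panels drawn from a block-modular Gaussian covariance; regional
proton-density vectors with CRP-linked slopes at designated regions; motion
traces with a configurable fraction of QC failures; and an optional linear
mediation ground truth embedded at the subject level.

Effect magnitudes are synthetic choices, not estimates from any dataset: they
are set for roughly 80% nominal power at the full cohort size so that
recovery of the injected structure is a meaningful end-to-end check.

CRP is drawn from a truncated normal whose post-truncation mean and standard
deviation are moment-matched to the configured values (truncation at the
3 mg/L stratification threshold from above for controls and low-CRP cases,
from below for high-CRP cases, and at zero always).

Reproducibility: a single global seed fans out to per-subject substreams via
``numpy.random.SeedSequence`` spawning, so results do not depend on subject
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import CASE_GROUPS, CRP_THRESHOLD, GROUPS, QMTRegionalVector, RegionalTimeSeriesPanel, MotionTrace
from .parcellation import ParcellationMeta, default_parcellation
from .preprocess import compute_fd, normalize_pd

# -- default effect geography ----------------------------------------------

#: 22 regions where PD increases with CRP: posterior cingulate / precuneus,
#: inferior-orbital-polar frontal, medial prefrontal, and scattered singles.
PD_POSITIVE_REGIONS = tuple(
    "L_" + r
    for r in (
        "RSC", "PCV", "7m", "POS1", "v23ab", "d23ab", "31pv", "31pd", "31a",
        "ProS", "IFJa", "IFSa", "a10p", "p10p", "p47r", "OFC", "pOFC", "25",
        "9a", "6r", "5m", "VMV1",
    )
)
#: 7 prefrontal / premotor regions where PD decreases with CRP.
PD_NEGATIVE_REGIONS = tuple(
    "L_" + r for r in ("FP01", "FP02", "FP03", "FP04", "MOT01", "MOT02", "MOT03")
)

#: default CRP-linked edge effects on the Fisher-z scale, per mg/L
DEFAULT_EDGE_EFFECTS = {
    ("L_v23ab", "L_RSC"): 0.02,
    ("L_POS1", "L_hippocampus"): 0.02,
    ("L_10r", "L_hippocampus"): 0.02,
    ("L_7Pm", "L_FOP1"): -0.02,
    ("L_d23ab", "L_a32pr"): -0.012,
    ("L_31pv", "L_a32pr"): -0.012,
}

#: PD slope magnitude (normalized-PD units per mg/L CRP). With regional noise
#: sd 0.02 and the cohort CRP spread this gives ~80% power per region at the
#: BH-effective nodal threshold for n = 129.
DEFAULT_PD_SLOPE = 0.003
DEFAULT_PD_NOISE_SD = 0.02


@dataclass(frozen=True)
class MediationSpec:
    """Subject-level linear mediation ground truth.

    ``m = a*x + noise``, ``y = b*m + c_prime*x + noise`` with x = CRP; m is
    embedded as the (pre-normalization) PD deviation of ``mediator_region``
    and y as the Fisher-z connectivity deviation of ``outcome_edge``.
    """

    a: float
    b: float
    c_prime: float
    mediator_region: str = "L_POS1"
    outcome_edge: tuple[str, str] = ("L_POS1", "L_hippocampus")
    noise_m: float = DEFAULT_PD_NOISE_SD
    noise_y: float = 0.064  # matches edge z sampling noise ~ 1/sqrt(T-3) at T=244


#: Canonical mediation ground truths. Path strengths are sized from the
#: cases-only design (n = 83, CRP sd ~ 2.9): the exposure->mediator slope a
#: gives a path t ~ 5 (a study-like association, exposure-mediator r ~ 0.5),
#: and the "significant" paths target >= 99% power after accounting for the
#: variance inflation from the mediator-exposure correlation, so the joint
#: ACME/ADE signature reproduces in well over 90% of cohorts.
MEDIATION_DIRECT_ONLY = MediationSpec(
    a=0.004, b=0.0, c_prime=0.015,
    mediator_region="L_POS1", outcome_edge=("L_POS1", "L_hippocampus"),
)
MEDIATION_MEDIATED = MediationSpec(
    a=0.01, b=1.5, c_prime=0.0,
    mediator_region="L_d23ab", outcome_edge=("L_d23ab", "L_a32pr"),
)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effects injected into a synthetic cohort."""

    pd_effects: dict = field(default_factory=dict)
    edge_effects: dict = field(default_factory=dict)
    #: additive change to case covariance entries involving a DMN node
    dmn_degree_shift: float = 0.0
    mediation: MediationSpec | None = None

    @classmethod
    def default(cls) -> "EffectSpec":
        pd_effects = {r: DEFAULT_PD_SLOPE for r in PD_POSITIVE_REGIONS}
        pd_effects.update({r: -DEFAULT_PD_SLOPE for r in PD_NEGATIVE_REGIONS})
        return cls(
            pd_effects=pd_effects,
            edge_effects=dict(DEFAULT_EDGE_EFFECTS),
            dmn_degree_shift=-0.03,
        )

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()

    def validate(self, meta: ParcellationMeta) -> None:
        for r, slope in self.pd_effects.items():
            meta.index_of(r)
            if not np.isfinite(slope):
                raise ValueError(f"non-finite PD slope for {r}")
        for (a, b), slope in self.edge_effects.items():
            meta.index_of(a), meta.index_of(b)
            if not np.isfinite(slope):
                raise ValueError(f"non-finite edge slope for ({a}, {b})")
        if not np.isfinite(self.dmn_degree_shift):
            raise ValueError("non-finite DMN degree shift")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design: group sizes and marginals from the study summary table,
    scan geometry, and the modular covariance of the simulated BOLD signal."""

    n_hc: int = 46
    n_locrp: int = 50
    n_hicrp: int = 33
    #: per-group CRP (mean, sd) in mg/L
    crp_params: dict = field(
        default_factory=lambda: {
            "HC": (0.9, 0.7),
            "loCRP": (1.0, 0.7),
            "hiCRP": (5.8, 2.6),
        }
    )
    age_params: dict = field(
        default_factory=lambda: {
            "HC": (35.5, 7.5),
            "loCRP": (36.8, 7.1),
            "hiCRP": (37.6, 7.6),
        }
    )
    bmi_params: dict = field(
        default_factory=lambda: {
            "HC": (24.5, 4.2),
            "loCRP": (25.6, 3.7),
            "hiCRP": (28.8, 3.9),
        }
    )
    #: fraction of female subjects per group (from the 27/19, 29/21, 28/5 splits)
    female_frac: dict = field(
        default_factory=lambda: {"HC": 27 / 46, "loCRP": 29 / 50, "hiCRP": 28 / 33}
    )
    centres: tuple = ("C1", "C2", "C3")
    t_points: int = 244
    tr: float = 2.57
    seed: int = 0
    module_block_correlation: float = 0.3
    between_module_correlation: float = 0.05
    #: case-only DMN <-> VA/DA coupling replacing the background correlation
    dmn_anticorrelation: float = -0.05

    def __post_init__(self):
        if min(self.n_hc, self.n_locrp, self.n_hicrp) < 0:
            raise ValueError("group sizes must be non-negative")
        for r in (self.module_block_correlation, self.between_module_correlation,
                  self.dmn_anticorrelation):
            if abs(r) >= 1:
                raise ValueError("correlations must lie in (-1, 1)")
        for g, (m, s) in self.crp_params.items():
            if m <= 0 or s < 0:
                raise ValueError(f"invalid CRP parameters for {g}: mean {m}, sd {s}")

    @property
    def n_total(self) -> int:
        return self.n_hc + self.n_locrp + self.n_hicrp


# -- truncated-normal CRP ----------------------------------------------------

@lru_cache(maxsize=64)
def _truncnorm_parent_params(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) such that the [lo, hi]-truncated normal has the
    requested mean and sd (moment matching)."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise ValueError(
            f"cannot moment-match truncated normal: mean {mean}, sd {sd} on [{lo}, {hi}]"
        )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _draw_crp(group: str, params: tuple[float, float], size: int, rng) -> np.ndarray:
    mean, sd = params
    if sd == 0:
        return np.full(size, float(mean))
    lo, hi = (CRP_THRESHOLD, np.inf) if group == "hiCRP" else (0.0, CRP_THRESHOLD)
    if not (lo < mean < hi if np.isfinite(hi) else mean > 0):
        # moment matching still possible for means outside the window, but a
        # hiCRP mean at or below zero is a configuration error
        if group == "hiCRP" and mean <= 0:
            raise ValueError("hiCRP CRP mean must be positive")
    mu, sigma = _truncnorm_parent_params(float(mean), float(sd), float(lo), float(hi))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a subject table with the configured group sizes and marginals.

    Deterministic given the seed (``config.seed`` unless overridden).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    sizes = {"HC": config.n_hc, "loCRP": config.n_locrp, "hiCRP": config.n_hicrp}
    for group in GROUPS:
        n = sizes[group]
        if n == 0:
            continue
        crp = _draw_crp(group, config.crp_params[group], n, rng)
        age_m, age_s = config.age_params[group]
        age = np.clip(rng.normal(age_m, age_s, n), 18, 80)
        bmi_m, bmi_s = config.bmi_params[group]
        bmi = np.clip(rng.normal(bmi_m, bmi_s, n), 15, 60)
        sex = np.where(rng.random(n) < config.female_frac[group], "F", "M")
        centre = rng.choice(config.centres, size=n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}_{i:03d}",
                    "group": group,
                    "crp": crp[i],
                    "age": age[i],
                    "sex": sex[i],
                    "bmi": bmi[i],
                    "centre": centre[i],
                    "qc_pass": True,
                }
            )
    from .core import validate_subject_table

    return validate_subject_table(pd.DataFrame(rows), strict_crp=True)


# -- covariance construction -------------------------------------------------

def nearest_positive_definite(c: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping at a small positive floor followed by diagonal
    renormalization to 1. Deterministic."""
    vals, vecs = np.linalg.eigh((c + c.T) / 2)
    vals = np.maximum(vals, floor)
    c2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c2))
    if (d <= 0).any() or not np.isfinite(d).all():
        raise ValueError("positive-definite projection failed")
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2


def _is_pd(c: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(c)
        return True
    except np.linalg.LinAlgError:
        return False


def build_group_covariance(
    meta: ParcellationMeta,
    config: CohortConfig,
    group: str,
    crp: float = 0.0,
    effects: EffectSpec = EffectSpec(),
    edge_z_offsets: dict | None = None,
) -> np.ndarray:
    """Block-modular covariance (unit diagonal) for one subject.

    Within-module blocks sit at ``module_block_correlation`` over a
    ``between_module_correlation`` background. For depressed cases the DMN is
    negatively coupled to the ventral/dorsal attention modules and all
    DMN-involving entries are shifted by ``effects.dmn_degree_shift``,
    reducing DMN hubness. CRP-scaled edge effects (and any extra per-subject
    z offsets, e.g. an embedded mediation outcome) are applied on the
    Fisher-z scale and back-transformed. The result is projected to the
    nearest positive-definite correlation matrix when needed.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    effects.validate(meta)
    n = meta.n_regions
    modules = meta.table["module"].to_numpy()
    c = np.full((n, n), config.between_module_correlation)
    for mod in np.unique(modules):
        m = modules == mod
        c[np.ix_(m, m)] = config.module_block_correlation

    if group in CASE_GROUPS:
        dmn = modules == "DMN"
        att = np.isin(modules, ("VA", "DA"))
        c[np.ix_(dmn, att)] = config.dmn_anticorrelation
        c[np.ix_(att, dmn)] = config.dmn_anticorrelation
        if effects.dmn_degree_shift:
            involves_dmn = dmn[:, None] | dmn[None, :]
            c[involves_dmn] += effects.dmn_degree_shift

    z_offsets = {}
    for (ra, rb), slope in effects.edge_effects.items():
        i, j = meta.index_of(ra), meta.index_of(rb)
        z_offsets[(i, j)] = z_offsets.get((i, j), 0.0) + slope * crp
    if edge_z_offsets:
        for (ra, rb), dz in edge_z_offsets.items():
            i, j = meta.index_of(ra), meta.index_of(rb)
            z_offsets[(i, j)] = z_offsets.get((i, j), 0.0) + dz
    for (i, j), dz in z_offsets.items():
        r = np.tanh(np.arctanh(np.clip(c[i, j], -1 + 1e-12, 1 - 1e-12)) + dz)
        c[i, j] = c[j, i] = r

    np.fill_diagonal(c, 1.0)
    if not _is_pd(c):
        c = nearest_positive_definite(c)
    return c


def simulate_panel(
    covariance: np.ndarray,
    t_points: int,
    tr: float,
    seed,
    subject_id: str = "sim",
) -> RegionalTimeSeriesPanel:
    """Zero-mean stationary Gaussian series with the target covariance.

    ``seed`` may be an int or a ``SeedSequence``. Deterministic given seed.
    """
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance must be positive definite") from e
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((t_points, covariance.shape[0])) @ chol.T
    return RegionalTimeSeriesPanel(subject_id=subject_id, matrix=x, tr=tr)


# -- PD and motion -----------------------------------------------------------

def _mediation_values(spec: MediationSpec, crp: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    m = spec.a * crp + rng.normal(0.0, spec.noise_m, crp.size)
    y = spec.b * m + spec.c_prime * crp + rng.normal(0.0, spec.noise_y, crp.size)
    return m, y


def simulate_mediation_dataset(
    crp: np.ndarray, spec: MediationSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level mediator and outcome values for a mediation ground
    truth; returns ``(m, y)`` for the given exposures."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _mediation_values(spec, np.asarray(crp, dtype=float), rng)


def simulate_pd(
    subjects: pd.DataFrame,
    meta: ParcellationMeta,
    effects: EffectSpec = EffectSpec(),
    noise_sd: float = DEFAULT_PD_NOISE_SD,
    seed: int = 0,
    baseline: float = 1.0,
) -> dict[str, QMTRegionalVector]:
    """Regional PD per subject: baseline + slope(region) * CRP + noise, then
    normalized to unit subject mean.

    When ``effects.mediation`` is set, the mediator region's value is the
    mediation ground-truth ``m`` (plus baseline) instead of the generic
    linear effect.
    """
    effects.validate(meta)
    slopes = np.zeros(meta.n_regions)
    for r, s in effects.pd_effects.items():
        slopes[meta.index_of(r)] = s
    ss = np.random.SeedSequence(seed)
    subject_streams = ss.spawn(len(subjects))
    med_idx = None
    if effects.mediation is not None:
        med_idx = meta.index_of(effects.mediation.mediator_region)
    out = {}
    for (row, sub_ss) in zip(subjects.itertuples(), subject_streams):
        rng = np.random.default_rng(sub_ss)
        raw = baseline + slopes * row.crp + rng.normal(0.0, noise_sd, meta.n_regions)
        if med_idx is not None:
            spec = effects.mediation
            m = spec.a * row.crp + rng.normal(0.0, spec.noise_m)
            raw[med_idx] = baseline + m
        out[row.subject_id] = QMTRegionalVector(
            subject_id=row.subject_id, pd=normalize_pd(raw)
        )
    return out


def simulate_motion(
    subjects: pd.DataFrame,
    t_points: int = 250,
    seed: int = 0,
    frac_bad: float = 3 / 132,
    spike_amplitude: float = 2.0,
) -> dict[str, MotionTrace]:
    """Autoregressive small-motion traces; a ``frac_bad`` fraction of subjects
    receive an injected spike (translation jump of ``spike_amplitude`` mm)
    that violates the max-FD threshold."""
    if not 0 <= frac_bad <= 1:
        raise ValueError("frac_bad must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    n_bad = int(round(frac_bad * len(subjects)))
    bad = set(
        pick_rng.choice(len(subjects), size=n_bad, replace=False).tolist()
        if n_bad
        else []
    )
    out = {}
    for i, (row, sub_ss) in enumerate(zip(subjects.itertuples(), ss.spawn(len(subjects) + 1)[1:])):
        rng = np.random.default_rng(sub_ss)
        steps = rng.normal(0.0, 1.0, (t_points, 6)) * np.array(
            [0.01, 0.01, 0.01, 2e-4, 2e-4, 2e-4]
        )
        params = np.cumsum(steps * 0.5, axis=0) + steps  # drift + jitter
        if i in bad:
            t_spike = rng.integers(t_points // 4, 3 * t_points // 4)
            params[t_spike:, 0] += spike_amplitude
        fd = compute_fd(params)
        out[row.subject_id] = MotionTrace(subject_id=row.subject_id, params=params, fd=fd)
    return out


# -- full dataset orchestration ----------------------------------------------

@dataclass
class SyntheticDataset:
    subjects: pd.DataFrame
    panels: dict
    qmt: dict
    motion: dict
    truth: dict
    meta: ParcellationMeta


def simulate_dataset(
    config: CohortConfig = CohortConfig(),
    effects: EffectSpec | None = None,
    meta: ParcellationMeta | None = None,
    seed: int | None = None,
    with_motion: bool = False,
) -> SyntheticDataset:
    """Generate a complete cohort: subject table, band-limited BOLD panels,
    PD vectors, optional motion traces, and a ground-truth record."""
    if effects is None:
        effects = EffectSpec.default()
    if meta is None:
        meta = default_parcellation()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_cohort, s_pd, s_panels, s_motion, s_med = ss.spawn(5)

    subjects = generate_cohort(config, seed=s_cohort.generate_state(1)[0] % 2**31)
    qmt = simulate_pd(
        subjects, meta, effects=effects, seed=s_pd.generate_state(1)[0] % 2**31
    )

    med_y = {}
    if effects.mediation is not None:
        spec = effects.mediation
        med_rng = np.random.default_rng(s_med)
        m_idx = meta.index_of(spec.mediator_region)
        for row in subjects.itertuples():
            m_dev = qmt[row.subject_id].pd[m_idx] - 1.0
            med_y[row.subject_id] = (
                spec.b * m_dev + spec.c_prime * row.crp
                + med_rng.normal(0.0, spec.noise_y)
            )

    panels = {}
    for row, sub_ss in zip(subjects.itertuples(), s_panels.spawn(len(subjects))):
        offsets = None
        if row.subject_id in med_y:
            offsets = {effects.mediation.outcome_edge: med_y[row.subject_id]}
        cov = build_group_covariance(
            meta, config, row.group, crp=row.crp, effects=effects,
            edge_z_offsets=offsets,
        )
        panels[row.subject_id] = simulate_panel(
            cov, config.t_points, config.tr, sub_ss, subject_id=row.subject_id
        )

    motion = (
        simulate_motion(subjects, seed=s_motion.generate_state(1)[0] % 2**31)
        if with_motion
        else {}
    )
    truth = {
        "pd_effects": dict(effects.pd_effects),
        "edge_effects": {f"{a}--{b}": v for (a, b), v in effects.edge_effects.items()},
        "dmn_degree_shift": effects.dmn_degree_shift,
        "mediation": None
        if effects.mediation is None
        else {
            "a": effects.mediation.a,
            "b": effects.mediation.b,
            "c_prime": effects.mediation.c_prime,
            "mediator_region": effects.mediation.mediator_region,
            "outcome_edge": list(effects.mediation.outcome_edge),
        },
        "seed": seed,
    }
    return SyntheticDataset(
        subjects=subjects, panels=panels, qmt=qmt, motion=motion, truth=truth, meta=meta
    )
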