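"""Hierarchical statistics: global distribution tests, then nodal and
edge-wise mass-univariate regressions, each family controlled by the
Benjamini-Hochberg false discovery rate.

The scheme proceeds from the whole-brain scale (two-sample Kolmogorov-Smirnov
tests on distributions of regional measures or edge weights) through the
regional scale (376 per-node regressions of an MRI measure on CRP, or
covariate-adjusted case-control contrasts) to the edge scale (70,500 per-edge
regressions, plus per-seed families of 375 or 187 edges). Later levels are
gated on significance at the preceding level unless gating is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import edge_values
from .core import CASE_GROUPS, stat_result_table
from .parcellation import ParcellationMeta

DEFAULT_COVARIATES = ("age", "centre")


# -- level 1: global distribution tests -------------------------------------

def ks_compare(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``method`` follows :func:`scipy.stats.ks_2samp`: 'auto' uses the exact
    null distribution for small samples (where it coincides with full
    permutation enumeration) and the asymptotic approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# -- FDR --------------------------------------------------------------------

def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q_values, reject)`` where q-values are the monotone-adjusted
    p*m/rank and ``reject`` is ``q_values < q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, qvals < q


# -- mass-univariate OLS ----------------------------------------------------

def _design_matrix(x: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None and len(covariates.columns):
        numeric = covariates.select_dtypes(include="number")
        categorical = covariates.drop(columns=numeric.columns)
        if len(categorical.columns):
            dummies = pd.get_dummies(categorical.astype(str), drop_first=True)
            cols.extend(dummies[c].to_numpy(float) for c in dummies.columns)
        cols.extend(numeric[c].to_numpy(float) for c in numeric.columns)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (degenerate predictors)")
    return X

def _ols_tests(Y: np.ndarray, X: np.ndarray):
    """Vectorized per-column OLS of Y on X; returns (beta, t, p, degenerate)
    for the predictor in column 1 of X."""
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} subjects for {p} parameters")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    beta = coef[1]
    degenerate = np.ptp(Y, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    beta = np.where(degenerate, 0.0, beta)
    t = np.where(degenerate, 0.0, t)
    pvals = np.where(degenerate, 1.0, pvals)
    return beta, t, np.clip(pvals, 0.0, 1.0), degenerate


def _subset_mask(subjects: pd.DataFrame, subset: str) -> np.ndarray:
    if subset == "all":
        return np.ones(len(subjects), dtype=bool)
    if subset == "cases_only":
        return subjects["group"].isin(CASE_GROUPS).to_numpy()
    if subset == "controls_only":
        return (subjects["group"] == "HC").to_numpy()
    raise ValueError(f"unknown subset {subset!r}")


def mass_univariate_regression(
    y_table: np.ndarray,
    subjects: pd.DataFrame,
    unit_ids,
    x_column: str = "crp",
    covariates=DEFAULT_COVARIATES,
    subset: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-unit OLS of an MRI measure on CRP with covariate adjustment.

    ``y_table`` is units x subjects; the reported beta/t/p are for the CRP
    slope; q is the BH-adjusted value within this family of units.
    """
    y_table = np.asarray(y_table, dtype=float)
    if y_table.ndim != 2 or y_table.shape[1] != len(subjects):
        raise ValueError("y_table must be units x subjects")
    if np.isnan(y_table).any():
        raise ValueError("y_table contains missing values")
    mask = _subset_mask(subjects, subset)
    sub = subjects.loc[mask]
    x = sub[x_column].to_numpy(float)
    cov = sub[list(covariates)] if covariates else None
    X = _design_matrix(x, cov)
    beta, t, p, degen = _ols_tests(y_table[:, mask].T, X)
    qvals, _ = fdr_bh(p, q=alpha)
    return stat_result_table(unit_ids, beta, t, p, qvals, alpha=alpha, degenerate=degen)


def group_difference(
    y_table: np.ndarray,
    subjects: pd.DataFrame,
    unit_ids,
    covariates=DEFAULT_COVARIATES,
    case_groups=CASE_GROUPS,
    control_group: str = "HC",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-unit covariate-adjusted case-control contrast (OLS with a group
    indicator; beta is the case minus control difference)."""
    y_table = np.asarray(y_table, dtype=float)
    groups = subjects["group"]
    is_case = groups.isin(case_groups).to_numpy()
    is_control = (groups == control_group).to_numpy()
    mask = is_case | is_control
    if is_case.sum() < 2 or is_control.sum() < 2:
        raise ValueError("need at least 2 subjects in each group")
    sub = subjects.loc[mask]
    indicator = is_case[mask].astype(float)
    cov = sub[list(covariates)] if covariates else None
    X = _design_matrix(indicator, cov)
    beta, t, p, degen = _ols_tests(y_table[:, mask].T, X)
    qvals, _ = fdr_bh(p, q=alpha)
    return stat_result_table(unit_ids, beta, t, p, qvals, alpha=alpha, degenerate=degen)


# -- hierarchy orchestration ------------------------------------------------

@dataclass
class HierarchyConfig:
    alpha: float = 0.05
    lenient_alpha: float = 0.1  # additionally reported for edge families
    covariates: tuple = DEFAULT_COVARIATES
    gate: bool = True
    gate_alpha: float = 0.05
    pd_subset: str = "all"  # PD ~ CRP uses cases and controls combined
    edge_subset: str = "cases_only"  # FC ~ CRP uses depressed cases only
    fisher_z_edges: bool = True
    global_distribution: str = "group_mean"  # or "pooled"
    seed_regions: tuple = ()
    seed_same_hemisphere: bool = False


@dataclass
class HierarchyResult:
    global_tests: list = field(default_factory=list)
    gate_passed: dict = field(default_factory=dict)
    nodal_tables: dict = field(default_factory=dict)
    edge_table: pd.DataFrame | None = None
    edge_table_lenient: pd.DataFrame | None = None
    seed_tables: dict = field(default_factory=dict)


def _group_values(values: np.ndarray, members: np.ndarray, how: str) -> np.ndarray:
    # values: units x subjects, members: boolean subject mask
    block = values[:, members]
    if how == "group_mean":
        return block.mean(axis=1)
    return block.ravel()


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def run_hierarchy(
    subjects: pd.DataFrame,
    pd_table: np.ndarray,
    degree_table: np.ndarray,
    matrices: dict,
    meta: ParcellationMeta,
    config: HierarchyConfig = HierarchyConfig(),
) -> HierarchyResult:
    """Run the full three-level scheme.

    Parameters
    ----------
    pd_table, degree_table : units x subjects arrays in subject-table order.
    matrices : mapping subject_id -> ConnectivityMatrix.
    """
    res = HierarchyResult()
    order = subjects["subject_id"].tolist()
    edge_mat = np.stack([edge_values(matrices[sid]) for sid in order], axis=1)

    is_case = subjects["group"].isin(CASE_GROUPS).to_numpy()
    comparisons = [
        ("cases_vs_controls", is_case, ~is_case),
        ("hiCRP_vs_loCRP", (subjects["group"] == "hiCRP").to_numpy(),
         (subjects["group"] == "loCRP").to_numpy()),
    ]
    modalities = {"pd": pd_table, "degree": degree_table, "edges": edge_mat}
    gate = {name: False for name in modalities}
    for mod_name, values in modalities.items():
        for comp_name, ma, mb in comparisons:
            a = _group_values(values, ma, config.global_distribution)
            b = _group_values(values, mb, config.global_distribution)
            d, p = ks_compare(a, b)
            res.global_tests.append(
                {"modality": mod_name, "comparison": comp_name, "D": d, "p": p}
            )
            if p < config.gate_alpha:
                gate[mod_name] = True
    res.gate_passed = gate

    region_ids = meta.region_ids
    if gate["pd"] or not config.gate:
        res.nodal_tables["pd_crp"] = mass_univariate_regression(
            pd_table, subjects, region_ids, covariates=config.covariates,
            subset=config.pd_subset, alpha=config.alpha,
        )
        res.nodal_tables["pd_group"] = group_difference(
            pd_table, subjects, region_ids, covariates=config.covariates,
            alpha=config.alpha,
        )
    if gate["degree"] or not config.gate:
        res.nodal_tables["degree_group"] = group_difference(
            degree_table, subjects, region_ids, covariates=config.covariates,
            alpha=config.alpha,
        )
    if gate["edges"] or not config.gate:
        y = fisher_z(edge_mat) if config.fisher_z_edges else edge_mat
        edge_ids = [
            f"{region_ids[i]}--{region_ids[j]}"
            for i, j in zip(*np.triu_indices(meta.n_regions, k=1))
        ]
        res.edge_table = mass_univariate_regression(
            y, subjects, edge_ids, covariates=config.covariates,
            subset=config.edge_subset, alpha=config.alpha,
        )
        lenient = res.edge_table.copy()
        lenient["significant"] = lenient["q"] < config.lenient_alpha
        res.edge_table_lenient = lenient
        for seed in config.seed_regions:
            res.seed_tables[seed] = seed_edge_regression(
                subjects, matrices, meta, seed,
                same_hemisphere=config.seed_same_hemisphere,
                covariates=config.covariates, subset=config.edge_subset,
                alpha=config.alpha, use_fisher_z=config.fisher_z_edges,
            )
    return res


def seed_edge_regression(
    subjects: pd.DataFrame,
    matrices: dict,
    meta: ParcellationMeta,
    seed_region: str,
    same_hemisphere: bool = False,
    covariates=DEFAULT_COVARIATES,
    subset: str = "cases_only",
    alpha: float = 0.05,
    use_fisher_z: bool = True,
) -> pd.DataFrame:
    """CRP regression on one seed's connectivity profile, FDR-controlled
    within the seed's own family of 375 (or 187 same-hemisphere) edges."""
    from .connectome import seed_connectivity

    order = subjects["subject_id"].tolist()
    rows = []
    for sid in order:
        ids, r = seed_connectivity(
            matrices[sid], seed_region, meta, same_hemisphere=same_hemisphere
        )
        rows.append(r)
    y = np.stack(rows, axis=1)
    if use_fisher_z:
        y = fisher_z(y)
    unit_ids = [f"{seed_region}--{t}" for t in ids]
    return mass_univariate_regression(
        y, subjects, unit_ids, covariates=covariates, subset=subset, alpha=alpha
    )
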