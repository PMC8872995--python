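"""Linear causal mediation: exposure (CRP) -> mediator (regional PD) ->
outcome (edge connectivity), with nonparametric bootstrap uncertainty.

The estimator is the classical product-of-coefficients linear structural
equation model:

    m = a*x  + covariates + error
    y = b*m + c'*x + covariates + error

ACME (average causal mediation effect, the indirect path) is a*b, ADE (average
direct effect) is c', and the total effect is a*b + c' -- an exact identity
for linear models. Confidence intervals are percentile intervals from a
case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_BOOT = 5000
#: |total| below this floor makes the proportion-mediated ratio unstable
PROP_MEDIATED_FLOOR = 1e-8


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float | None
    ci_acme: tuple[float, float]
    ci_ade: tuple[float, float]
    ci_total: tuple[float, float]
    n: int
    n_boot: int
    seed: int

    def __post_init__(self):
        for lo, hi in (self.ci_acme, self.ci_ade, self.ci_total):
            if lo > hi:
                raise ValueError("confidence interval lower bound exceeds upper")


def _design(x: np.ndarray, covariates: np.ndarray | None, extra: np.ndarray | None = None):
    cols = [np.ones_like(x)]
    if extra is not None:
        cols.append(extra)
    cols.append(x)
    if covariates is not None:
        cols.extend(covariates.T)
    return np.column_stack(cols)


def _fit_paths(x, m, y, covariates):
    """Point estimates (a, b, c') by two OLS fits."""
    Xm = _design(x, covariates)
    a = np.linalg.lstsq(Xm, m, rcond=None)[0][1]
    Xy = _design(x, covariates, extra=m)
    coefs = np.linalg.lstsq(Xy, y, rcond=None)[0]
    b, c_prime = coefs[1], coefs[2]
    return a, b, c_prime


def _batched_paths(x, m, y, covariates, idx):
    """(a, b, c') for every bootstrap resample in ``idx`` (B x n)."""
    B, n = idx.shape
    xb, mb, yb = x[idx], m[idx], y[idx]
    cb = covariates[idx] if covariates is not None else None

    def solve(design_cols, target):
        X = np.stack(design_cols, axis=2)  # B x n x p
        XtX = np.einsum("bni,bnj->bij", X, X)
        Xty = np.einsum("bni,bn->bi", X, target)
        return np.linalg.solve(XtX, Xty[..., None])[..., 0]

    ones = np.ones_like(xb)
    cov_cols = [cb[:, :, k] for k in range(cb.shape[2])] if cb is not None else []
    a = solve([ones, xb] + cov_cols, mb)[:, 1]
    coefs_y = solve([ones, mb, xb] + cov_cols, yb)
    return a, coefs_y[:, 1], coefs_y[:, 2]


def mediate(
    x,
    m,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Estimate ACME, ADE and the total effect with bootstrap percentile CIs.

    ``x``, ``m``, ``y`` are per-subject exposure, mediator and outcome values;
    categorical covariate columns are dummy-coded automatically.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError("need at least 10 subjects for mediation analysis")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    if x.std() == 0 or m.std() == 0:
        raise ValueError("exposure and mediator must vary")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) >= 1 - 1e-12:
        raise ValueError("mediator is collinear with exposure")

    cov = None
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            numeric = covariates.select_dtypes(include="number")
            rest = covariates.drop(columns=numeric.columns)
            parts = [numeric.to_numpy(float)] if len(numeric.columns) else []
            if len(rest.columns):
                parts.append(
                    pd.get_dummies(rest.astype(str), drop_first=True).to_numpy(float)
                )
            cov = np.column_stack(parts) if parts else None
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]

    a, b, c_prime = _fit_paths(x, m, y, cov)
    acme, ade = a * b, c_prime
    total = acme + ade

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab, bb, cb = _batched_paths(x, m, y, cov, idx)
    acme_b, ade_b = ab * bb, cb
    total_b = acme_b + ade_b
    lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100

    def ci(v):
        return tuple(np.percentile(v, [lo, hi]))

    prop = acme / total if abs(total) > PROP_MEDIATED_FLOOR else None
    return MediationResult(
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        prop_mediated=None if prop is None else float(prop),
        ci_acme=ci(acme_b),
        ci_ade=ci(ade_b),
        ci_total=ci(total_b),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


def mediation_screen(
    candidates,
    subjects: pd.DataFrame,
    pd_table: np.ndarray,
    matrices: dict,
    meta,
    covariates=None,
    subset: str = "cases_only",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`mediate` for each (mediator_regions, outcome_edge) candidate.

    ``candidates`` is a list of ``(mediator, (edge_a, edge_b))`` where
    ``mediator`` is a region id or a tuple of region ids (multiple mediator
    regions are averaged into a composite PD mediator). The outcome is the
    Fisher-z connectivity of the named edge. By default analysis is restricted
    to depressed cases, matching the connectivity-CRP convention.
    """
    from .core import CASE_GROUPS
    from .inference import fisher_z

    if subset == "cases_only":
        mask = subjects["group"].isin(CASE_GROUPS).to_numpy()
    elif subset == "all":
        mask = np.ones(len(subjects), dtype=bool)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    sub = subjects.loc[mask]
    x = sub["crp"].to_numpy(float)
    order = sub["subject_id"].tolist()
    cov = sub[list(covariates)] if covariates else None

    rows = []
    for mediator, (ea, eb) in candidates:
        regions = (mediator,) if isinstance(mediator, str) else tuple(mediator)
        midx = [meta.index_of(r) for r in regions]
        m = pd_table[np.ix_(midx, np.flatnonzero(mask))].mean(axis=0)
        i, j = meta.index_of(ea), meta.index_of(eb)
        y = fisher_z(np.array([matrices[sid].r[i, j] for sid in order]))
        res = mediate(x, m, y, covariates=cov, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "mediator": "+".join(regions),
                "edge": f"{ea}--{eb}",
                "acme": res.acme,
                "ade": res.ade,
                "total": res.total,
                "prop_mediated": res.prop_mediated,
                "acme_lo": res.ci_acme[0],
                "acme_hi": res.ci_acme[1],
                "ade_lo": res.ci_ade[0],
                "ade_hi": res.ci_ade[1],
                "acme_significant": not (res.ci_acme[0] <= 0 <= res.ci_acme[1]),
                "ade_significant": not (res.ci_ade[0] <= 0 <= res.ci_ade[1]),
            }
        )
    return pd.DataFrame(rows)
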