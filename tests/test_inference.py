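"""KS tests, mass-univariate OLS, BH-FDR, and the hierarchy orchestration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crpconn.connectome import functional_connectivity, weighted_degree
from crpconn.inference import (
    HierarchyConfig,
    fdr_bh,
    group_difference,
    ks_compare,
    mass_univariate_regression,
    run_hierarchy,
)
from crpconn.synth import CohortConfig, EffectSpec, simulate_dataset, simulate_pd


def _subjects(n, rng, crp=None):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": "loCRP",
            "crp": rng.uniform(0.1, 2.9, n) if crp is None else crp,
            "age": rng.uniform(20, 60, n),
            "sex": "F",
            "bmi": 25.0,
            "centre": rng.choice(["C1", "C2"], n),
            "qc_pass": True,
        }
    )


class TestKS:
    def test_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_samples_match_permutation_enumeration(self):
        """Exact p for {1,2,3} vs {4,5,6}: of the 20 label splits, 2 give
        D = 1, so p = 0.1."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        d, p = ks_compare(a, b)
        assert d == 1.0
        assert p == pytest.approx(_permutation_ks_p(a, b))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6), (2, 6)])
    def test_small_sample_p_equals_permutation(self, na, nb, rng):
        a = rng.standard_normal(na)
        b = rng.standard_normal(nb) + 0.5
        _, p = ks_compare(a, b)
        assert p == pytest.approx(_permutation_ks_p(a, b), abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])

    def test_large_shift_detected(self, rng):
        a = rng.standard_normal(70_500)
        b = rng.standard_normal(70_500) + 0.1
        _, p = ks_compare(a, b)
        assert p < 1e-16


def _permutation_ks_p(a, b):
    """Brute-force two-sample KS p: enumerate every assignment of the pooled
    values into groups of the original sizes."""
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = _ks_stat(np.sort(a), np.sort(b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        d = _ks_stat(np.sort(pooled[mask]), np.sort(pooled[~mask]))
        count += d >= obs - 1e-12
        total += 1
    return count / total


def _ks_stat(a, b):
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    return np.abs(cdf_a - cdf_b).max()


class TestFdrBH:
    def test_all_ones_no_rejections(self):
        q, rej = fdr_bh(np.ones(10))
        assert not rej.any()

    def test_hand_stepup_example(self):
        q, rej = fdr_bh([0.001, 0.02, 0.03, 0.5], q=0.05)
        assert rej.tolist() == [True, True, True, False]
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_single_p_identity(self):
        q, rej = fdr_bh([0.04], q=0.05)
        assert q[0] == pytest.approx(0.04) and rej[0]

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        q, _ = fdr_bh(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_bh_dominates_bonferroni(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 200))
            _, rej_bh = fdr_bh(p, q=0.05)
            rej_bonf = p < 0.05 / p.size
            assert (rej_bh | ~rej_bonf).all()  # BH rejects a superset

    def test_q_at_least_p(self, rng):
        p = rng.random(1000)
        q, _ = fdr_bh(p)
        assert (q >= p - 1e-12).all()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestMassUnivariate:
    def test_noiseless_recovery(self, rng):
        subjects = _subjects(40, rng)
        y = (2 + 0.1 * subjects["crp"].to_numpy())[None, :].repeat(3, axis=0)
        res = mass_univariate_regression(
            y, subjects, ["u1", "u2", "u3"], covariates=()
        )
        np.testing.assert_allclose(res["beta"], 0.1, atol=1e-12)
        assert (res["p"] < 1e-10).all()

    def test_constant_crp_degenerate_design(self, rng):
        subjects = _subjects(20, rng, crp=np.full(20, 1.5))
        with pytest.raises(ValueError, match="rank-deficient"):
            mass_univariate_regression(
                np.zeros((2, 20)), subjects, ["a", "b"], covariates=()
            )

    def test_constant_y_flagged(self, rng):
        subjects = _subjects(30, rng)
        y = np.vstack([np.full(30, 5.0), rng.standard_normal(30)])
        res = mass_univariate_regression(y, subjects, ["const", "noise"])
        row = res.set_index("unit_id").loc["const"]
        assert row["p"] == 1.0 and row["beta"] == 0.0 and row["degenerate"]

    def test_beta_matches_normal_equations_oracle(self, rng):
        """Per-unit betas equal the closed-form (X'X)^-1 X'y solution."""
        for _ in range(10):
            n = int(rng.integers(20, 60))
            subjects = _subjects(n, rng)
            y = rng.standard_normal((5, n))
            res = mass_univariate_regression(y, subjects, list("abcde"))
            # oracle: explicit normal equations with dummy-coded centre
            x = subjects["crp"].to_numpy()
            centre = (subjects["centre"] == "C2").to_numpy(float)
            X = np.column_stack([np.ones(n), x, centre, subjects["age"]])
            beta_hat = np.linalg.solve(X.T @ X, X.T @ y.T)[1]
            np.testing.assert_allclose(res["beta"], beta_hat, atol=1e-8)

    def test_covariate_adjustment_changes_estimate(self, rng):
        subjects = _subjects(60, rng)
        y = (0.05 * subjects["age"].to_numpy() + rng.standard_normal(60))[None, :]
        r_adj = mass_univariate_regression(y, subjects, ["u"], covariates=("age",))
        r_raw = mass_univariate_regression(y, subjects, ["u"], covariates=())
        assert r_adj["beta"].iloc[0] != r_raw["beta"].iloc[0]


class TestGroupDifference:
    def test_label_shuffle_gives_uniform_p(self, rng):
        """With identical group distributions the p-values are uniform
        (KS against U(0,1) does not reject)."""
        n = 120
        subjects = _subjects(n, rng)
        subjects["group"] = np.where(np.arange(n) % 2 == 0, "HC", "loCRP")
        y = rng.standard_normal((376, n))
        res = group_difference(y, subjects, [f"r{i}" for i in range(376)],
                               covariates=())
        from scipy import stats

        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_single_group_rejected(self, rng):
        subjects = _subjects(20, rng)  # all loCRP
        with pytest.raises(ValueError, match="each group"):
            group_difference(np.zeros((2, 20)), subjects, ["a", "b"])

    def test_known_shift_detected(self, rng):
        n = 100
        subjects = _subjects(n, rng)
        subjects.loc[: n // 2 - 1, "group"] = "HC"
        y = rng.standard_normal((10, n)) * 0.1
        is_case = (subjects["group"] != "HC").to_numpy()
        y[0] += is_case * 1.0
        res = group_difference(y, subjects, [f"u{i}" for i in range(10)],
                               covariates=())
        assert res["significant"].iloc[0]
        assert res["beta"].iloc[0] == pytest.approx(1.0, abs=0.1)


@pytest.fixture(scope="module")
def dataset():
    return simulate_dataset(
        CohortConfig(n_hc=8, n_locrp=8, n_hicrp=8, t_points=64), seed=21
    )


class TestHierarchy:
    def _tables(self, ds):
        order = ds.subjects["subject_id"]
        matrices = {s: functional_connectivity(ds.panels[s]) for s in order}
        pd_table = np.stack([ds.qmt[s].pd for s in order], axis=1)
        degree = np.stack([weighted_degree(matrices[s]).k for s in order], axis=1)
        return pd_table, degree, matrices

    def test_full_run_produces_all_levels(self, dataset):
        pd_table, degree, matrices = self._tables(dataset)
        config = HierarchyConfig(gate=False, covariates=())
        res = run_hierarchy(dataset.subjects, pd_table, degree, matrices,
                            dataset.meta, config)
        assert {t["modality"] for t in res.global_tests} == {"pd", "degree", "edges"}
        assert "pd_crp" in res.nodal_tables
        assert "degree_group" in res.nodal_tables
        assert len(res.edge_table) == 70500

    def test_gating_disabled_equals_stagewise(self, dataset):
        pd_table, degree, matrices = self._tables(dataset)
        config = HierarchyConfig(gate=False, covariates=())
        res = run_hierarchy(dataset.subjects, pd_table, degree, matrices,
                            dataset.meta, config)
        direct = mass_univariate_regression(
            pd_table, dataset.subjects, dataset.meta.region_ids,
            covariates=(), subset=config.pd_subset,
        )
        pd.testing.assert_frame_equal(res.nodal_tables["pd_crp"], direct)

    def test_null_cohort_gate_closed_for_pd(self, meta, rng):
        """With no effects the PD gate typically stays shut and nodal PD
        tables are not produced."""
        config = CohortConfig(n_hc=30, n_locrp=30, n_hicrp=30, t_points=64)
        from crpconn.synth import generate_cohort

        subjects = generate_cohort(config, seed=33)
        qmt = simulate_pd(subjects, meta, EffectSpec.null(), seed=33)
        pd_table = np.stack([qmt[s].pd for s in subjects["subject_id"]], axis=1)
        # degree/edge inputs: identical panels not needed; reuse pd-based nulls
        degree = rng.standard_normal(pd_table.shape) * 0.01 + 0.2
        from crpconn.core import ConnectivityMatrix
        from crpconn.synth import simulate_panel

        matrices = {
            s: functional_connectivity(simulate_panel(np.eye(20), 64, 2.57, seed=i))
            for i, s in enumerate(subjects["subject_id"])
        }
        # shrink meta-dependent steps by using gate-only config
        config_h = HierarchyConfig(gate=True, covariates=())

        class SmallMeta:
            n_regions = 20
            region_ids = np.array([f"r{i}" for i in range(20)])

        res = run_hierarchy(
            subjects, pd_table[:20], degree[:20], matrices, SmallMeta(), config_h
        )
        assert res.gate_passed["pd"] is False
        assert "pd_crp" not in res.nodal_tables
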