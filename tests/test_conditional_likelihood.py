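import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import calspline as cs
from calspline import SplineBasis, stratum_loglik
from calspline.calibration import impute_biomarker

from conftest import random_nm_strata

QUARTILES = (-0.6744897501960817, 0.0, 0.6744897501960817)


# ----------------------------------------------------------------------
# independent brute-force oracle: direct enumeration of all case-sets
# ----------------------------------------------------------------------
def brute_stratum_loglik(beta, y, G):
    """log P(observed case set | stratum, #cases) by full enumeration."""
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y)
    n_cases = int(y.sum())
    cases = tuple(np.flatnonzero(y == 1))
    terms = {}
    for subset in combinations(range(len(y)), n_cases):
        terms[subset] = float(beta @ G[list(subset)].sum(axis=0))
    mx = max(terms.values())
    denom = sum(math.exp(v - mx) for v in terms.values())
    return terms[cases] - mx - math.log(denom)


def brute_total_negloglik(beta, strata):
    return -sum(brute_stratum_loglik(beta, y, G) for y, G in strata)


def dataset_to_strata(dataset, basis):
    imp = impute_biomarker(dataset, {}, "naive")
    fx = cs.eval_basis(basis, imp.values)
    out = []
    for _, g in dataset.table.assign(_f1=fx[:, 0], _f2=fx[:, 1]).groupby(
        ["study", "stratum"], sort=False
    ):
        out.append((g["case"].to_numpy(), g[["_f1", "_f2"]].to_numpy()))
    return out


# ----------------------------------------------------------------------
class TestStratumLoglik:
    def test_null_one_to_one_is_log_half(self):
        val = stratum_loglik([0.0], None, y=[0, 1], f_x=[[1.0], [2.0]])
        assert val == pytest.approx(-math.log(2), abs=1e-12)

    @pytest.mark.parametrize("n,m", [(1, 1), (1, 3), (2, 2), (3, 4)])
    def test_null_nm_is_log_binomial(self, n, m):
        y = [0] * m + [1] * n
        fx = np.random.default_rng(0).normal(size=(n + m, 1))
        val = stratum_loglik([0.0], None, y=y, f_x=fx)
        assert val == pytest.approx(-math.log(math.comb(n + m, n)), abs=1e-12)

    def test_one_to_one_scalar_value(self):
        # f(ctrl) - f(case) = 1, beta = 0.5 -> -log(1 + e^0.5)
        val = stratum_loglik([0.5], None, y=[0, 1], f_x=[[1.0], [0.0]])
        assert val == pytest.approx(-math.log(1 + math.exp(0.5)), abs=1e-12)

    def test_matches_brute_force_on_random_strata(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            total = rng.integers(2, 9)
            n_cases = rng.integers(1, total)
            y = np.r_[np.zeros(total - n_cases, int), np.ones(n_cases, int)]
            G = rng.normal(size=(total, 2))
            beta = rng.normal(scale=0.7, size=2)
            ours = stratum_loglik(beta, None, y=y, f_x=G)
            assert ours == pytest.approx(brute_stratum_loglik(beta, y, G), abs=1e-10)

    def test_shift_invariance_within_stratum(self):
        rng = np.random.default_rng(4)
        y = [0, 0, 1, 1]
        G = rng.normal(size=(4, 2))
        beta = [0.3, -0.2]
        shifted = G + np.array([5.0, -7.0])
        assert stratum_loglik(beta, None, y=y, f_x=G) == pytest.approx(
            stratum_loglik(beta, None, y=y, f_x=shifted), abs=1e-10
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1, 0, 1, 0])
        G = rng.normal(size=(5, 2))
        beta = [0.4, 0.1]
        base = stratum_loglik(beta, None, y=y, f_x=G)
        perm = rng.permutation(5)
        assert stratum_loglik(beta, None, y=y[perm], f_x=G[perm]) == pytest.approx(
            base, abs=1e-10
        )

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(cs.ValidationError):
            stratum_loglik([0.1], None, y=[0, 1], f_x=[[np.nan], [0.0]])


@pytest.fixture(scope="module")
def nm_dataset():
    return random_nm_strata(np.random.default_rng(12), n_strata=10)


class TestTotalAndDerivatives:

    def test_null_total_is_sum_of_log_binomials(self, nm_dataset):
        basis = SplineBasis(QUARTILES)
        imp = impute_biomarker(nm_dataset, {}, "naive")
        total = cs.total_negloglik(np.zeros(2), nm_dataset, imp, basis)
        sizes = nm_dataset.table.groupby(["study", "stratum"], sort=False)["case"].agg(
            ["size", "sum"]
        )
        expected = sum(math.log(math.comb(int(s), int(c))) for s, c in sizes.to_numpy())
        assert total == pytest.approx(expected, abs=1e-10)

    def test_score_zero_on_mirrored_strata(self):
        # stratum 2 swaps the case/control biomarkers of stratum 1
        frame = pd.DataFrame(
            {
                "study": "s1",
                "stratum": [1, 1, 2, 2],
                "case": [0, 1, 0, 1],
                "local_value": [0.3, 1.1, 1.1, 0.3],
                "reference_value": [0.3, 1.1, 1.1, 0.3],
                "in_calibration": 0,
            }
        )
        data = cs.PooledDataset.from_frame(frame)
        basis = SplineBasis(QUARTILES)
        imp = impute_biomarker(data, {}, "naive")
        g = cs.score(np.zeros(2), data, imp, basis)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_score_matches_finite_differences(self, nm_dataset):
        basis = SplineBasis(QUARTILES)
        imp = impute_biomarker(nm_dataset, {}, "naive")
        rng = np.random.default_rng(7)
        beta = rng.normal(scale=0.5, size=2)
        g = cs.score(beta, nm_dataset, imp, basis)
        h = 1e-6
        fd = np.empty_like(g)
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            fd[k] = -(
                cs.total_negloglik(beta + e, nm_dataset, imp, basis)
                - cs.total_negloglik(beta - e, nm_dataset, imp, basis)
            ) / (2 * h)
        assert np.max(np.abs(g - fd) / (1 + np.abs(fd))) < 1e-5

    def test_hessian_matches_finite_differences_and_is_nsd(self, nm_dataset):
        basis = SplineBasis(QUARTILES)
        imp = impute_biomarker(nm_dataset, {}, "naive")
        rng = np.random.default_rng(8)
        for _ in range(5):
            beta = rng.normal(scale=0.6, size=2)
            H = cs.hessian(beta, nm_dataset, imp, basis)
            h = 1e-5
            fd = np.empty((2, 2))
            for k in range(2):
                e = np.zeros(2)
                e[k] = h
                fd[:, k] = (
                    cs.score(beta + e, nm_dataset, imp, basis)
                    - cs.score(beta - e, nm_dataset, imp, basis)
                ) / (2 * h)
            assert np.max(np.abs(H - fd) / (1 + np.abs(fd))) < 1e-5
            assert np.all(np.linalg.eigvalsh(H) <= 1e-10)


class TestFitDoseResponse:
    def test_matches_brute_force_fit_on_reference_data(self):
        """All-reference n:m data: Newton fit equals an independently
        optimized full-enumeration conditional likelihood to 1e-6."""
        data = random_nm_strata(np.random.default_rng(30), n_strata=40, max_total=8)
        basis = SplineBasis(QUARTILES)
        fit = cs.fit_dose_response(data, basis=basis, method="full")
        assert fit.converged
        strata = dataset_to_strata(data, basis)
        res = optimize.minimize(
            brute_total_negloglik,
            np.zeros(2),
            args=(strata,),
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        assert np.max(np.abs(fit.beta_x - res.x)) < 1e-6
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_matches_statsmodels_conditional_logit(self, reference_dataset):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        basis = SplineBasis(QUARTILES)
        fit = cs.fit_dose_response(reference_dataset, basis=basis, method="full")
        df = reference_dataset.table
        fx = cs.eval_basis(basis, df["reference_value"].to_numpy(dtype=float))
        groups = pd.factorize(pd.Series(list(zip(df["study"], df["stratum"]))))[0]
        sm_fit = ConditionalLogit(df["case"].to_numpy(), fx, groups=groups).fit(disp=0)
        assert np.allclose(fit.beta_x, sm_fit.params, atol=1e-5)
        assert np.allclose(fit.se("model"), sm_fit.bse, atol=1e-5)

    def test_row_permutation_invariance(self, small_dataset):
        basis = SplineBasis(QUARTILES)
        base = cs.fit_dose_response(small_dataset, basis=basis, method="full")
        rng = np.random.default_rng(9)
        shuffled = small_dataset.table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        refit = cs.fit_dose_response(
            cs.PooledDataset(shuffled, (), frozenset()), basis=basis, method="full"
        )
        assert np.allclose(base.beta_x, refit.beta_x, atol=1e-10)
        assert np.allclose(base.sandwich_cov, refit.sandwich_cov, atol=1e-10)

    def test_null_recovery(self):
        config = cs.default_scenario(
            beta_x=(0.0, 0.0), pairs_per_study=400, n_studies=2,
            a=(-1.0, 1.0), b=(0.8, 1.25), sigma2_w=(1.2, 0.6),
            calibration_proportion=0.3,
        )
        data = cs.generate_pooled_data(config, seed=77)
        fit = cs.fit_dose_response(data, basis=SplineBasis(QUARTILES), method="full")
        se = fit.se("sandwich")
        assert fit.converged
        assert np.all(np.abs(fit.beta_x) < 3.5 * se[:2])

    def test_separation_raises(self):
        # cases always have the larger biomarker value -> unbounded likelihood
        n = 30
        rng = np.random.default_rng(13)
        x_ctrl = rng.normal(size=n)
        frame = pd.DataFrame(
            {
                "study": "s1",
                "stratum": np.repeat(np.arange(n), 2),
                "case": np.tile([0, 1], n),
                "local_value": np.column_stack([x_ctrl, x_ctrl + 3.0]).ravel(),
                "reference_value": np.column_stack([x_ctrl, x_ctrl + 3.0]).ravel(),
                "in_calibration": 0,
            }
        )
        data = cs.PooledDataset.from_frame(frame)
        with pytest.raises((cs.SeparationError, np.linalg.LinAlgError)):
            fit = cs.fit_dose_response(data, basis=SplineBasis(QUARTILES), method="full")
            assert not fit.converged
            raise cs.SeparationError("fit flagged non-convergence instead of diverging")

    def test_oversized_stratum_rejected(self):
        rows = []
        for i in range(25):
            rows.append(dict(study="s1", stratum=0, case=int(i < 12), local_value=float(i),
                             reference_value=float(i), in_calibration=0))
        data = cs.PooledDataset.from_frame(pd.DataFrame(rows))
        with pytest.raises(cs.ValidationError, match="enumeration"):
            cs.fit_dose_response(data, basis=SplineBasis(QUARTILES), method="full")
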