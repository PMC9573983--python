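"""REML animal models: oracle agreement, BLUP identities, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from shrimpqg.linear_mixed_model import (
    DegenerateInputError,
    _RotatedWorkspace,
    _design,
    fit_bivariate,
    fit_univariate,
    heritability,
    read_phenotype_csv,
    summarize_table1,
    write_phenotype_csv,
)
from shrimpqg.pedigree import a_matrix
from shrimpqg.synthetic_data import simulate_pedigree, simulate_traits

from .conftest import small_sim_config


def dense_reml_oracle(y, X, M, start=(0.5, 0.5)):
    """Derivative-free maximisation of the explicit dense restricted ll."""
    n = len(y)

    def negll(logtheta):
        sa, se = np.exp(logtheta)
        V = sa * M + se * np.eye(n)
        try:
            np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
        r = y - X @ beta
        return 0.5 * (
            np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1] + r @ Vinv @ y
        )

    res = minimize(
        negll,
        np.log(np.asarray(start) * np.var(y, ddof=1)),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
    )
    return np.exp(res.x), -res.fun


def dense_blup_oracle(y, X, M, A, animal_idx, sa, se):
    """GLS fixed effects + BLUP breeding values from dense algebra."""
    n = len(y)
    V = sa * M + se * np.eye(n)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = y - X @ beta
    # cov(a_all, y) = sa * A[:, records]
    return sa * A[:, animal_idx] @ (Vinv @ resid)


class TestHeritability:
    @pytest.mark.parametrize(
        "sa,se,expected",
        [(1.51, 2.75, 0.35), (1.78, 30.92, 0.05), (0.0, 2.0, 0.0)],
    )
    def test_published_component_identities(self, sa, se, expected):
        assert round(heritability(sa, se), 2) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            heritability(-0.1, 1.0)
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


class TestUnivariate:
    def test_matches_dense_likelihood_oracle(self):
        """AI-REML optimum equals a derivative-free dense-V optimiser."""
        cfg = small_sim_config(seed=2, n_progeny=40)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        vc, _ = fit_univariate(ds.phenotypes, "t", ped, compute_reliability=False)
        Y, X, aidx = _design(ds.phenotypes, ["t"], ped)
        A = a_matrix(ped).toarray()
        M = A[np.ix_(aidx, aidx)]
        (sa, se), ll = dense_reml_oracle(Y[:, 0], X, M)
        assert vc.sigma2_A == pytest.approx(sa, abs=1e-4)
        assert vc.sigma2_e == pytest.approx(se, abs=1e-4)
        assert vc.loglik >= ll - 1e-6

    def test_blup_matches_dense_gls_oracle(self):
        cfg = small_sim_config(seed=3, n_progeny=50)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        vc, ebv = fit_univariate(ds.phenotypes, "t", ped)
        Y, X, aidx = _design(ds.phenotypes, ["t"], ped)
        A = a_matrix(ped).toarray()
        M = A[np.ix_(aidx, aidx)]
        oracle = dense_blup_oracle(Y[:, 0], X, M, A, aidx, vc.sigma2_A, vc.sigma2_e)
        assert np.abs(ebv.aligned(ped.ids) - oracle).max() < 1e-8

    def test_invariant_to_record_reordering(self):
        cfg = small_sim_config(seed=4, n_progeny=60)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        vc1, _ = fit_univariate(ds.phenotypes, "t", ped, compute_reliability=False)
        shuffled = ds.phenotypes.sample(frac=1, random_state=1).reset_index(drop=True)
        vc2, _ = fit_univariate(shuffled, "t", ped, compute_reliability=False)
        assert vc1.sigma2_A == pytest.approx(vc2.sigma2_A, abs=1e-6)
        assert vc1.sigma2_e == pytest.approx(vc2.sigma2_e, abs=1e-6)

    def test_null_genetic_variance_estimated_near_zero(self):
        cfg = small_sim_config(seed=5, sigma2_A=0.0, n_progeny=150)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        vc, _ = fit_univariate(ds.phenotypes, "t", ped, compute_reliability=False)
        assert vc.h2 < 0.1

    def test_animals_without_records_get_ebvs(self):
        cfg = small_sim_config(seed=6)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        _, ebv = fit_univariate(ds.phenotypes, "t", ped)
        assert set(ebv.ebv) == set(ped.ids)  # founders have no records
        assert ebv.reliability is not None
        assert all(0 <= r <= 1 for r in ebv.reliability.values())

    def test_missing_phenotypes_dropped_and_degenerate_rejected(self):
        cfg = small_sim_config(seed=7)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        phenos = ds.phenotypes.copy()
        phenos.loc[phenos.index[:10], "t"] = np.nan
        vc, _ = fit_univariate(phenos, "t", ped, compute_reliability=False)
        assert vc.n_records == len(phenos) - 10
        phenos["const"] = 1.0
        with pytest.raises(DegenerateInputError):
            fit_univariate(phenos, "const", ped)

    def test_missing_pond_rejected(self):
        cfg = small_sim_config(seed=8)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        phenos = ds.phenotypes.copy()
        phenos.loc[phenos.index[0], "pond"] = np.nan
        with pytest.raises(ValueError, match="pond"):
            fit_univariate(phenos, "t", ped)


class TestBivariate:
    @staticmethod
    def _pair_config(seed, rg=0.8, h2=0.3, n_progeny=400):
        from shrimpqg.synthetic_data import SimulationConfig

        G = np.array([[h2, rg * h2], [rg * h2, h2]])
        E = np.array([[1 - h2, 0.1], [0.1, 1 - h2]])
        return SimulationConfig(
            n_sires=20, n_dams=20, n_families=25, n_progeny=n_progeny, n_ponds=3,
            trait_names=["x", "y"], G=G, E=E,
            pond_effect_sd={"x": 0.3, "y": 0.3}, seed=seed,
        )

    def test_same_genetic_basis_gives_high_rg(self):
        """trait y = x's genetics + independent noise => rg near 1."""
        cfg = small_sim_config(seed=9, n_progeny=400)
        cfg.n_sires = cfg.n_dams = 25
        cfg.n_families = 30
        cfg.__post_init__()
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        phenos = ds.phenotypes.copy()
        rng = np.random.default_rng(0)
        phenos["t2"] = phenos["t"] + rng.normal(0, 0.5, size=len(phenos))
        ce = fit_bivariate(phenos, ("t", "t2"), ped)
        assert ce.rg >= 0.95

    def test_identical_traits_hit_the_boundary(self):
        cfg = small_sim_config(seed=10, n_progeny=200)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        phenos = ds.phenotypes.copy()
        phenos["t2"] = phenos["t"]
        ce = fit_bivariate(phenos, ("t", "t2"), ped)
        assert ce.rg == pytest.approx(1.0, abs=1e-6)
        assert ce.boundary

    def test_independent_traits_centered_on_zero(self):
        rgs = []
        for seed in range(6):
            cfg = self._pair_config(seed, rg=0.0)
            ped = simulate_pedigree(cfg)
            ds = simulate_traits(ped, cfg)
            rgs.append(fit_bivariate(ds.phenotypes, ("x", "y"), ped).rg)
        assert abs(np.mean(rgs)) < 0.25

    def test_rg_and_rp_within_bounds(self):
        cfg = self._pair_config(11)
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        ce = fit_bivariate(ds.phenotypes, ("x", "y"), ped)
        assert -1 <= ce.rg <= 1 and -1 <= ce.rp <= 1
        assert ce.G2[0, 1] == ce.G2[1, 0]
        assert np.all(np.diag(ce.G2) >= 0) and np.all(np.diag(ce.E2) >= 0)


class TestDescriptives:
    def test_cv_from_published_mean_and_sd(self):
        df = pd.DataFrame(
            {"animal": ["a", "b"], "pond": ["A", "A"], "w": [10.14, 17.14]}
        )
        out = summarize_table1(df, ["w"])
        assert out.loc[0, "mean"] == pytest.approx(13.64)
        # CV formula identity on the published body-weight mean/SD
        assert 100 * 3.50 / 13.64 == pytest.approx(25.7, abs=0.05)

    def test_two_value_closed_form(self):
        df = pd.DataFrame({"animal": ["a", "b"], "pond": ["A", "A"], "t": [1.0, 3.0]})
        out = summarize_table1(df, ["t"]).iloc[0]
        assert out["mean"] == 2.0
        assert out["sd"] == pytest.approx(np.sqrt(2))
        assert out["min"] == 1.0 and out["max"] == 3.0

    def test_constant_trait_zero_cv(self):
        df = pd.DataFrame({"animal": list("abc"), "pond": ["A"] * 3, "t": [2.0] * 3})
        out = summarize_table1(df, ["t"]).iloc[0]
        assert out["sd"] == 0.0 and out["cv_pct"] == 0.0

    def test_phenotype_csv_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"animal": ["a", "b"], "pond": ["A", "B"], "t": [1.5, np.nan]}
        )
        path = tmp_path / "ph.csv"
        write_phenotype_csv(df, path)
        back = read_phenotype_csv(path)
        assert back["t"].isna().sum() == 1
        assert list(back["animal"]) == ["a", "b"]
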