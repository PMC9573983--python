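"""Simulated pedigrees and phenotypes: structure, moments, determinism."""

import math

import numpy as np
import pytest
from scipy.special import expit

from shrimpqg import study_params as sp_
from shrimpqg.synthetic_data import (
    SimulationConfig,
    default_config,
    liability_to_ordinal,
    marginal_thresholds,
    nearest_psd,
    simulate_pedigree,
    simulate_traits,
)

from .conftest import small_sim_config


class TestConfig:
    def test_default_config_matches_study_design(self):
        cfg = default_config(seed=0)
        assert (cfg.n_sires, cfg.n_dams, cfg.n_families, cfg.n_progeny, cfg.n_ponds) == (
            55, 52, 67, 838, 7,
        )
        assert np.linalg.eigvalsh(cfg.G).min() >= -1e-8
        assert np.linalg.eigvalsh(cfg.E).min() >= -1e-8
        for trait, (c, theta) in cfg.ordinal_specs.items():
            assert len(theta) == c - 1 and np.all(np.diff(theta) > 0)
        # ordinal residual is the logistic variance
        for trait in sp_.ORDINAL_TRAITS:
            i = cfg.trait_names.index(trait)
            assert cfg.E[i, i] == pytest.approx(math.pi**2 / 3)

    @pytest.mark.parametrize(
        "override,message",
        [
            (dict(n_families=5), "n_families"),
            (dict(n_progeny=5), "n_progeny"),
            (dict(n_families=100), "families"),
        ],
    )
    def test_infeasible_counts_rejected(self, override, message):
        base = dict(
            n_sires=8, n_dams=8, n_families=10, n_progeny=60, n_ponds=3,
            trait_names=["t"], G=np.eye(1), E=np.eye(1), pond_effect_sd={"t": 0.1},
        )
        base.update(override)
        with pytest.raises(ValueError, match=message):
            SimulationConfig(**base)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationConfig(
                n_sires=4, n_dams=4, n_families=4, n_progeny=8, n_ponds=2,
                trait_names=["a", "b"], G=bad, E=np.eye(2),
                pond_effect_sd={"a": 0.1, "b": 0.1},
            )

    def test_nearest_psd_projection(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        fixed = nearest_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(nearest_psd(np.eye(3)), np.eye(3))


class TestSimulatePedigree:
    def test_study_design_counts(self):
        ped = simulate_pedigree(default_config(seed=4))
        assert len(ped) == 945
        pairs = {
            (r.sire, r.dam) for r in ped.records if r.sire is not None
        }
        assert len(pairs) == 67
        assert len(ped.sires) == 55 and len(ped.dams) == 52

    def test_monogamous_design_is_full_sib_only(self):
        cfg = SimulationConfig(
            n_sires=6, n_dams=6, n_families=6, n_progeny=30, n_ponds=2,
            trait_names=["t"], G=np.eye(1), E=np.eye(1), pond_effect_sd={"t": 0.1},
        )
        ped = simulate_pedigree(cfg)
        sires_of = {}
        for r in ped.records:
            if r.sire is not None:
                sires_of.setdefault(r.sire, set()).add(r.dam)
        assert all(len(d) == 1 for d in sires_of.values())

    def test_same_seed_identical(self):
        cfg = default_config(seed=9)
        assert simulate_pedigree(cfg).ids == simulate_pedigree(default_config(seed=9)).ids


class TestBreedingValues:
    def test_zero_genetic_variance_gives_zero_bvs(self):
        cfg = small_sim_config(seed=1, sigma2_A=0.0)
        ds = simulate_traits(simulate_pedigree(cfg), cfg)
        assert np.allclose(ds.true_breeding_values.to_numpy(), 0.0)

    def test_founder_bv_covariance_matches_G(self):
        """Founder breeding values are N(0, G): Monte-Carlo moment check."""
        G = np.array([[1.0, 0.6], [0.6, 2.0]])
        cfg = SimulationConfig(
            n_sires=5000, n_dams=5000, n_families=5000, n_progeny=5000, n_ponds=2,
            trait_names=["x", "y"], G=G, E=np.eye(2),
            pond_effect_sd={"x": 0.0, "y": 0.0}, seed=5,
        )
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        founders = [r.animal for r in ped.records if r.sire is None and r.dam is None]
        bv = ds.true_breeding_values.loc[founders].to_numpy()
        emp = np.cov(bv.T)
        n = len(founders)
        # var of sample (co)variances ~ (G_ii G_jj + G_ij^2)/n
        for i in range(2):
            for j in range(2):
                se = math.sqrt((G[i, i] * G[j, j] + G[i, j] ** 2) / n)
                assert abs(emp[i, j] - G[i, j]) < 3 * se

    def test_full_sib_bv_correlation_near_half(self):
        cfg = SimulationConfig(
            n_sires=2500, n_dams=2500, n_families=2500, n_progeny=5000, n_ponds=2,
            trait_names=["t"], G=np.eye(1), E=np.eye(1),
            pond_effect_sd={"t": 0.0}, seed=6,
        )
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        fams: dict[tuple, list[str]] = {}
        for r in ped.records:
            if r.sire is not None:
                fams.setdefault((r.sire, r.dam), []).append(r.animal)
        pairs = [v[:2] for v in fams.values() if len(v) >= 2]
        bv = ds.true_breeding_values["t"]
        x = np.array([bv[a] for a, _ in pairs])
        y = np.array([bv[b] for _, b in pairs])
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r - 0.5) < 3.0 / math.sqrt(len(pairs))

    def test_parent_offspring_regression_recovers_h2(self):
        """Slope of offspring on sire phenotype ~ h2/2 (no pond effects)."""
        h2 = 0.4
        cfg = SimulationConfig(
            n_sires=5000, n_dams=5000, n_families=5000, n_progeny=10000, n_ponds=2,
            trait_names=["t"], G=np.array([[h2]]), E=np.array([[1 - h2]]),
            pond_effect_sd={"t": 0.0}, seed=7,
        )
        ped = simulate_pedigree(cfg)
        ds = simulate_traits(ped, cfg)
        bv = ds.true_breeding_values["t"]
        rng = np.random.default_rng(8)
        # phenotype sires as well (founders have no records by design)
        sire_ph = {
            s: bv[s] + rng.normal(0, math.sqrt(1 - h2)) for s in ped.sires
        }
        ph = ds.phenotypes.set_index("animal")["t"]
        sire_of = {r.animal: r.sire for r in ped.records if r.sire is not None}
        x = np.array([sire_ph[sire_of[a]] for a in ph.index])
        y = ph.to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(h2 / 2, abs=0.03)


class TestOrdinal:
    def test_boundary_liabilities(self):
        theta = np.array([-1.0, 0.5, 2.0])
        assert liability_to_ordinal(-1e308, theta, add_residual=False)[0] == 1
        assert liability_to_ordinal(1e308, theta, add_residual=False)[0] == 4

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            liability_to_ordinal(0.0, np.array([1.0, 0.5]), add_residual=False)

    def test_logistic_symmetry_at_zero_threshold(self):
        rng = np.random.default_rng(9)
        scores = liability_to_ordinal(np.zeros(200_000), np.array([0.0]), rng=rng)
        p1 = np.mean(scores == 1)
        assert p1 == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(200_000))

    def test_marginals_match_proportional_odds_closed_form(self):
        """Independent liabilities: score CDF equals the logistic mixture."""
        rng = np.random.default_rng(10)
        sd = 0.8
        theta = np.array([-1.2, 0.3, 1.5])
        liab = rng.normal(0, sd, size=100_000)
        scores = liability_to_ordinal(liab, theta, rng=rng)
        # closed form by quadrature
        from scipy.special import roots_hermitenorm

        nodes, w = roots_hermitenorm(80)
        w = w / w.sum()
        for k, t in enumerate(theta, start=1):
            target = float(w @ expit(t - nodes * sd))
            obs = np.mean(scores <= k)
            se = math.sqrt(target * (1 - target) / 100_000)
            assert abs(obs - target) < 4 * se

    def test_study_marginals_across_seeds(self):
        """Mean category frequencies across seeds match the published ones."""
        target = np.array([29, 272, 424, 113]) / 838
        props = []
        for seed in range(10):
            cfg = default_config(seed=seed)
            ds = simulate_traits(simulate_pedigree(cfg), cfg)
            y = ds.phenotypes["manual_uncooked"]
            props.append([(y == k).mean() for k in (1, 2, 3, 4)])
        props = np.asarray(props)
        se = props.std(axis=0, ddof=1) / math.sqrt(len(props))
        assert np.all(np.abs(props.mean(axis=0) - target) < 3 * se + 0.01)

    def test_marginal_thresholds_invert_the_quadrature(self):
        cum = np.array([0.1, 0.5, 0.9])
        theta = marginal_thresholds(cum, liability_sd=1.3)
        from scipy.special import roots_hermitenorm

        nodes, w = roots_hermitenorm(61)
        w = w / w.sum()
        back = [float(w @ expit(t - nodes * 1.3)) for t in theta]
        assert np.allclose(back, cum, atol=1e-10)


class TestDeterminism:
    def test_identical_seeds_bitwise_identical(self):
        cfg = small_sim_config(seed=33)
        ds1 = simulate_traits(simulate_pedigree(cfg), cfg)
        cfg2 = small_sim_config(seed=33)
        ds2 = simulate_traits(simulate_pedigree(cfg2), cfg2)
        assert ds1.phenotypes.equals(ds2.phenotypes)
        assert ds1.true_breeding_values.equals(ds2.true_breeding_values)

    def test_different_seed_differs(self):
        cfg = small_sim_config(seed=33)
        cfg2 = small_sim_config(seed=34)
        ds1 = simulate_traits(simulate_pedigree(cfg), cfg)
        ds2 = simulate_traits(simulate_pedigree(cfg2), cfg2)
        assert not ds1.phenotypes["t"].equals(ds2.phenotypes["t"])
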