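"""Synthetic pedigrees and phenotypes with the study's statistical structure.

The generator emulates the design of the shrimp cohort the analysis is
calibrated to: 55 sires and 52 dams producing 67 full-/half-sib
families and 838 progeny reared in 7 ponds.  Continuous traits follow
``y = mu + pond + a + e`` with breeding values generated by the
Mendelian-sampling recursion over the pedigree
(``a_i = 0.5 (a_s + a_d) + m_i``, ``m_i ~ N(0, 0.5 (1 - (F_s+F_d)/2) G)``),
and ordinal scores arise from a logistic liability crossing ordered
thresholds — the proportional-odds (cumulative logit) model, whose
residual variance is pi^2/3.

Default parameters are the published estimates in
:mod:`shrimpqg.study_params`; thresholds are solved so that the
marginal score frequencies match the published score distribution, and
pond-effect magnitudes (not reported in the source tables) default to
0.3 phenotypic SD — an invented but visibly pond-structured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from . import study_params as sp_
from .pedigree import Pedigree, PedigreeRecord, build_pedigree, inbreeding_coefficients

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_config",
    "simulate_pedigree",
    "simulate_traits",
    "simulate_dataset",
    "liability_to_ordinal",
    "marginal_thresholds",
    "nearest_psd",
    "single_trait_study_config",
    "ordinal_study_config",
    "trait_pair_study_config",
]


@dataclass
class SimulationConfig:
    """Design sizes, covariance structure and ordinal specs for a simulation."""

    n_sires: int
    n_dams: int
    n_families: int
    n_progeny: int
    n_ponds: int
    trait_names: list[str]
    G: np.ndarray
    E: np.ndarray
    pond_effect_sd: dict[str, float]
    ordinal_specs: dict[str, tuple[int, np.ndarray]] = field(default_factory=dict)
    trait_means: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        t = len(self.trait_names)
        self.G = np.asarray(self.G, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        for name, mat in (("G", self.G), ("E", self.E)):
            if mat.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t} to match trait_names")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(mat).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.n_families < max(self.n_sires, self.n_dams):
            raise ValueError("n_families must be >= max(n_sires, n_dams)")
        if self.n_progeny < self.n_families:
            raise ValueError("n_progeny must be >= n_families")
        if self.n_families > self.n_sires * self.n_dams:
            raise ValueError("more families than distinct sire x dam pairs")
        for trait, (c, theta) in self.ordinal_specs.items():
            theta = np.asarray(theta, dtype=float)
            if trait not in self.trait_names:
                raise ValueError(f"ordinal trait {trait!r} not in trait_names")
            if len(theta) != c - 1 or np.any(np.diff(theta) <= 0):
                raise ValueError(f"thresholds for {trait!r} must be {c - 1} increasing values")
            self.ordinal_specs[trait] = (c, theta)

    @property
    def continuous_traits(self) -> list[str]:
        return [t for t in self.trait_names if t not in self.ordinal_specs]


@dataclass
class SimulatedDataset:
    """Pedigree + phenotypes + the true breeding values that generated them."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame  # animal x trait
    true_parameters: SimulationConfig


def nearest_psd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Nearest (in Frobenius sense) PSD matrix by eigenvalue clipping."""
    mat = 0.5 * (mat + mat.T)
    w, V = np.linalg.eigh(mat)
    if w.min() >= 0:
        return mat
    w = np.clip(w, eps, None)
    return V @ np.diag(w) @ V.T


def marginal_thresholds(
    cum_probs: np.ndarray, liability_sd: float, n_quad: int = 61
) -> np.ndarray:
    """Thresholds giving target marginal cumulative score probabilities.

    The marginal P(score <= k) under a N(0, liability_sd^2) systematic
    liability plus standard-logistic residual is
    ``E_x[ logistic(theta_k - x) ]``; each theta_k is solved by 1-D
    root finding with Gauss-Hermite quadrature over x.
    """
    cum_probs = np.asarray(cum_probs, dtype=float)
    if np.any(np.diff(cum_probs) <= 0) or cum_probs.min() <= 0 or cum_probs.max() >= 1:
        raise ValueError("cumulative probabilities must be increasing in (0, 1)")
    nodes, weights = roots_hermitenorm(n_quad)
    weights = weights / weights.sum()
    x = nodes * liability_sd

    def marginal(theta):
        return float(weights @ expit(theta - x))

    return np.array(
        [brentq(lambda t, p=p: marginal(t) - p, -60, 60, xtol=1e-12) for p in cum_probs]
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """The study conditions: published design sizes and parameter tables.

    G is assembled from the published additive variances and genetic
    correlations, E from residual variances and the residual
    covariances implied by the phenotypic correlations
    (cov_E = rp sqrt(P_x P_y) - cov_G over A + E); covariances between
    an ordinal liability residual and anything else are zero (the
    logistic residual is independent).  Both matrices are projected to
    the nearest PSD matrix if assembly leaves them indefinite.
    """
    traits = list(sp_.TRAITS)
    t = len(traits)
    s2a = np.array([sp_.VARIANCE_COMPONENTS[x][0] for x in traits])
    s2e = np.array([sp_.VARIANCE_COMPONENTS[x][1] for x in traits])
    sd_a = np.sqrt(s2a)
    G = sp_.GENETIC_CORRELATIONS * np.outer(sd_a, sd_a)
    G = nearest_psd(G)
    P = s2a + s2e
    covP = sp_.PHENOTYPIC_CORRELATIONS * np.outer(np.sqrt(P), np.sqrt(P))
    E = covP - G
    np.fill_diagonal(E, s2e)
    ordinal_idx = [traits.index(x) for x in sp_.ORDINAL_TRAITS]
    for i in ordinal_idx:  # logistic residual is independent of everything
        E[i, :] = 0.0
        E[:, i] = 0.0
        E[i, i] = sp_.LOGISTIC_RESIDUAL_VARIANCE
    E = nearest_psd(E)
    np.fill_diagonal(E, s2e)
    E = nearest_psd(E)

    pond_sd = {x: 0.3 * math.sqrt(s2a[i] + s2e[i]) for i, x in enumerate(traits)}
    ordinal_specs = {}
    for trait, c in sp_.ORDINAL_TRAITS.items():
        counts = sp_.SCORE_COUNTS[trait]
        n = sum(counts.values())
        cum = np.cumsum([counts[k] for k in sorted(counts)])[:-1] / n
        liab_sd = math.sqrt(
            sp_.VARIANCE_COMPONENTS[trait][0] + pond_sd[trait] ** 2
        )
        ordinal_specs[trait] = (c, marginal_thresholds(cum, liab_sd))
    means = {x: sp_.DESCRIPTIVES[x][1] for x in traits if x in sp_.DESCRIPTIVES}
    return SimulationConfig(
        n_sires=sp_.DESIGN["n_sires"],
        n_dams=sp_.DESIGN["n_dams"],
        n_families=sp_.DESIGN["n_families"],
        n_progeny=sp_.DESIGN["n_progeny"],
        n_ponds=sp_.DESIGN["n_ponds"],
        trait_names=traits,
        G=G,
        E=E,
        pond_effect_sd=pond_sd,
        ordinal_specs=ordinal_specs,
        trait_means=means,
        seed=seed,
    )


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Simulate the mating design: unrelated founders, recurring mates.

    Every sire and every dam is used at least once; the remaining
    families re-use parents at random (producing the half-sib
    structure), and progeny are allocated to families as evenly as the
    totals allow.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sires = [f"S{i + 1:03d}" for i in range(cfg.n_sires)]
    dams = [f"D{i + 1:03d}" for i in range(cfg.n_dams)]
    records = [PedigreeRecord(x) for x in sires + dams]
    # guarantee full usage: pair i-th sire with i-th dam cyclically
    base = max(cfg.n_sires, cfg.n_dams)
    pairs = {(sires[i % cfg.n_sires], dams[i % cfg.n_dams]) for i in range(base)}
    while len(pairs) < cfg.n_families:
        pairs.add((sires[rng.integers(cfg.n_sires)], dams[rng.integers(cfg.n_dams)]))
    families = sorted(pairs)
    rng.shuffle(families)
    counts = np.full(len(families), cfg.n_progeny // len(families))
    counts[: cfg.n_progeny % len(families)] += 1
    prog = 0
    for (sire, dam), k in zip(families, counts):
        for _ in range(int(k)):
            prog += 1
            records.append(PedigreeRecord(f"P{prog:04d}", sire, dam))
    return build_pedigree(records)


def _breeding_values(ped: Pedigree, G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian-sampling recursion for multivariate breeding values."""
    t = G.shape[0]
    # eigen square root: robust to singular (e.g. all-zero) G
    w, V = np.linalg.eigh(G)
    Lg = V * np.sqrt(np.clip(w, 0.0, None))
    F = inbreeding_coefficients(ped)
    n = len(ped)
    a = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0 and di < 0:
            a[i] = Lg @ z[i]
            continue
        mean = np.zeros(t)
        frac = 1.0
        fs = fd = 0.0
        if si >= 0:
            mean += 0.5 * a[si]
            fs = F[si]
        if di >= 0:
            mean += 0.5 * a[di]
            fd = F[di]
        if si >= 0 and di >= 0:
            frac = 0.5 * (1.0 - 0.5 * (fs + fd))
        elif si >= 0 or di >= 0:
            fk = fs if si >= 0 else fd
            frac = 0.75 - 0.25 * fk
        a[i] = mean + math.sqrt(frac) * (Lg @ z[i])
    return a


def liability_to_ordinal(
    liability: np.ndarray | float,
    thresholds: np.ndarray,
    rng: np.random.Generator | None = None,
    add_residual: bool = True,
) -> np.ndarray:
    """Score = 1 + number of thresholds below (liability + logistic noise).

    With ``add_residual`` a standard-logistic residual (variance
    pi^2/3) is added, so marginal category probabilities follow the
    proportional-odds model.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    liab = np.atleast_1d(np.asarray(liability, dtype=float))
    if add_residual:
        if rng is None:
            raise ValueError("rng required when adding the logistic residual")
        liab = liab + rng.logistic(size=liab.shape)
    return (liab[:, None] > thresholds[None, :]).sum(axis=1).astype(np.int64) + 1


def simulate_traits(ped: Pedigree, cfg: SimulationConfig) -> SimulatedDataset:
    """Phenotypes for all progeny of a simulated pedigree.

    Progeny (animals with known parents) are assigned uniformly to
    ponds; pond effects are drawn N(0, pond_effect_sd^2) per trait but
    fitted downstream as fixed effects.  Continuous phenotypes are
    mu + pond + a + e with e ~ N(0, E); ordinal scores come from the
    pond + a liability with an added logistic residual.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    traits = cfg.trait_names
    a = _breeding_values(ped, cfg.G, rng)
    ids = ped.ids
    is_progeny = (ped.sire_idx >= 0) | (ped.dam_idx >= 0)
    prog_idx = np.flatnonzero(is_progeny)
    n = len(prog_idx)
    pond_labels = np.array([chr(ord("A") + k) for k in range(cfg.n_ponds)])
    pond_of = rng.integers(cfg.n_ponds, size=n)
    pond_effects = {
        trait: rng.normal(0.0, cfg.pond_effect_sd.get(trait, 0.0), size=cfg.n_ponds)
        for trait in traits
    }
    cont = cfg.continuous_traits
    cont_idx = [traits.index(x) for x in cont]
    Ec = cfg.E[np.ix_(cont_idx, cont_idx)]
    Lc = np.linalg.cholesky(Ec + 1e-12 * np.eye(len(cont_idx)))
    resid = rng.standard_normal((n, len(cont_idx))) @ Lc.T
    data: dict[str, np.ndarray] = {
        "animal": np.array(ids, dtype=object)[prog_idx],
        "pond": pond_labels[pond_of],
    }
    for j, trait in zip(cont_idx, cont):
        mu = cfg.trait_means.get(trait, 0.0)
        data[trait] = (
            mu
            + pond_effects[trait][pond_of]
            + a[prog_idx, j]
            + resid[:, cont.index(trait)]
        )
    for trait, (c, theta) in cfg.ordinal_specs.items():
        j = traits.index(trait)
        liab = pond_effects[trait][pond_of] + a[prog_idx, j]
        data[trait] = liability_to_ordinal(liab, theta, rng=rng)
    phenos = pd.DataFrame(data)
    tbv = pd.DataFrame(a, index=pd.Index(ids, name="animal"), columns=traits)
    return SimulatedDataset(
        pedigree=ped,
        phenotypes=phenos,
        true_breeding_values=tbv,
        true_parameters=cfg,
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Convenience: simulate_pedigree + simulate_traits in one call."""
    return simulate_traits(simulate_pedigree(cfg), cfg)


def single_trait_study_config(
    sigma2_A: float, sigma2_e: float, seed: int, pond_sd_frac: float = 0.3
) -> SimulationConfig:
    """Study-design simulation of one continuous trait (recovery experiments)."""
    sd = pond_sd_frac * math.sqrt(sigma2_A + sigma2_e)
    return SimulationConfig(
        **sp_.DESIGN,
        trait_names=["t"],
        G=np.array([[sigma2_A]]),
        E=np.array([[sigma2_e]]),
        pond_effect_sd={"t": sd},
        seed=seed,
    )


def ordinal_study_config(
    sigma2_A: float,
    c: int,
    seed: int,
    cum_probs: np.ndarray | None = None,
    pond_sd_frac: float = 0.3,
) -> SimulationConfig:
    """Study-design simulation of one ordinal trait under proportional odds.

    Thresholds are solved so the marginal score frequencies match
    ``cum_probs`` (default: the published uncooked/cooked distribution
    for c = 4 / c = 3).
    """
    if cum_probs is None:
        counts = sp_.SCORE_COUNTS["manual_uncooked" if c == 4 else "manual_cooked"]
        n = sum(counts.values())
        cum_probs = np.cumsum([counts[k] for k in sorted(counts)])[:-1] / n
    res = sp_.LOGISTIC_RESIDUAL_VARIANCE
    pond_sd = pond_sd_frac * math.sqrt(sigma2_A + res)
    theta = marginal_thresholds(np.asarray(cum_probs), math.sqrt(sigma2_A + pond_sd**2))
    return SimulationConfig(
        **sp_.DESIGN,
        trait_names=["s"],
        G=np.array([[sigma2_A]]),
        E=np.array([[res]]),
        pond_effect_sd={"s": pond_sd},
        ordinal_specs={"s": (c, theta)},
        seed=seed,
    )


def trait_pair_study_config(
    rg: float,
    h2_x: float,
    h2_y: float,
    seed: int,
    ordinal_x: int | None = None,
    pond_sd_frac: float = 0.3,
) -> SimulationConfig:
    """Study-design simulation of a trait pair with genetic correlation rg.

    Both traits have unit residual-scale phenotypic structure; if
    ``ordinal_x`` is a category count, trait x becomes an ordinal score
    whose liability has the logistic residual and additive variance
    chosen to give the requested liability h2.
    """
    res = sp_.LOGISTIC_RESIDUAL_VARIANCE
    if ordinal_x:
        s2x = h2_x / (1.0 - h2_x) * res
        e_x = res
    else:
        s2x, e_x = h2_x, 1.0 - h2_x
    s2y, e_y = h2_y, 1.0 - h2_y
    cov = rg * math.sqrt(s2x * s2y)
    G = np.array([[s2x, cov], [cov, s2y]])
    E = np.diag([e_x, e_y])
    pond_sd = {
        "x": pond_sd_frac * math.sqrt(s2x + e_x),
        "y": pond_sd_frac * math.sqrt(s2y + e_y),
    }
    ordinal_specs = {}
    if ordinal_x:
        counts = sp_.SCORE_COUNTS["manual_uncooked" if ordinal_x == 4 else "manual_cooked"]
        n = sum(counts.values())
        cum = np.cumsum([counts[k] for k in sorted(counts)])[:-1] / n
        theta = marginal_thresholds(cum, math.sqrt(s2x + pond_sd["x"] ** 2))
        ordinal_specs["x"] = (ordinal_x, theta)
    return SimulationConfig(
        **sp_.DESIGN,
        trait_names=["x", "y"],
        G=G,
        E=E,
        pond_effect_sd=pond_sd,
        ordinal_specs=ordinal_specs,
        seed=seed,
    )
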