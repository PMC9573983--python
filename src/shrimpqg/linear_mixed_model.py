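"""Univariate and bivariate animal models fitted by REML.

The model for a continuous trait is ``y_ij = mu + Pond_j + a_i + e_ij``
with pond a fixed effect, ``a ~ N(0, sigma2_A A)`` the additive genetic
effect (A the numerator relationship matrix from the pedigree) and
``e ~ N(0, sigma2_e I)``.  Heritability is
``h2 = sigma2_A / (sigma2_A + sigma2_e)``.

Estimation strategy
-------------------
Writing ``M = Z A Z'`` for the genetic covariance among the phenotyped
records, the phenotypic covariance is ``V = sigma2_A M + sigma2_e I``.
After one eigendecomposition ``M = U D U'`` the rotated data have
diagonal covariance ``sigma2_A D + sigma2_e I``, so every restricted
log-likelihood, gradient and average-information evaluation costs
O(n p^2) instead of O(n^3).  The univariate fit runs average-information
(AI) REML on the log-variance scale with step-halving and a
multiplicative EM-like fallback; the bivariate fit maximises the same
rotated restricted likelihood over Cholesky factors of the 2x2 genetic
and residual covariance matrices (which keeps both PSD by
construction).

Breeding values (EBVs) are BLUPs from the mixed-model equations at the
REML estimates, using the sparse pedigree-based inverse of A, so
animals without records are evaluated through their relatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize

from .pedigree import Pedigree, a_inverse, a_matrix, inbreeding_coefficients

__all__ = [
    "VarianceComponents",
    "EBVSet",
    "CorrelationEstimate",
    "DegenerateInputError",
    "fit_univariate",
    "fit_bivariate",
    "heritability",
    "summarize_table1",
    "read_phenotype_csv",
    "write_phenotype_csv",
]

logger = logging.getLogger(__name__)

_VARIANCE_FLOOR_FRAC = 1e-10  # of the phenotypic variance
_MAX_ITER = 100
_LL_TOL = 1e-8
_PAR_TOL = 1e-6


class DegenerateInputError(ValueError):
    """Trait with no usable variation (or no usable records)."""


@dataclass
class VarianceComponents:
    """REML variance components and heritability for one trait."""

    trait: str
    sigma2_A: float
    sigma2_e: float
    h2: float
    se_sigma2_A: float = np.nan
    se_sigma2_e: float = np.nan
    se_h2: float = np.nan
    converged: bool = True
    n_iterations: int = 0
    loglik: float = np.nan
    n_records: int = 0


@dataclass
class EBVSet:
    """Predicted breeding values for every pedigree animal."""

    trait: str
    ebv: dict[str, float]
    reliability: dict[str, float] | None = None

    def aligned(self, ids: list[str]) -> np.ndarray:
        return np.array([self.ebv[i] for i in ids])


@dataclass
class CorrelationEstimate:
    """Bivariate REML genetic and phenotypic correlation for a trait pair."""

    trait_pair: tuple[str, str]
    G2: np.ndarray
    E2: np.ndarray
    rg: float
    rp: float
    se_rg: float = np.nan
    converged: bool = True
    boundary: bool = False
    n_records: int = 0


def heritability(sigma2_A: float, sigma2_e: float) -> float:
    """h2 = sigma2_A / (sigma2_A + sigma2_e)."""
    if sigma2_A < 0 or sigma2_e <= 0:
        raise ValueError("need sigma2_A >= 0 and sigma2_e > 0")
    return sigma2_A / (sigma2_A + sigma2_e)


# ---------------------------------------------------------------------------
# Design construction


def _design(
    phenos: pd.DataFrame, traits: list[str], ped: Pedigree
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Y (n x t), X, animal_indices) for complete-case records."""
    if "animal" not in phenos.columns or "pond" not in phenos.columns:
        raise ValueError("phenotype table needs 'animal' and 'pond' columns")
    for t in traits:
        if t not in phenos.columns:
            raise KeyError(f"trait {t!r} not in phenotype table")
    df = phenos.dropna(subset=list(traits))
    if df["pond"].isna().any():
        raise ValueError("records with missing pond are not allowed")
    unknown = set(df["animal"].astype(str)) - set(ped.order)
    if unknown:
        raise ValueError(f"phenotyped animals missing from pedigree: {sorted(unknown)[:5]}")
    if len(df) == 0:
        raise DegenerateInputError("no complete records for " + ", ".join(traits))
    Y = df[list(traits)].to_numpy(dtype=float)
    if np.any(Y.std(axis=0) == 0):
        raise DegenerateInputError("zero phenotypic variance")
    ponds = sorted(df["pond"].astype(str).unique())
    n = len(df)
    # intercept + full-rank pond dummies (first pond is the reference)
    X = np.ones((n, 1 + max(len(ponds) - 1, 0)))
    pond_codes = df["pond"].astype(str).to_numpy()
    for k, p in enumerate(ponds[1:], start=1):
        X[:, k] = (pond_codes == p).astype(float)
    animal_idx = np.array([ped.order[a] for a in df["animal"].astype(str)])
    return Y, X, animal_idx


class _RotatedWorkspace:
    """Eigen-rotated REML workspace shared by the uni- and bivariate fits."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, animal_idx: np.ndarray, ped: Pedigree):
        A = a_matrix(ped).toarray()
        M = A[np.ix_(animal_idx, animal_idx)]  # Z A Z' for one record per row
        d, U = np.linalg.eigh(M)
        d = np.clip(d, 0.0, None)
        self.d = d
        self.Y = U.T @ Y
        self.X = U.T @ X
        self.n, self.p = X.shape


# ---------------------------------------------------------------------------
# Univariate AI-REML


def _uni_reml_quantities(theta: np.ndarray, ws: _RotatedWorkspace, y: np.ndarray):
    """Restricted ll, Py and projection helpers at (sigma2_A, sigma2_e)."""
    sa, se = theta
    v = sa * ws.d + se
    w = 1.0 / v
    X = ws.X
    Xw = X * w[:, None]
    C = X.T @ Xw  # X' V^-1 X
    Cinv = np.linalg.inv(C)
    b = Xw.T @ y

    def Pdot(u):
        wu = w * u
        return wu - Xw @ (Cinv @ (Xw.T @ u))

    Py = Pdot(y)
    yPy = float(y @ Py)
    _, ldC = np.linalg.slogdet(C)
    ll = -0.5 * (np.sum(np.log(v)) + ldC + yPy)
    return ll, Py, Pdot, w, Xw, Cinv


def _uni_loglik(theta, ws, y):
    if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
        return -np.inf
    try:
        return _uni_reml_quantities(theta, ws, y)[0]
    except np.linalg.LinAlgError:
        return -np.inf


def _fit_univariate_reml(ws: _RotatedWorkspace) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    """AI-REML on the log-variance scale; returns (theta, AI, converged, iters, ll)."""
    y = ws.Y[:, 0]
    vary = float(np.var(y, ddof=1))
    floor = _VARIANCE_FLOOR_FRAC * vary
    theta = np.array([0.5 * vary, 0.5 * vary])
    ll, Py, Pdot, w, Xw, Cinv = _uni_reml_quantities(theta, ws, y)
    AI = np.eye(2)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        d = ws.d
        # traces of P V_dot: tr(PD) and tr(P)
        XwT = Xw.T
        trPD = float(np.sum(w * d) - np.einsum("ij,ji->", Cinv, XwT @ (Xw * d[:, None])))
        trP = float(np.sum(w) - np.einsum("ij,ji->", Cinv, XwT @ Xw))
        u_a = d * Py
        u_e = Py
        # scores: dl/ds_i = -0.5 [tr(P Vdot_i) - Py' Vdot_i Py]
        score = -0.5 * np.array([trPD - float(Py @ u_a), trP - float(Py @ u_e)])
        Pu_a, Pu_e = Pdot(u_a), Pdot(u_e)
        AI = 0.5 * np.array(
            [
                [float(u_a @ Pu_a), float(u_a @ Pu_e)],
                [float(u_e @ Pu_a), float(u_e @ Pu_e)],
            ]
        )
        # KKT: a component pinned at the floor with a negative score stays put
        active = (theta <= floor * (1 + 1e-12)) & (score < 0)
        free = ~active
        if not np.any(free):
            converged = True
            break
        # work on the log scale to stay positive, over free components only
        J = np.diag(theta[free])
        g_log = J @ score[free]
        H_log = J @ AI[np.ix_(free, free)] @ J
        try:
            step_free = np.linalg.solve(H_log + 1e-12 * np.eye(free.sum()), g_log)
        except np.linalg.LinAlgError:
            step_free = g_log / max(np.abs(np.diag(H_log)).max(), 1.0)
        # a near-singular AI matrix (variance near the boundary) can propose
        # arbitrarily large log-scale steps; trust region of 4 log units
        norm = np.abs(step_free).max()
        if not np.isfinite(norm):
            step_free = g_log / (1 + np.abs(g_log))
        elif norm > 4.0:
            step_free = step_free * (4.0 / norm)
        step = np.zeros(2)
        step[free] = step_free
        new_ll = -np.inf
        accepted = False
        for _ in range(30):
            cand = np.maximum(np.exp(np.log(theta) + step), floor)
            cand_ll = _uni_loglik(cand, ws, y)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                new_ll, accepted = cand_ll, True
                break
            step *= 0.5
        if not accepted:
            # multiplicative EM-like fallback: guaranteed-positive update
            num = np.array([float(Py @ u_a), float(Py @ u_e)])
            den = np.array([max(trPD, 1e-12), max(trP, 1e-12)])
            cand = theta.copy()
            cand[free] = np.maximum(
                (theta * np.sqrt(np.maximum(num, 0.0) / den))[free], floor
            )
            cand_ll = _uni_loglik(cand, ws, y)
            if not np.isfinite(cand_ll) or cand_ll < ll - 1e-9:
                converged = True  # no direction improves: at the optimum
                break
            new_ll = cand_ll
        rel = np.max(np.abs(cand - theta) / np.maximum(theta, floor))
        dll = new_ll - ll
        theta = cand
        ll, Py, Pdot, w, Xw, Cinv = _uni_reml_quantities(theta, ws, y)
        if abs(dll) < _LL_TOL and rel < _PAR_TOL:
            converged = True
            break
    return theta, AI, converged, it, ll


def _solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    animal_idx: np.ndarray,
    ped: Pedigree,
    sigma2_A: float,
    sigma2_e: float,
    compute_reliability: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """BLUP solutions of the mixed-model equations for all pedigree animals."""
    q = len(ped)
    n, p = X.shape
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), animal_idx)), shape=(n, q))
    Ainv = a_inverse(ped).values
    lam = sigma2_e / max(sigma2_A, _VARIANCE_FLOOR_FRAC * float(np.var(y, ddof=1)))
    Zd = Z.toarray()
    C = np.block(
        [
            [X.T @ X, X.T @ Zd],
            [Zd.T @ X, Zd.T @ Zd + lam * Ainv.toarray()],
        ]
    )
    rhs = np.concatenate([X.T @ y, Zd.T @ y])
    if compute_reliability:
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        pev = np.diag(Cinv)[p:] * sigma2_e
        F = inbreeding_coefficients(ped)
        denom = (1.0 + F) * max(sigma2_A, 1e-300)
        rel = np.clip(1.0 - pev / denom, 0.0, 1.0)
    else:
        sol = np.linalg.solve(C, rhs)
        rel = None
    return sol[p:], rel


def fit_univariate(
    phenos: pd.DataFrame,
    trait: str,
    ped: Pedigree,
    compute_reliability: bool = True,
) -> tuple[VarianceComponents, EBVSet]:
    """REML fit of the univariate animal model with pond fixed effects.

    Returns the variance components (with approximate standard errors
    from the inverse average-information matrix and the delta method
    for h2) and BLUP breeding values for every pedigree animal.
    Non-convergence is flagged on the result, not raised.
    """
    Y, X, animal_idx = _design(phenos, [trait], ped)
    ws = _RotatedWorkspace(Y, X, animal_idx, ped)
    theta, AI, converged, iters, ll = _fit_univariate_reml(ws)
    sa, se = float(theta[0]), float(theta[1])
    h2 = heritability(sa, se)
    se_sa = se_se = se_h2 = np.nan
    try:
        cov = np.linalg.inv(AI)
        se_sa, se_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        ph = sa + se
        grad = np.array([se / ph**2, -sa / ph**2])
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - singular AI
        pass
    if not converged:
        logger.warning("univariate REML for %s did not converge in %d iterations", trait, iters)
    vc = VarianceComponents(
        trait=trait,
        sigma2_A=sa,
        sigma2_e=se,
        h2=h2,
        se_sigma2_A=float(se_sa),
        se_sigma2_e=float(se_se),
        se_h2=float(se_h2),
        converged=converged,
        n_iterations=iters,
        loglik=float(ll),
        n_records=ws.n,
    )
    ebv, rel = _solve_mme(
        Y[:, 0], X, animal_idx, ped, sa, se, compute_reliability=compute_reliability
    )
    ids = ped.ids
    ebv_set = EBVSet(
        trait=trait,
        ebv=dict(zip(ids, map(float, ebv))),
        reliability=None if rel is None else dict(zip(ids, map(float, rel))),
    )
    return vc, ebv_set


# ---------------------------------------------------------------------------
# Bivariate REML (Cholesky-parameterised)


def _chol_from_params(p3: np.ndarray) -> np.ndarray:
    L = np.zeros((2, 2))
    L[0, 0] = np.exp(p3[0])
    L[1, 0] = p3[1]
    L[1, 1] = np.exp(p3[2])
    return L


def _biv_neg_loglik(params: np.ndarray, ws: _RotatedWorkspace) -> float:
    La = _chol_from_params(params[:3])
    Le = _chol_from_params(params[3:])
    G = La @ La.T
    E = Le @ Le.T
    return -_biv_loglik_GE(G, E, ws)


def _biv_loglik_GE(G: np.ndarray, E: np.ndarray, ws: _RotatedWorkspace) -> float:
    """Rotated bivariate restricted log-likelihood at covariance (G, E)."""
    d = ws.d
    y1, y2 = ws.Y[:, 0], ws.Y[:, 1]
    X = ws.X
    s11 = d * G[0, 0] + E[0, 0]
    s12 = d * G[0, 1] + E[0, 1]
    s22 = d * G[1, 1] + E[1, 1]
    det = s11 * s22 - s12 * s12
    if np.any(det <= 0) or np.any(s11 <= 0) or np.any(s22 <= 0):
        return -np.inf
    i11 = s22 / det
    i12 = -s12 / det
    i22 = s11 / det
    yVy = float(i11 @ y1**2 + 2 * (i12 @ (y1 * y2)) + i22 @ y2**2)
    B11 = X.T @ (X * i11[:, None])
    B12 = X.T @ (X * i12[:, None])
    B22 = X.T @ (X * i22[:, None])
    C = np.block([[B11, B12], [B12, B22]])
    r = np.concatenate(
        [X.T @ (i11 * y1 + i12 * y2), X.T @ (i12 * y1 + i22 * y2)]
    )
    sign, ldC = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    try:
        beta = np.linalg.solve(C, r)
    except np.linalg.LinAlgError:
        return -np.inf
    yPy = yVy - float(r @ beta)
    return -0.5 * (float(np.sum(np.log(det))) + ldC + yPy)


def _pack_GE(G: np.ndarray, E: np.ndarray) -> np.ndarray:
    return np.array([G[0, 0], G[0, 1], G[1, 1], E[0, 0], E[0, 1], E[1, 1]])


def _biv_loglik_packed(v: np.ndarray, ws: _RotatedWorkspace) -> float:
    G = np.array([[v[0], v[1]], [v[1], v[2]]])
    E = np.array([[v[3], v[4]], [v[4], v[5]]])
    return _biv_loglik_GE(G, E, ws)


def fit_bivariate(
    phenos: pd.DataFrame,
    traits: tuple[str, str],
    ped: Pedigree,
) -> CorrelationEstimate:
    """Bivariate REML animal model for a pair of continuous traits.

    Records missing either trait are dropped (complete-case).  The 2x2
    genetic and residual covariance matrices are optimised through
    their Cholesky factors (always PSD); the genetic correlation is
    clamped to [-1, 1] with a boundary flag, and its standard error
    comes from the numerical observed information of the restricted
    likelihood in covariance coordinates.
    """
    tx, ty = traits
    Y, X, animal_idx = _design(phenos, [tx, ty], ped)
    ws = _RotatedWorkspace(Y, X, animal_idx, ped)
    v1, v2 = np.var(ws.Y[:, 0], ddof=1), np.var(ws.Y[:, 1], ddof=1)
    # start at h2 ~ 0.33 and modest positive correlations
    start = []
    for share, cross in ((1 / 3, 0.05), (2 / 3, 0.05)):
        s1, s2 = share * v1, share * v2
        l11 = np.sqrt(s1)
        l21 = cross * np.sqrt(s1 * s2) / l11
        l22 = np.sqrt(max(s2 - l21**2, 1e-8 * s2))
        start += [np.log(l11), l21, np.log(l22)]
    res = minimize(
        _biv_neg_loglik,
        np.array(start),
        args=(ws,),
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    La = _chol_from_params(res.x[:3])
    Le = _chol_from_params(res.x[3:])
    G = La @ La.T
    E = Le @ Le.T
    denom_g = np.sqrt(G[0, 0] * G[1, 1])
    rg_raw = G[0, 1] / denom_g if denom_g > 0 else np.nan
    boundary = bool(abs(rg_raw) > 1 - 1e-6 or min(G[0, 0], G[1, 1]) < 1e-8 * max(v1, v2))
    rg = float(np.clip(rg_raw, -1.0, 1.0))
    P = G + E
    rp = float((G[0, 1] + E[0, 1]) / np.sqrt(P[0, 0] * P[1, 1]))
    se_rg = _se_rg_numeric(G, E, ws)
    return CorrelationEstimate(
        trait_pair=(tx, ty),
        G2=G,
        E2=E,
        rg=rg,
        rp=rp,
        se_rg=se_rg,
        converged=bool(res.success),
        boundary=boundary,
        n_records=ws.n,
    )


def _se_rg_numeric(G: np.ndarray, E: np.ndarray, ws: _RotatedWorkspace) -> float:
    """Delta-method SE of rg from the numerical observed information."""
    v0 = _pack_GE(G, E)
    scale = np.maximum(np.abs(v0), 1e-6)
    h = 1e-4 * scale
    k = 6
    H = np.zeros((k, k))
    f0 = _biv_loglik_packed(v0, ws)
    if not np.isfinite(f0):
        return np.nan
    for i in range(k):
        for j in range(i, k):
            vpp = v0.copy(); vpp[i] += h[i]; vpp[j] += h[j]
            vpm = v0.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
            vmp = v0.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
            vmm = v0.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
            vals = [_biv_loglik_packed(v, ws) for v in (vpp, vpm, vmp, vmm)]
            if not np.all(np.isfinite(vals)):
                return np.nan
            H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.nan
    g00, g01, g11 = v0[0], v0[1], v0[2]
    if g00 <= 0 or g11 <= 0:
        return np.nan
    s = np.sqrt(g00 * g11)
    grad = np.zeros(k)
    grad[0] = -0.5 * g01 / (s * g00)
    grad[1] = 1.0 / s
    grad[2] = -0.5 * g01 / (s * g11)
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else np.nan


# ---------------------------------------------------------------------------
# Descriptive statistics


def summarize_table1(phenos: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait n, mean, SD, CV%, min, max (CV% = 100 SD / mean)."""
    if traits is None:
        traits = [
            c
            for c in phenos.columns
            if c not in ("animal", "pond") and pd.api.types.is_numeric_dtype(phenos[c])
        ]
    rows = []
    for t in traits:
        x = phenos[t].dropna().to_numpy(dtype=float)
        if x.size == 0:
            raise DegenerateInputError(f"no records for trait {t!r}")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if mean == 0 and sd > 0:
            cv = np.nan
        else:
            cv = 0.0 if sd == 0 else 100.0 * sd / mean
        rows.append(
            {
                "trait": t,
                "n": int(x.size),
                "mean": mean,
                "sd": sd,
                "cv_pct": cv,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phenotype CSV dialect: `animal,pond,<trait columns>`; empty cell = missing.


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "animal" not in df.columns or "pond" not in df.columns:
        raise ValueError("phenotype CSV must start with 'animal,pond' columns")
    df["animal"] = df["animal"].astype(str)
    df["pond"] = df["pond"].astype(str)
    return df


def write_phenotype_csv(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, index=False)
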