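"""Trait-evolution model fitting, PGLS, evolutionary correlations and ANOVA.

The likelihood engine is Felsenstein's pruning algorithm for Brownian motion
(BM) on a (possibly transformed) tree: Ornstein–Uhlenbeck (OU), Pagel's
lambda and kappa likelihoods are obtained by transforming branch lengths so
that the BM covariance of the transformed tree equals the model covariance,
then pruning.  The root state ``z0`` and the rate ``sigma2`` are profiled in
closed form (GLS mean, mean squared GLS residual), so every shape parameter
is a bounded one-dimensional search.  All fits are maximum likelihood (not
REML) so AIC values are comparable across models.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo_core import (
    Phylogeny,
    PhyloCovariance,
    kappa_tree,
    lambda_tree,
    ou_tree,
    transform_lambda,
    transform_ou,
    vcv_matrix,
)

__all__ = [
    "EvoModelFit",
    "SignalResult",
    "PglsFit",
    "MvPglsFit",
    "AncestralStates",
    "AnovaResult",
    "bm_loglik",
    "fit_model",
    "select_model",
    "phylo_signal_lambda",
    "pgls",
    "mv_pgls",
    "asr_bm",
    "class_anova",
    "model_covariance",
]

MODELS = ("BM", "lambda", "kappa", "OU")
_MODEL_ORDER = {m: i for i, m in enumerate(("BM", "lambda", "kappa", "OU"))}

# bounded searches for the shape parameters (see docs/methods.md)
KAPPA_MAX = 3.0
OU_ALPHA_REL_BOUNDS = (1e-8, 100.0)  # alpha * T bounds
_XATOL = 1e-8


def _align(tree: Phylogeny, x, what: str = "trait") -> np.ndarray:
    """Order a keyed vector by the tree's tip names, or validate an array."""
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, Mapping):
        missing = [t for t in tree.tip_names if t not in x]
        extra = [k for k in x if k not in set(tree.tip_names)]
        if missing or extra:
            raise ValueError(
                f"{what} does not match tree tips; missing from {what}: "
                f"{missing[:5]}, not in tree: {extra[:5]}"
            )
        arr = np.array([float(x[t]) for t in tree.tip_names])
    else:
        arr = np.asarray(x, dtype=float)
        if arr.shape != (tree.n_tips,):
            raise ValueError(
                f"{what} length {arr.shape} does not match {tree.n_tips} tips"
            )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {what}")
    return arr


# ---------------------------------------------------------------------------
# Pruning likelihood engine
# ---------------------------------------------------------------------------


def _pruning_stats(tree: Phylogeny, x: np.ndarray):
    """One pruning pass; returns (sum_log_v, sum_sq, m_root, v_root).

    ``sum_log_v`` and ``sum_sq`` accumulate the log-variances and normalized
    squared contrasts of the n-1 pairwise combines; the root mean/variance
    give the final factor.  For unit rate the log-likelihood at root state z0
    is ``-n/2 log(2 pi) - (sum_log_v + log v_root)/2
    - (sum_sq + (m_root - z0)^2 / v_root)/2``.
    """
    m = np.zeros(tree.n_nodes)
    v = np.zeros(tree.n_nodes)
    m[: tree.n_tips] = x
    blen = tree.blen
    sum_log = 0.0
    sum_sq = 0.0
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        k0 = kids[0]
        mm = m[k0]
        vv = v[k0] + blen[k0]
        for k in kids[1:]:
            mk = m[k]
            vk = v[k] + blen[k]
            V = vv + vk
            if V <= 0:
                raise ValueError(
                    "degenerate (zero-variance) contrast: two lineages with "
                    "zero total branch length meet"
                )
            d = mm - mk
            sum_log += math.log(V)
            sum_sq += d * d / V
            mm = (mm * vk + mk * vv) / V
            vv = vv * vk / V
        m[node] = mm
        v[node] = vv
    root = tree.root
    if v[root] <= 0:
        raise ValueError("singular tree: zero variance at the root")
    return sum_log, sum_sq, m[root], v[root]


def bm_loglik(tree: Phylogeny, x, sigma2: float, z0: float) -> float:
    """Brownian-motion log-likelihood by pruning (equals the dense MVN density)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    xv = _align(tree, x)
    n = tree.n_tips
    sum_log, sum_sq, m_root, v_root = _pruning_stats(tree, xv)
    quad = sum_sq + (m_root - z0) ** 2 / v_root
    return (
        -0.5 * n * math.log(2.0 * math.pi * sigma2)
        - 0.5 * (sum_log + math.log(v_root))
        - 0.5 * quad / sigma2
    )


def _profile_loglik(tree: Phylogeny, xv: np.ndarray):
    """Maximized (z0, sigma2 profiled) BM log-likelihood on a tree.

    Returns (loglik, sigma2_hat, z0_hat).
    """
    n = tree.n_tips
    sum_log, sum_sq, m_root, v_root = _pruning_stats(tree, xv)
    sigma2 = sum_sq / n
    if sigma2 <= 0:
        raise ValueError("zero phylogenetic variance: constant trait")
    ll = (
        -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        - 0.5 * (sum_log + math.log(v_root))
    )
    return ll, sigma2, m_root


# ---------------------------------------------------------------------------
# Model fitting and selection
# ---------------------------------------------------------------------------


@dataclass
class EvoModelFit:
    """A fitted single-trait evolutionary model."""

    model: str
    sigma2: float
    z0: float
    shape: float | None  # alpha (OU), lambda, or kappa; None for BM
    loglik: float
    n_params: int
    n: int
    tip_names: tuple
    data_hash: str
    note: str | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def shape_name(self) -> str | None:
        return {"BM": None, "OU": "alpha", "lambda": "lambda", "kappa": "kappa"}[
            self.model
        ]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sigma2": self.sigma2,
            "z0": self.z0,
            "shape_name": self.shape_name,
            "shape": self.shape,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "n": self.n,
            "note": self.note,
        }


def _data_hash(tree: Phylogeny, xv: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(",".join(tree.tip_names).encode())
    h.update(xv.tobytes())
    return h.hexdigest()


def _model_tree(tree: Phylogeny, model: str, shape: float | None) -> Phylogeny:
    if model == "BM":
        return tree
    if model == "lambda":
        return lambda_tree(tree, shape)
    if model == "kappa":
        return kappa_tree(tree, shape)
    if model == "OU":
        return ou_tree(tree, shape)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def fit_model(tree: Phylogeny, x, model: str = "BM") -> EvoModelFit:
    """ML fit of a trait-evolution model (BM, OU, Pagel's lambda or kappa).

    The root state and rate are profiled in closed form; the shape parameter
    is found by bounded Brent search (lambda in [0, 1], kappa in [0, 3],
    log alpha in [log(1e-8/T), log(100/T)]).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips to fit an evolutionary model")
    xv = _align(tree, x)
    dh = _data_hash(tree, xv)

    if model == "BM":
        ll, s2, z0 = _profile_loglik(tree, xv)
        return EvoModelFit("BM", s2, z0, None, ll, 2, tree.n_tips, tuple(tree.tip_names), dh)

    if model == "lambda":
        lo, hi = 0.0, 1.0
        to_shape = lambda t: t
    elif model == "kappa":
        lo, hi = 0.0, KAPPA_MAX
        to_shape = lambda t: t
    else:  # OU
        T = tree.height
        lo = math.log(OU_ALPHA_REL_BOUNDS[0] / T)
        hi = math.log(OU_ALPHA_REL_BOUNDS[1] / T)
        to_shape = math.exp

    def negll(t: float) -> float:
        try:
            ll, _, _ = _profile_loglik(_model_tree(tree, model, to_shape(t)), xv)
        except ValueError:
            return np.inf
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(lo, hi), method="bounded", options={"xatol": _XATOL}
    )
    if not res.success:
        raise RuntimeError(
            f"shape-parameter optimization failed for {model}: {res.message}; "
            f"best so far {to_shape(res.x)} with -logLik {res.fun}"
        )
    # compare against the bounds: bounded Brent can miss boundary optima
    cand = [(res.fun, res.x)] + [(negll(b), b) for b in (lo, hi)]
    fun, t_hat = min(cand, key=lambda c: c[0])
    shape = to_shape(t_hat)
    ll, s2, z0 = _profile_loglik(_model_tree(tree, model, shape), xv)

    note = None
    probe = [-negll(lo + f * (hi - lo)) for f in (0.0, 0.5, 1.0)]
    if max(probe) - min(probe) < 1e-6 and abs(max(probe) - ll) < 1e-6:
        note = "shape parameter unidentifiable (flat likelihood profile)"
    return EvoModelFit(
        model, s2, z0, shape, ll, 3, tree.n_tips, tuple(tree.tip_names), dh, note
    )


def select_model(fits: Sequence[EvoModelFit]) -> EvoModelFit:
    """Lowest-AIC fit; ties go to fewer parameters, then BM<lambda<kappa<OU."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    ref = (fits[0].tip_names, fits[0].data_hash)
    for f in fits[1:]:
        if (f.tip_names, f.data_hash) != ref:
            raise ValueError("model fits were computed on different data")
    return min(fits, key=lambda f: (f.aic, f.n_params, _MODEL_ORDER[f.model]))


def model_covariance(tree: Phylogeny, fit: EvoModelFit | None) -> PhyloCovariance:
    """Tip covariance structure implied by a fitted model (unit rate)."""
    if fit is None or fit.model == "BM":
        return vcv_matrix(tree)
    if fit.model == "lambda":
        return transform_lambda(vcv_matrix(tree), fit.shape)
    if fit.model == "kappa":
        return vcv_matrix(kappa_tree(tree, fit.shape))
    return transform_ou(tree, fit.shape)


# ---------------------------------------------------------------------------
# Phylogenetic signal (Pagel's lambda, permutation p-value)
# ---------------------------------------------------------------------------


@dataclass
class SignalResult:
    """Pagel's lambda with a tip-shuffling permutation p-value."""

    lambda_hat: float
    p_value: float
    n_permutations: int
    loglik_mle: float
    loglik_zero: float
    degenerate: bool = False

    @property
    def lr(self) -> float:
        return 2.0 * (self.loglik_mle - self.loglik_zero)


def _lambda_grid_loglik(eigs, T, n, W, Z, grid):
    """Profile log-likelihoods over a lambda grid for many trait columns.

    ``W`` is U'1, ``Z`` is U'X for the eigendecomposition C = U diag(eigs) U'
    of the BM covariance of an ultrametric tree of height T.  Returns an
    array (len(grid), n_columns).
    """
    out = np.empty((len(grid), Z.shape[1]))
    W2 = W**2
    for gi, lam in enumerate(grid):
        d = lam * eigs + (1.0 - lam) * T
        if np.any(d <= 0):
            out[gi] = -np.inf
            continue
        inv = 1.0 / d
        p0 = W2 @ inv
        q = (W * inv) @ Z
        r = inv @ (Z**2)
        rss = r - q**2 / p0
        with np.errstate(divide="ignore"):
            out[gi] = (
                -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
                - 0.5 * np.sum(np.log(d))
            )
    return out


def phylo_signal_lambda(
    tree: Phylogeny,
    x,
    n_permutations: int = 999,
    seed: int = 0,
    grid_size: int = 101,
) -> SignalResult:
    """Pagel's lambda with a permutation p-value.

    The statistic is the likelihood ratio LR = 2 (logL(lambda_hat) -
    logL(lambda = 0)); the null distribution shuffles tip values on the fixed
    tree.  p = (1 + #{LR_perm >= LR_obs}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    xv = _align(tree, x)
    if np.ptp(xv) == 0:
        return SignalResult(
            float("nan"), float("nan"), n_permutations, float("nan"), float("nan"),
            degenerate=True,
        )
    rng = np.random.default_rng(seed)
    perms = np.column_stack(
        [xv] + [rng.permutation(xv) for _ in range(n_permutations)]
    )
    grid = np.linspace(0.0, 1.0, grid_size)
    n = tree.n_tips

    if tree.is_ultrametric():
        C = vcv_matrix(tree).matrix
        T = tree.height
        eigs, U = np.linalg.eigh(C)
        eigs = np.clip(eigs, 0.0, None)
        W = U.T @ np.ones(n)
        Z = U.T @ perms
        ll = _lambda_grid_loglik(eigs, T, n, W, Z, grid)
        ll_max = ll.max(axis=0)
        lr = 2.0 * (ll_max - ll[0])
    else:
        lr = np.empty(perms.shape[1])
        ll0_cache = None
        trees = [(_model_tree(tree, "lambda", g)) for g in grid]
        for j in range(perms.shape[1]):
            lls = np.array([_profile_loglik(tg, perms[:, j])[0] for tg in trees])
            lr[j] = 2.0 * (lls.max() - lls[0])

    fit = fit_model(tree, x, "lambda")  # Brent-refined lambda_hat for reporting
    ll_zero, _, _ = _profile_loglik(_model_tree(tree, "lambda", 0.0), xv)
    p = (1.0 + np.sum(lr[1:] >= lr[0])) / (n_permutations + 1.0)
    return SignalResult(fit.shape, float(p), n_permutations, fit.loglik, ll_zero)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass
class PglsFit:
    """Univariate phylogenetic GLS regression of y on x with intercept."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_t: float
    intercept_t: float
    slope_p: float
    intercept_p: float
    sigma2_resid: float
    transform: str
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def pgls(tree: Phylogeny, y, x, transform: EvoModelFit | None = None) -> PglsFit:
    """GLS regression with phylogenetic error covariance.

    ``transform`` is a fitted evolutionary model (typically the best-AIC model
    of the predictor's evolution); its covariance is used as the error
    correlation structure, with the overall scale profiled out.  ``None``
    means plain Brownian motion.
    """
    yv = _align(tree, y, "response")
    xv = _align(tree, x, "predictor")
    n = tree.n_tips
    if n < 3:
        raise ValueError("need at least 3 species for PGLS")
    V = model_covariance(tree, transform).matrix
    X = np.column_stack([np.ones(n), xv])
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(V)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, yv, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("singular design matrix (constant predictor?)")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df = n - 2
    sigma2 = rss / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    name = transform.model if transform is not None else "BM"
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(se[1]),
        intercept_se=float(se[0]),
        slope_t=float(tvals[1]),
        intercept_t=float(tvals[0]),
        slope_p=float(pvals[1]),
        intercept_p=float(pvals[0]),
        sigma2_resid=float(sigma2),
        transform=name,
        n=n,
    )


# ---------------------------------------------------------------------------
# Multivariate PGLS with measurement error
# ---------------------------------------------------------------------------


@dataclass
class MvPglsFit:
    """Multivariate phylogenetic regression under a shared Pagel's lambda.

    The m responses share one lambda; the tip covariance of response pair
    (k, l) is ``R_kl * C_lambda`` plus, on the diagonal pairs, a per-response
    measurement-error variance ``e_k * I``.  ``corr`` holds the evolutionary
    correlations ``R_kl / sqrt(R_kk R_ll)``.
    """

    B: pd.DataFrame  # (intercept, slope) x responses
    R: pd.DataFrame  # evolutionary covariance (per Myr)
    corr: pd.DataFrame
    lambda_hat: float
    meas_error: pd.Series
    loglik: float
    n: int
    converged: bool


def _chol_unpack(theta: np.ndarray, m: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from a packed parameter vector."""
    L = np.zeros((m, m))
    idx = 0
    for i in range(m):
        for j in range(i + 1):
            L[i, j] = math.exp(theta[idx]) if i == j else theta[idx]
            idx += 1
    return L


def _chol_pack(R: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(R)
    out = []
    for i in range(R.shape[0]):
        for j in range(i + 1):
            out.append(math.log(max(L[i, i], 1e-12)) if i == j else L[i, j])
    return np.array(out)


def mv_pgls(
    tree: Phylogeny,
    Y: pd.DataFrame,
    x,
    estimate_error: bool = True,
) -> MvPglsFit:
    """Joint ML fit of responses ``Y`` on predictor ``x`` with shared lambda.

    On ultrametric trees the lambda-transformed covariance shares the
    eigenbasis of the BM covariance, so each likelihood evaluation factorizes
    into n independent m x m blocks; regression coefficients are profiled by
    GLS inside the objective and (lambda, chol(R), log e) are optimized by
    L-BFGS-B.
    """
    if not isinstance(Y, pd.DataFrame):
        raise TypeError("Y must be a DataFrame of responses keyed by species")
    resp = list(Y.columns)
    m = len(resp)
    ok = Y.dropna().index
    sp = [t for t in tree.tip_names if t in set(ok)]
    if len(sp) < len(tree.tip_names):
        tree = tree.retain_tips(sp)
    Ym = np.column_stack([_align(tree, Y[c], c) for c in resp])
    xv = _align(tree, x, "predictor")
    n = tree.n_tips
    if n < m + 2:
        raise ValueError("too few complete cases for a multivariate fit")
    if not tree.is_ultrametric():
        raise ValueError("mv_pgls requires an ultrametric (dated) tree")

    C = vcv_matrix(tree).matrix
    T = tree.height
    eigs, U = np.linalg.eigh(C)
    eigs = np.clip(eigs, 0.0, None)
    W = U.T @ np.ones(n)
    Z = U.T @ xv
    Yt = U.T @ Ym
    G = np.column_stack([W, Z])  # transformed design (intercept, slope)

    def unpack(theta):
        lam = theta[0]
        L = _chol_unpack(theta[1 : 1 + m * (m + 1) // 2], m)
        R = L @ L.T
        if estimate_error:
            e = np.exp(theta[1 + m * (m + 1) // 2 :])
        else:
            e = np.zeros(m)
        return lam, R, e

    def eval_fit(theta):
        lam, R, e = unpack(theta)
        d = lam * eigs + (1.0 - lam) * T
        M = d[:, None, None] * R[None, :, :] + np.diag(e)[None, :, :]
        try:
            Lm = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet = 2.0 * np.sum(np.log(np.einsum("ikk->ik", Lm)))
        Minv = np.linalg.inv(M)
        # GLS for B (2 x m): A vec(B) = b in (coef, response) packing
        A = np.einsum("ia,ib,ikl->akbl", G, G, Minv).reshape(2 * m, 2 * m)
        b = np.einsum("ia,ikl,il->ak", G, Minv, Yt).reshape(2 * m)
        B = np.linalg.solve(A, b).reshape(2, m)
        resid = Yt - G @ B
        quad = np.einsum("ik,ikl,il->", resid, Minv, resid)
        ll = -0.5 * (n * m * math.log(2.0 * math.pi) + logdet + quad)
        return -ll, B, R

    # initial values: OLS residual covariance split between rate and error
    Xd = np.column_stack([np.ones(n), xv])
    B_ols, *_ = np.linalg.lstsq(Xd, Ym, rcond=None)
    res_ols = Ym - Xd @ B_ols
    S = np.cov(res_ols.T) if m > 1 else np.atleast_2d(np.var(res_ols))
    S = np.atleast_2d(S)
    R0 = 0.9 * S / T + 1e-8 * np.eye(m)
    theta0 = np.concatenate([[0.5], _chol_pack(R0)])
    bounds: list[tuple] = [(0.0, 1.0)] + [(None, None)] * (m * (m + 1) // 2)
    if estimate_error:
        e0 = np.log(0.1 * np.diag(S) + 1e-12)
        theta0 = np.concatenate([theta0, e0])
        bounds += [(math.log(1e-10 * max(d, 1e-12)), math.log(10.0 * d + 1e-12))
                   for d in np.diag(S)]

    res = optimize.minimize(
        lambda t: eval_fit(t)[0],
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    negll, B, R = eval_fit(res.x)
    lam, _, e = unpack(res.x)
    if B is None:
        raise RuntimeError("mv_pgls likelihood evaluation failed at the optimum")
    sd = np.sqrt(np.diag(R))
    corr = R / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return MvPglsFit(
        B=pd.DataFrame(B, index=["intercept", "slope"], columns=resp),
        R=pd.DataFrame(R, index=resp, columns=resp),
        corr=pd.DataFrame(corr, index=resp, columns=resp),
        lambda_hat=float(lam),
        meas_error=pd.Series(e, index=resp),
        loglik=float(-negll),
        n=n,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Ancestral states under Brownian motion
# ---------------------------------------------------------------------------


@dataclass
class AncestralStates:
    """ML/GLS ancestral estimates under BM; tips pass through unchanged."""

    estimates: np.ndarray  # per node, tree node indexing
    tree: Phylogeny

    @property
    def root_estimate(self) -> float:
        return float(self.estimates[self.tree.root])

    def tip_series(self) -> pd.Series:
        return pd.Series(self.estimates[: self.tree.n_tips], index=self.tree.tip_names)


def asr_bm(tree: Phylogeny, x) -> AncestralStates:
    """Ancestral state reconstruction under Brownian motion.

    Two-pass message passing: a downpass computes each node's subtree
    estimate and variance (Felsenstein pruning), an uppass folds in the rest
    of the tree; each node's estimate is the precision-weighted combination,
    equal to the conditional expectation given the tips.  The root estimate
    is the GLS phylogenetic mean.
    """
    xv = _align(tree, x)
    nn = tree.n_nodes
    m_down = np.zeros(nn)
    v_down = np.zeros(nn)
    m_down[: tree.n_tips] = xv
    blen = tree.blen
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        prec = 0.0
        wsum = 0.0
        for k in kids:
            vk = v_down[k] + blen[k]
            if vk <= 0:
                raise ValueError("zero-length terminal path in ASR")
            prec += 1.0 / vk
            wsum += m_down[k] / vk
        v_down[node] = 1.0 / prec
        m_down[node] = wsum / prec

    # uppass: precision-form "rest of tree" message at each node
    prec_up = np.zeros(nn)
    mean_up = np.zeros(nn)
    est = np.empty(nn)
    root = tree.root
    order = tree.postorder[::-1]  # preorder: parents before children
    for node in order:
        if node == root:
            est[node] = m_down[node]
        else:
            # combine above message with down message at the node
            pd_ = prec_up[node]
            pv = 1.0 / v_down[node] if v_down[node] > 0 else np.inf
            if np.isinf(pv):  # tip: known state
                est[node] = m_down[node]
            else:
                est[node] = (pd_ * mean_up[node] + pv * m_down[node]) / (pd_ + pv)
        kids = tree.children[node]
        if not kids:
            continue
        # totals over children messages plus the above message
        pres = [1.0 / (v_down[k] + blen[k]) for k in kids]
        mens = [m_down[k] for k in kids]
        tot_p = prec_up[node] + sum(pres)
        tot_w = prec_up[node] * mean_up[node] + sum(p * mm for p, mm in zip(pres, mens))
        for k, pk, mk in zip(kids, pres, mens):
            p_ex = tot_p - pk
            if p_ex <= 0:
                raise ValueError("isolated subtree in ASR uppass")
            m_ex = (tot_w - pk * mk) / p_ex
            v_at_k = 1.0 / p_ex + blen[k]
            prec_up[k] = 1.0 / v_at_k
            mean_up[k] = m_ex
    est[: tree.n_tips] = xv
    return AncestralStates(est, tree)


# ---------------------------------------------------------------------------
# Cross-clade ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def class_anova(values, labels) -> AnovaResult:
    """One-way ANOVA of a metric across clades, plus Tukey HSD.

    The clades are treated as independent groups (deep splits, no shared
    phylogenetic structure modelled at this level).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, arr in zip(pd.unique(labels), groups):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    F, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    return AnovaResult(
        F=float(F),
        df_between=len(groups) - 1,
        df_within=int(values.size - len(groups)),
        p_value=float(p),
        tukey=tukey,
    )
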