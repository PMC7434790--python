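"""Generalized partial credit model: probabilities, information, MML-EM
estimation, EAP scoring, and Cronbach's alpha.

Model
-----
For an item with discrimination ``a`` and step difficulties
``b_1..b_m`` the probability of scored category ``c`` (0..m) at trait
level ``theta`` is

    P(c | theta)  proportional to  exp( sum_{k<=c} a (theta - b_k) )

with the empty sum equal to zero.  Each ``b_j`` is the trait level at
which categories ``j-1`` and ``j`` are equally probable; the steps need
not be ordered (reversed steps are legitimate GPCM solutions).

Fisher information of an item is ``a^2 Var(C | theta)`` where C is the
category score, and the total-trait-range integral of the information
equals ``a * m`` exactly, a useful analytic check.

Estimation is marginal maximum likelihood with a standard-normal latent
prior on a fixed quadrature grid, via EM: the E-step forms posterior
weights over grid points, the M-step runs per-item Newton updates in the
slope/intercept parametrisation (in which the complete-data likelihood
is concave).  The latent scale is identified by the N(0,1) prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .bank import ResponseMatrix, ValidationError

__all__ = [
    "ItemParameters",
    "LatentGrid",
    "GpcmFit",
    "FULL_RANGE",
    "category_probs",
    "expected_score",
    "item_information",
    "total_item_information",
    "test_information",
    "standard_error_curve",
    "fit_gpcm",
    "eap_scores",
    "cronbach_alpha",
]

#: Integration bounds standing in for the entire trait range; beyond
#: +-8 the information of any realistic item (|b| < 6, a < 4) is
#: negligible relative to the a*m identity.
FULL_RANGE = (-8.0, 8.0)


@dataclass(frozen=True)
class ItemParameters:
    """One item's discrimination ``a`` and step difficulties ``b``."""

    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if len(self.b) < 1:
            raise ValueError("need at least one step difficulty")
        if not (np.isfinite(self.a) and np.all(np.isfinite(self.b))):
            raise ValueError("item parameters must be finite")

    @property
    def m(self) -> int:
        """Number of steps (categories - 1)."""
        return len(self.b)


@dataclass(frozen=True)
class LatentGrid:
    """Evaluation/quadrature grid over the latent trait."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.points.ndim != 1 or self.points.shape != self.weights.shape:
            raise ValueError("points and weights must be equal-length 1-D")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("points must be strictly increasing")

    @classmethod
    def normal(cls, n: int = 61, lo: float = -6.0, hi: float = 6.0
               ) -> "LatentGrid":
        """Evenly spaced points with normalized standard-normal weights."""
        pts = np.linspace(lo, hi, n)
        w = norm.pdf(pts)
        return cls(points=pts, weights=w / w.sum())

    @classmethod
    def gauss_hermite(cls, n: int = 61) -> "LatentGrid":
        """Gauss-Hermite nodes/weights rescaled for a N(0,1) kernel."""
        x, w = np.polynomial.hermite.hermgauss(n)
        return cls(points=x * math.sqrt(2.0), weights=w / math.sqrt(math.pi))

    @classmethod
    def even(cls, n: int = 61, lo: float = -3.0, hi: float = 3.0
             ) -> "LatentGrid":
        """Evenly spaced points with equal weights (for SE averaging)."""
        pts = np.linspace(lo, hi, n)
        return cls(points=pts, weights=np.full(n, 1.0 / n))


# ---------------------------------------------------------------------
# model functions


def _eta(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Category log-weights eta_c = sum_{k<=c} a (theta - b_k)."""
    theta = np.asarray(theta, float)
    b = np.asarray(item.b)
    steps = item.a * (theta[..., None] - b)          # (..., m)
    return np.concatenate(
        [np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1
    )


def category_probs(item: ItemParameters, theta) -> np.ndarray:
    """P(category c | theta) for c = 0..m; last axis sums to one."""
    scalar = np.isscalar(theta)
    eta = _eta(item, np.atleast_1d(np.asarray(theta, float)))
    eta -= eta.max(axis=-1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=-1, keepdims=True)
    return p[0] if scalar else p


def expected_score(item: ItemParameters, theta) -> np.ndarray:
    p = category_probs(item, theta)
    c = np.arange(item.m + 1)
    return (p * c).sum(axis=-1)


def item_information(item: ItemParameters, theta) -> np.ndarray:
    """Fisher information ``a^2 Var(C | theta)``."""
    p = category_probs(item, theta)
    c = np.arange(item.m + 1)
    m1 = (p * c).sum(axis=-1)
    m2 = (p * c * c).sum(axis=-1)
    return item.a ** 2 * (m2 - m1 * m1)


def total_item_information(item: ItemParameters,
                           bounds: Union[str, tuple[float, float]] = "full"
                           ) -> float:
    """Integral of the item information over a trait range.

    ``bounds="full"`` integrates over :data:`FULL_RANGE`; over the whole
    real line the result equals ``a * m`` exactly.
    """
    lo, hi = FULL_RANGE if bounds == "full" else bounds
    if lo >= hi:
        raise ValueError(f"invalid integration range ({lo}, {hi})")
    val, _ = quad(lambda t: float(item_information(item, t)), lo, hi,
                  limit=200)
    return val


def test_information(params: Sequence[ItemParameters],
                     theta=None,
                     bounds: Union[str, tuple[float, float], None] = None):
    """Sum of item informations, pointwise (``theta``) or integrated
    (``bounds``)."""
    if not params:
        raise ValueError("need at least one item")
    if (theta is None) == (bounds is None):
        raise ValueError("give exactly one of theta or bounds")
    if theta is not None:
        return sum(item_information(it, theta) for it in params)
    return float(sum(total_item_information(it, bounds) for it in params))


def standard_error_curve(params: Sequence[ItemParameters],
                         grid: Optional[LatentGrid] = None
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """SE(theta) = 1/sqrt(I(theta)) on a grid, plus its unweighted mean.

    The default grid is 61 evenly spaced points on (-3, 3).  Returns
    ``(points, se, average)``; grid points with zero information get
    ``inf`` with a warning.
    """
    if grid is None:
        grid = LatentGrid.even(61, -3.0, 3.0)
    info = test_information(params, theta=grid.points)
    se = np.empty_like(info)
    zero = info <= 0
    if np.any(zero):
        import warnings

        warnings.warn("zero test information at some grid points; SE = inf")
    se[zero] = np.inf
    se[~zero] = 1.0 / np.sqrt(info[~zero])
    return grid.points, se, float(np.mean(se))


# ---------------------------------------------------------------------
# estimation

# Internally the M-step works in (a, gamma) with gamma_c = a * sum_{k<=c} b_k,
# so eta_c = c*a*theta - gamma_c is linear in the parameters and the
# complete-data likelihood is a concave multinomial logit.

_A_CLIP = 8.0
_G_CLIP = 80.0


def _gamma_from(item: ItemParameters) -> np.ndarray:
    return item.a * np.cumsum(item.b)


def _item_from_gamma(a: float, gamma: np.ndarray) -> ItemParameters:
    full = np.concatenate([[0.0], gamma])
    if abs(a) < 1e-8:
        # zero discrimination: steps undefined; report zeros
        b = np.zeros(len(gamma))
    else:
        b = np.diff(full) / a
    return ItemParameters(a=float(a), b=tuple(b))


def _probs_from_gamma(a: float, gamma: np.ndarray, theta: np.ndarray
                      ) -> np.ndarray:
    """(Q, K) category probabilities from slope/intercept parameters."""
    c = np.arange(len(gamma) + 1)
    eta = c[None, :] * a * theta[:, None]
    eta[:, 1:] -= gamma[None, :]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _mstep_newton(a: float, gamma: np.ndarray, r: np.ndarray,
                  theta: np.ndarray, n_inner: int = 3) -> tuple[float, np.ndarray]:
    """A few damped Newton steps on the expected complete-data loglik."""
    K = r.shape[1]
    m = K - 1
    c = np.arange(K, dtype=float)
    nq = r.sum(axis=1)

    def objective(a_, g_):
        p = _probs_from_gamma(a_, g_, theta)
        return float((r * np.log(np.clip(p, 1e-300, None))).sum())

    obj = objective(a, gamma)
    for _ in range(n_inner):
        p = _probs_from_gamma(a, gamma, theta)     # (Q, K)
        m1 = p @ c                                  # E[C] per q
        resid = r - nq[:, None] * p                # (Q, K)
        g = np.empty(1 + m)
        g[0] = float((resid * (c[None, :] * theta[:, None])).sum())
        g[1:] = -resid[:, 1:].sum(axis=0)
        # Hessian = -sum_q nq Cov_P(z), z = (c*theta, -e_c)
        H = np.zeros((1 + m, 1 + m))
        m2 = p @ (c * c)
        H[0, 0] = float((nq * theta ** 2 * (m2 - m1 ** 2)).sum())
        # Cov(c*theta, -e_j) = -theta * P_j (j - m1)
        cov_ag = -(nq[:, None] * theta[:, None] * p[:, 1:]
                   * (c[None, 1:] - m1[:, None])).sum(axis=0)
        H[0, 1:] = cov_ag
        H[1:, 0] = cov_ag
        pj = nq[:, None] * p[:, 1:]
        H[1:, 1:] = np.diag(pj.sum(axis=0)) - np.einsum(
            "q,qj,qk->jk", nq, p[:, 1:], p[:, 1:])
        H = -H
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(1 + m), g)
        except np.linalg.LinAlgError:
            step = g  # gradient fallback
        step = -step
        lam = 1.0
        for _half in range(20):
            a_new = float(np.clip(a + lam * step[0], -_A_CLIP, _A_CLIP))
            g_new = np.clip(gamma + lam * step[1:], -_G_CLIP, _G_CLIP)
            obj_new = objective(a_new, g_new)
            if obj_new >= obj - 1e-12:
                break
            lam *= 0.5
        if obj_new < obj:
            break
        a, gamma, obj = a_new, g_new, obj_new
    return a, gamma


@dataclass
class GpcmFit:
    """Result of a marginal-ML GPCM fit."""

    item_ids: list[str]
    params: dict[str, ItemParameters]
    loglik: float
    n_iter: int
    converged: bool
    grid: LatentGrid
    n_persons: int
    se_params: Optional[dict[str, tuple[float, tuple[float, ...]]]] = None
    loglik_history: list[float] = field(default_factory=list)
    scores: Optional[np.ndarray] = None

    def param_list(self, item_ids: Optional[Sequence[str]] = None
                   ) -> list[ItemParameters]:
        ids = list(item_ids) if item_ids is not None else self.item_ids
        return [self.params[i] for i in ids]

    def to_json(self, path: str | Path) -> None:
        out = {
            "item_ids": self.item_ids,
            "params": {k: {"a": v.a, "b": list(v.b)}
                       for k, v in self.params.items()},
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_persons": self.n_persons,
            "se_params": None if self.se_params is None else {
                k: {"a": v[0], "b": list(v[1])}
                for k, v in self.se_params.items()},
        }
        Path(path).write_text(json.dumps(out, indent=1))

    @classmethod
    def from_params(cls, params: dict[str, ItemParameters],
                    grid: Optional[LatentGrid] = None) -> "GpcmFit":
        """Wrap a known parameter set (e.g. a published calibration) in a
        fit object so the reduction/assembly machinery can consume it."""
        return cls(item_ids=list(params), params=dict(params),
                   loglik=float("nan"), n_iter=0, converged=True,
                   grid=grid or LatentGrid.normal(), n_persons=0)


def _as_codes(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, ResponseMatrix):
        return data.codes, data.item_ids
    arr = np.asarray(data, dtype=int)
    if arr.ndim != 2:
        raise ValidationError("data must be 2-D")
    if arr.min() < 0:
        raise ValidationError("plain arrays must hold 0-based codes")
    return arr, [f"item{j + 1}" for j in range(arr.shape[1])]


def _log_prob_table(params_g: list[tuple[float, np.ndarray]],
                    theta: np.ndarray) -> list[np.ndarray]:
    return [np.log(np.clip(_probs_from_gamma(a, g, theta), 1e-300, None))
            for a, g in params_g]


def _person_loglik(logP: list[np.ndarray], X: np.ndarray,
                   logw: np.ndarray) -> np.ndarray:
    """(n, Q) log joint of responses and grid point (incl. prior)."""
    n = X.shape[0]
    L = np.tile(logw[None, :], (n, 1))
    for j, lp in enumerate(logP):
        L += lp[:, X[:, j]].T
    return L


def fit_gpcm(data, grid: Optional[LatentGrid] = None, tol: float = 1e-4,
             max_iter: int = 500, se: bool = True) -> GpcmFit:
    """Fit the GPCM by marginal maximum likelihood (EM).

    Parameters
    ----------
    data : ResponseMatrix or int array
        Scored responses; plain arrays must be 0-based category codes.
    grid : LatentGrid, optional
        Quadrature grid; default 61 normal-weighted points on (-6, 6).
    tol : float
        Convergence threshold on the largest absolute parameter change
        (on the (a, b) scale) between EM iterations.
    max_iter : int
        EM iteration cap; non-convergence is flagged, not raised.
    se : bool
        Compute observed-information standard errors (Louis identity).
    """
    X, item_ids = _as_codes(data)
    n, p = X.shape
    grid = grid or LatentGrid.normal()
    theta = grid.points
    logw = np.log(np.clip(grid.weights, 1e-300, None))

    n_cats = []
    for j in range(p):
        obs = np.unique(X[:, j])
        if len(obs) < 2:
            raise ValidationError(
                f"item {item_ids[j]} has a single observed category")
        if isinstance(data, ResponseMatrix):
            n_cats.append(data.bank[j].n_scored_categories)
        else:
            n_cats.append(int(X[:, j].max()) + 1)

    # one-hot caches for the E-step count accumulation
    onehots = [np.eye(K, dtype=float)[X[:, j]] for j, K in enumerate(n_cats)]

    # start values: a = 1, gamma from marginal frequencies
    params_g: list[tuple[float, np.ndarray]] = []
    for j, K in enumerate(n_cats):
        freq = onehots[j].sum(axis=0) + 0.5
        gamma = np.log(freq[0] / freq[1:])
        params_g.append((1.0, gamma))

    loglik_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logP = _log_prob_table(params_g, theta)
        L = _person_loglik(logP, X, logw)
        Lmax = L.max(axis=1, keepdims=True)
        post = np.exp(L - Lmax)
        marg = post.sum(axis=1, keepdims=True)
        loglik = float((np.log(marg) + Lmax).sum())
        post /= marg
        loglik_history.append(loglik)

        old = [(a, g.copy()) for a, g in params_g]
        new_params = []
        for j in range(p):
            r = post.T @ onehots[j]                  # (Q, K) expected counts
            a, gamma = _mstep_newton(*params_g[j], r, theta)
            new_params.append((a, gamma))
        params_g = new_params

        delta = 0.0
        for (a0, g0), (a1, g1) in zip(old, params_g):
            it0 = _item_from_gamma(a0, g0)
            it1 = _item_from_gamma(a1, g1)
            delta = max(delta, abs(it1.a - it0.a),
                        float(np.max(np.abs(np.array(it1.b)
                                            - np.array(it0.b)))))
        if delta < tol:
            converged = True
            break

    # log-likelihood at the final (post-M-step) parameters
    logP = _log_prob_table(params_g, theta)
    L = _person_loglik(logP, X, logw)
    Lmax = L.max(axis=1)
    loglik_history.append(float(
        (np.log(np.exp(L - Lmax[:, None]).sum(axis=1)) + Lmax).sum()))

    params = {item_ids[j]: _item_from_gamma(*params_g[j]) for j in range(p)}
    fit = GpcmFit(item_ids=item_ids, params=params,
                  loglik=loglik_history[-1], n_iter=it, converged=converged,
                  grid=grid, n_persons=n, loglik_history=loglik_history)
    if se:
        from ._information import single_group_se

        ses = single_group_se(params_g, X, n_cats, grid)
        fit.se_params = {item_ids[j]: ses[j] for j in range(p)}
    return fit


def marginal_loglik(params: Sequence[ItemParameters], data,
                    grid: Optional[LatentGrid] = None) -> float:
    """Marginal log-likelihood of fixed parameters for given responses."""
    X, _ = _as_codes(data)
    grid = grid or LatentGrid.normal()
    params_g = [(it.a, _gamma_from(it)) for it in params]
    logP = _log_prob_table(params_g, grid.points)
    L = _person_loglik(logP, X, np.log(np.clip(grid.weights, 1e-300, None)))
    Lmax = L.max(axis=1)
    return float((np.log(np.exp(L - Lmax[:, None]).sum(axis=1)) + Lmax).sum())


def eap_scores(fit: GpcmFit, data, item_ids: Optional[Sequence[str]] = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Expected-a-posteriori trait estimates and posterior SDs.

    The posterior combines the N(0,1) prior (grid weights) with the
    person's response pattern under the fitted parameters.
    """
    X, ids = _as_codes(data)
    if item_ids is None and not isinstance(data, ResponseMatrix) \
            and X.shape[1] == len(fit.item_ids):
        ids = fit.item_ids  # plain arrays align positionally with the fit
    use_ids = list(item_ids) if item_ids is not None else ids
    for i in use_ids:
        if i not in fit.params:
            raise KeyError(f"item {i!r} not covered by the fit")
        if i not in ids:
            raise KeyError(f"item {i!r} not present in the data")
    if item_ids is not None:
        cols = [ids.index(i) for i in use_ids]
        X = X[:, cols]
    params_g = [(fit.params[i].a, _gamma_from(fit.params[i]))
                for i in use_ids]
    theta = fit.grid.points
    for j, i in enumerate(use_ids):
        if X[:, j].max() > fit.params[i].m:
            raise ValidationError(
                f"response category outside fitted range for item {i}")
    logP = _log_prob_table(params_g, theta)
    L = _person_loglik(logP, X,
                       np.log(np.clip(fit.grid.weights, 1e-300, None)))
    L -= L.max(axis=1, keepdims=True)
    post = np.exp(L)
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ theta
    var = post @ (theta ** 2) - mean ** 2
    return mean, np.sqrt(np.clip(var, 0.0, None))


def cronbach_alpha(matrix, subset: Optional[Sequence[str]] = None) -> float:
    """Cronbach's alpha ``k/(k-1) * (1 - sum(var_i)/var(sum))``."""
    if isinstance(matrix, ResponseMatrix):
        ids = list(subset) if subset is not None else matrix.item_ids
        cols = [matrix.column(i) for i in ids]
        arr = matrix.values[:, cols].astype(float)
    else:
        arr = np.asarray(matrix, float)
        if subset is not None:
            arr = arr[:, list(subset)]
    k = arr.shape[1]
    if k < 2:
        raise ValidationError("alpha needs at least 2 items")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValidationError("zero total-score variance")
    return k / (k - 1) * (1.0 - arr.var(axis=0, ddof=1).sum() / total_var)
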