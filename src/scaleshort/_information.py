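"""Observed information for marginal-ML GPCM fits via the Louis identity.

The observed information of the marginal likelihood equals the posterior
expectation of the complete-data information minus the posterior variance
of the complete-data score, summed over persons:

    I_obs = sum_p E_post[-H_c] - ( E_post[g_c g_c'] - s_p s_p' )

All three pieces are available in closed form on the quadrature grid in
the slope/intercept parametrisation (a, gamma), where the complete-data
model is a multinomial logit: the complete-data score for category c is
u_c - E_P[u] with parameter-free covariates u_c = (c*theta, -e_c), and
the complete-data information is the covariate covariance under the
model.  Group latent-distribution parameters (focal mean/SD in two-group
fits) enter as two extra columns with Gaussian score/curvature terms.

Covariances on the user-facing (a, b) scale come from the delta method,
b_k = (gamma_k - gamma_{k-1}) / a.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["louis_information", "gamma_block_jacobian", "single_group_se"]


def _probs_from_gamma(a: float, gamma: np.ndarray, theta: np.ndarray
                      ) -> np.ndarray:
    c = np.arange(len(gamma) + 1)
    eta = c[None, :] * a * theta[:, None]
    eta[:, 1:] -= gamma[None, :]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _score_tensor(a: float, gamma: np.ndarray, theta: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """S[q, c, :] = u_c - E_P[u] and probabilities P[q, c]."""
    P = _probs_from_gamma(a, gamma, theta)
    Q, K = P.shape
    c = np.arange(K, dtype=float)
    m1 = P @ c
    S = np.zeros((Q, K, K))                 # d = 1 + m = K
    S[:, :, 0] = theta[:, None] * (c[None, :] - m1[:, None])
    for j in range(1, K):
        S[:, j, j] -= 1.0
        S[:, :, j] += P[:, j][:, None]
    return S, P


def _complete_info_block(P: np.ndarray, theta: np.ndarray, W: np.ndarray
                         ) -> np.ndarray:
    """sum_q W(q) Cov_P(u)(q) for one item; d x d."""
    Q, K = P.shape
    c = np.arange(K, dtype=float)
    m1 = P @ c
    m2 = P @ (c * c)
    H = np.zeros((K, K))
    H[0, 0] = float((W * theta ** 2 * (m2 - m1 ** 2)).sum())
    cov_ag = -(W[:, None] * theta[:, None] * P[:, 1:]
               * (c[None, 1:] - m1[:, None])).sum(axis=0)
    H[0, 1:] = cov_ag
    H[1:, 0] = cov_ag
    H[1:, 1:] = (np.diag((W[:, None] * P[:, 1:]).sum(axis=0))
                 - np.einsum("q,qj,qk->jk", W, P[:, 1:], P[:, 1:]))
    return H


def louis_information(theta: np.ndarray, groups: Sequence[dict],
                      n_params: int) -> np.ndarray:
    """Observed information matrix over all free parameters.

    Each entry of ``groups`` is a dict with keys

    - ``X``: (n, p) 0-based response codes for this group's persons,
    - ``post``: (n, Q) posterior weights over grid points,
    - ``items``: list of (slice, a, gamma) with ``slice`` the global
      parameter slice this item's block occupies *for this group*
      (shared items point both groups at the same slice),
    - ``dist``: None, or (mu, sigma, slice) for a free latent N(mu,
      sigma^2) whose two parameters occupy ``slice``.
    """
    I = np.zeros((n_params, n_params))
    all_scores = []
    for gspec in groups:
        X = gspec["X"]
        post = gspec["post"]
        n, Q = post.shape
        W = post.sum(axis=0)
        A = np.zeros((n, Q, n_params))
        for j, (sl, a, gamma) in enumerate(gspec["items"]):
            S, P = _score_tensor(a, gamma, theta)
            A[:, :, sl] = S[:, X[:, j], :].transpose(1, 0, 2)
            I[sl, sl] += _complete_info_block(P, theta, W)
        dist = gspec.get("dist")
        if dist is not None:
            mu, sigma, sl = dist
            k = sl.stop - sl.start      # 1 = mean only, 2 = mean and SD
            z = (theta - mu) / sigma
            cols = [z / sigma, (z ** 2 - 1.0) / sigma][:k]
            t = np.stack(cols, axis=1)
            A[:, :, sl] = t[None, :, :]
            Hd = np.zeros((k, k))
            Hd[0, 0] = W.sum() / sigma ** 2
            if k == 2:
                Hd[0, 1] = Hd[1, 0] = float((W * 2 * z / sigma ** 2).sum())
                Hd[1, 1] = float((W * (3 * z ** 2 - 1.0)
                                  / sigma ** 2).sum())
            I[sl, sl] += Hd
        scores = np.einsum("pq,pqs->ps", post, A)
        I -= np.einsum("pq,pqs,pqt->st", post, A, A)
        all_scores.append(scores)
    S = np.concatenate(all_scores, axis=0)
    I += S.T @ S
    return I


def gamma_block_jacobian(a: float, gamma: np.ndarray) -> np.ndarray:
    """Jacobian d(a, b)/d(a, gamma) for one item block."""
    m = len(gamma)
    full = np.concatenate([[0.0], gamma])
    b = np.diff(full) / a
    J = np.zeros((1 + m, 1 + m))
    J[0, 0] = 1.0
    for k in range(1, 1 + m):
        J[k, 0] = -b[k - 1] / a
        J[k, k] = 1.0 / a
        if k > 1:
            J[k, k - 1] = -1.0 / a
    return J


def single_group_se(params_g: Sequence[tuple[float, np.ndarray]],
                    X: np.ndarray, n_cats: Sequence[int], grid
                    ) -> dict:
    """Per-item (se_a, se_b) for a single-group fit, on the (a, b) scale."""
    theta = grid.points
    logw = np.log(np.clip(grid.weights, 1e-300, None))
    n, p = X.shape
    # posterior at the fitted parameters
    L = np.tile(logw[None, :], (n, 1))
    for j, (a, gamma) in enumerate(params_g):
        logP = np.log(np.clip(_probs_from_gamma(a, gamma, theta),
                              1e-300, None))
        L += logP[:, X[:, j]].T
    L -= L.max(axis=1, keepdims=True)
    post = np.exp(L)
    post /= post.sum(axis=1, keepdims=True)

    slices = []
    off = 0
    for K in n_cats:
        slices.append(slice(off, off + K))
        off += K
    group = {
        "X": X,
        "post": post,
        "items": [(slices[j], params_g[j][0], params_g[j][1])
                  for j in range(p)],
        "dist": None,
    }
    I = louis_information(theta, [group], off)
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(I)
    out = {}
    for j, sl in enumerate(slices):
        a, gamma = params_g[j]
        J = gamma_block_jacobian(a, gamma)
        block = J @ cov[sl, sl] @ J.T
        ses = np.sqrt(np.clip(np.diag(block), 0.0, None))
        out[j] = (float(ses[0]), tuple(float(s) for s in ses[1:]))
    return out
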