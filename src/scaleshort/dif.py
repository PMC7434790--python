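"""Differential item functioning by group under the GPCM.

Implements the iterative Wald workflow used for gender-DIF screening of
patient-reported outcome items:

- :func:`multigroup_fit` — joint two-group marginal-ML fit with the
  reference group's latent trait fixed at N(0,1), the focal group's mean
  and variance estimated, and a chosen set of items freed to take
  group-specific parameters (all other items anchored, i.e. constrained
  equal across groups);
- :func:`wald2_scan` — the all-others-as-anchors scan: every item is
  tested in turn with all remaining items anchored (Wald-2);
- :func:`maxa5_anchors` — anchor selection by largest discrimination
  (the MaxA5 rule);
- :func:`iterative_wald1` — the purified Wald-1 procedure: with a fixed
  anchor set, candidates are tested one at a time, significant items are
  freed, and testing repeats until the flagged set stabilises.

Wald statistics are quadratic forms d' V^{-1} d on the vector of
between-group differences in (a, b1..bm), with V taken from the inverse
observed information (Louis identity) of the joint fit and df = 1 + m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from ._information import louis_information, gamma_block_jacobian
from .bank import ResponseMatrix, ValidationError
from .gpcm import (GpcmFit, ItemParameters, LatentGrid, _as_codes,
                   _item_from_gamma, _log_prob_table, _mstep_newton,
                   _probs_from_gamma)

__all__ = [
    "MultigroupFit",
    "DifResult",
    "multigroup_fit",
    "wald_statistic",
    "wald_item_test",
    "wald2_scan",
    "maxa5_anchors",
    "iterative_wald1",
]


@dataclass
class MultigroupFit:
    """Joint two-group GPCM fit with a set of freed (studied) items."""

    item_ids: list[str]
    free_items: set[str]
    params_ref: dict[str, ItemParameters]
    params_focal: dict[str, ItemParameters]
    focal_mean: float
    focal_sd: float
    loglik: float
    n_iter: int
    converged: bool
    grid: LatentGrid
    reference_label: object
    focal_label: object
    fix_focal_var: bool = False
    loglik_history: list[float] = field(default_factory=list)
    # internals needed for the information matrix
    _state: Optional[dict] = field(default=None, repr=False)
    _cov: Optional[np.ndarray] = field(default=None, repr=False)


def _focal_weights(theta: np.ndarray, base_w: np.ndarray, mu: float,
                   sigma: float) -> np.ndarray:
    """Quadrature weights for a N(mu, sigma^2) latent density.

    The base weights encode the N(0,1) density times the local quadrature
    measure, so the focal weights are the base weights reweighted by the
    density ratio N(theta; mu, sigma^2) / N(theta; 0, 1), renormalised.
    """
    log_ratio = (-0.5 * ((theta - mu) / sigma) ** 2 - np.log(sigma)
                 + 0.5 * theta ** 2)
    w = base_w * np.exp(log_ratio - log_ratio.max())
    return w / w.sum()


def _split_groups(matrix: ResponseMatrix, group_labels, reference):
    labels = matrix.group if group_labels is None else np.asarray(group_labels)
    if labels is None:
        raise ValidationError("no group labels supplied")
    levels = list(np.unique(labels))
    if len(levels) != 2:
        raise ValidationError(
            f"exactly 2 groups required, found {len(levels)}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not present")
    focal = [lv for lv in levels if lv != reference][0]
    return labels, reference, focal


def multigroup_fit(matrix: ResponseMatrix,
                   group_labels=None,
                   free_items: Sequence[str] = (),
                   reference=None,
                   grid: Optional[LatentGrid] = None,
                   tol: float = 1e-4,
                   max_iter: int = 500,
                   fix_focal_var: bool = False,
                   start: Optional[dict[str, ItemParameters]] = None
                   ) -> MultigroupFit:
    """Two-group marginal-ML GPCM fit.

    Items in ``free_items`` get separate parameters per group; all other
    items are anchored (equal parameters).  The reference group's latent
    distribution is N(0,1); the focal group's mean (and, unless
    ``fix_focal_var``, variance) is estimated, which identifies the
    common scale through the anchors.
    """
    X, item_ids = _as_codes(matrix)
    labels, ref_label, focal_label = _split_groups(matrix, group_labels,
                                                   reference)
    free = set(free_items)
    unknown = free - set(item_ids)
    if unknown:
        raise ValidationError(f"unknown free items: {sorted(unknown)}")
    grid = grid or LatentGrid.normal()
    theta = grid.points
    base_w = grid.weights

    is_ref = labels == ref_label
    Xr, Xf = X[is_ref], X[~is_ref]
    n_r, n_f = len(Xr), len(Xf)
    if n_r == 0 or n_f == 0:
        raise ValidationError("each group needs at least one person")
    p = X.shape[1]
    n_cats = []
    for j in range(p):
        if len(np.unique(X[:, j])) < 2:
            raise ValidationError(
                f"item {item_ids[j]} has a single observed category")
        n_cats.append(matrix.bank[j].n_scored_categories
                      if isinstance(matrix, ResponseMatrix)
                      else int(X[:, j].max()) + 1)

    onehot_r = [np.eye(K)[Xr[:, j]] for j, K in enumerate(n_cats)]
    onehot_f = [np.eye(K)[Xf[:, j]] for j, K in enumerate(n_cats)]

    def start_params(Xg):
        out = []
        for j, K in enumerate(n_cats):
            freq = np.bincount(X[:, j], minlength=K) + 0.5
            out.append((1.0, np.log(freq[0] / freq[1:])))
        return out

    if start is not None:
        from .gpcm import _gamma_from

        par_r = [(start[iid].a, _gamma_from(start[iid]))
                 for iid in item_ids]
    else:
        par_r = start_params(Xr)      # reference (and shared) parameters
    par_f = [(a, g.copy()) for a, g in par_r]  # focal copies for freed items
    mu, sigma = 0.0, 1.0
    freed = [j for j, iid in enumerate(item_ids) if iid in free]

    loglik_history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step per group
        logP_r = _log_prob_table(par_r, theta)
        logP_f = [logP_r[j] if j not in freed else None for j in range(p)]
        for j in freed:
            logP_f[j] = np.log(np.clip(
                _probs_from_gamma(par_f[j][0], par_f[j][1], theta),
                1e-300, None))
        w_f = _focal_weights(theta, base_w, mu, sigma)

        def posterior(Xg, logP, w):
            L = np.tile(np.log(np.clip(w, 1e-300, None))[None, :],
                        (len(Xg), 1))
            for j in range(p):
                L += logP[j][:, Xg[:, j]].T
            Lmax = L.max(axis=1, keepdims=True)
            po = np.exp(L - Lmax)
            marg = po.sum(axis=1, keepdims=True)
            ll = float((np.log(marg) + Lmax).sum())
            return po / marg, ll

        post_r, ll_r = posterior(Xr, logP_r, base_w)
        post_f, ll_f = posterior(Xf, logP_f, w_f)
        loglik_history.append(ll_r + ll_f)

        old = ([(a, g.copy()) for a, g in par_r],
               [(a, g.copy()) for a, g in par_f], mu, sigma)

        # M-step
        for j in range(p):
            r_r = post_r.T @ onehot_r[j]
            r_f = post_f.T @ onehot_f[j]
            if j in freed:
                par_r[j] = _mstep_newton(*par_r[j], r_r, theta)
                par_f[j] = _mstep_newton(*par_f[j], r_f, theta)
            else:
                par_r[j] = _mstep_newton(*par_r[j], r_r + r_f, theta)
                par_f[j] = par_r[j]
        tot = post_f.sum(axis=0)
        mu = float((tot * theta).sum() / n_f)
        if not fix_focal_var:
            var = float((tot * theta ** 2).sum() / n_f - mu ** 2)
            sigma = float(np.sqrt(max(var, 1e-4)))

        delta = max(abs(mu - old[2]), abs(sigma - old[3]))
        for pa, pb in ((par_r, old[0]), (par_f, old[1])):
            for (a1, g1), (a0, g0) in zip(pa, pb):
                i1, i0 = _item_from_gamma(a1, g1), _item_from_gamma(a0, g0)
                delta = max(delta, abs(i1.a - i0.a),
                            float(np.max(np.abs(np.array(i1.b)
                                                - np.array(i0.b)))))
        if delta < tol:
            converged = True
            break

    fit = MultigroupFit(
        item_ids=item_ids, free_items=free,
        params_ref={item_ids[j]: _item_from_gamma(*par_r[j])
                    for j in range(p)},
        params_focal={item_ids[j]: _item_from_gamma(*par_f[j])
                      for j in range(p)},
        focal_mean=mu, focal_sd=sigma,
        loglik=loglik_history[-1], n_iter=it, converged=converged,
        grid=grid, reference_label=ref_label, focal_label=focal_label,
        fix_focal_var=fix_focal_var, loglik_history=loglik_history)
    fit._state = {
        "Xr": Xr, "Xf": Xf, "par_r": par_r, "par_f": par_f,
        "n_cats": n_cats, "freed": freed,
    }
    return fit


def _fit_covariance(fit: MultigroupFit) -> tuple[np.ndarray, dict]:
    """Inverse observed information over all free parameters, cached."""
    st = fit._state
    theta = fit.grid.points
    base_w = fit.grid.weights
    p = len(fit.item_ids)
    n_cats, freed = st["n_cats"], st["freed"]

    # layout: shared/ref blocks, then focal blocks for freed items, dist
    slices_ref, slices_focal = {}, {}
    off = 0
    for j in range(p):
        slices_ref[j] = slice(off, off + n_cats[j])
        off += n_cats[j]
    for j in freed:
        slices_focal[j] = slice(off, off + n_cats[j])
        off += n_cats[j]
    n_dist = 1 if fit.fix_focal_var else 2
    dist_slice = slice(off, off + n_dist)
    off += n_dist

    mu, sigma = fit.focal_mean, fit.focal_sd
    w_f = _focal_weights(theta, base_w, mu, sigma)

    def posterior(Xg, pars, w):
        L = np.tile(np.log(np.clip(w, 1e-300, None))[None, :],
                    (len(Xg), 1))
        for j in range(p):
            lp = np.log(np.clip(
                _probs_from_gamma(pars[j][0], pars[j][1], theta),
                1e-300, None))
            L += lp[:, Xg[:, j]].T
        L -= L.max(axis=1, keepdims=True)
        po = np.exp(L)
        return po / po.sum(axis=1, keepdims=True)

    post_r = posterior(st["Xr"], st["par_r"], base_w)
    par_f_full = [st["par_f"][j] if j in freed else st["par_r"][j]
                  for j in range(p)]
    post_f = posterior(st["Xf"], par_f_full, w_f)

    group_r = {"X": st["Xr"], "post": post_r,
               "items": [(slices_ref[j], *st["par_r"][j])
                         for j in range(p)],
               "dist": None}
    group_f = {"X": st["Xf"], "post": post_f,
               "items": [((slices_focal[j] if j in freed
                           else slices_ref[j]), *par_f_full[j])
                         for j in range(p)],
               "dist": (mu, sigma, dist_slice)}
    I = louis_information(theta, [group_r, group_f], off)
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular information matrix; more data or fewer freed "
            "parameters are needed") from None
    layout = {"ref": slices_ref, "focal": slices_focal}
    return cov, layout


def wald_statistic(d: np.ndarray, V: np.ndarray) -> float:
    """Quadratic form d' V^{-1} d (solved, not inverted explicitly)."""
    d = np.asarray(d, float)
    try:
        sol = np.linalg.solve(V, d)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular Wald covariance; more data or fewer parameters "
            "are needed") from None
    return float(d @ sol)


def wald_item_test(fit: MultigroupFit, item: str
                   ) -> tuple[float, int, float]:
    """Wald test of equal (a, b) across groups for a freed item."""
    if item not in fit.free_items:
        raise ValidationError(f"item {item!r} was not freed in this fit")
    if fit._cov is None:
        fit._cov = _fit_covariance(fit)
    cov, layout = fit._cov
    j = fit.item_ids.index(item)
    st = fit._state
    a_r, g_r = st["par_r"][j]
    a_f, g_f = st["par_f"][j]
    pr = _item_from_gamma(a_r, g_r)
    pf = _item_from_gamma(a_f, g_f)
    d = np.concatenate([[pf.a - pr.a],
                        np.array(pf.b) - np.array(pr.b)])
    Jr = gamma_block_jacobian(a_r, g_r)
    Jf = gamma_block_jacobian(a_f, g_f)
    sl_r, sl_f = layout["ref"][j], layout["focal"][j]
    V = (Jf @ cov[sl_f, sl_f] @ Jf.T + Jr @ cov[sl_r, sl_r] @ Jr.T
         - Jf @ cov[sl_f, sl_r] @ Jr.T - Jr @ cov[sl_r, sl_f] @ Jf.T)
    stat = wald_statistic(d, V)
    df = 1 + pr.m
    return stat, df, float(chi2_dist.sf(stat, df))


@dataclass
class DifResult:
    """Per-item DIF verdicts from a Wald scan or iterative procedure."""

    method: str
    items: list[str]
    statistics: dict[str, float]
    dfs: dict[str, int]
    p_values: dict[str, float]
    flagged: list[str]
    anchors: list[str]
    alpha: float
    focal_mean: float
    focal_var: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": i,
                 "wald": self.statistics.get(i, np.nan),
                 "df": self.dfs.get(i, np.nan),
                 "p": self.p_values.get(i, np.nan),
                 "flagged": i in self.flagged}
                for i in self.items]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        out = {
            "method": self.method,
            "alpha": self.alpha,
            "anchors": self.anchors,
            "flagged": self.flagged,
            "focal_mean": self.focal_mean,
            "focal_var": self.focal_var,
            "per_item": {i: {"wald": self.statistics.get(i),
                             "df": self.dfs.get(i),
                             "p": self.p_values.get(i)}
                         for i in self.items},
        }
        Path(path).write_text(json.dumps(out, indent=1))


def wald2_scan(matrix: ResponseMatrix, group_labels=None,
               alpha: float = 0.05, reference=None,
               grid: Optional[LatentGrid] = None,
               fix_focal_var: bool = False) -> DifResult:
    """All-others-as-anchors (Wald-2) DIF scan over every item."""
    from .gpcm import fit_gpcm

    ids = matrix.item_ids
    stats, dfs, pvals = {}, {}, {}
    pooled = fit_gpcm(matrix, grid=grid, se=False)
    last_fit = None
    for iid in ids:
        fit = multigroup_fit(matrix, group_labels, free_items=[iid],
                             reference=reference, grid=grid,
                             fix_focal_var=fix_focal_var,
                             start=pooled.params)
        stats[iid], dfs[iid], pvals[iid] = wald_item_test(fit, iid)
        last_fit = fit
    flagged = [i for i in ids if pvals[i] < alpha]
    return DifResult(method="wald2", items=ids, statistics=stats, dfs=dfs,
                     p_values=pvals, flagged=flagged,
                     anchors=[i for i in ids if i not in flagged],
                     alpha=alpha, focal_mean=last_fit.focal_mean,
                     focal_var=last_fit.focal_sd ** 2)


def maxa5_anchors(fit, n_anchors: int = 5) -> list[str]:
    """The ``n_anchors`` items with the largest discriminations.

    ``fit`` may be a pooled single-group :class:`GpcmFit` or a plain
    dict of item id -> :class:`ItemParameters`.  Ties break by item
    order.
    """
    params = fit.params if isinstance(fit, GpcmFit) else dict(fit)
    ids = list(params)
    if len(ids) < n_anchors + 1:
        raise ValidationError(
            f"need at least {n_anchors + 1} items to anchor {n_anchors}")
    a = np.array([params[i].a for i in ids])
    order = np.argsort(-a, kind="stable")
    return [ids[k] for k in order[:n_anchors]]


def iterative_wald1(matrix: ResponseMatrix, group_labels=None,
                    anchors: Sequence[str] = (), alpha: float = 0.05,
                    reference=None, grid: Optional[LatentGrid] = None,
                    fix_focal_var: bool = False) -> DifResult:
    """Iterative Wald-1 DIF testing with a fixed anchor set.

    Candidates (non-anchor items) are tested one at a time: each test
    fits the model with the currently flagged items plus the candidate
    freed, all anchors and remaining candidates constrained.  Newly
    significant items join the flagged set and testing repeats until no
    item is added.  Flag growth is monotone, so at most ``n_items``
    rounds occur.
    """
    ids = matrix.item_ids
    anchors = list(anchors)
    if not anchors:
        raise ValidationError("anchor set must be non-empty")
    unknown = set(anchors) - set(ids)
    if unknown:
        raise ValidationError(f"unknown anchors: {sorted(unknown)}")
    candidates = [i for i in ids if i not in anchors]
    if not candidates:
        raise ValidationError("no candidate items outside the anchor set")

    from .gpcm import fit_gpcm

    pooled = fit_gpcm(matrix, grid=grid, se=False)
    flagged: list[str] = []
    stats, dfs, pvals = {}, {}, {}
    focal_mean = focal_var = np.nan
    for _round in range(len(ids)):
        new = []
        for cand in [c for c in candidates if c not in flagged]:
            fit = multigroup_fit(matrix, group_labels,
                                 free_items=flagged + [cand],
                                 reference=reference, grid=grid,
                                 fix_focal_var=fix_focal_var,
                                 start=pooled.params)
            stats[cand], dfs[cand], pvals[cand] = wald_item_test(fit, cand)
            focal_mean, focal_var = fit.focal_mean, fit.focal_sd ** 2
            if pvals[cand] < alpha:
                new.append(cand)
        if not new:
            break
        flagged.extend(new)
        if len(flagged) == len(candidates):
            break
    return DifResult(method="wald1_iterative", items=ids,
                     statistics=stats, dfs=dfs, p_values=pvals,
                     flagged=flagged, anchors=anchors, alpha=alpha,
                     focal_mean=focal_mean, focal_var=focal_var)
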