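"""Item-reduction procedures and decision rules for short-form assembly.

Two reduction routes are provided:

1. **Iterative information-based removal** — drop items with
   discrimination below 0.4, then DIF-flagged items, then repeatedly the
   item with the least total information, tracking test information
   (entire range and (-3, 3)) and average SE along the way.  The stop
   index marks the first removal whose relative test-information drop
   exceeds a configurable fraction (default 7%); that removal is the
   last one accepted, so the retained form sits just past the knee of
   the trajectory.  The full trajectory is always returned because the
   "substantial deterioration" judgement is ultimately the analyst's.

2. **Optimal test assembly (OTA)** — for each candidate length L, the
   item subset maximising summed test information over five anchor
   trait levels (-3, -1, 0, 1, 3) is found exactly by branch-and-bound
   over the LP relaxation, optionally under per-domain minimum-count
   constraints.  The short form is the smallest L whose subset passes
   three decision criteria relative to the full form: (1) summed- and
   factor-score correlations with the full form of at least 0.95,
   (2) convergent-validity correlations within 0.05 of the full form's,
   and (3) Cronbach's alpha at least 95% of the full form's.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bank import ResponseMatrix, ValidationError, total_score
from .gpcm import (GpcmFit, ItemParameters, LatentGrid, cronbach_alpha,
                   eap_scores, fit_gpcm, item_information,
                   standard_error_curve, test_information,
                   total_item_information)

__all__ = [
    "OtaConfig",
    "RemovalStep",
    "ReductionTrajectory",
    "ShortFormCandidate",
    "iterative_removal",
    "anchor_information",
    "ota_select",
    "exhaustive_select",
    "decision_rules",
    "shortest_satisfying_form",
    "compare_versions",
    "retention_percent",
]


@dataclass(frozen=True)
class OtaConfig:
    """Configuration of the OTA search and decision criteria."""

    anchor_points: tuple[float, ...] = (-3.0, -1.0, 0.0, 1.0, 3.0)
    length_min: int = 3
    length_max: Optional[int] = None
    content_constraints: Optional[dict[str, int]] = None
    score_corr_min: float = 0.95
    convergent_tolerance: float = 0.05
    alpha_fraction_min: float = 0.95

    def __post_init__(self) -> None:
        pts = np.asarray(self.anchor_points, float)
        if np.any(np.diff(pts) <= 0):
            raise ValidationError("anchor points must be strictly increasing")
        if not (0.0 <= self.score_corr_min <= 1.0):
            raise ValidationError("score_corr_min must be in [0, 1]")
        if not (0.0 <= self.alpha_fraction_min <= 1.0):
            raise ValidationError("alpha_fraction_min must be in [0, 1]")
        if self.length_min < 1:
            raise ValidationError("length_min must be >= 1")


def _resolve_params(fit, item: Optional[str] = None):
    if isinstance(fit, GpcmFit):
        params = fit.params
    elif isinstance(fit, dict):
        params = fit
    elif isinstance(fit, ItemParameters):
        return fit
    else:
        raise TypeError("expected GpcmFit, dict, or ItemParameters")
    if item is not None:
        return params[item]
    return params


# ---------------------------------------------------------------------
# iterative removal


@dataclass(frozen=True)
class RemovalStep:
    removed: str
    remaining: tuple[str, ...]
    ti_full: float
    ti_range: float
    avg_se: float
    rel_drop: float  # relative drop of full-range TI vs the previous step


@dataclass
class ReductionTrajectory:
    """Ordered record of the information-based removal process."""

    initial_items: tuple[str, ...]
    initial_ti_full: float
    initial_ti_range: float
    initial_avg_se: float
    steps: list[RemovalStep]
    stop_index: Optional[int]
    stop_threshold: float

    @property
    def removal_order(self) -> list[str]:
        return [s.removed for s in self.steps]

    @property
    def retained(self) -> tuple[str, ...]:
        """Items kept at the stop point (after the knee-marking removal)."""
        if self.stop_index is None:
            return self.steps[-1].remaining if self.steps else self.initial_items
        return self.steps[self.stop_index].remaining

    def to_frame(self) -> pd.DataFrame:
        rows = [{"removed": "", "n_items": len(self.initial_items),
                 "ti_full": self.initial_ti_full,
                 "ti_range": self.initial_ti_range,
                 "avg_se": self.initial_avg_se, "rel_drop": 0.0}]
        rows += [{"removed": s.removed, "n_items": len(s.remaining),
                  "ti_full": s.ti_full, "ti_range": s.ti_range,
                  "avg_se": s.avg_se, "rel_drop": s.rel_drop}
                 for s in self.steps]
        return pd.DataFrame(rows)


def iterative_removal(fit, data=None, stop_threshold: float = 0.07,
                      a_threshold: float = 0.4,
                      dif_flagged: Sequence[str] = (),
                      min_items: int = 3,
                      theta_range: tuple[float, float] = (-3.0, 3.0)
                      ) -> ReductionTrajectory:
    """Information-based iterative item removal.

    Items are removed in three passes: discrimination below
    ``a_threshold`` first, DIF-flagged items next, then ascending
    full-range item information.  The information ranking is computed
    once from the supplied fit (no refitting between removals).
    """
    params = _resolve_params(fit)
    ids = list(params)
    info = {i: total_item_information(params[i], "full") for i in ids}
    info_rng = {i: total_item_information(params[i], theta_range)
                for i in ids}

    low_a = sorted([i for i in ids if params[i].a < a_threshold],
                   key=lambda i: params[i].a)
    flagged = [i for i in dif_flagged if i in ids and i not in low_a]
    rest = [i for i in ids if i not in low_a and i not in flagged]
    order = low_a + flagged + sorted(rest, key=lambda i: info[i])

    remaining = list(ids)
    ti_full = sum(info.values())
    ti_rng = sum(info_rng.values())
    _, _, avg_se = standard_error_curve([params[i] for i in remaining])
    traj = ReductionTrajectory(
        initial_items=tuple(ids), initial_ti_full=ti_full,
        initial_ti_range=ti_rng, initial_avg_se=avg_se, steps=[],
        stop_index=None, stop_threshold=stop_threshold)

    prev_full = ti_full
    for iid in order:
        if len(remaining) - 1 < min_items:
            warnings.warn(
                f"stopping removal: fewer than {min_items} items would "
                "remain")
            break
        remaining.remove(iid)
        cur_full = sum(info[i] for i in remaining)
        cur_rng = sum(info_rng[i] for i in remaining)
        _, _, avg_se = standard_error_curve([params[i] for i in remaining])
        rel = (prev_full - cur_full) / prev_full if prev_full > 0 else 1.0
        traj.steps.append(RemovalStep(
            removed=iid, remaining=tuple(remaining), ti_full=cur_full,
            ti_range=cur_rng, avg_se=avg_se, rel_drop=rel))
        prev_full = cur_full
    for idx, s in enumerate(traj.steps):
        if s.rel_drop > stop_threshold:
            traj.stop_index = idx
            break
    return traj


# ---------------------------------------------------------------------
# optimal test assembly


def anchor_information(fit, item: str, anchor_points: Sequence[float]
                       = (-3.0, -1.0, 0.0, 1.0, 3.0)) -> float:
    """Sum of an item's Fisher information over the anchor trait levels."""
    par = _resolve_params(fit, item)
    return float(sum(float(item_information(par, t)) for t in anchor_points))


def _check_feasible(L: int, ids: Sequence[str], domains: dict[str, str],
                    min_counts: dict[str, int]) -> None:
    needed = 0
    for dom, mn in min_counts.items():
        avail = sum(1 for i in ids if domains.get(i) == dom)
        if avail < mn:
            raise ValidationError(
                f"domain {dom!r} minimum {mn} infeasible: only {avail} "
                "items available")
        needed += mn
    if needed > L:
        raise ValidationError(
            f"domain minimums require {needed} items but L = {L}")


def _branch_and_bound(ids: list[str], values: dict[str, float], L: int,
                      domains: Optional[dict[str, str]] = None,
                      min_counts: Optional[dict[str, int]] = None
                      ) -> list[str]:
    """Exact 0/1 maximisation of sum(values) at cardinality L.

    Depth-first branch-and-bound; the bound at each node is the greedy
    fractional (LP-relaxation) optimum of the remaining cardinality
    problem.  Include-branches are explored first in item order, and the
    incumbent is replaced only on strict improvement, so the returned
    optimum is the lexicographically first by item order.
    """
    n = len(ids)
    min_counts = min_counts or {}
    domains = domains or {}
    if min_counts:
        _check_feasible(L, ids, domains, min_counts)

    # suffix structures for bounds and feasibility
    vals = np.array([values[i] for i in ids])
    best: dict = {"obj": -np.inf, "set": None}
    eps = 1e-12

    def dom_remaining(k: int) -> dict[str, int]:
        out: dict[str, int] = {}
        for i in ids[k:]:
            d = domains.get(i)
            if d is not None:
                out[d] = out.get(d, 0) + 1
        return out

    def recurse(k: int, chosen: list[int], cur: float,
                counts: dict[str, int]) -> None:
        picked = len(chosen)
        if picked == L:
            deficit = sum(max(0, mn - counts.get(d, 0))
                          for d, mn in min_counts.items())
            if deficit == 0 and cur > best["obj"] + eps:
                best["obj"] = cur
                best["set"] = list(chosen)
            return
        if k == n or n - k < L - picked:
            return
        # domain feasibility of the remainder
        if min_counts:
            rem = dom_remaining(k)
            deficit = 0
            for d, mn in min_counts.items():
                short = mn - counts.get(d, 0)
                if short > rem.get(d, 0):
                    return
                deficit += max(0, short)
            if deficit > L - picked:
                return
        # LP/greedy upper bound: take the largest remaining values
        need = L - picked
        top = np.sort(vals[k:])[::-1][:need]
        if cur + top.sum() <= best["obj"] + eps:
            return
        d = domains.get(ids[k])
        if d is not None:
            counts[d] = counts.get(d, 0) + 1
        recurse(k + 1, chosen + [k], cur + vals[k], counts)
        if d is not None:
            counts[d] -= 1
        recurse(k + 1, chosen, cur, counts)

    recurse(0, [], 0.0, {})
    if best["set"] is None:
        raise ValidationError("no feasible selection found")
    return [ids[k] for k in best["set"]]


def ota_select(fit, L: int, config: Optional[OtaConfig] = None,
               bank=None) -> list[str]:
    """Optimal-test-assembly selection of L items.

    Maximises the summed anchor-point information using the full-model
    parameters (no refitting inside the search), subject to the
    cardinality constraint and any per-domain minimum counts in
    ``config.content_constraints``.
    """
    config = config or OtaConfig()
    params = _resolve_params(fit)
    ids = list(params)
    if not (1 <= L <= len(ids)):
        raise ValidationError(f"L = {L} outside 1..{len(ids)}")
    values = {i: anchor_information(params, i, config.anchor_points)
              for i in ids}
    domains = {}
    if bank is not None:
        domains = {it.item_id: it.domain for it in bank}
    return sorted(_branch_and_bound(ids, values, L, domains,
                                    config.content_constraints),
                  key=ids.index)


def exhaustive_select(fit, L: int, config: Optional[OtaConfig] = None,
                      bank=None) -> list[str]:
    """Brute-force OTA oracle: enumerate all C(p, L) subsets."""
    from itertools import combinations

    config = config or OtaConfig()
    params = _resolve_params(fit)
    ids = list(params)
    values = {i: anchor_information({i: params[i]}, i, config.anchor_points)
              for i in ids}
    domains = {it.item_id: it.domain for it in bank} if bank else {}
    mins = config.content_constraints or {}
    best, best_val = None, -np.inf
    for combo in combinations(ids, L):
        if mins:
            counts: dict[str, int] = {}
            for i in combo:
                d = domains.get(i)
                if d is not None:
                    counts[d] = counts.get(d, 0) + 1
            if any(counts.get(d, 0) < mn for d, mn in mins.items()):
                continue
        val = sum(values[i] for i in combo)
        if val > best_val + 1e-12:
            best, best_val = combo, val
    if best is None:
        raise ValidationError("no feasible selection found")
    return list(best)


# ---------------------------------------------------------------------
# decision rules and comparison


@dataclass
class ShortFormCandidate:
    """An item subset with its evaluation against the decision criteria."""

    items: tuple[str, ...]
    objective: float
    refit: GpcmFit
    alpha: float
    alpha_full: float
    corr_summed: float
    corr_factor: float
    convergent_summed: float
    convergent_factor: float
    convergent_full_summed: float
    convergent_full_factor: float
    criteria: tuple[bool, bool, bool]
    admissible: bool = True

    @property
    def passed(self) -> bool:
        return all(self.criteria)

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "objective": self.objective,
            "alpha": self.alpha,
            "alpha_full": self.alpha_full,
            "corr_summed": self.corr_summed,
            "corr_factor": self.corr_factor,
            "convergent_summed": self.convergent_summed,
            "convergent_factor": self.convergent_factor,
            "convergent_full_summed": self.convergent_full_summed,
            "convergent_full_factor": self.convergent_full_factor,
            "criteria": list(self.criteria),
            "admissible": self.admissible,
        }


def _corr(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero-variance scores in correlation")
    return float(np.corrcoef(x, y)[0, 1])


def decision_rules(full_fit: GpcmFit, matrix: ResponseMatrix,
                   candidate: Sequence[str],
                   config: Optional[OtaConfig] = None) -> ShortFormCandidate:
    """Evaluate a candidate subset against the three decision criteria.

    The candidate is refitted on its own columns; summed and EAP factor
    scores of the short and full forms are correlated with each other
    and with the convergent criterion.
    """
    config = config or OtaConfig()
    candidate = list(candidate)
    unknown = set(candidate) - set(matrix.item_ids)
    if unknown:
        raise ValidationError(f"candidate items not in matrix: {unknown}")
    if matrix.criterion is None:
        raise ValidationError("matrix has no convergent criterion scores")

    summed_full = total_score(matrix)
    eap_full, _ = eap_scores(full_fit, matrix)
    sub = matrix.subset(candidate)
    refit = fit_gpcm(sub, grid=full_fit.grid, se=False)
    summed_short = total_score(sub)
    eap_short, _ = eap_scores(refit, sub)

    corr_summed = _corr(summed_short, summed_full)
    corr_factor = _corr(eap_short, eap_full)
    conv_s = _corr(summed_short, matrix.criterion)
    conv_f = _corr(eap_short, matrix.criterion)
    conv_fs = _corr(summed_full, matrix.criterion)
    conv_ff = _corr(eap_full, matrix.criterion)
    alpha_short = cronbach_alpha(sub)
    alpha_full = cronbach_alpha(matrix)

    c1 = bool(corr_summed >= config.score_corr_min
              and corr_factor >= config.score_corr_min)
    c2 = bool(abs(conv_s - conv_fs) <= config.convergent_tolerance
              and abs(conv_f - conv_ff) <= config.convergent_tolerance)
    c3 = bool(alpha_short >= config.alpha_fraction_min * alpha_full)

    objective = sum(anchor_information({i: full_fit.params[i]}, i,
                                       config.anchor_points)
                    for i in candidate)
    return ShortFormCandidate(
        items=tuple(candidate), objective=objective, refit=refit,
        alpha=alpha_short, alpha_full=alpha_full,
        corr_summed=corr_summed, corr_factor=corr_factor,
        convergent_summed=conv_s, convergent_factor=conv_f,
        convergent_full_summed=conv_fs, convergent_full_factor=conv_ff,
        criteria=(c1, c2, c3))


def shortest_satisfying_form(matrix: ResponseMatrix,
                             config: Optional[OtaConfig] = None,
                             fit: Optional[GpcmFit] = None,
                             exclude: Sequence[str] = ()
                             ) -> ShortFormCandidate:
    """Smallest OTA-selected form passing all three decision criteria.

    ``exclude`` removes DIF-flagged items from candidacy.  If no length
    passes, the full (non-excluded) set is returned with
    ``admissible=False``.
    """
    config = config or OtaConfig()
    if fit is None:
        fit = fit_gpcm(matrix, se=False)
    available = [i for i in matrix.item_ids if i not in set(exclude)]
    params = {i: fit.params[i] for i in available}
    lmax = config.length_max or len(available)
    bank = [it for it in matrix.bank if it.item_id in set(available)]
    for L in range(config.length_min, min(lmax, len(available)) + 1):
        sel = ota_select(params, L, config, bank=bank)
        cand = decision_rules(fit, matrix, sel, config)
        if cand.passed:
            return cand
    full_cand = decision_rules(fit, matrix, available, config)
    full_cand.admissible = False
    return full_cand


def retention_percent(ti_version: float, ti_full: float) -> float:
    """Test-information retention of a version vs the full form, in %."""
    return 100.0 * ti_version / ti_full


def compare_versions(candidates: Sequence[tuple[str, ShortFormCandidate]]
                     ) -> pd.DataFrame:
    """Comparison table across scale versions.

    ``candidates`` is a list of (label, ShortFormCandidate); the first
    entry is treated as the full form for the retention columns.  Test
    information is computed from each version's own refitted parameters.
    """
    if len(candidates) < 2:
        raise ValidationError("need the full form plus at least one other")
    rows = []
    ti_full_ref = ti_rng_ref = None
    for label, cand in candidates:
        params = cand.refit.param_list()
        ti_full = test_information(params, bounds="full")
        ti_rng = test_information(params, bounds=(-3.0, 3.0))
        if ti_full_ref is None:
            ti_full_ref, ti_rng_ref = ti_full, ti_rng
        rows.append({
            "version": label,
            "n_items": len(cand.items),
            "test_information": ti_full,
            "test_information_33": ti_rng,
            "alpha": cand.alpha,
            "convergent_validity": cand.convergent_summed,
            "retention_full_pct": retention_percent(ti_full, ti_full_ref),
            "retention_33_pct": retention_percent(ti_rng, ti_rng_ref),
        })
    return pd.DataFrame(rows)
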