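"""Synthetic datasets emulating a 404-adult calibration study of the
12-item Chinese NRSS.

The generator inverts the GPCM that the analysis pipeline fits: latent
traits are standard-normal, responses are drawn from the per-item
category distributions, a PSQI-like 0-21 convergent criterion is an
affine-in-theta Gaussian rounded and clipped, and gender labels are
assigned at the study's 60% female split.  The default item parameters
are the reference GPCM calibration of the scale (discriminations 0.33 to
2.10, step difficulties -6.42 to 2.20), so every downstream stage can be
exercised without access to the original, undeposited responses.

Optional differential item functioning is injected by shifting one
item's parameters in the focal (male) group only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .bank import ItemDefinition, ResponseMatrix, default_bank, write_responses, save_bank
from .gpcm import ItemParameters, category_probs

__all__ = [
    "REFERENCE_ITEM_PARAMS",
    "SimulationProfile",
    "DifSpec",
    "Fixture",
    "simulate_thetas",
    "simulate_gpcm_responses",
    "simulate_criterion",
    "inject_dif",
    "make_fixture",
]

#: Reference GPCM calibration of the 12-item Chinese NRSS, used as the
#: default simulation profile.  Values are (a; b1..b4) on the scored
#: five-category scale.
REFERENCE_ITEM_PARAMS: dict[str, ItemParameters] = {
    "Q1": ItemParameters(1.74, (-2.12, -1.20, -0.12, 2.14)),
    "Q2": ItemParameters(1.39, (-3.21, -1.70, -0.50, 1.55)),
    "Q3": ItemParameters(1.24, (-2.08, -0.84, -0.27, 1.76)),
    "Q4": ItemParameters(0.43, (-5.26, -1.83, 0.03, -0.54)),
    "Q5": ItemParameters(0.33, (-0.72, -4.68, -1.58, -2.87)),
    "Q6": ItemParameters(0.65, (-4.94, -1.41, 0.73, -0.61)),
    "Q7": ItemParameters(0.53, (-6.42, -1.67, -0.81, -1.74)),
    "Q8": ItemParameters(1.12, (-2.07, -1.65, -0.42, 2.20)),
    "Q9": ItemParameters(1.36, (-2.50, -1.73, -0.44, 2.14)),
    "Q10": ItemParameters(2.10, (-2.20, -1.77, -0.74, 1.46)),
    "Q11": ItemParameters(0.40, (-5.64, -1.29, 0.37, -0.18)),
    "Q12": ItemParameters(0.98, (-2.50, -2.88, -1.07, -0.09)),
}

#: Default target correlation between the criterion score and theta.
#: Under the reference parameters corr(summed 12-item score, theta) is
#: about 0.904, so -0.6/0.904 = -0.664 yields the intended -0.60
#: correlation between the criterion and the summed scale score.
_DEFAULT_CRITERION_RHO = -0.664

#: Midpoint and spread of the latent criterion before rounding/clipping
#: to the 0-21 scale; SD 3.5 keeps clipping below 1% of persons.
_CRITERION_CENTER = 10.5
_CRITERION_SCALE = 3.5


@dataclass(frozen=True)
class DifSpec:
    """Parameter shifts applied to one item in the focal group."""

    item_id: str
    a_shift: float = 0.0
    b_shift: float = 0.0  # added to every step difficulty


@dataclass
class SimulationProfile:
    """Study conditions for a synthetic fixture."""

    item_params: dict[str, ItemParameters] = field(
        default_factory=lambda: dict(REFERENCE_ITEM_PARAMS))
    n_persons: int = 404
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    prop_female: float = 0.60
    criterion_rho: float = _DEFAULT_CRITERION_RHO
    dif_spec: Optional[DifSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not (0.0 < self.prop_female < 1.0):
            raise ValueError("prop_female must be in (0, 1)")
        if not abs(self.criterion_rho) < 1.0:
            raise ValueError("|criterion_rho| must be < 1")
        if self.theta_sd < 0:
            raise ValueError("theta_sd must be >= 0")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-stage RNG streams from one fixture seed."""
    names = ["theta", "responses", "criterion", "gender"]
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def simulate_thetas(profile: SimulationProfile,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw n_persons latent traits from N(theta_mean, theta_sd^2)."""
    if rng is None:
        rng = _stage_rngs(profile.seed)["theta"]
    if profile.theta_sd == 0:
        return np.full(profile.n_persons, profile.theta_mean)
    return rng.normal(profile.theta_mean, profile.theta_sd,
                      profile.n_persons)


def simulate_gpcm_responses(item_params, thetas: np.ndarray,
                            rng: Optional[np.random.Generator] = None,
                            bank: Optional[list[ItemDefinition]] = None,
                            seed: Optional[int] = None) -> ResponseMatrix:
    """Draw scored responses from the GPCM category distributions.

    ``item_params`` may be a dict (ids -> ItemParameters) or, for
    per-group DIF designs, a callable mapping person index -> dict.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if isinstance(item_params, dict):
        ids = list(item_params)
        params = item_params
    else:
        raise TypeError("item_params must be a dict of ItemParameters")
    thetas = np.asarray(thetas, float)
    n = len(thetas)
    values = np.empty((n, len(ids)), dtype=int)
    for j, iid in enumerate(ids):
        p = category_probs(params[iid], thetas)      # (n, K)
        u = rng.random((n, 1))
        values[:, j] = (p.cumsum(axis=1) < u).sum(axis=1) + 1
    if bank is None:
        if set(ids) == {f"Q{i}" for i in range(1, 13)}:
            by_id = {it.item_id: it for it in default_bank()}
            bank = [by_id[i] for i in ids]
        else:
            bank = [ItemDefinition(item_id=i, n_raw_categories=5,
                                   n_scored_categories=params[i].m + 1)
                    for i in ids]
    return ResponseMatrix(values=values, bank=bank)


def simulate_criterion(thetas: np.ndarray, profile: SimulationProfile,
                       rng: Optional[np.random.Generator] = None
                       ) -> np.ndarray:
    """A 0-21 integer criterion with target correlation to theta.

    criterion* = center + rho*scale*z(theta) + scale*sqrt(1-rho^2)*eps,
    rounded and clipped to [0, 21]; rho < 0 makes higher criterion
    scores correspond to lower traits (worse sleep).
    """
    thetas = np.asarray(thetas, float)
    if thetas.std() == 0:
        raise ValueError("degenerate theta vector (zero variance)")
    if rng is None:
        rng = _stage_rngs(profile.seed)["criterion"]
    rho = profile.criterion_rho
    z = (thetas - thetas.mean()) / thetas.std()
    cstar = (_CRITERION_CENTER + rho * _CRITERION_SCALE * z
             + _CRITERION_SCALE * np.sqrt(1.0 - rho ** 2)
             * rng.normal(size=len(thetas)))
    return np.clip(np.round(cstar), 0, 21).astype(int)


def inject_dif(item_params: dict[str, ItemParameters], dif_spec: DifSpec
               ) -> tuple[dict[str, ItemParameters], dict[str, ItemParameters]]:
    """Reference and focal parameter sets under the given DIF shifts."""
    if dif_spec.item_id not in item_params:
        raise KeyError(f"unknown item id {dif_spec.item_id!r}")
    if not (np.isfinite(dif_spec.a_shift) and np.isfinite(dif_spec.b_shift)):
        raise ValueError("DIF shifts must be finite")
    ref = dict(item_params)
    focal = dict(item_params)
    old = item_params[dif_spec.item_id]
    focal[dif_spec.item_id] = ItemParameters(
        a=old.a + dif_spec.a_shift,
        b=tuple(bk + dif_spec.b_shift for bk in old.b))
    return ref, focal


@dataclass
class Fixture:
    """A simulated study: responses plus the generating truth."""

    matrix: ResponseMatrix
    thetas: np.ndarray
    params_ref: dict[str, ItemParameters]
    params_focal: dict[str, ItemParameters]
    profile: SimulationProfile


def make_fixture(profile: Optional[SimulationProfile] = None,
                 out_dir: Optional[str | Path] = None) -> Fixture:
    """Generate a full study fixture (responses, gender, criterion).

    Deterministic under ``profile.seed``.  When ``out_dir`` is given the
    response CSV, bank JSON, and generating-truth JSON are written there.
    """
    profile = profile or SimulationProfile()
    rngs = _stage_rngs(profile.seed)
    thetas = simulate_thetas(profile, rngs["theta"])

    n = profile.n_persons
    n_female = int(round(profile.prop_female * n))
    group = np.array(["M"] * n, dtype=object)
    female_idx = rngs["gender"].permutation(n)[:n_female]
    group[female_idx] = "F"

    params_ref = dict(profile.item_params)
    if profile.dif_spec is not None:
        params_ref, params_focal = inject_dif(params_ref, profile.dif_spec)
    else:
        params_focal = dict(params_ref)

    rng_resp = rngs["responses"]
    mat_ref = simulate_gpcm_responses(params_ref, thetas, rng_resp)
    mat_focal = simulate_gpcm_responses(params_focal, thetas, rng_resp)
    values = np.where((group == "F")[:, None], mat_ref.values,
                      mat_focal.values)

    criterion = simulate_criterion(thetas, profile, rngs["criterion"])
    matrix = ResponseMatrix(values=values, bank=mat_ref.bank,
                            group=group, criterion=criterion)
    fixture = Fixture(matrix=matrix, thetas=thetas, params_ref=params_ref,
                      params_focal=params_focal, profile=profile)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_responses(matrix, out / "responses.csv")
        save_bank(matrix.bank, out / "bank.json")
        truth = {
            "seed": profile.seed,
            "n_persons": n,
            "theta": list(map(float, thetas)),
            "params_ref": {k: {"a": v.a, "b": list(v.b)}
                           for k, v in params_ref.items()},
            "params_focal": {k: {"a": v.a, "b": list(v.b)}
                             for k, v in params_focal.items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return fixture
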