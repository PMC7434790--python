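"""IRT assumption screening: polychoric correlations, sampling adequacy,
minimum-residual factoring, and unidimensionality / local-independence
verdicts.

Polychoric correlations are estimated by the standard two-step method:
thresholds fixed at inverse-normal marginal cumulative proportions, then
the latent bivariate-normal correlation maximising the contingency-table
likelihood.  Factoring is minimum-residual (minres): communalities are
chosen to minimise the off-diagonal sum of squared residuals of
R - Lambda Lambda'.

The verdicts mirror common applied practice for IRT screening: a scale
is treated as essentially unidimensional when the first-to-second
eigenvalue ratio exceeds 3 and the first factor explains at least 20% of
total variance; local independence is accepted when every off-diagonal
residual correlation after removing the first factor is below 0.25 in
absolute value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm, multivariate_normal

from .bank import ResponseMatrix, ValidationError

__all__ = [
    "CorrelationMatrix",
    "EfaResult",
    "UnidimensionalityReport",
    "polychoric",
    "polychoric_matrix",
    "kmo",
    "bartlett",
    "minres_efa",
    "eigenvalue_ratio",
    "unidimensionality_report",
    "local_independence",
]


@dataclass
class CorrelationMatrix:
    """A symmetric correlation matrix with its sample size."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValidationError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1.0 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float
                ) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for all table cells."""
    # pad thresholds with effectively +-infinity
    tx = np.concatenate([[-30.0], tau_x, [30.0]])
    ty = np.concatenate([[-30.0], tau_y, [30.0]])
    gx, gy = np.meshgrid(tx, ty, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mvn = multivariate_normal(mean=[0.0, 0.0],
                              cov=[[1.0, rho], [rho, 1.0]],
                              allow_singular=True)
    F = mvn.cdf(pts).reshape(gx.shape)
    cells = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(cells, 1e-12, None)


def polychoric(x: Sequence[int], y: Sequence[int]) -> float:
    """Two-step polychoric correlation of two ordinal vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValidationError("vectors must have equal length")
    ux, xi = np.unique(x, return_inverse=True)
    uy, yi = np.unique(y, return_inverse=True)
    if len(ux) < 2 or len(uy) < 2:
        raise ValidationError("each variable needs >= 2 observed categories")
    table = np.zeros((len(ux), len(uy)))
    np.add.at(table, (xi, yi), 1.0)
    n = table.sum()
    tau_x = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    tau_y = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)

    def negll(rho: float) -> float:
        return -float((table * np.log(_cell_probs(tau_x, tau_y, rho))).sum())

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(matrix: ResponseMatrix, smooth: bool = True
                      ) -> CorrelationMatrix:
    """Pairwise polychoric correlations of all items.

    Non-positive-definite results are eigenvalue-clipped (floor 1e-6)
    and rescaled to unit diagonal, with a warning.
    """
    X = matrix.values
    p = X.shape[1]
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = polychoric(X[:, i], X[:, j])
    if smooth:
        w, V = np.linalg.eigh(R)
        if w.min() < 1e-6:
            warnings.warn("polychoric matrix not positive definite; "
                          "eigenvalues clipped at 1e-6")
            w = np.clip(w, 1e-6, None)
            R = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            R = (R + R.T) / 2.0
            np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(values=R, n=matrix.n_persons)


def kmo(R: CorrelationMatrix) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy in [0, 1]."""
    V = R.values
    try:
        inv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular correlation matrix; consider smoothing") from None
    d = np.sqrt(np.abs(np.diag(inv)))
    partial = -inv / np.outer(d, d)
    iu = np.triu_indices(R.p, k=1)
    r2 = (V[iu] ** 2).sum()
    q2 = (partial[iu] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett(R: CorrelationMatrix, n: Optional[int] = None
             ) -> tuple[float, int, float]:
    """Bartlett's sphericity test: (chi2, df, p).

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2.
    """
    from scipy.stats import chi2 as chi2_dist

    n = n if n is not None else R.n
    p = R.p
    if n <= p:
        raise ValidationError("Bartlett's test needs n > p")
    sign, logdet = np.linalg.slogdet(R.values)
    if sign <= 0:
        raise ValidationError("correlation matrix must be positive definite")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    stat = max(stat, 0.0)
    df = p * (p - 1) // 2
    pval = float(chi2_dist.sf(stat, df))
    return float(stat), df, pval


@dataclass
class EfaResult:
    """Minimum-residual factor solution."""

    loadings: np.ndarray          # p x k
    communalities: np.ndarray     # p
    eigenvalues: np.ndarray       # p, of the correlation matrix, descending
    variance_explained: np.ndarray  # k, fractions of total variance
    residual_matrix: np.ndarray   # p x p, diagonal not meaningful
    n_iter: int
    converged: bool


def _minres_loadings(R: np.ndarray, h2: np.ndarray, k: int) -> np.ndarray:
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    w, V = np.linalg.eigh(Rr)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    L = V[:, order] * np.sqrt(lam)
    # sign convention: each factor's loading sum nonnegative
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    return L * signs


def minres_efa(R: CorrelationMatrix, k: int = 1, max_iter: int = 1000
               ) -> EfaResult:
    """Minimum-residual (minres) exploratory factor analysis.

    Communalities minimise the off-diagonal sum of squared residuals of
    ``R - Lambda Lambda'``; deterministic given R (started from squared
    multiple correlations).
    """
    V = R.values
    p = R.p
    if not (1 <= k < p):
        raise ValidationError("need 1 <= k < p factors")
    iu = np.triu_indices(p, k=1)

    def objective(h2: np.ndarray) -> float:
        L = _minres_loadings(V, h2, k)
        resid = V - L @ L.T
        return float((resid[iu] ** 2).sum())

    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(V))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    x0 = np.clip(smc, 0.01, 0.99)
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            bounds=[(1e-3, 1.0)] * p,
                            options={"maxiter": max_iter, "ftol": 1e-12})
    if not res.success and res.nit >= max_iter:
        raise ValidationError(
            f"minres failed to converge after {res.nit} iterations")
    h2 = res.x
    L = _minres_loadings(V, h2, k)
    resid = V - L @ L.T
    eig = np.sort(np.linalg.eigvalsh(V))[::-1]
    var_explained = (L ** 2).sum(axis=0) / p
    return EfaResult(loadings=L,
                     communalities=np.clip((L ** 2).sum(axis=1), 0.0, 1.0),
                     eigenvalues=eig,
                     variance_explained=var_explained,
                     residual_matrix=resid,
                     n_iter=int(res.nit), converged=bool(res.success))


def eigenvalue_ratio(eigenvalues: np.ndarray) -> float:
    """First-to-second eigenvalue ratio; +inf when the second is <= 0."""
    lam1, lam2 = eigenvalues[0], eigenvalues[1]
    if lam2 <= 0:
        return float("inf")
    return float(lam1 / lam2)


@dataclass
class UnidimensionalityReport:
    """Verdict bundle for the IRT unidimensionality screen."""

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    ratio: float
    first_factor_variance: float
    unidimensional: bool
    max_abs_residual: float
    locally_independent: bool
    efa: EfaResult = field(repr=False)
    correlation: CorrelationMatrix = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        out = {
            "kmo": self.kmo,
            "bartlett": {"chi2": self.bartlett_chi2,
                         "df": self.bartlett_df, "p": self.bartlett_p},
            "eigenvalues": list(map(float, self.eigenvalues)),
            "eigenvalue_ratio": (None if np.isinf(self.ratio)
                                 else self.ratio),
            "first_factor_variance": self.first_factor_variance,
            "unidimensional": self.unidimensional,
            "max_abs_residual": self.max_abs_residual,
            "locally_independent": self.locally_independent,
        }
        Path(path).write_text(json.dumps(out, indent=1))


def local_independence(matrix_or_R, efa: EfaResult,
                       threshold: float = 0.25) -> tuple[float, bool]:
    """Largest |residual correlation| after removing the first factor.

    Returns (max_abs_residual, verdict); verdict is True when every
    off-diagonal residual is below the threshold in absolute value.
    """
    if isinstance(matrix_or_R, CorrelationMatrix):
        R = matrix_or_R.values
    elif isinstance(matrix_or_R, ResponseMatrix):
        R = polychoric_matrix(matrix_or_R).values
    else:
        R = np.asarray(matrix_or_R, float)
    L1 = efa.loadings[:, :1]
    resid = R - L1 @ L1.T
    iu = np.triu_indices(R.shape[0], k=1)
    mx = float(np.max(np.abs(resid[iu])))
    return mx, mx < threshold


def unidimensionality_report(matrix: ResponseMatrix,
                             ratio_threshold: float = 3.0,
                             variance_threshold: float = 0.20,
                             residual_threshold: float = 0.25
                             ) -> UnidimensionalityReport:
    """Run the full IRT-assumption screen on a response matrix."""
    R = polychoric_matrix(matrix)
    chi2, df, pval = bartlett(R)
    efa = minres_efa(R, k=1)
    ratio = eigenvalue_ratio(efa.eigenvalues)
    var1 = float(efa.variance_explained[0])
    uni = (ratio > ratio_threshold) and (var1 >= variance_threshold)
    mx, li = local_independence(R, efa, residual_threshold)
    return UnidimensionalityReport(
        kmo=kmo(R), bartlett_chi2=chi2, bartlett_df=df, bartlett_p=pval,
        eigenvalues=efa.eigenvalues, ratio=ratio,
        first_factor_variance=var1, unidimensional=uni,
        max_abs_residual=mx, locally_independent=li,
        efa=efa, correlation=R)
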