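"""Linear mixed model under the no-region-effect null, and its invariants.

The trait model is ``y = X alpha + b + eps`` with ``b ~ N(0, sigma_b^2 R)``
and ``eps ~ N(0, sigma_e^2 I)``, so ``y ~ N(X alpha, V)`` with
``V = sigma_b^2 R + sigma_e^2 I``.  Fitting is a single eigendecomposition
of ``R`` followed by a 1-D profile-likelihood search over the heritability
``h2 = sigma_b^2 / (sigma_b^2 + sigma_e^2)``: for each candidate h2 the
covariate effects and the total variance have closed-form profile
estimates in the rotated basis.

Everything the per-region score test needs that does not depend on
genotypes — ``q = V^{-1} P y``, ``V^{-1} P`` and the Cholesky factor of
``V`` — is computed once by :func:`precompute_invariants`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix

logger = logging.getLogger("kinskat")

__all__ = [
    "PhenotypeData",
    "NullModel",
    "NullPrecompute",
    "fit_null",
    "loglikelihood",
    "precompute_invariants",
    "adjust_trait",
]

H2_UPPER = 1.0 - 1e-6
_PSD_TOL = -1e-8


@dataclass
class PhenotypeData:
    """Complete-case trait vector, covariate design matrix and sample ids.

    ``X`` always contains an intercept column (first).  Construction from a
    table with missing values goes through :meth:`from_frame`, which drops
    incomplete rows and logs their ids.
    """

    y: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    covariate_names: list[str] = field(default_factory=lambda: ["intercept"])

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n or len(self.sample_ids) != n:
            raise ValueError("y, X and sample_ids must agree in length")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in phenotype data; filter first")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")
        if self.X.shape[1] >= n:
            raise ValueError("more covariates than samples")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait: str,
        covariates: list[str] | None = None,
        id_column: str = "id",
    ) -> "PhenotypeData":
        """Build from a phenotype table, removing incomplete rows."""
        covariates = list(covariates or [])
        cols = [trait] + covariates
        for c in [id_column] + cols:
            if c not in frame.columns:
                raise KeyError(f"column {c!r} not in phenotype table")
        sub = frame[[id_column] + cols].copy()
        keep = sub[cols].notna().all(axis=1)
        dropped = sub.loc[~keep, id_column].tolist()
        if dropped:
            logger.info("complete-case filter removed %d samples: %s",
                        len(dropped), dropped[:10])
        sub = sub.loc[keep]
        n = len(sub)
        X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(float) for c in covariates])
        return cls(
            y=sub[trait].to_numpy(float),
            X=X,
            sample_ids=sub[id_column].astype(str).tolist(),
            covariate_names=["intercept"] + covariates,
        )


@dataclass
class NullModel:
    """Fitted null-model parameters plus the cached eigendecomposition of R."""

    sigma2_b: float
    sigma2_e: float
    alpha: np.ndarray
    loglik: float
    h2: float
    eigen_R: tuple[np.ndarray, np.ndarray]  # (ascending eigenvalues, vectors)
    method: str = "ML"
    flags: list[str] = field(default_factory=list)

    @property
    def total_variance(self) -> float:
        return self.sigma2_b + self.sigma2_e


@dataclass
class NullPrecompute:
    """Genotype-independent quantities reused by every region.

    ``q = V^{-1} P y`` enters the score statistic; ``VinvP = V^{-1} P``
    (symmetric) enters the reduced m-by-m eigenvalue problem; ``chol_V``
    (lower triangular, ``L L^T = V``) whitens general kernels.
    """

    q: np.ndarray
    VinvP: np.ndarray
    chol_V: np.ndarray


def _check_alignment(pheno: PhenotypeData, R: KinshipMatrix) -> None:
    if list(R.sample_ids) != list(pheno.sample_ids):
        raise ValueError(
            "kinship matrix and phenotype data are not aligned; "
            "subset the kinship matrix by id first"
        )


def _profile(h2: float, d: np.ndarray, ty: np.ndarray, tX: np.ndarray, method: str):
    """Profile out alpha and the total variance at fixed h2.

    Returns (loglik, sigma2_total, alpha) in the rotated basis where
    ``V = sigma2 * diag(delta)`` and ``delta = h2 * d + (1 - h2)``.
    """
    n, p = tX.shape
    delta = h2 * d + (1.0 - h2)
    if np.any(delta <= 0):
        return -np.inf, np.nan, np.full(p, np.nan)
    wX = tX / delta[:, None]
    XtVX = tX.T @ wX
    try:
        alpha = np.linalg.solve(XtVX, wX.T @ ty)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.full(p, np.nan)
    resid = ty - tX @ alpha
    rss = float(resid @ (resid / delta))
    logdet = float(np.sum(np.log(delta)))
    if rss <= 0.0:  # exact fit: zero residual variance, unbounded density
        return np.inf, 0.0, alpha
    if method == "REML":
        df = n - p
        sigma2 = rss / df
        sign, ld_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf, np.nan, alpha
        ll = -0.5 * (df * np.log(2 * np.pi * sigma2) + logdet + ld_xvx + df)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, sigma2, alpha


def fit_null(
    pheno: PhenotypeData,
    R: KinshipMatrix,
    method: str = "ML",
    eigen_R: tuple[np.ndarray, np.ndarray] | None = None,
) -> NullModel:
    """Fit ``y ~ N(X alpha, sigma_b^2 R + sigma_e^2 I)`` by ML (default) or REML.

    A single symmetric eigendecomposition ``R = U D U^T`` rotates the
    problem so that each candidate heritability costs O(n p^2); the
    heritability is then found by a grid scan plus bounded 1-D
    minimization on ``[0, 1 - 1e-6]``.

    Degenerate geometries are flagged rather than silently resolved:
    a flat profile (``R`` proportional to ``I`` makes h2 unidentifiable)
    yields ``h2 = 0`` with flag ``h2_unidentifiable``; a maximum at the
    upper bound yields flag ``h2_boundary``.

    ``eigen_R`` may pass a previously computed ``(eigenvalues, vectors)``
    pair for R (ascending order, as cached on a NullModel) to skip the
    decomposition when many traits are fitted against one kinship matrix.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown method {method!r}")
    _check_alignment(pheno, R)
    d, U = eigen_R if eigen_R is not None else np.linalg.eigh(R.values)
    if d[0] < _PSD_TOL * max(1.0, abs(d[-1])):
        raise ValueError(
            f"kinship matrix is not positive semi-definite (min eigenvalue {d[0]:.3g}); "
            "check the matrix for entry or alignment errors"
        )
    d = np.clip(d, 0.0, None)
    ty = U.T @ pheno.y
    tX = U.T @ pheno.X

    grid = np.linspace(0.0, H2_UPPER, 21)
    grid_ll = np.array([_profile(h, d, ty, tX, method)[0] for h in grid])
    flags: list[str] = []
    finite_ll = grid_ll[np.isfinite(grid_ll)]
    if finite_ll.size == 0:
        # exact fit everywhere (zero-noise trait): report the iid limit
        h2_hat = 0.0
        flags.append("degenerate_fit")
    elif np.ptp(finite_ll) < 1e-10 and finite_ll.size == grid_ll.size:
        h2_hat = 0.0
        flags.append("h2_unidentifiable")
        logger.warning("h2 profile is flat (R ~ I?); reporting h2 = 0")
    else:
        k = int(np.argmax(grid_ll))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda h: -_profile(h, d, ty, tX, method)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h2_hat = float(res.x)
        # the bounded minimizer never lands exactly on an endpoint
        for endpoint in (0.0, H2_UPPER):
            if _profile(endpoint, d, ty, tX, method)[0] > -res.fun:
                h2_hat = endpoint
        if h2_hat >= H2_UPPER - 1e-6:
            flags.append("h2_boundary")
            logger.warning("h2 estimate at the upper boundary")
    ll, sigma2, alpha = _profile(h2_hat, d, ty, tX, method)
    return NullModel(
        sigma2_b=h2_hat * sigma2,
        sigma2_e=(1.0 - h2_hat) * sigma2,
        alpha=alpha,
        loglik=ll,
        h2=h2_hat,
        eigen_R=(d, U),
        method=method,
        flags=flags,
    )


def loglikelihood(
    pheno: PhenotypeData,
    R: KinshipMatrix,
    sigma2_b: float,
    sigma2_e: float,
    alpha: np.ndarray,
) -> float:
    """Exact multivariate-normal log-density at the given parameters.

    Dense evaluation (build V, factorize, quadratic form); serves as the
    brute-force reference for :func:`fit_null`.
    """
    if sigma2_b < 0 or sigma2_e <= 0:
        raise ValueError("require sigma2_b >= 0 and sigma2_e > 0")
    _check_alignment(pheno, R)
    n = len(pheno.y)
    V = sigma2_b * R.values + sigma2_e * np.eye(n)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance matrix V is singular")
    r = pheno.y - pheno.X @ np.asarray(alpha, dtype=float)
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def build_V(null: NullModel, R: KinshipMatrix) -> np.ndarray:
    """Covariance matrix implied by the fitted null model."""
    return null.sigma2_b * R.values + null.sigma2_e * np.eye(len(R.sample_ids))


def precompute_invariants(
    null: NullModel, pheno: PhenotypeData, R: KinshipMatrix
) -> NullPrecompute:
    """Compute ``q = V^{-1} P y``, ``V^{-1} P`` and the Cholesky factor of V.

    ``P = I - X (X^T V^{-1} X)^{-1} X^T V^{-1}`` is the generalized
    least-squares projection annihilating the covariates; ``V^{-1} P`` is
    symmetric, which the m-by-m eigenvalue reduction relies on.
    """
    _check_alignment(pheno, R)
    V = build_V(null, R)
    L = sla.cholesky(V, lower=True)
    Vinv_X = sla.cho_solve((L, True), pheno.X)
    XtVinvX = pheno.X.T @ Vinv_X
    try:
        B = np.linalg.solve(XtVinvX, Vinv_X.T)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "X^T V^-1 X is singular: covariates are collinear"
        ) from e
    Vinv = sla.cho_solve((L, True), np.eye(V.shape[0]))
    VinvP = Vinv - Vinv_X @ B
    VinvP = 0.5 * (VinvP + VinvP.T)
    q = VinvP @ pheno.y
    return NullPrecompute(q=q, VinvP=VinvP, chol_V=L)


def adjust_trait(pheno: PhenotypeData) -> PhenotypeData:
    """Pre-adjust the trait: replace y by its OLS residuals on X.

    Returns a new :class:`PhenotypeData` whose trait is the ordinary
    least-squares residual and whose design is intercept-only, for the
    analysis mode where covariates are regressed out before testing
    instead of being carried in the mixed model.  With an intercept-only
    design there is nothing to adjust and the input is returned as is.
    """
    if pheno.X.shape[1] == 1:
        return pheno
    coef, _, rank, _ = np.linalg.lstsq(pheno.X, pheno.y, rcond=None)
    if rank < pheno.X.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")
    resid = pheno.y - pheno.X @ coef
    return PhenotypeData(
        y=resid,
        X=np.ones((len(resid), 1)),
        sample_ids=list(pheno.sample_ids),
        covariate_names=["intercept"],
    )
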