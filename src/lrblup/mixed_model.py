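"""Animal-model mixed-model equations (Henderson) and EM-REML.

Solves, for records ``y = X b + Z u + e`` with ``u ~ N(0, K sigma2_g)`` and
``e ~ N(0, I sigma2_e)``::

    [ X'X      X'Z          ] [ b ]   [ X'y ]
    [ Z'X      Z'Z + K^-1 l ] [ u ] = [ Z'y ],    l = sigma2_e / sigma2_g

The model genetic variance ``sigma2_g`` is the equilibrium variance
``sigma2_u_inf`` (equal to the base variance without selection), so the
prediction-error (co)variances ``C_uu = sigma2_e * (animal block of the
coefficient-matrix inverse)`` and the fixed-effect error covariance
``C_bb`` refer to the same ``G = K sigma2_u_inf`` used by the LR
expectations.  Individuals without records are predicted through their
relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import RelationshipMatrix, variance_factor

__all__ = [
    "VarianceComponents",
    "FixedDesign",
    "EvaluationResult",
    "EMREMLResult",
    "solve_mme",
    "accuracy_from_pev",
    "precorrect",
    "em_reml",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Additive and residual variances, with optional equilibrium variance.

    ``sigma2_u_inf`` is the additive variance at equilibrium under selection
    (Bulmer effect); it defaults to ``sigma2_u`` (no selection) and is an
    input, never estimated internally.
    """

    sigma2_u: float
    sigma2_e: float
    sigma2_u_inf: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be positive")
        if self.sigma2_u_inf is None:
            object.__setattr__(self, "sigma2_u_inf", self.sigma2_u)
        if self.sigma2_u_inf <= 0 or self.sigma2_u_inf > self.sigma2_u:
            raise ValueError("sigma2_u_inf must be in (0, sigma2_u]")

    @property
    def k(self) -> float:
        """Variance reduction due to selection, ``1 - sigma2_u_inf/sigma2_u``."""
        return 1.0 - self.sigma2_u_inf / self.sigma2_u

    @property
    def lam(self) -> float:
        """Base-scale variance ratio ``sigma2_e / sigma2_u``."""
        return self.sigma2_e / self.sigma2_u

    @property
    def lam_model(self) -> float:
        """Ratio used in the MME, ``sigma2_e / sigma2_u_inf``."""
        return self.sigma2_e / self.sigma2_u_inf

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    @property
    def h2_inf(self) -> float:
        """Heritability on the equilibrium (selected-population) scale."""
        return self.sigma2_u_inf / (self.sigma2_u_inf + self.sigma2_e)


class FixedDesign:
    """Fixed-effect specification: factor and covariate column names.

    Factors are treatment-coded (first level dropped) next to an intercept;
    precorrected data ``y* = y - X b_hat`` are invariant to that choice.
    Call :meth:`fit` on the data used for estimation, then :meth:`matrix`
    for any rows with the same columns.
    """

    def __init__(
        self,
        factors: Sequence[str] = (),
        covariates: Sequence[str] = (),
        intercept: bool = True,
    ):
        if not intercept and factors:
            raise ValueError("factors require an intercept (treatment coding)")
        self.factors = list(factors)
        self.covariates = list(covariates)
        self.intercept = intercept
        self.levels_: dict[str, list] | None = None
        self.columns_: list[str] | None = None

    def fit(self, data: pd.DataFrame) -> "FixedDesign":
        self.levels_ = {}
        cols = ["(intercept)"] if self.intercept else []
        for f in self.factors:
            lv = sorted(data[f].astype(str).unique())
            self.levels_[f] = lv
            cols += [f"{f}[{l}]" for l in lv[1:]]
        cols += list(self.covariates)
        self.columns_ = cols
        return self

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        if self.levels_ is None:
            raise RuntimeError("design not fitted")
        n = len(data)
        blocks = [np.ones((n, 1))] if self.intercept else [np.empty((n, 0))]
        for f in self.factors:
            lv = self.levels_[f]
            vals = data[f].astype(str).to_numpy()
            unseen = set(vals) - set(lv)
            if unseen:
                raise ValueError(
                    f"factor {f!r} has level(s) {sorted(unseen)} absent from the fitted design"
                )
            X = np.zeros((n, len(lv) - 1))
            for j, l in enumerate(lv[1:]):
                X[:, j] = vals == l
            blocks.append(X)
        for c in self.covariates:
            blocks.append(data[c].to_numpy(dtype=float).reshape(-1, 1))
        return np.hstack(blocks)


@dataclass
class EvaluationResult:
    """BLUE/BLUP solutions plus exact error (co)variance blocks.

    ``C_uu`` carries PEV on the diagonal and PEC off-diagonal for every
    individual in the relationship matrix (``None`` if not requested);
    ``C_bb`` is the fixed-effect error covariance.
    """

    ids: list[str]
    beta_hat: pd.Series
    u_hat: pd.Series
    C_uu: np.ndarray | None
    C_bb: np.ndarray | None
    vc: VarianceComponents
    design: FixedDesign
    model: str = "pblup"
    data_tag: str = "whole"

    def mean_pev(self, focal: Sequence[str] | None = None) -> float:
        ix = self._focal_ix(focal)
        return float(np.mean(np.diag(self.C_uu)[ix]))

    def mean_pec(self, focal: Sequence[str] | None = None) -> float:
        """Grand mean of the focal PEV/PEC block (diagonal included)."""
        ix = self._focal_ix(focal)
        return float(np.mean(self.C_uu[np.ix_(ix, ix)]))

    def _focal_ix(self, focal: Sequence[str] | None) -> np.ndarray:
        if self.C_uu is None:
            raise ValueError("PEV/PEC were not computed (compute_cov=False)")
        if focal is None:
            return np.arange(len(self.ids))
        index = {i: k for k, i in enumerate(self.ids)}
        return np.asarray([index[i] for i in focal], dtype=np.int64)


def _design_matrices(
    phenotypes: pd.DataFrame,
    design: FixedDesign,
    K: RelationshipMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if "id" not in phenotypes.columns or "y" not in phenotypes.columns:
        raise ValueError("phenotype table must have 'id' and 'y' columns")
    y = phenotypes["y"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing phenotype values in included rows")
    rec_ix = K.indices(phenotypes["id"].astype(str).tolist())
    X = design.matrix(phenotypes)
    return X, y, rec_ix


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the columns a pivoted QR leaves out of the basis
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(columns[j] for j in piv[r:])
        raise ValueError(f"fixed-effect design is rank deficient; confounded columns: {bad}")


def solve_mme(
    phenotypes: pd.DataFrame,
    design: FixedDesign,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    compute_cov: bool = True,
    model: str | None = None,
    data_tag: str = "whole",
) -> EvaluationResult:
    """Solve the animal-model MME for one trait.

    `phenotypes` has columns ``id``, ``y`` plus the design's factor and
    covariate columns; repeated records per individual are allowed (iid
    residuals).  Every id must be present in `K`.
    """
    design = FixedDesign(design.factors, design.covariates, design.intercept).fit(phenotypes)
    X, y, rec_ix = _design_matrices(phenotypes, design, K)
    _check_rank(X, design.columns_)
    q = len(K)
    p = X.shape[1]
    Z = np.zeros((len(y), q))
    Z[np.arange(len(y)), rec_ix] = 1.0

    lam = vc.lam_model
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + K.inverse * lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    cf = cho_factor(C, lower=True)
    sol = cho_solve(cf, rhs)

    C_uu = C_bb = None
    if compute_cov:
        Cinv = cho_solve(cf, np.eye(p + q))
        C_bb = vc.sigma2_e * Cinv[:p, :p]
        C_uu = vc.sigma2_e * Cinv[p:, p:]

    return EvaluationResult(
        ids=list(K.ids),
        beta_hat=pd.Series(sol[:p], index=design.columns_),
        u_hat=pd.Series(sol[p:], index=list(K.ids)),
        C_uu=C_uu,
        C_bb=C_bb,
        vc=vc,
        design=design,
        model=model or ("gblup" if K.source == "genomic" else "pblup"),
        data_tag=data_tag,
    )


def accuracy_from_pev(
    result: EvaluationResult,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    focal: Sequence[str],
) -> float:
    """Population accuracy of a focal cohort from PEV/PEC.

    ``acc = sqrt( (vf*s2 - (mean PEV - mean PEC)) / (vf*s2) )`` with
    ``vf = mean(diag K_f) - mean(K_f)`` and ``s2 = sigma2_u_inf``.  A
    slightly negative numerator (numerical noise) is clipped to 0 with a
    warning.
    """
    vf = variance_factor(K, focal)
    if vf <= 0:
        raise ValueError(
            "variance factor <= 0 (e.g. a single individual): population accuracy undefined"
        )
    den = vf * vc.sigma2_u_inf
    num = den - (result.mean_pev(focal) - result.mean_pec(focal))
    if num < 0:
        if num < -1e-6 * den:
            warnings.warn(
                f"negative accuracy numerator ({num:.3g}) clipped to 0", stacklevel=2
            )
        num = 0.0
    return float(np.sqrt(num / den))


def precorrect(phenotypes: pd.DataFrame, result: EvaluationResult) -> pd.Series:
    """``y* = y - X beta_hat`` rowwise, using the fitted (whole-data) BLUE."""
    X = result.design.matrix(phenotypes)
    return pd.Series(
        phenotypes["y"].to_numpy(dtype=float) - X @ result.beta_hat.to_numpy(),
        index=phenotypes.index,
        name="y_star",
    )


@dataclass
class EMREMLResult:
    vc: VarianceComponents
    n_iter: int
    converged: bool
    boundary: bool
    trajectory: list[tuple[float, float]] = field(repr=False, default_factory=list)

    @property
    def h2(self) -> float:
        return self.vc.h2


def em_reml(
    phenotypes: pd.DataFrame,
    design: FixedDesign,
    K: RelationshipMatrix,
    start: VarianceComponents,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EMREMLResult:
    """EM-REML for (sigma2_u, sigma2_e) in the single-trait animal model.

    The relationship matrix is marginalized to phenotyped individuals (the
    REML likelihood is unchanged).  Updates::

        sigma2_u <- (u'K^-1 u + tr(K^-1 C_uu)) / q
        sigma2_e <- (y'y - b'X'y - u'Z'y) / (n - rank X)

    Because the EM map contracts slowly when heritability is far from the
    truth, every fifth iteration applies componentwise Aitken extrapolation
    to the iterate sequence (rejected if it leaves the parameter space);
    convergence is judged on the unaccelerated EM step.  A collapse of
    either variance toward its boundary (e.g. sigma2_u below 1e-3 of
    sigma2_e) is flagged, not raised.
    """
    obs_ids = list(dict.fromkeys(phenotypes["id"].astype(str)))
    Ksub = RelationshipMatrix(obs_ids, K.submatrix(obs_ids), source=K.source)
    design = FixedDesign(design.factors, design.covariates, design.intercept).fit(phenotypes)
    X, y, rec_ix = _design_matrices(phenotypes, design, Ksub)
    _check_rank(X, design.columns_)
    n, p = X.shape
    q = len(obs_ids)
    if n <= p:
        raise ValueError("need more records than fixed-effect parameters")
    Z = np.zeros((n, q))
    Z[np.arange(n), rec_ix] = 1.0
    Kinv = Ksub.inverse
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty = X.T @ y, Z.T @ y
    yty = float(y @ y)

    def em_step(s2u: float, s2e: float) -> tuple[float, float, float]:
        """One EM update plus the current -2 restricted log-likelihood."""
        lam = s2e / s2u
        C = np.empty((p + q, p + q))
        C[:p, :p], C[:p, p:] = XtX, XtZ
        C[p:, :p], C[p:, p:] = XtZ.T, ZtZ + Kinv * lam
        cf = cho_factor(C, lower=True)
        sol = cho_solve(cf, np.concatenate([Xty, Zty]))
        b, u = sol[:p], sol[p:]
        Cinv_uu = cho_solve(cf, np.eye(p + q))[p:, p:]
        resid = float(yty - b @ Xty - u @ Zty)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        m2ll = (
            logdet_C
            + (n - p - q) * np.log(s2e)
            + q * np.log(s2u)
            + resid / s2e
        )
        s2u_new = float(u @ Kinv @ u + s2e * np.sum(Kinv * Cinv_uu)) / q
        s2e_new = resid / (n - p)
        return s2u_new, s2e_new, m2ll

    s2u, s2e = start.sigma2_u, start.sigma2_e
    traj: list[tuple[float, float]] = []
    m2ll_prev = np.inf
    pending: tuple[tuple[float, float], float] | None = None  # (fallback, m2ll bound)
    for it in range(1, max_iter + 1):
        s2u_new, s2e_new, m2ll = em_step(s2u, s2e)
        if pending is not None:
            fallback, bound = pending
            pending = None
            if not np.isfinite(m2ll) or m2ll > bound:
                # extrapolation did not improve the likelihood: revert
                s2u, s2e = fallback
                m2ll_prev = bound
                continue
        traj.append((s2u_new, s2e_new))
        delta = max(abs(s2u_new - s2u) / max(s2u, 1e-12), abs(s2e_new - s2e) / s2e)
        # a flat restricted likelihood means converged even if a component
        # is still drifting geometrically toward a boundary
        if abs(m2ll_prev - m2ll) < 1e-6:
            delta = 0.0
        m2ll_prev = m2ll
        s2u, s2e = s2u_new, s2e_new
        boundary = s2u < 1e-8 or s2u < 1e-3 * s2e or s2e < 1e-6 * s2u
        if boundary:
            s2u = max(s2u, 1e-10 * s2e)
            s2e = max(s2e, 1e-10 * s2u)
        if delta < tol or boundary:
            return EMREMLResult(
                VarianceComponents(s2u, s2e), it, converged=True,
                boundary=boundary, trajectory=traj,
            )
        if it % 5 == 0 and len(traj) >= 3:
            # Aitken extrapolation of the slowly contracting EM sequence,
            # accepted at the next iteration only if the likelihood improves
            x0, x1, x2 = (np.asarray(t) for t in traj[-3:])
            d1, d2 = x1 - x0, x2 - x1
            denom = d2 - d1
            safe = np.abs(denom) > 1e-14 * np.maximum(np.abs(x2), 1e-300)
            acc = np.where(safe, x2 - np.divide(d2**2, denom, where=safe, out=np.zeros(2)), x2)
            if np.all(np.isfinite(acc)) and acc[0] > 0 and acc[1] > 0 and (
                abs(acc[0] - x2[0]) > 1e-12 or abs(acc[1] - x2[1]) > 1e-12
            ):
                pending = ((s2u, s2e), m2ll)
                s2u, s2e = float(acc[0]), float(acc[1])
    raise RuntimeError(
        f"EM-REML did not converge in {max_iter} iterations; trajectory tail: {traj[-5:]}"
    )
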