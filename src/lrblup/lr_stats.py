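"""The LR statistics and their theoretical expectations.

Given EBV of the same focal individuals from a "partial" (old) and a
"whole" (old + new) evaluation, the LR method estimates

* bias           ``mu_wp    = mean(u_p) - mean(u_w)``          (expected 0),
* dispersion     ``b_wp     = cov(u_p, u_w) / var(u_p)``       (expected 1),
* accuracy ratio ``rho_wp   = corr(u_p, u_w)``                 (expected acc_p/acc_w),
* reliability    ``rho2_cov = cov(u_p, u_w) / (vf * s2_inf)``  (expected acc_p^2),
* and the reverse slope ``b_pw`` (expected acc_p^2/acc_w^2),

where ``vf = 1 + F_bar - 2 f_bar`` is the variance factor of the cohort and
``s2_inf`` the equilibrium genetic variance.  Sample (co)variances use the
1/n convention (it cancels in every ratio); the variance of EBV change uses
1/(n-1).  Out-of-range accuracy estimates are *flagged, never clipped*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .kinship import RelationshipMatrix, variance_factor
from .mixed_model import EvaluationResult, VarianceComponents, accuracy_from_pev

__all__ = [
    "EbvPair",
    "LRStatistics",
    "LRExpectations",
    "mu_wp",
    "slope_w_on_p",
    "slope_p_on_w",
    "rho_w_p",
    "rho2_cov",
    "ebv_change",
    "predictivity",
    "acc_from_predictivity",
    "precorrection_inflation",
    "selected_to_unselected_acc",
    "young_bull_counterexample",
    "compute_lr_statistics",
    "lr_expectations",
]


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    """Sample covariance with 1/n normalization."""
    return float(np.mean((a - a.mean()) * (b - b.mean())))


@dataclass
class EbvPair:
    """Aligned partial- and whole-data EBV with optional subset labels."""

    ids: list[str]
    u_hat_p: np.ndarray
    u_hat_w: np.ndarray
    subset_labels: np.ndarray | None = None  # 'r' | 'v' per individual

    def __post_init__(self) -> None:
        self.u_hat_p = np.asarray(self.u_hat_p, dtype=float)
        self.u_hat_w = np.asarray(self.u_hat_w, dtype=float)
        if not (len(self.ids) == self.u_hat_p.size == self.u_hat_w.size):
            raise ValueError("ids and EBV vectors must have equal length")
        if np.isnan(self.u_hat_p).any() or np.isnan(self.u_hat_w).any():
            raise ValueError("missing EBV values")

    @classmethod
    def from_results(
        cls,
        partial: EvaluationResult,
        whole: EvaluationResult,
        focal: Sequence[str] | None = None,
        validation: Sequence[str] | None = None,
    ) -> "EbvPair":
        ids = list(focal) if focal is not None else list(whole.ids)
        labels = None
        if validation is not None:
            vset = set(validation)
            labels = np.asarray(["v" if i in vset else "r" for i in ids])
        return cls(
            ids,
            partial.u_hat.loc[ids].to_numpy(),
            whole.u_hat.loc[ids].to_numpy(),
            labels,
        )

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, tag: str) -> "EbvPair":
        """Restrict to the reference ('r') or validation ('v') individuals."""
        if tag == "all":
            return self
        if self.subset_labels is None:
            raise ValueError("no subset labels on this EBV pair")
        m = self.subset_labels == tag
        return EbvPair(
            [i for i, k in zip(self.ids, m) if k], self.u_hat_p[m], self.u_hat_w[m]
        )


def mu_wp(pair: EbvPair) -> float:
    """Bias statistic ``mean(u_hat_p) - mean(u_hat_w)`` (partial minus whole)."""
    return float(pair.u_hat_p.mean() - pair.u_hat_w.mean())


def slope_w_on_p(pair: EbvPair) -> float:
    """Dispersion statistic: regression of whole-data on partial-data EBV."""
    v = _cov(pair.u_hat_p, pair.u_hat_p)
    if v <= 0:
        raise ZeroDivisionError("var(u_hat_p) is zero")
    return _cov(pair.u_hat_p, pair.u_hat_w) / v


def slope_p_on_w(pair: EbvPair) -> float:
    """Regression of partial-data on whole-data EBV (expected acc_p^2/acc_w^2)."""
    v = _cov(pair.u_hat_w, pair.u_hat_w)
    if v <= 0:
        raise ZeroDivisionError("var(u_hat_w) is zero")
    return _cov(pair.u_hat_p, pair.u_hat_w) / v


def rho_w_p(pair: EbvPair) -> float:
    """Correlation of partial- and whole-data EBV (expected acc_p/acc_w)."""
    vp = _cov(pair.u_hat_p, pair.u_hat_p)
    vw = _cov(pair.u_hat_w, pair.u_hat_w)
    if vp <= 0 or vw <= 0:
        raise ZeroDivisionError("zero EBV variance")
    return _cov(pair.u_hat_p, pair.u_hat_w) / float(np.sqrt(vp * vw))


def rho2_cov(
    pair: EbvPair,
    K: RelationshipMatrix,
    focal: Sequence[str],
    sigma2_u_inf: float,
) -> float:
    """Direct estimator of squared population accuracy of the partial EBV.

    ``cov(u_p, u_w) / (vf * sigma2_u_inf)``.  Being a noisy estimator it may
    fall outside [0, 1]; such values are returned as-is with a warning.
    """
    if sigma2_u_inf <= 0:
        raise ValueError("sigma2_u_inf must be positive")
    vf = variance_factor(K, focal)
    if vf <= 0:
        raise ValueError("variance factor <= 0: squared accuracy undefined")
    val = _cov(pair.u_hat_p, pair.u_hat_w) / (vf * sigma2_u_inf)
    if not 0.0 <= val <= 1.0:
        warnings.warn(f"rho2_cov = {val:.4f} outside [0, 1] (noise)", stacklevel=2)
    return val


def ebv_change(pair: EbvPair) -> tuple[float, float]:
    """Mean absolute EBV change and its variance, ``(d_wp, Vd_wp)``.

    ``d = mean|u_w - u_p|`` and ``Vd = var(u_w - u_p)`` with 1/(n-1).
    """
    diff = pair.u_hat_w - pair.u_hat_p
    return float(np.abs(diff).mean()), float(diff.var(ddof=1)) if len(diff) > 1 else 0.0


def predictivity(y_star: np.ndarray, u_hat_p: np.ndarray) -> float:
    """Correlation of precorrected phenotypes with partial-data EBV."""
    y_star = np.asarray(y_star, dtype=float)
    u_hat_p = np.asarray(u_hat_p, dtype=float)
    if y_star.size != u_hat_p.size or y_star.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if y_star.std() == 0 or u_hat_p.std() == 0:
        raise ZeroDivisionError("zero variance in predictivity input")
    return float(np.corrcoef(y_star, u_hat_p)[0, 1])


def acc_from_predictivity(r: float, h_inf: float) -> float:
    """Population accuracy implied by a predictivity ``r``: ``r / h_inf``.

    ``h_inf`` is the square root of the heritability on the equilibrium
    scale (use base-scale h without selection).  Values above 1 are
    returned with a warning, not clipped.
    """
    if h_inf <= 0:
        raise ValueError("h_inf must be positive")
    acc = r / h_inf
    if acc > 1:
        warnings.warn(f"accuracy estimate {acc:.3f} > 1", stacklevel=2)
    return acc


def precorrection_inflation(n: int, m: int) -> float:
    """Proportional accuracy inflation from imperfect precorrection.

    For a balanced design with ``n`` records in ``m`` fixed-effect levels
    the apparent accuracy r/h overestimates acc by the factor
    ``1 + (m-1)/(n-(m-1))``; this returns ``(m-1)/(n-(m-1))``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m - 1:
        raise ValueError("need n > m - 1")
    return (m - 1) / (n - (m - 1))


def selected_to_unselected_acc(acc_sel: float, k: float) -> float:
    """Convert an equilibrium-scale accuracy to the unselected base scale.

    With the same prediction error variance, reliability changes with the
    reference genetic variance: ``rel_unsel = 1 - (1-k)(1-rel_sel)``, i.e.
    ``acc_unsel = sqrt(k + (1-k) acc_sel^2)`` for variance reduction
    ``k = 1 - sigma2_u_inf/sigma2_u``.
    """
    if not 0 <= k < 1:
        raise ValueError("k must be in [0, 1)")
    if not 0 <= acc_sel <= 1:
        raise ValueError("acc_sel must be in [0, 1]")
    return float(np.sqrt(k + (1.0 - k) * acc_sel**2))


def young_bull_counterexample(n: int, h2: float) -> tuple[float, float]:
    """Closed-form ``(cov(u_p, u_w), var(u_p))`` for the dropped-data case.

    A young bull is first evaluated from one record of its dam
    (``var(u_p) = h^4/4``) and later from ``n`` half-sib progeny records
    *without* the dam record, giving
    ``cov(u_p, u_w) = (h^4/8) * 2n/(n + lambda)`` with the progeny-testing
    ratio ``lambda = (4 - h^2)/h^2`` (phenotypic variance 1).  For finite n
    the covariance is below var(u_p): dropping data breaks the identity
    Cov(u_p, u_w) = Var(u_p).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    lam = (4.0 - h2) / h2
    var_p = h2**2 / 4.0
    cov_pw = (h2**2 / 8.0) * (2.0 * n / (n + lam)) if n > 0 else 0.0
    return cov_pw, var_p


@dataclass
class LRStatistics:
    """The LR statistics for one focal set (subset tag 'all' | 'r' | 'v')."""

    n: int
    subset: str
    mu_wp: float
    b_wp: float
    b_pw: float
    rho_wp: float
    d_wp: float
    Vd_wp: float
    rho2_cov: float | None = None
    predictivity_r: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class LRExpectations:
    """Theoretical expectations from PEV/PEC trace formulas."""

    acc_p: float
    acc_w: float
    expected_b_wp: float = 1.0

    @property
    def expected_rho_wp(self) -> float:
        return self.acc_p / self.acc_w

    @property
    def expected_b_pw(self) -> float:
        return self.acc_p**2 / self.acc_w**2

    @staticmethod
    def theta_ratio(theta_p: float, theta_w: float) -> float:
        """Expected b_wp under uniform over/under-dispersion scalars."""
        return theta_w / theta_p

    def as_dict(self) -> dict:
        return {
            "acc_p": self.acc_p,
            "acc_w": self.acc_w,
            "expected_b_wp": self.expected_b_wp,
            "expected_rho_wp": self.expected_rho_wp,
            "expected_b_pw": self.expected_b_pw,
            "expected_rho2_cov": self.acc_p**2,
        }


def compute_lr_statistics(
    pair: EbvPair,
    subset: str = "all",
    K: RelationshipMatrix | None = None,
    sigma2_u_inf: float | None = None,
    y_star: np.ndarray | None = None,
) -> LRStatistics:
    """All LR statistics on one subset of an EBV pair.

    ``rho2_cov`` needs `K` and `sigma2_u_inf`; ``predictivity_r`` needs the
    precorrected phenotypes of the subset individuals (same order).
    """
    sub = pair.subset(subset)
    if len(sub) < 2:
        raise ValueError("need at least 2 individuals for covariance-based statistics")
    d, vd = ebv_change(sub)
    r2c = None
    if K is not None and sigma2_u_inf is not None:
        r2c = rho2_cov(sub, K, sub.ids, sigma2_u_inf)
    pred = None
    if y_star is not None:
        pred = predictivity(y_star, sub.u_hat_p)
    return LRStatistics(
        n=len(sub),
        subset=subset,
        mu_wp=mu_wp(sub),
        b_wp=slope_w_on_p(sub),
        b_pw=slope_p_on_w(sub),
        rho_wp=rho_w_p(sub),
        d_wp=d,
        Vd_wp=vd,
        rho2_cov=r2c,
        predictivity_r=pred,
    )


def lr_expectations(
    partial: EvaluationResult,
    whole: EvaluationResult,
    K: RelationshipMatrix,
    focal: Sequence[str],
    vc: VarianceComponents,
) -> LRExpectations:
    """Expected LR statistics for a focal cohort from the two PEV/PEC blocks."""
    return LRExpectations(
        acc_p=accuracy_from_pev(partial, K, vc, focal),
        acc_w=accuracy_from_pev(whole, K, vc, focal),
    )
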