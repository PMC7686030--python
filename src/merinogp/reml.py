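"""REML variance-component estimation and BLUP for genomic mixed models.

Fits models of the form

    y = X b + sum_k u_k + e,   u_k ~ N(0, K_k sigma2_k),   e ~ N(0, I sigma2_e)

where each ``K_k`` is a genomic relationship matrix (additive G, dominance D)
and there is one record per individual.  The additive-only model is called
``MAG`` and the additive-plus-dominance model ``MADG``.

Estimation maximises the restricted log-likelihood with average-information
(AI) updates, falling back to EM-REML steps whenever an AI step would leave
the parameter space or fail to improve the objective.  Components driven to
zero are pinned at the boundary and reported as 0 with a standard error taken
from the (unconstrained) AI matrix evaluated at the final parameters.  BLUPs
are the conditional means ``u_k = sigma2_k K_k P y``, which solve Henderson's
mixed-model equations at the final variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .relationship import KinshipMatrix

__all__ = [
    "ModelSpec",
    "FixedDesign",
    "REMLFit",
    "VarianceRatios",
    "build_fixed_design",
    "restricted_loglik",
    "fit_reml",
    "variance_ratios",
    "ratios_from_components",
    "mme_system",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ModelSpec:
    """Which genetic random terms a fit includes.

    ``MAG``: additive term only; ``MADG``: additive plus dominance.
    """

    model: str = "MAG"
    trait: str | None = None
    fixed_factors: tuple[str, ...] = ("sex", "herd")

    def __post_init__(self) -> None:
        if self.model not in ("MAG", "MADG"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def random_terms(self) -> tuple[str, ...]:
        return ("additive",) if self.model == "MAG" else ("additive", "dominance")


@dataclass
class FixedDesign:
    """Full-rank fixed-effect design (intercept + treatment-coded factors)."""

    X: np.ndarray
    columns: list[str]
    reference_levels: dict[str, str]


@dataclass
class REMLFit:
    components: dict[str, float]
    component_se: dict[str, float]
    beta: np.ndarray
    blups: dict[str, np.ndarray]
    loglik: float
    iterations: int
    converged: bool
    ai_covariance: np.ndarray
    component_names: list[str]
    pinned: list[str]
    trace: list[dict] = field(default_factory=list, repr=False)

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()))


@dataclass
class VarianceRatios:
    h2: float
    h2_se: float
    d2: float | None = None
    d2_se: float | None = None


# ---------------------------------------------------------------------------
# fixed-effect design


def build_fixed_design(
    samples: pd.DataFrame, factors: Sequence[str] = ("sex", "herd")
) -> FixedDesign:
    """Intercept plus treatment-coded factor columns.

    The reference level of each factor is the lexicographically first observed
    level, so the design is deterministic for a given data set.  A factor with
    a single observed level contributes no columns (warned).  Missing factor
    values are a validation error.
    """
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    refs: dict[str, str] = {}
    for factor in factors:
        vals = samples[factor]
        if vals.isna().any():
            raise ValueError(f"missing values in fixed-effect factor {factor!r}")
        levels = sorted(map(str, vals.unique()))
        refs[factor] = levels[0]
        if len(levels) == 1:
            warnings.warn(
                f"factor {factor!r} has a single level; no columns added",
                stacklevel=2,
            )
            continue
        as_str = vals.astype(str).to_numpy()
        for level in levels[1:]:
            cols.append((as_str == level).astype(float))
            names.append(f"{factor}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return FixedDesign(X, names, refs)


# ---------------------------------------------------------------------------
# restricted likelihood machinery


def _as_matrix(k) -> np.ndarray:
    return k.values if isinstance(k, KinshipMatrix) else np.asarray(k, dtype=float)


def _kinship_list(kinships: Mapping[str, object]):
    names = list(kinships)
    mats = [_as_matrix(kinships[name]) for name in names]
    return names, mats


@dataclass
class _Quantities:
    loglik: float
    P: np.ndarray
    Py: np.ndarray
    Vinv: np.ndarray
    beta: np.ndarray
    XtViX_inv: np.ndarray


def _reml_quantities(theta: np.ndarray, y: np.ndarray, X: np.ndarray, mats) -> _Quantities:
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], mats):
        if t != 0.0:
            V += t * K
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"V is not positive definite at theta={theta.tolist()}"
        ) from exc
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X is singular")
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vinv - ViX @ XtViX_inv @ ViX.T
    Py = P @ y
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + yPy + (n - p) * LOG2PI)
    beta = XtViX_inv @ (ViX.T @ y)
    return _Quantities(ll, P, Py, Vinv, beta, XtViX_inv)


def restricted_loglik(
    theta: Sequence[float],
    y: np.ndarray,
    X: np.ndarray,
    kinships: Mapping[str, object],
) -> float:
    """Restricted log-likelihood at variance components ``theta``.

    ``theta`` orders the genetic components as in ``kinships`` with the
    residual variance last.  Includes the ``-(n-p)/2 log 2 pi`` constant.
    """
    _, mats = _kinship_list(kinships)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(mats) + 1,):
        raise ValueError("theta must hold one genetic component per kinship "
                         "plus the residual variance")
    return _reml_quantities(theta, np.asarray(y, float), np.asarray(X, float), mats).loglik


def _scores_and_ai(theta, y, q: _Quantities, mats, n):
    """REML score vector and average-information matrix over all components
    (genetic terms in order, residual last)."""
    k = len(mats)
    PKy = [K @ q.Py for K in mats] + [q.Py.copy()]  # residual K = I
    trPK = [float(np.sum(q.P * K)) for K in mats] + [float(np.trace(q.P))]
    yPKPy = [float(q.Py @ v) for v in PKy]
    score = np.array([-0.5 * (trPK[i] - yPKPy[i]) for i in range(k + 1)])
    Pw = [q.P @ v for v in PKy]
    ai = np.empty((k + 1, k + 1))
    for i in range(k + 1):
        for j in range(i, k + 1):
            ai[i, j] = ai[j, i] = 0.5 * float(PKy[i] @ Pw[j])
    return score, ai, trPK, yPKPy


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    kinships: Mapping[str, object],
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_theta: float = 1e-6,
    start: Sequence[float] | None = None,
    method: str = "ai",
) -> REMLFit:
    """AI-REML fit with EM fallback and boundary pinning.

    Parameters
    ----------
    y, X
        Response vector and full-rank fixed-effect design (same records).
    kinships
        Ordered mapping ``{"additive": G, "dominance": D, ...}`` of
        :class:`~merinogp.relationship.KinshipMatrix` or plain arrays, all
        stabilised (positive definite when scaled into V).
    method
        ``"ai"`` (default) or ``"em"`` for pure EM-REML iterations (used for
        cross-checking the optimiser).

    Starting values split half the ordinary-least-squares residual variance
    equally across the genetic terms, the other half to the residual.
    Convergence requires both a restricted log-likelihood change below
    ``tol_loglik`` and a maximum relative component change below
    ``tol_theta``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be a vector aligned with the rows of X")
    names, mats = _kinship_list(kinships)
    n, p = X.shape
    k = len(mats)
    if n < p + k + 1:
        raise ValueError("too few records for the number of parameters")

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    vary = float(resid @ resid) / max(n - p, 1)
    if start is not None:
        theta = np.asarray(start, dtype=float).copy()
    else:
        theta = np.array([0.5 * vary / k] * k + [0.5 * vary])
    pin_floor = 1e-6 * vary  # boundary-pinning threshold, scale free
    tiny = 1e-10 * vary
    active = np.ones(k + 1, dtype=bool)  # residual stays active throughout

    q = _reml_quantities(theta, y, X, mats)
    trace: list[dict] = []
    converged = False
    iteration = 0

    def _try(cand):
        try:
            return _reml_quantities(cand, y, X, mats)
        except np.linalg.LinAlgError:
            return None

    def _em_theta(free, trPK, yPKPy):
        cand = theta.copy()
        for i in free:
            cand[i] = theta[i] + theta[i] ** 2 * (yPKPy[i] - trPK[i]) / n
        cand[free] = np.maximum(cand[free], tiny)
        return cand

    def _ai_theta(free, score, ai):
        """Newton step from the AI matrix; components pushed negative are sent
        to the boundary region and the step re-solved for the rest."""
        free = list(free)
        at_tiny: list[int] = []
        while True:
            if not free:
                if not at_tiny:
                    return None
                cand = theta.copy()
                cand[at_tiny] = tiny
                return cand
            try:
                delta = np.linalg.solve(ai[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                return None
            cand = theta.copy()
            cand[at_tiny] = tiny
            cand[free] = theta[free] + delta
            neg = [i for i in free if cand[i] <= 0.0]
            if not neg:
                return cand
            at_tiny.extend(neg)
            free = [i for i in free if i not in neg]

    for iteration in range(1, max_iter + 1):
        score, ai, trPK, yPKPy = _scores_and_ai(theta, y, q, mats, n)
        free = np.flatnonzero(active)
        used = "em"
        new_theta = None
        q_new = None
        if method == "ai":
            cand = _ai_theta(free, score, ai)
            if cand is not None:
                q_cand = _try(cand)
                # halve toward the current point while the step loses likelihood
                for _ in range(8):
                    if q_cand is not None and q_cand.loglik >= q.loglik - 1e-10:
                        break
                    cand = theta + 0.5 * (cand - theta)
                    q_cand = _try(cand)
                if q_cand is not None and q_cand.loglik >= q.loglik - 1e-10:
                    new_theta, q_new, used = cand, q_cand, "ai"
        if new_theta is None:
            new_theta = _em_theta(free, trPK, yPKPy)
            q_new = _try(new_theta)
            if q_new is None:
                raise np.linalg.LinAlgError(
                    "REML update produced a non-positive-definite covariance"
                )

        # pin genetic components collapsing to the boundary; the score at the
        # current point must also favour the boundary
        pinned_now = False
        for i in range(k):
            if active[i] and new_theta[i] < pin_floor and score[i] < 0.0:
                new_theta[i] = 0.0
                active[i] = False
                pinned_now = True
        if pinned_now:
            q_pinned = _try(new_theta)
            if q_pinned is not None:
                q_new = q_pinned

        dll = q_new.loglik - q.loglik
        denom = np.maximum(np.abs(theta), pin_floor)
        dtheta = float(np.max(np.abs(new_theta - theta) / denom))
        trace.append(
            {"iter": iteration, "loglik": q_new.loglik, "step": used,
             "theta": new_theta.tolist()}
        )
        theta, q = new_theta, q_new
        if abs(dll) < tol_loglik and dtheta < tol_theta:
            converged = True
            break

    # final quantities, SEs from the unconstrained AI matrix at theta_hat
    q = _reml_quantities(theta, y, X, mats)
    score, ai, _, _ = _scores_and_ai(theta, y, q, mats, n)
    try:
        ai_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(ai)
    se = np.sqrt(np.clip(np.diag(ai_cov), 0.0, None))

    blups = {
        name: theta[i] * (mats[i] @ q.Py) for i, name in enumerate(names)
    }
    all_names = names + ["residual"]
    fit = REMLFit(
        components={name: float(theta[i]) for i, name in enumerate(all_names)},
        component_se={name: float(se[i]) for i, name in enumerate(all_names)},
        beta=q.beta,
        blups=blups,
        loglik=q.loglik,
        iterations=iteration,
        converged=converged,
        ai_covariance=ai_cov,
        component_names=all_names,
        pinned=[names[i] for i in range(k) if not active[i]],
        trace=trace,
    )
    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations", stacklevel=2
        )
    return fit


# ---------------------------------------------------------------------------
# derived quantities


def ratios_from_components(
    sigma2_a: float, sigma2_e: float, sigma2_d: float | None = None
) -> dict[str, float]:
    """Variance ratios from raw components.

    With only additive and residual components, ``h2 = sa / (sa + se)``; with
    a dominance component the total is ``sa + sd + se`` and the dominance
    proportion ``d2 = sd / total`` is returned alongside ``h2``.
    """
    total = sigma2_a + sigma2_e + (sigma2_d or 0.0)
    if total <= 0:
        raise ValueError("total variance must be positive")
    out = {"h2": sigma2_a / total}
    if sigma2_d is not None:
        out["d2"] = sigma2_d / total
    return out


def variance_ratios(fit: REMLFit) -> VarianceRatios:
    """Heritability (and dominance proportion for MADG fits) with
    delta-method standard errors from the AI covariance."""
    names = fit.component_names
    theta = np.array([fit.components[n] for n in names])
    total = theta.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    cov = fit.ai_covariance

    def _ratio(idx: int):
        grad = -theta[idx] / total**2 * np.ones(len(names))
        grad[idx] += 1.0 / total
        var = float(grad @ cov @ grad)
        return float(theta[idx] / total), float(np.sqrt(max(var, 0.0)))

    genetic = [n for n in names if n != "residual"]
    additive_name = "additive" if "additive" in names else genetic[0]
    h2, h2_se = _ratio(names.index(additive_name))
    if "dominance" in names:
        d2, d2_se = _ratio(names.index("dominance"))
        return VarianceRatios(h2, h2_se, d2, d2_se)
    return VarianceRatios(h2, h2_se)


def component_confidence_intervals(fit: REMLFit, level: float = 0.95) -> dict:
    """Confidence intervals for the variance components.

    Variance components are non-negative with right-skewed likelihoods, so a
    symmetric Wald interval both undercovers large true values (upper bound
    too low) and can exclude an attainable boundary.  The interval used here
    is asymmetric: lower bound ``max(0, theta - z se)`` (Wald, truncated at
    the parameter boundary) and upper bound ``theta * exp(z se / theta)``
    (log-scale Wald, the usual recommendation for positive variance
    parameters).  A component pinned at the boundary gets ``[0, z se]``.
    """
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + level / 2.0))
    out = {}
    for name in fit.component_names:
        est, se = fit.components[name], fit.component_se[name]
        if est <= 0.0:
            out[name] = (0.0, z * se)
        else:
            out[name] = (max(0.0, est - z * se), est * np.exp(z * se / est))
    return out


def mme_system(
    y: np.ndarray,
    X: np.ndarray,
    kinships: Mapping[str, object],
    theta: Sequence[float],
):
    """Henderson mixed-model equations coefficient matrix and right-hand side.

    Unknowns are stacked as ``[beta, u_1, ..., u_K]``.  Kinship matrices must
    be invertible (stabilised) and all genetic components strictly positive.
    Used to verify that REML BLUP solutions satisfy the MME.
    """
    _, mats = _kinship_list(kinships)
    theta = np.asarray(theta, dtype=float)
    se2 = theta[-1]
    n, p = X.shape
    k = len(mats)
    size = p + k * n
    A = np.zeros((size, size))
    rhs = np.zeros(size)
    A[:p, :p] = X.T @ X / se2
    rhs[:p] = X.T @ y / se2
    for i, K in enumerate(mats):
        r0 = p + i * n
        A[:p, r0:r0 + n] = X.T / se2
        A[r0:r0 + n, :p] = X / se2
        rhs[r0:r0 + n] = y / se2
        for j in range(k):
            c0 = p + j * n
            A[r0:r0 + n, c0:c0 + n] = np.eye(n) / se2
        A[r0:r0 + n, r0:r0 + n] += np.linalg.inv(K) / theta[i]
    return A, rhs
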