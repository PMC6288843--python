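"""Maximum-likelihood mean/variance models underlying all single-locus QTL tests.

Four model families are fitted here, all assuming ``y_i ~ N(m_i, sigma_i^2)``
with a linear predictor ``m_i = x_i' beta`` for the mean and differing
structure for the residual variance:

* **normal linear model** (SLM): a single shared variance ``sigma^2``;
* **double generalized linear model** (DGLM): log-linear variance
  ``sigma_i^2 = exp(z_i' gamma)``, fitted by alternating weighted least
  squares for the mean with a gamma-family log-link regression of squared
  residuals for the variance (full maximum likelihood);
* **grouped-variance model** (Cao): one free variance ``phi_g`` per
  genotype group, fitted by iterating generalized least squares with
  within-group moment updates to the joint ML solution;
* **Levene's deviation statistic**: an ANOVA on absolute deviations from
  group means, the classical test for variance heterogeneity.

Every fit uses the same likelihood definition (ML throughout, squared
residuals used raw with no leverage correction) so that likelihood-ratio
statistics across nested models are coherent.
"""

from __future__ import annotations

import logging
from dataclasses import InitVar, dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg as slinalg
from scipy import stats

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: relative floor applied to squared residuals in the variance sub-model,
#: as a fraction of Var(y); keeps gamma-regression working values finite.
RESIDUAL_SQ_FLOOR = 1e-12

#: default convergence tolerance on the change in log-likelihood.
DEFAULT_TOL = 1e-8

#: default iteration cap for the iterative fits.
DEFAULT_MAX_ITER = 50


class DesignError(ValueError):
    """A design matrix is malformed (rank-deficient, misaligned, ...)."""


class InsufficientDataError(ValueError):
    """Too few observations for the number of parameters."""


class DegenerateDataError(ValueError):
    """The phenotype carries no information (e.g. zero variance)."""


class SmallGroupError(ValueError):
    """A genotype group has fewer than two members."""


class NonConvergenceError(RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, fit: "ModelFit"):
        super().__init__(message)
        self.fit = fit


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Mean and log-variance design matrices for one model fit.

    Both matrices must include their own intercept column and share the
    phenotype's row count.  Rank deficiency is an error (checked unless
    ``check=False`` for trusted internal callers).
    """

    mean_columns: np.ndarray
    variance_columns: np.ndarray
    check: InitVar[bool] = True

    def __post_init__(self, check: bool):
        self.mean_columns = np.atleast_2d(np.asarray(self.mean_columns, dtype=float))
        self.variance_columns = np.atleast_2d(
            np.asarray(self.variance_columns, dtype=float)
        )
        if self.mean_columns.shape[0] != self.variance_columns.shape[0]:
            raise DesignError(
                "mean and variance designs have different row counts: "
                f"{self.mean_columns.shape[0]} vs {self.variance_columns.shape[0]}"
            )
        if check:
            for label, mat in (
                ("mean", self.mean_columns),
                ("variance", self.variance_columns),
            ):
                if np.linalg.matrix_rank(mat) < mat.shape[1]:
                    raise DesignError(f"{label} design is rank-deficient")

    @property
    def n(self) -> int:
        return self.mean_columns.shape[0]

    @classmethod
    def build(
        cls,
        n: int,
        mean_covariates: Optional[np.ndarray] = None,
        variance_covariates: Optional[np.ndarray] = None,
        check: bool = True,
    ) -> "DesignSpec":
        """Assemble designs from covariate columns, prepending intercepts."""
        X = _with_intercept(n, mean_covariates)
        Z = _with_intercept(n, variance_covariates)
        return cls(X, Z, check=check)


def _with_intercept(n: int, cols: Optional[np.ndarray]) -> np.ndarray:
    ones = np.ones((n, 1))
    if cols is None:
        return ones
    cols = np.asarray(cols, dtype=float)
    if cols.ndim == 1:
        cols = cols[:, None]
    if cols.shape[1] == 0:
        return ones
    return np.hstack([ones, cols])


@dataclass
class ModelFit:
    """A fitted mean/variance model.

    ``variance_coefficients`` are on the log scale for the DGLM
    (``sigma_i^2 = exp(z_i' gamma)``), per-group variances ``phi_g`` for the
    grouped-variance model, and the scalar ML variance for the SLM.
    """

    mean_coefficients: np.ndarray
    variance_coefficients: np.ndarray
    fitted_means: np.ndarray
    fitted_variances: np.ndarray
    residuals: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    group_levels: Optional[np.ndarray] = None
    mean_design: Optional[np.ndarray] = None
    mean_blocks: Optional[dict] = None

    @property
    def n(self) -> int:
        return self.residuals.shape[0]


@dataclass
class LeveneComputation:
    """All intermediate quantities of Levene's W on absolute deviations."""

    abs_deviations: np.ndarray
    group_deviation_means: np.ndarray
    overall_deviation_mean: float
    group_means: np.ndarray
    group_sizes: np.ndarray
    group_levels: np.ndarray
    W: float
    df_num: int
    df_den: int
    p_value: float


# ---------------------------------------------------------------------------
# numerical core
# ---------------------------------------------------------------------------


def _solve_ls(X: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None) -> np.ndarray:
    """(Weighted) least-squares solve, robust to collinear columns.

    Falls back to a minimum-norm solution when the normal equations are
    singular, so that e.g. a constant locus column degrades to the nested
    model rather than erroring (the LR statistic is then ~0).
    """
    Xw = X if w is None else X * w[:, None]
    XtX = Xw.T @ X
    Xty = Xw.T @ y
    try:
        c, low = slinalg.cho_factor(XtX, check_finite=False)
        return slinalg.cho_solve((c, low), Xty, check_finite=False)
    except (np.linalg.LinAlgError, slinalg.LinAlgError, ValueError):
        if w is None:
            return np.linalg.lstsq(X, y, rcond=None)[0]
        sw = np.sqrt(w)
        return np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]


def normal_loglik(residuals: np.ndarray, variances: np.ndarray) -> float:
    """Sum of normal log-densities at (0, variances) evaluated at residuals."""
    variances = np.asarray(variances, dtype=float)
    r2 = residuals * residuals
    if variances.ndim == 0:
        n = residuals.shape[0]
        return -0.5 * (n * (_LOG2PI + np.log(variances)) + r2.sum() / variances)
    return -0.5 * (
        residuals.shape[0] * _LOG2PI + np.log(variances).sum() + (r2 / variances).sum()
    )


def _as_vector(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        y = y.ravel()
    return y


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


def fit_normal_linear(y, design: DesignSpec) -> ModelFit:
    """Homoskedastic normal linear model by OLS with the ML variance RSS/n.

    The variance design must be intercept-only; the log-likelihood is exact
    at the ML estimates, so LR statistics against the heteroskedastic
    families are directly comparable.
    """
    y = _as_vector(y)
    X = design.mean_columns
    n, p = X.shape
    if y.shape[0] != n:
        raise DesignError("phenotype length does not match design rows")
    if design.variance_columns.shape[1] != 1:
        raise DesignError("normal linear model requires an intercept-only variance design")
    if n < p + 1:
        raise InsufficientDataError(f"n={n} too small for {p} mean parameters")
    beta = _solve_ls(X, y)
    fitted = X @ beta
    resid = y - fitted
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0.0:
        raise DegenerateDataError("phenotype has zero residual variance")
    ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)
    return ModelFit(
        mean_coefficients=beta,
        variance_coefficients=np.array([sigma2]),
        fitted_means=fitted,
        fitted_variances=np.full(n, sigma2),
        residuals=resid,
        weights=np.full(n, 1.0 / sigma2),
        log_likelihood=float(ll),
        converged=True,
        n_iterations=1,
        mean_design=X,
    )


def fit_dglm(
    y,
    design: DesignSpec,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    on_nonconvergence: str = "return",
) -> ModelFit:
    """Joint ML fit of the double generalized linear model.

    Alternates (i) weighted least squares for the mean with weights
    ``1/sigma_i^2`` and (ii) one Fisher-scoring step of a gamma-family
    log-link regression of squared residuals on the variance design
    (dispersion fixed at 2), until the log-likelihood changes by less than
    ``tol``.  With an intercept-only variance design the solution coincides
    with :func:`fit_normal_linear`.

    ``on_nonconvergence``: ``"return"`` flags ``converged=False`` on the
    returned fit; ``"raise"`` raises :class:`NonConvergenceError` carrying it.
    """
    y = _as_vector(y)
    X = design.mean_columns
    Z = design.variance_columns
    n = X.shape[0]
    if y.shape[0] != n:
        raise DesignError("phenotype length does not match design rows")
    if n <= X.shape[1] + Z.shape[1]:
        raise InsufficientDataError(
            f"n={n} does not exceed the {X.shape[1] + Z.shape[1]} parameters"
        )
    vary = float(np.var(y))
    if vary <= 0.0:
        raise DegenerateDataError("phenotype is constant")
    floor = RESIDUAL_SQ_FLOOR * vary

    # initialization: homoskedastic OLS fit, variance predictor flat at log(RSS/n)
    beta = _solve_ls(X, y)
    resid = y - X @ beta
    s2 = max(float(resid @ resid) / n, floor)
    gamma = _solve_ls(Z, np.full(n, np.log(s2)))
    eta = Z @ gamma
    ll = normal_loglik(resid, np.exp(eta))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.exp(-eta)
        beta = _solve_ls(X, y, w)
        resid = y - X @ beta
        d = np.maximum(resid * resid, floor)
        # gamma-family Fisher scoring step (log link, unit IRLS weights)
        mu = np.exp(eta)
        gamma_new = _solve_ls(Z, eta + d / mu - 1.0)
        eta_new = Z @ gamma_new
        ll_new = normal_loglik(resid, np.exp(eta_new))
        # step-halve the variance update if it overshoots
        halvings = 0
        while ll_new < ll - 1e-10 and halvings < 10:
            gamma_new = 0.5 * (gamma_new + gamma)
            eta_new = Z @ gamma_new
            ll_new = normal_loglik(resid, np.exp(eta_new))
            halvings += 1
        gamma, eta = gamma_new, eta_new
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    fitted_var = np.exp(eta)
    fit = ModelFit(
        mean_coefficients=beta,
        variance_coefficients=gamma,
        fitted_means=X @ beta,
        fitted_variances=fitted_var,
        residuals=resid,
        weights=1.0 / fitted_var,
        log_likelihood=float(ll),
        converged=converged,
        n_iterations=it,
        mean_design=X,
    )
    if not converged:
        logger.warning("DGLM fit did not converge after %d iterations", max_iter)
        if on_nonconvergence == "raise":
            raise NonConvergenceError(
                f"DGLM fit did not converge after {max_iter} iterations", fit
            )
    return fit


def fit_group_variance_model(
    y,
    mean_design: DesignSpec,
    groups,
    levels: Optional[np.ndarray] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = 100,
) -> ModelFit:
    """Joint ML fit of the grouped-variance (Cao) model.

    Iterates generalized least squares for the mean with weights
    ``1/phi_g[i]`` and the moment update ``phi_g = mean of squared residuals
    within group g`` to convergence of the joint likelihood.  The two-step
    profile fit is the first iteration and is typically already very close.
    """
    y = _as_vector(y)
    X = mean_design.mean_columns
    n = X.shape[0]
    if y.shape[0] != n:
        raise DesignError("phenotype length does not match design rows")
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise DesignError("group labels do not match phenotype length")
    if levels is not None:
        levels = np.asarray(levels)
        present = np.unique(groups)
        empty = [lv for lv in levels if lv not in present]
        if empty:
            logger.warning("dropping %d empty group level(s): %s", len(empty), empty)
    uniq, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise SmallGroupError(
            f"group {uniq[int(np.argmin(sizes))]!r} has fewer than 2 members"
        )
    G = uniq.shape[0]
    vary = float(np.var(y))
    if vary <= 0.0:
        raise DegenerateDataError("phenotype is constant")
    floor = RESIDUAL_SQ_FLOOR * vary

    beta = _solve_ls(X, y)
    resid = y - X @ beta
    phi = np.maximum(np.bincount(codes, weights=resid * resid) / sizes, floor)
    ll = normal_loglik(resid, phi[codes])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / phi[codes]
        beta = _solve_ls(X, y, w)
        resid = y - X @ beta
        phi = np.maximum(np.bincount(codes, weights=resid * resid) / sizes, floor)
        ll_new = normal_loglik(resid, phi[codes])
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("grouped-variance fit did not converge after %d iterations", max_iter)

    fitted_var = phi[codes]
    return ModelFit(
        mean_coefficients=beta,
        variance_coefficients=phi,
        fitted_means=X @ beta,
        fitted_variances=fitted_var,
        residuals=resid,
        weights=1.0 / fitted_var,
        log_likelihood=float(ll),
        converged=converged,
        n_iterations=it,
        group_levels=uniq,
        mean_design=X,
    )


def levene_W(y, groups) -> LeveneComputation:
    """Levene's test on absolute deviations from group means.

    ``W`` is the one-way ANOVA F statistic applied to ``z_i = |y_i - ybar_g|``
    and is referred to ``F(G-1, n-G)`` under the null of equal variances.
    Mean-based deviations are used (not the median-based Brown-Forsythe
    variant).
    """
    y = _as_vector(y)
    groups = np.asarray(groups)
    if groups.shape[0] != y.shape[0]:
        raise DesignError("group labels do not match phenotype length")
    uniq, codes = np.unique(groups, return_inverse=True)
    G = uniq.shape[0]
    n = y.shape[0]
    if G < 2:
        raise SmallGroupError("Levene's test needs at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise SmallGroupError(
            f"group {uniq[int(np.argmin(sizes))]!r} has fewer than 2 members"
        )
    group_means = np.bincount(codes, weights=y) / sizes
    z = np.abs(y - group_means[codes])
    zbar_g = np.bincount(codes, weights=z) / sizes
    zbar = float(z.mean())
    num = float((sizes * (zbar_g - zbar) ** 2).sum()) / (G - 1)
    den = float(((z - zbar_g[codes]) ** 2).sum()) / (n - G)
    if den <= 0.0:
        # identical deviation profiles in every group; the statistic vanishes
        W = 0.0 if num <= 0.0 else np.inf
    else:
        W = num / den
    p = float(stats.f.sf(W, G - 1, n - G))
    return LeveneComputation(
        abs_deviations=z,
        group_deviation_means=zbar_g,
        overall_deviation_mean=zbar,
        group_means=group_means,
        group_sizes=sizes,
        group_levels=uniq,
        W=float(W),
        df_num=G - 1,
        df_den=n - G,
        p_value=p,
    )
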