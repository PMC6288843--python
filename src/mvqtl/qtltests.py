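"""The eight single-locus tests for mean (mQTL), variance (vQTL) and joint
(mvQTL) effects.

Each test is a likelihood-ratio comparison of two nested fits from
:mod:`mvqtl.mvmodels` (Levene's test rides along in the same envelope with
its F reference):

========  ===========================================  =====================
test      alternative model                            null model
========  ===========================================  =====================
slm       SLM with locus mean columns                  SLM without locus
cao_m     grouped-variance full                        grouped-variance, no locus mean term
cao_v     grouped-variance full                        SLM full (shared variance)
cao_mv    grouped-variance full                        SLM null
dglm_m    DGLM full                                    DGLM without locus mean term (locus kept in variance)
dglm_v    DGLM full                                    DGLM without locus variance term (locus kept in mean)
dglm_mv   DGLM full                                    DGLM without locus anywhere
levene    deviation ANOVA on hard genotype groups
========  ===========================================  =====================

The locus enters as additive + dominance columns for an F2 intercross
(2 df for mean or variance alone, 4 df jointly) and a single additive
column for a backcross.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

import numpy as np
from scipy import stats

from . import mvmodels
from .mvmodels import (
    DesignError,
    DesignSpec,
    ModelFit,
    fit_dglm,
    fit_group_variance_model,
    fit_normal_linear,
    levene_W,
)

MEAN_TESTS = ("slm", "cao_m", "dglm_m")
VARIANCE_TESTS = ("levene", "cao_v", "dglm_v")
JOINT_TESTS = ("cao_mv", "dglm_mv")
ALL_TESTS = MEAN_TESTS + VARIANCE_TESTS + JOINT_TESTS

#: tests that model the locus inside a DGLM and therefore accept variance covariates
DGLM_TESTS = ("dglm_m", "dglm_v", "dglm_mv")
#: tests that need hard (categorical) genotype calls
GROUP_TESTS = ("levene", "cao_m", "cao_v", "cao_mv")

CROSS_TYPES = ("f2", "backcross")

#: LR statistics more negative than this indicate a broken nesting, not
#: convergence slack, and raise instead of being clamped.
_NEGATIVE_T_LIMIT = -1e-3


class InternalConsistencyError(RuntimeError):
    """A likelihood-ratio statistic was substantially negative."""


def canonical_test_name(name: str) -> str:
    key = str(name).strip().lower().replace("'", "").replace("-", "_").replace(" ", "_")
    aliases = {
        "levenes_test": "levene", "lv": "levene", "caom": "cao_m",
        "caov": "cao_v", "caomv": "cao_mv", "dglmm": "dglm_m",
        "dglmv": "dglm_v", "dglmmv": "dglm_mv",
    }
    key = aliases.get(key, key)
    if key not in ALL_TESTS:
        raise ValueError(f"unknown test {name!r}; choose from {ALL_TESTS}")
    return key


def locus_df(test_name: str, cross_type: str) -> int:
    """Degrees of freedom of the locus contrast for a test and cross type."""
    name = canonical_test_name(test_name)
    cross_type = str(cross_type).lower()
    if cross_type not in CROSS_TYPES:
        raise ValueError(f"unknown cross type {cross_type!r}")
    per_block = 2 if cross_type == "f2" else 1
    return 2 * per_block if name in JOINT_TESTS else per_block


@dataclass
class TestSpec:
    """One test at one locus.

    ``locus`` is any object exposing per-individual additive dosage ``a``,
    dominance ``d`` (F2 only) and optional categorical ``hard_calls``
    (see :class:`mvqtl.scan.LocusEncoding`).  Covariate matrices exclude the
    intercept, which is added internally; ``variance_covariates`` are only
    legal for the DGLM-based tests.
    """

    test_name: str
    phenotype: np.ndarray
    locus: Any
    mean_covariates: Optional[np.ndarray] = None
    variance_covariates: Optional[np.ndarray] = None
    cross_type: str = "f2"

    __test__ = False  # not a pytest class despite the name


@dataclass
class TestResult:
    """Outcome of one test: LR statistic (or Levene's W), df, asymptotic p."""

    test_name: str
    T: float
    df: int
    p_asymptotic: float
    alt_fit: Optional[ModelFit] = None
    null_fit: Optional[ModelFit] = None
    converged: bool = True
    df_denominator: Optional[int] = None  # Levene's F denominator df


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


class _Components:
    """Preassembled design matrices for one (phenotype, locus, covariates).

    Shared by :func:`run_test` and the permutation procedures so that the
    null fit can be reused across permutation replicates.
    """

    __slots__ = (
        "name", "cross_type", "y", "n", "X0", "Z0", "L", "groups",
        "k_locus", "n_covariates",
    )

    def __init__(self, spec: TestSpec, validate: bool = True):
        self.name = canonical_test_name(spec.test_name)
        self.cross_type = str(spec.cross_type).lower()
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"unknown cross type {spec.cross_type!r}")
        self.y = np.asarray(spec.phenotype, dtype=float).ravel()
        self.n = self.y.shape[0]
        if spec.variance_covariates is not None and self.name not in DGLM_TESTS:
            vc = np.asarray(spec.variance_covariates)
            if vc.size:
                raise DesignError(
                    f"test {self.name!r} does not accept variance covariates"
                )
        self.X0 = mvmodels._with_intercept(self.n, spec.mean_covariates)
        self.Z0 = mvmodels._with_intercept(
            self.n, spec.variance_covariates if self.name in DGLM_TESTS else None
        )
        if self.X0.shape[0] != self.n or self.Z0.shape[0] != self.n:
            raise DesignError("covariates are not row-aligned with the phenotype")
        self.L = locus_mean_columns(spec.locus, self.cross_type)
        if self.L.shape[0] != self.n:
            raise DesignError("locus encoding is not row-aligned with the phenotype")
        self.k_locus = self.L.shape[1]
        self.n_covariates = self.X0.shape[1] - 1
        if self.name in GROUP_TESTS:
            hc = getattr(spec.locus, "hard_calls", None)
            if hc is None:
                hc = np.asarray(spec.locus)  # raw group labels
                if hc.dtype.kind == "f" or hc.ndim != 1:
                    raise DesignError(
                        f"test {self.name!r} requires hard genotype groups"
                    )
            self.groups = np.asarray(hc)
            if self.groups.shape[0] != self.n:
                raise DesignError("group labels are not row-aligned with the phenotype")
        else:
            self.groups = None
        if validate:
            for label, mat in (("mean covariate", self.X0), ("variance covariate", self.Z0)):
                if np.linalg.matrix_rank(mat) < mat.shape[1]:
                    raise DesignError(f"{label} design is rank-deficient")

    def X1(self, L: Optional[np.ndarray] = None) -> np.ndarray:
        return np.hstack([self.X0, self.L if L is None else L])

    def Z1(self, L: Optional[np.ndarray] = None) -> np.ndarray:
        return np.hstack([self.Z0, self.L if L is None else L])


def locus_mean_columns(locus: Any, cross_type: str) -> np.ndarray:
    """Design columns contributed by the locus: [additive, dominance] for an
    F2, [additive] for a backcross.  Accepts any encoding object with ``a``
    (and ``d``) attributes, or a bare genotype vector ``q`` in {-1,0,1}
    (F2, dominance = indicator of the heterozygote) / {0,1} (backcross)."""
    a = getattr(locus, "a", None)
    if a is None:
        q = np.asarray(locus, dtype=float).ravel()
        if cross_type == "f2":
            return np.column_stack([q, (q == 0.0).astype(float)])
        return q[:, None]
    a = np.asarray(a, dtype=float).ravel()
    if cross_type == "f2":
        d = np.asarray(locus.d, dtype=float).ravel()
        return np.column_stack([a, d])
    return a[:, None]


# ---------------------------------------------------------------------------
# test execution
# ---------------------------------------------------------------------------


def _ols(y, X):
    return fit_normal_linear(y, DesignSpec(X, np.ones((X.shape[0], 1)), check=False))


def _cao(y, X, groups):
    return fit_group_variance_model(
        y, DesignSpec(X, np.ones((X.shape[0], 1)), check=False), groups
    )


def _dglm(y, X, Z, tol=mvmodels.DEFAULT_TOL, max_iter=mvmodels.DEFAULT_MAX_ITER):
    return fit_dglm(y, DesignSpec(X, Z, check=False), tol=tol, max_iter=max_iter)


def _fit_pair(c: _Components, y: Optional[np.ndarray] = None):
    """Fit (alternative, null) for the components' test on phenotype ``y``.

    Returns ``(T, df, alt_fit, null_fit)`` with the LR statistic clamped at
    zero.  ``y`` defaults to the observed phenotype.
    """
    if y is None:
        y = c.y
    name = c.name
    if name == "levene":
        comp = levene_W(y, c.groups)
        return comp.W, comp.df_num, comp, None
    if name == "slm":
        alt = _ols(y, c.X1())
        null = _ols(y, c.X0)
        df = c.k_locus
    elif name.startswith("cao"):
        alt = _cao(y, c.X1(), c.groups)
        n_groups = alt.variance_coefficients.shape[0]
        if name == "cao_m":
            null = _cao(y, c.X0, c.groups)
            df = c.k_locus
        elif name == "cao_v":
            null = _ols(y, c.X1())
            df = n_groups - 1
        else:  # cao_mv
            null = _ols(y, c.X0)
            df = c.k_locus + n_groups - 1
    else:  # dglm family
        alt = _dglm(y, c.X1(), c.Z1())
        if name == "dglm_m":
            null = _dglm(y, c.X0, c.Z1())
            df = c.k_locus
        elif name == "dglm_v":
            null = _dglm(y, c.X1(), c.Z0)
            df = c.k_locus
        else:  # dglm_mv
            null = _dglm(y, c.X0, c.Z0)
            df = 2 * c.k_locus
    T = 2.0 * (alt.log_likelihood - null.log_likelihood)
    if T < _NEGATIVE_T_LIMIT:
        raise InternalConsistencyError(
            f"{name}: LR statistic {T:.6g} is negative beyond convergence slack"
        )
    return max(T, 0.0), df, alt, null


def run_test(spec: TestSpec, validate: bool = True, keep_fits: bool = True) -> TestResult:
    """Run one of the eight tests at one locus and return its LR statistic,
    degrees of freedom and asymptotic p-value (chi-square upper tail; F for
    Levene's test)."""
    c = _Components(spec, validate=validate)
    T, df, alt, null = _fit_pair(c)
    if c.name == "levene":
        comp: mvmodels.LeveneComputation = alt
        return TestResult(
            test_name=c.name, T=comp.W, df=comp.df_num,
            p_asymptotic=comp.p_value, alt_fit=None, null_fit=None,
            converged=True, df_denominator=comp.df_den,
        )
    p = float(stats.chi2.sf(T, df))
    converged = alt.converged and null.converged
    if keep_fits and alt.mean_design is not None:
        k = c.X0.shape[1]
        alt.mean_blocks = {
            "intercept": slice(0, 1),
            "covariates": slice(1, k),
            "locus": slice(k, k + c.k_locus),
        }
    return TestResult(
        test_name=c.name, T=T, df=df, p_asymptotic=p,
        alt_fit=alt if keep_fits else None,
        null_fit=null if keep_fits else None,
        converged=converged,
    )
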