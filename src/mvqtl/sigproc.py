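"""Nominal-significance procedures for a single-locus test.

Four procedures are offered:

* ``standard`` — the asymptotic chi-square (or F) p-value;
* ``rint`` — the same after a rank-based inverse normal transform of the
  phenotype, ``RINT(y_i) = PhiInv[(rank(y_i) - 3/8) / (n + 1/4)]``;
* ``residperm`` — permutes the residuals of the test's fitted null model to
  build pseudo-null phenotypes and recomputes the full test on each;
* ``locusperm`` — permutes only the locus design columns that distinguish
  the alternative from the null model (both blocks under one permutation
  for the joint tests), so the null log-likelihood never needs refitting.

Empirical p-values use ``(1 + #{T_r >= T_obs}) / (R + 1)``, which is never
zero and is valid under exchangeability.  One root seed spawns an
independent RNG stream per replicate, so results are reproducible and
order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from . import qtltests
from .mvmodels import LeveneComputation, levene_W
from .qtltests import TestResult, TestSpec, _Components, _fit_pair, _ols

logger = logging.getLogger(__name__)

PROCEDURES = ("standard", "rint", "residperm", "locusperm")

#: default number of randomizations, matching the permutation counts used
#: to estimate the empirical nulls in the simulation study.
DEFAULT_R = 1000

#: numerical slack when counting replicate statistics at least as extreme
#: as the observed one (an identity permutation reproduces T_obs exactly;
#: the slack guards equality against floating-point noise only).
_COUNT_TOL = 1e-9


@dataclass
class EmpiricalNull:
    """Record of one permutation null: replicate statistics and the
    permutations that produced them (for exact reproducibility)."""

    procedure: str
    statistics: np.ndarray
    R: int
    seed: Optional[int]
    permutations: np.ndarray  # shape (R, n), each row a bijection of 0..n-1
    n_excluded: int = 0

    @property
    def effective_R(self) -> int:
        return self.R - self.n_excluded


def rint_transform(y) -> np.ndarray:
    """Rank-based inverse normal transform with Blom-type offsets 3/8, 1/4.

    Ties receive average ranks; the output is order-isomorphic to the input
    and invariant to monotone transformations of it.  A constant input maps
    to all zeros (with a logged warning)."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty phenotype")
    ranks = stats.rankdata(y, method="average")
    if np.all(y == y[0]) and n > 1:
        logger.warning("RINT of a constant vector; returning zeros")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _spawn_permutations(n: int, R: int, seed: Optional[int]) -> np.ndarray:
    """R permutations of 0..n-1, one independent child stream each."""
    children = np.random.SeedSequence(seed).spawn(R)
    perms = np.empty((R, n), dtype=np.intp)
    for r, child in enumerate(children):
        perms[r] = np.random.default_rng(child).permutation(n)
    return perms


def _empirical_p(t_obs: float, stats_r: np.ndarray) -> float:
    count = int(np.sum(stats_r >= t_obs - _COUNT_TOL))
    return (1 + count) / (stats_r.shape[0] + 1)


# ---------------------------------------------------------------------------
# residual permutation
# ---------------------------------------------------------------------------


def _residperm_null_fit(c: _Components):
    """Fitted means and residuals of the null model used to build
    pseudo-null phenotypes.  Levene has no likelihood-based null of its own,
    so the SLM null (covariates-only linear model) approximates it."""
    if c.name == "levene":
        fit = _ols(c.y, c.X0)
        return fit.fitted_means, fit.residuals
    _, _, _, null = _fit_pair(c)
    return null.fitted_means, null.residuals


def residperm_statistics(spec: TestSpec, permutations: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Replicate statistics for explicit permutations (row = one bijection).

    Returns ``(statistics, converged_mask)``; the full test (both fits) is
    recomputed on each pseudo-null phenotype ``m_hat + eps_hat[perm]``.
    """
    c = _Components(spec)
    mhat, ehat = _residperm_null_fit(c)
    permutations = np.asarray(permutations, dtype=np.intp)
    R = permutations.shape[0]
    out = np.empty(R)
    ok = np.ones(R, dtype=bool)
    for r in range(R):
        y_r = mhat + ehat[permutations[r]]
        if c.name == "levene":
            out[r] = levene_W(y_r, c.groups).W
        else:
            T, _, alt, null = _fit_pair(c, y_r)
            out[r] = T
            ok[r] = alt.converged and null.converged
    return out, ok


def residperm_pvalue(
    spec: TestSpec, R: int = DEFAULT_R, seed: Optional[int] = None
) -> Tuple[float, EmpiricalNull]:
    """Empirical p-value from permuting null-model residuals."""
    if R < 1:
        raise ValueError("R must be at least 1")
    obs = qtltests.run_test(spec, keep_fits=False)
    perms = _spawn_permutations(np.asarray(spec.phenotype).shape[0], R, seed)
    stats_r, ok = residperm_statistics(spec, perms)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("residperm: excluding %d non-converged replicates", n_bad)
    p = _empirical_p(obs.T, stats_r[ok])
    null = EmpiricalNull(
        procedure="residperm", statistics=stats_r, R=R, seed=seed,
        permutations=perms, n_excluded=n_bad,
    )
    return p, null


# ---------------------------------------------------------------------------
# locus permutation
# ---------------------------------------------------------------------------


def _locusperm_stat(c: _Components, ll0: float, perm: np.ndarray) -> Tuple[float, bool]:
    """One replicate of the locus permutation for non-Levene tests: refit
    the alternative model with the distinguishing locus block(s) permuted,
    reusing the unpermuted null log-likelihood."""
    name = c.name
    y = c.y
    Lp = c.L[perm]
    if name == "slm":
        alt = _ols(y, c.X1(Lp))
    elif name == "cao_m":
        alt = qtltests._cao(y, c.X1(Lp), c.groups)
    elif name == "cao_v":
        alt = qtltests._cao(y, c.X1(), c.groups[perm])
    elif name == "cao_mv":
        alt = qtltests._cao(y, c.X1(Lp), c.groups[perm])
    elif name == "dglm_m":
        alt = qtltests._dglm(y, c.X1(Lp), c.Z1())
    elif name == "dglm_v":
        alt = qtltests._dglm(y, c.X1(), c.Z1(Lp))
    else:  # dglm_mv: both blocks under the same permutation
        alt = qtltests._dglm(y, c.X1(Lp), c.Z1(Lp))
    return 2.0 * (alt.log_likelihood - ll0), alt.converged


def locusperm_statistics(spec: TestSpec, permutations: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Replicate statistics for explicit permutations of the locus block(s)."""
    c = _Components(spec)
    permutations = np.asarray(permutations, dtype=np.intp)
    R = permutations.shape[0]
    out = np.empty(R)
    ok = np.ones(R, dtype=bool)
    if c.name == "levene":
        for r in range(R):
            out[r] = levene_W(c.y, c.groups[permutations[r]]).W
        return out, ok
    _, _, _, null = _fit_pair(c)
    ll0 = null.log_likelihood
    for r in range(R):
        out[r], ok[r] = _locusperm_stat(c, ll0, permutations[r])
    return out, ok


def locusperm_pvalue(
    spec: TestSpec, R: int = DEFAULT_R, seed: Optional[int] = None
) -> Tuple[float, EmpiricalNull]:
    """Empirical p-value from permuting the locus design columns that
    distinguish the alternative from the null model."""
    if R < 1:
        raise ValueError("R must be at least 1")
    obs = qtltests.run_test(spec, keep_fits=False)
    perms = _spawn_permutations(np.asarray(spec.phenotype).shape[0], R, seed)
    stats_r, ok = locusperm_statistics(spec, perms)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("locusperm: excluding %d non-converged replicates", n_bad)
    p = _empirical_p(obs.T, stats_r[ok])
    null = EmpiricalNull(
        procedure="locusperm", statistics=stats_r, R=R, seed=seed,
        permutations=perms, n_excluded=n_bad,
    )
    return p, null


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def nominal_pvalue(
    spec: TestSpec,
    procedure: str = "standard",
    R: int = DEFAULT_R,
    seed: Optional[int] = None,
) -> Tuple[float, Optional[EmpiricalNull]]:
    """p-value of one test under one of the four procedures."""
    procedure = str(procedure).lower()
    if procedure == "standard":
        return qtltests.run_test(spec, keep_fits=False).p_asymptotic, None
    if procedure == "rint":
        tspec = TestSpec(
            test_name=spec.test_name,
            phenotype=rint_transform(spec.phenotype),
            locus=spec.locus,
            mean_covariates=spec.mean_covariates,
            variance_covariates=spec.variance_covariates,
            cross_type=spec.cross_type,
        )
        return qtltests.run_test(tspec, keep_fits=False).p_asymptotic, None
    if procedure == "residperm":
        return residperm_pvalue(spec, R=R, seed=seed)
    if procedure == "locusperm":
        return locusperm_pvalue(spec, R=R, seed=seed)
    raise ValueError(f"unknown procedure {procedure!r}; choose from {PROCEDURES}")
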