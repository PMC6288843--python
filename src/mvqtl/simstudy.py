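"""Simulation study of all test x procedure combinations.

The study design is fixed: experiments of ``n = 300`` individuals, an
F2-style single-locus genotype ``q in {-1, 0, 1}`` drawn with probabilities
``{0.25, 0.5, 0.25}``, and a five-level categorical covariate assigned in
contiguous blocks of ``n/5``.  Phenotypes are drawn as

    y_i ~ Normal(q_i * alpha,  exp(2 * (z_i' gamma + q_i * theta)))

so ``alpha`` is the additive locus effect on the mean, ``theta`` the
additive locus effect on the log residual standard deviation, and
``gamma`` the covariate effect on the log residual SD (background variance
heterogeneity, BVH).  Eight canonical scenarios cross the four locus types
(null, mQTL, vQTL, mvQTL) with BVH absent/present.

Every test fits the locus as additive + heterozygote-indicator columns
(2 df for a mean or variance contrast, 4 df jointly); the five-level
covariate enters every mean sub-model and, for the DGLM-based tests, the
variance sub-model as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import qtltests, sigproc
from .qtltests import TestSpec
from .scan import LocusEncoding

logger = logging.getLogger(__name__)

#: covariate effects on the log residual SD used whenever BVH is present.
GAMMA_BVH = np.array([-0.4, -0.2, 0.0, 0.2, 0.4])

DEFAULT_N = 300

#: F2 genotype values and their probabilities.
GENOTYPE_VALUES = np.array([-1.0, 0.0, 1.0])
GENOTYPE_PROBS = np.array([0.25, 0.5, 0.25])


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: locus effects on mean (``alpha``) and log
    SD (``theta``), covariate log-SD effects (``gamma``), sample size."""

    label: str
    alpha: float
    theta: float
    gamma: Tuple[float, ...]
    n: int = DEFAULT_N

    @property
    def is_null(self) -> bool:
        return self.alpha == 0.0 and self.theta == 0.0


def scenario_table() -> Tuple[ScenarioSpec, ...]:
    """The eight canonical scenarios of the study design."""
    g0 = (0.0,) * 5
    gb = tuple(GAMMA_BVH)
    return (
        ScenarioSpec("null_bvh_absent", 0.0, 0.0, g0),
        ScenarioSpec("null_bvh_present", 0.0, 0.0, gb),
        ScenarioSpec("mqtl_bvh_absent", 0.22, 0.0, g0),
        ScenarioSpec("mqtl_bvh_present", 0.25, 0.0, gb),
        ScenarioSpec("vqtl_bvh_absent", 0.0, 0.17, g0),
        ScenarioSpec("vqtl_bvh_present", 0.0, 0.17, gb),
        ScenarioSpec("mvqtl_bvh_absent", 0.18, 0.14, g0),
        ScenarioSpec("mvqtl_bvh_present", 0.20, 0.136, gb),
    )


def get_scenario(label: str) -> ScenarioSpec:
    for s in scenario_table():
        if s.label == label:
            return s
    raise KeyError(
        f"unknown scenario {label!r}; choose from "
        f"{[s.label for s in scenario_table()]}"
    )


@dataclass
class RateEstimate:
    """A binomial positive-rate estimate with its standard error and a 95%
    Clopper-Pearson interval."""

    rate: float
    se: float
    n_sims: int
    alpha_level: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# generative model
# ---------------------------------------------------------------------------


def simulate_genotypes(n: int, seed_or_rng=None) -> np.ndarray:
    """i.i.d. F2-style genotypes in {-1, 0, 1} w.p. {0.25, 0.5, 0.25}."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    u = rng.random(n)
    return GENOTYPE_VALUES[np.searchsorted(np.cumsum(GENOTYPE_PROBS)[:-1], u)]


def covariate_blocks(n: int) -> np.ndarray:
    """Fixed five-level covariate in contiguous equal blocks (levels 1..5)."""
    if n % 5 != 0:
        raise ValueError(f"n={n} is not divisible by 5")
    return np.repeat(np.arange(1, 6), n // 5)


def simulate_phenotype(q, covariate, spec: ScenarioSpec, seed_or_rng=None) -> np.ndarray:
    """Phenotypes ``y_i ~ N(q_i alpha, exp(2 (z_i' gamma + q_i theta)))``."""
    q = np.asarray(q, dtype=float)
    covariate = np.asarray(covariate)
    if q.shape != covariate.shape:
        raise ValueError("genotype and covariate lengths differ")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    gamma = np.asarray(spec.gamma, dtype=float)
    levels = np.unique(covariate)
    if levels.shape[0] != gamma.shape[0]:
        raise ValueError(
            f"covariate has {levels.shape[0]} levels but gamma has {gamma.shape[0]}"
        )
    level_index = np.searchsorted(levels, covariate)
    log_sd = gamma[level_index] + q * spec.theta
    return rng.normal(q * spec.alpha, np.exp(log_sd))


def rate_with_se(pvalues, alpha_level: float = 0.05) -> RateEstimate:
    """Fraction of p-values below the level, with binomial SE and 95%
    Clopper-Pearson interval."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = int(np.sum(p < alpha_level))
    n = p.size
    rate = k / n
    se = float(np.sqrt(rate * (1.0 - rate) / n))
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return RateEstimate(
        rate=rate, se=se, n_sims=n, alpha_level=alpha_level, ci_low=lo, ci_high=hi
    )


# ---------------------------------------------------------------------------
# the study
# ---------------------------------------------------------------------------


def _sim_locus(q: np.ndarray) -> LocusEncoding:
    return LocusEncoding(a=q, d=(q == 0.0).astype(float), hard_calls=q.astype(int))


def simulate_cell_pvalues(
    scenario: Union[str, ScenarioSpec],
    test: str,
    procedure: str,
    n_sims: int,
    R: int = sigproc.DEFAULT_R,
    seed: int = 0,
    scenario_index: int = 0,
) -> Tuple[np.ndarray, int]:
    """p-values of one (scenario, test, procedure) cell over ``n_sims``
    independent simulated experiments.

    Each simulation draws from a dedicated RNG stream derived from
    ``(seed, scenario_index, simulation index)``, so any single cell (or
    single simulation) is reproducible in isolation.  Returns the p-values
    and the count of simulations whose observed-data fits did not converge
    (those p-values are still included; the final iterate is used).
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    test = qtltests.canonical_test_name(test)
    procedure = str(procedure).lower()
    if procedure not in sigproc.PROCEDURES:
        raise ValueError(f"unknown procedure {procedure!r}")
    n = scenario.n
    covariate = covariate_blocks(n)
    # treatment-coded covariate columns, fixed across simulations
    cov_cols = (covariate[:, None] == np.arange(2, 6)[None, :]).astype(float)
    var_cols = cov_cols if test in qtltests.DGLM_TESTS else None
    pvals = np.empty(n_sims)
    n_nonconverged = 0
    for i in range(n_sims):
        ss = np.random.SeedSequence(seed, spawn_key=(scenario_index, i))
        rng = np.random.default_rng(ss)
        q = simulate_genotypes(n, rng)
        y = simulate_phenotype(q, covariate, scenario, rng)
        spec = TestSpec(
            test_name=test, phenotype=y, locus=_sim_locus(q),
            mean_covariates=cov_cols, variance_covariates=var_cols,
            cross_type="f2",
        )
        if procedure == "standard":
            res = qtltests.run_test(spec, validate=False, keep_fits=False)
            pvals[i] = res.p_asymptotic
            n_nonconverged += not res.converged
        elif procedure == "rint":
            spec.phenotype = sigproc.rint_transform(y)
            res = qtltests.run_test(spec, validate=False, keep_fits=False)
            pvals[i] = res.p_asymptotic
            n_nonconverged += not res.converged
        else:
            proc_seed = int(rng.integers(2**31))
            if procedure == "residperm":
                pvals[i], emp = sigproc.residperm_pvalue(spec, R=R, seed=proc_seed)
            else:
                pvals[i], emp = sigproc.locusperm_pvalue(spec, R=R, seed=proc_seed)
            n_nonconverged += emp.n_excluded > 0
    return pvals, n_nonconverged


def run_simulation_study(
    scenarios: Sequence[Union[str, ScenarioSpec]] = None,
    tests: Sequence[str] = qtltests.ALL_TESTS,
    procedures: Sequence[str] = ("standard",),
    n_sims: int = 1000,
    R: int = sigproc.DEFAULT_R,
    seed: int = 0,
    alpha_level: float = 0.05,
    keep_pvalues: bool = False,
) -> pd.DataFrame:
    """Empirical positive rate of each (scenario, test, procedure) cell.

    Returns a long-format table with one row per cell: the fraction of
    simulations with ``p < alpha_level`` (FPR for null scenarios, power
    otherwise), its binomial standard error and 95% Clopper-Pearson
    interval, and the non-convergence count.  With ``keep_pvalues`` the raw
    p-value vector of each cell is included (for QQ/ROC-style summaries).
    """
    if scenarios is None:
        scenarios = scenario_table()
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        if isinstance(scenario, str):
            scenario = get_scenario(scenario)
        for test in tests:
            for procedure in procedures:
                pvals, n_bad = simulate_cell_pvalues(
                    scenario, test, procedure, n_sims=n_sims, R=R,
                    seed=seed, scenario_index=s_idx,
                )
                est = rate_with_se(pvals, alpha_level)
                row = {
                    "scenario": scenario.label,
                    "test": qtltests.canonical_test_name(test),
                    "procedure": procedure,
                    "rate": est.rate,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_sims": n_sims,
                    "n_nonconverged": n_bad,
                    "is_null": scenario.is_null,
                }
                if keep_pvalues:
                    row["pvalues"] = pvals
                rows.append(row)
                logger.info(
                    "%s / %s / %s: rate=%.4f (se %.4f)",
                    scenario.label, test, procedure, est.rate, est.se,
                )
    return pd.DataFrame(rows)


def rate_table_wide(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format study result to test x procedure rows with one
    column per scenario (the study's conventional presentation)."""
    return results.pivot_table(
        index=["test", "procedure"], columns="scenario", values="rate", sort=False
    )
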