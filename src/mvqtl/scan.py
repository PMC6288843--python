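"""Genome scans, genomewide significance, positional confidence intervals
and percent variance explained.

A scan runs one of the eight single-locus tests at every locus of an
experimental cross whose genotypes are available as probabilities
(Haley-Knott dosages ``a = 2 p(AA) + p(AB)``, ``d = p(AB)`` for an F2).
Genomewide family-wise error is controlled by the genome-permutation
procedure: one permutation per replicate is applied to the locus design
blocks identically across all loci, the maximum statistic per replicate is
recorded, and a generalized extreme value (GEV) distribution fitted to the
maxima supplies FWER-adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import qtltests, sigproc
from .mvmodels import ModelFit
from .qtltests import TestSpec, _Components, _fit_pair

logger = logging.getLogger(__name__)

#: below this many genome permutations the GEV tail fit is unstable.
MIN_STABLE_PERMS = 100

#: fitted GEV shapes beyond this magnitude trigger the empirical fallback.
MAX_GEV_SHAPE = 1.0


@dataclass
class LocusEncoding:
    """Per-individual locus dosages: additive ``a``, dominance ``d`` (F2
    only) and optional hard genotype calls for the group-based tests."""

    a: np.ndarray
    d: Optional[np.ndarray] = None
    hard_calls: Optional[np.ndarray] = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float).ravel()
        if self.d is not None:
            self.d = np.asarray(self.d, dtype=float).ravel()


@dataclass
class GEVParams:
    """Generalized extreme value parameters, standard ``xi`` sign
    convention (``xi = 0`` is the Gumbel limit)."""

    location: float
    scale: float
    shape: float

    def sf(self, x) -> np.ndarray:
        # scipy's genextreme uses c = -shape
        return stats.genextreme.sf(x, -self.shape, loc=self.location, scale=self.scale)

    def cdf(self, x) -> np.ndarray:
        return stats.genextreme.cdf(x, -self.shape, loc=self.location, scale=self.scale)


@dataclass
class ScanResult:
    """Per-locus scan statistics, asymptotic and (optionally) FWER-adjusted
    p-values, and the fitted permutation-maximum GEV."""

    loci: pd.DataFrame  # columns: chromosome, position, name
    test_name: str
    T: np.ndarray
    df: np.ndarray
    p_asymptotic: np.ndarray
    p_fwer: Optional[np.ndarray] = None
    gev: Optional[GEVParams] = None
    n_perms: int = 0
    perm_maxima: Optional[np.ndarray] = None

    def table(self) -> pd.DataFrame:
        out = self.loci.copy()
        out["T"] = self.T
        out["df"] = self.df
        out["p_asymptotic"] = self.p_asymptotic
        if self.p_fwer is not None:
            out["p_fwer"] = self.p_fwer
        return out

    @property
    def peak(self) -> pd.Series:
        idx = int(np.nanargmax(self.T))
        return self.table().iloc[idx]


# ---------------------------------------------------------------------------
# locus encodings
# ---------------------------------------------------------------------------


def encode_f2_locus(probs: np.ndarray) -> LocusEncoding:
    """Haley-Knott encoding of F2 genotype probabilities (AA, AB, BB).

    ``a = 2 p(AA) + p(AB)`` in [0, 2], ``d = p(AB)`` in [0, 1]; hard calls
    are the maximum-probability genotype coded -1/0/1 for BB/AB/AA, with
    ties broken toward the heterozygote.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of genotype probabilities")
    if np.any(probs < -1e-9):
        raise ValueError("genotype probabilities must be nonnegative")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("genotype probability rows must sum to 1")
    a = 2.0 * probs[:, 0] + probs[:, 1]
    d = probs[:, 1].copy()
    best = probs.max(axis=1)
    hard = np.where(
        probs[:, 1] >= best - 1e-12, 0, np.where(probs[:, 0] >= probs[:, 2], 1, -1)
    )
    return LocusEncoding(a=a, d=d, hard_calls=hard)


def encode_backcross_locus(probs: np.ndarray) -> LocusEncoding:
    """Backcross encoding: single additive dosage ``a = p(het)`` in [0, 1]."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of genotype probabilities")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("genotype probability rows must sum to 1")
    hard = (probs[:, 1] >= probs[:, 0]).astype(int)
    return LocusEncoding(a=probs[:, 1].copy(), d=None, hard_calls=hard)


def _encode(probs: np.ndarray, cross_type: str) -> LocusEncoding:
    return encode_f2_locus(probs) if cross_type == "f2" else encode_backcross_locus(probs)


def _covariate_matrix(covariates: Optional[pd.DataFrame], names) -> Optional[np.ndarray]:
    """Numeric model columns for the named covariates; categorical and
    string columns expand to treatment-coded indicators."""
    if not names:
        return None
    cols = []
    for name in names:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _scan_components(
    cross,
    test_name: str,
    phenotype: Optional[str],
    mean_covariates,
    variance_covariates,
) -> Tuple[pd.DataFrame, List[Optional[_Components]]]:
    name = qtltests.canonical_test_name(test_name)
    pheno_name = phenotype or cross.phenotypes.columns[0]
    y = cross.phenotypes[pheno_name].to_numpy(dtype=float)
    Xc = _covariate_matrix(cross.covariates, mean_covariates)
    Zc = _covariate_matrix(cross.covariates, variance_covariates)
    comps: List[Optional[_Components]] = []
    for l in range(cross.genotype_probabilities.shape[0]):
        enc = _encode(cross.genotype_probabilities[l], cross.cross_type)
        spec = TestSpec(
            test_name=name, phenotype=y, locus=enc,
            mean_covariates=Xc, variance_covariates=Zc,
            cross_type=cross.cross_type,
        )
        comps.append(_Components(spec, validate=(l == 0)))
    return cross.map.copy().reset_index(drop=True), comps


def genome_scan(
    cross,
    test_name: str,
    mean_covariates: Sequence[str] = (),
    variance_covariates: Sequence[str] = (),
    phenotype: Optional[str] = None,
) -> ScanResult:
    """Run one test at every locus, returning asymptotic p-values.

    Loci whose fits fail are reported with missing statistics; an error is
    raised only if every locus fails.
    """
    loci, comps = _scan_components(
        cross, test_name, phenotype, mean_covariates, variance_covariates
    )
    L = len(comps)
    if L == 0:
        raise ValueError("cross contains no loci")
    T = np.full(L, np.nan)
    df = np.zeros(L, dtype=int)
    p = np.full(L, np.nan)
    n_failed = 0
    for l, c in enumerate(comps):
        try:
            t_l, df_l, alt, null = _fit_pair(c)
        except Exception as exc:  # rank problems, degenerate groups, ...
            logger.warning("locus %d failed: %s", l, exc)
            n_failed += 1
            continue
        if c.name != "levene" and not (alt.converged and null.converged):
            logger.warning("locus %d: non-converged fit; statistic dropped", l)
            n_failed += 1
            continue
        T[l] = t_l
        df[l] = df_l
        p[l] = (
            stats.f.sf(t_l, df_l, alt.df_den)
            if c.name == "levene"
            else stats.chi2.sf(t_l, df_l)
        )
    if n_failed == L:
        raise RuntimeError("all loci failed to fit")
    return ScanResult(
        loci=loci, test_name=comps[0].name, T=T, df=df, p_asymptotic=p
    )


def fit_gev(maxima: np.ndarray) -> GEVParams:
    """Maximum-likelihood GEV fit to permutation maxima (shape
    unconstrained)."""
    c, loc, scale = stats.genextreme.fit(np.asarray(maxima, dtype=float))
    return GEVParams(location=float(loc), scale=float(scale), shape=float(-c))


def genomeperm_fwer(
    cross,
    test_name: str,
    mean_covariates: Sequence[str] = (),
    variance_covariates: Sequence[str] = (),
    phenotype: Optional[str] = None,
    R: int = 1000,
    seed: Optional[int] = None,
) -> ScanResult:
    """Genome scan with FWER-adjusted p-values from genome permutation.

    For each replicate one permutation is applied to the locus blocks of
    every locus (mirroring the locusperm semantics of the chosen test); the
    per-replicate maximum statistic feeds a GEV whose upper tail gives
    ``p_fwer``.  Falls back to the empirical permutation tail if the GEV
    fit fails or its shape is extreme.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    if R < MIN_STABLE_PERMS:
        logger.warning("R=%d genome permutations; GEV tail fit may be unstable", R)
    result = genome_scan(
        cross, test_name, mean_covariates, variance_covariates, phenotype
    )
    loci, comps = _scan_components(
        cross, test_name, phenotype, mean_covariates, variance_covariates
    )
    n = comps[0].n
    # per-locus null log-likelihoods, computed once
    ll0 = np.full(len(comps), np.nan)
    for l, c in enumerate(comps):
        if c.name == "levene":
            continue
        try:
            _, _, _, null = _fit_pair(c)
            ll0[l] = null.log_likelihood
        except Exception:
            pass
    perms = sigproc._spawn_permutations(n, R, seed)
    maxima = np.empty(R)
    for r in range(R):
        perm = perms[r]
        best = -np.inf
        for l, c in enumerate(comps):
            if np.isnan(result.T[l]):
                continue
            if c.name == "levene":
                t_rl = sigproc.levene_W(c.y, c.groups[perm]).W
            else:
                if np.isnan(ll0[l]):
                    continue
                t_rl, ok = sigproc._locusperm_stat(c, ll0[l], perm)
                if not ok:
                    logger.warning(
                        "replicate %d locus %d non-converged; excluded from maximum", r, l
                    )
                    continue
            if t_rl > best:
                best = t_rl
        maxima[r] = best
    gev = None
    p_fwer = None
    try:
        gev = fit_gev(maxima)
        if not np.isfinite([gev.location, gev.scale, gev.shape]).all() or abs(
            gev.shape
        ) > MAX_GEV_SHAPE or gev.scale <= 0:
            raise RuntimeError(f"implausible GEV fit: {gev}")
        p_fwer = gev.sf(result.T)
    except Exception as exc:
        logger.warning("GEV fit failed (%s); using empirical permutation tail", exc)
        gev = None
        p_fwer = np.array(
            [
                np.nan
                if np.isnan(t)
                else (1 + np.sum(maxima >= t - 1e-9)) / (R + 1)
                for t in result.T
            ]
        )
    result.p_fwer = np.asarray(p_fwer, dtype=float)
    result.gev = gev
    result.n_perms = R
    result.perm_maxima = maxima
    return result


def bootstrap_position_ci(
    cross,
    test_name: str,
    mean_covariates: Sequence[str] = (),
    variance_covariates: Sequence[str] = (),
    phenotype: Optional[str] = None,
    chromosome=None,
    B: int = 1000,
    level: float = 0.9,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Equal-tailed bootstrap confidence interval for a QTL peak position.

    Resamples individuals with replacement ``B`` times, rescans the
    chromosome and records the position of the maximum statistic each time.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if chromosome is None:
        raise ValueError("a chromosome must be specified")
    mask = (cross.map["chromosome"] == chromosome).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"chromosome {chromosome!r} has fewer than 2 loci")
    loci, comps = _scan_components(
        cross, test_name, phenotype, mean_covariates, variance_covariates
    )
    comps = [c for c, m in zip(comps, mask) if m]
    positions = loci.loc[mask, "position"].to_numpy(dtype=float)
    y = comps[0].y
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    peak_positions = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        best_t, best_pos = -np.inf, positions[0]
        for c, pos in zip(comps, positions):
            cb = _resampled_components(c, idx)
            try:
                t_b, _, _, _ = _fit_pair(cb)
            except Exception:
                continue
            if t_b > best_t:
                best_t, best_pos = t_b, pos
        peak_positions[b] = best_pos
    lo, hi = np.quantile(peak_positions, [(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    return float(lo), float(hi)


def _resampled_components(c: _Components, idx: np.ndarray) -> _Components:
    cb = object.__new__(_Components)
    cb.name = c.name
    cb.cross_type = c.cross_type
    cb.y = c.y[idx]
    cb.n = idx.shape[0]
    cb.X0 = c.X0[idx]
    cb.Z0 = c.Z0[idx]
    cb.L = c.L[idx]
    cb.groups = None if c.groups is None else c.groups[idx]
    cb.k_locus = c.k_locus
    cb.n_covariates = c.n_covariates
    return cb


# ---------------------------------------------------------------------------
# percent variance explained
# ---------------------------------------------------------------------------


def percent_variance_explained(
    dglm_fit: ModelFit, locus: LocusEncoding
) -> Tuple[float, np.ndarray]:
    """Average and per-individual percent variance explained by a QTL.

    PVE is the ratio of the QTL mean-contribution variance to the sum of
    QTL variance, covariate variance and residual variance.  Under variance
    heterogeneity the residual variance differs per individual, so each
    individual has its own PVE; the average uses the mean fitted residual
    variance.
    """
    blocks = dglm_fit.mean_blocks
    if blocks is None or "locus" not in blocks or dglm_fit.mean_design is None:
        raise ValueError("fit does not record locus mean effects")
    X = dglm_fit.mean_design
    beta = dglm_fit.mean_coefficients
    lsl = blocks["locus"]
    if lsl.stop - lsl.start == 0:
        raise ValueError("fit has an empty locus block")
    q_contrib = X[:, lsl] @ beta[lsl]
    csl = blocks.get("covariates", slice(0, 0))
    c_contrib = X[:, csl] @ beta[csl]
    var_q = float(np.var(q_contrib))
    var_c = float(np.var(c_contrib))
    per_individual = var_q / (var_q + var_c + dglm_fit.fitted_variances)
    average = var_q / (var_q + var_c + float(dglm_fit.fitted_variances.mean()))
    return average, per_individual
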