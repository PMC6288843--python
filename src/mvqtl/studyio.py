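"""File formats and fixture generation for experimental-cross data.

The on-disk cross format is the comma-separated layout popularized by the
qtl ecosystem: a header row of column names (phenotypes/covariates first,
then markers), a second row giving the chromosome of each marker (blank
for non-marker columns), a third row giving the map position in cM, and
one row per individual after that.  Genotypes are letters (``AA``/``AB``/
``BB`` for an F2, ``AA``/``AB`` for a backcross); missing genotypes become
uniform probability rows, with a logged count.  Estimated genotype
probabilities may be supplied separately as a long-format TSV
(locus, individual, one column per genotype class), which overrides the
letter-derived probabilities.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import simstudy
from .simstudy import GAMMA_BVH

logger = logging.getLogger(__name__)

F2_GENOTYPES = ("AA", "AB", "BB")
BACKCROSS_GENOTYPES = ("AA", "AB")
MISSING_TOKENS = {"", "-", "NA", "N/A", "na", "nan"}

#: header comment written on every scan / rate-table TSV.
TSV_SCHEMA_VERSION = "mvqtl-tsv-v1"


@dataclass
class CrossData:
    """An experimental cross: phenotypes, covariates, per-locus genotype
    probabilities and a genetic map, all row-aligned."""

    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    genotype_probabilities: np.ndarray  # (n_loci, n_individuals, n_classes)
    map: pd.DataFrame  # columns: chromosome, position, name
    cross_type: str = "f2"

    def __post_init__(self):
        n = len(self.phenotypes)
        if len(self.covariates) != n:
            raise ValueError("covariates are not row-aligned with phenotypes")
        probs = np.asarray(self.genotype_probabilities, dtype=float)
        if probs.ndim != 3 or probs.shape[1] != n:
            raise ValueError(
                "genotype probabilities must have shape (n_loci, n_individuals, classes)"
            )
        expected_classes = 3 if self.cross_type == "f2" else 2
        if probs.shape[2] != expected_classes:
            raise ValueError(
                f"{self.cross_type} cross requires {expected_classes} genotype classes"
            )
        if np.any(np.abs(probs.sum(axis=2) - 1.0) > 1e-6):
            raise ValueError("genotype probability rows must sum to 1")
        self.genotype_probabilities = probs
        if len(self.map) != probs.shape[0]:
            raise ValueError("map length does not match number of loci")
        for chrom, grp in self.map.groupby("chromosome", sort=False):
            if not grp["position"].is_monotonic_increasing:
                raise ValueError(f"map positions on chromosome {chrom!r} are not sorted")

    @property
    def n_individuals(self) -> int:
        return len(self.phenotypes)

    @property
    def n_loci(self) -> int:
        return self.genotype_probabilities.shape[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_cross(
    cross_file,
    probability_file=None,
    covariate_names: Sequence[str] = (),
    cross_type: str = "f2",
) -> CrossData:
    """Read a cross CSV (and optional genotype-probability TSV).

    Columns named in ``covariate_names`` are treated as covariates; other
    non-marker columns are phenotypes.  Structural inconsistencies are
    rejected; the single silent-ish repair is imputing missing genotypes to
    uniform probability rows, which is logged.
    """
    raw = pd.read_csv(cross_file, header=None, dtype=str, keep_default_na=False)
    if raw.shape[0] < 4:
        raise ValueError("cross file needs header, chromosome, position and data rows")
    names = [str(v).strip() for v in raw.iloc[0]]
    if len(set(names)) != len(names):
        raise ValueError("duplicate column names in cross file header")
    chrom_row = [str(v).strip() for v in raw.iloc[1]]
    pos_row = [str(v).strip() for v in raw.iloc[2]]
    body = raw.iloc[3:].reset_index(drop=True)
    marker_cols = [j for j, c in enumerate(chrom_row) if c != ""]
    other_cols = [j for j, c in enumerate(chrom_row) if c == ""]
    if not marker_cols:
        raise ValueError("cross file contains no marker columns")
    for j in marker_cols:
        if pos_row[j] == "":
            raise ValueError(f"marker column {names[j]!r} lacks a map position")

    pheno_cols, covar_cols = [], []
    for j in other_cols:
        (covar_cols if names[j] in covariate_names else pheno_cols).append(j)
    missing_covs = set(covariate_names) - {names[j] for j in covar_cols}
    if missing_covs:
        raise ValueError(f"declared covariates not in file: {sorted(missing_covs)}")
    if not pheno_cols:
        raise ValueError("cross file contains no phenotype columns")

    def _numeric(j):
        col = body.iloc[:, j].replace(list(MISSING_TOKENS), np.nan)
        return pd.to_numeric(col, errors="raise")

    phenotypes = pd.DataFrame({names[j]: _numeric(j) for j in pheno_cols})
    covariates = pd.DataFrame({names[j]: body.iloc[:, j] for j in covar_cols})
    for name in covariates.columns:
        try:
            covariates[name] = pd.to_numeric(covariates[name])
        except (ValueError, TypeError):
            pass  # stays categorical

    letters = F2_GENOTYPES if cross_type == "f2" else BACKCROSS_GENOTYPES
    n = len(body)
    L = len(marker_cols)
    probs = np.zeros((L, n, len(letters)))
    n_missing = 0
    for l, j in enumerate(marker_cols):
        for i, val in enumerate(body.iloc[:, j]):
            val = str(val).strip()
            if val in MISSING_TOKENS:
                probs[l, i, :] = 1.0 / len(letters)
                n_missing += 1
            elif val in letters:
                probs[l, i, letters.index(val)] = 1.0
            else:
                raise ValueError(
                    f"marker {names[j]!r}, individual {i + 1}: bad genotype {val!r}"
                )
    if n_missing:
        logger.warning("imputed %d missing genotypes to uniform probabilities", n_missing)

    cmap = pd.DataFrame(
        {
            "chromosome": [chrom_row[j] for j in marker_cols],
            "position": [float(pos_row[j]) for j in marker_cols],
            "name": [names[j] for j in marker_cols],
        }
    )

    if probability_file is not None:
        probs = _read_probability_table(probability_file, cmap, n, len(letters))

    return CrossData(
        phenotypes=phenotypes,
        covariates=covariates,
        genotype_probabilities=probs,
        map=cmap,
        cross_type=cross_type,
    )


def _read_probability_table(path, cmap: pd.DataFrame, n: int, k: int) -> np.ndarray:
    tab = pd.read_csv(path, sep="\t")
    required = ["locus", "individual"]
    prob_cols = [c for c in tab.columns if c not in required]
    if len(prob_cols) != k:
        raise ValueError(
            f"probability table has {len(prob_cols)} genotype columns, expected {k}"
        )
    name_to_idx = {name: l for l, name in enumerate(cmap["name"])}
    probs = np.full((len(cmap), n, k), np.nan)
    for _, row in tab.iterrows():
        if row["locus"] not in name_to_idx:
            raise ValueError(f"probability table names unknown locus {row['locus']!r}")
        i = int(row["individual"]) - 1
        if not 0 <= i < n:
            raise ValueError(f"individual index {row['individual']} out of range")
        probs[name_to_idx[row["locus"]], i] = [row[c] for c in prob_cols]
    if np.isnan(probs).any():
        raise ValueError("probability table does not cover every locus x individual")
    if np.any(np.abs(probs.sum(axis=2) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    return probs


def write_cross(cross: CrossData, cross_file) -> None:
    """Write a cross back to the CSV layout read by :func:`read_cross`.

    Probabilistic genotypes are written as their hard call when the row is
    certain (a 0/1 triple) and as missing otherwise; use
    :func:`write_probability_table` to preserve soft probabilities.
    """
    letters = F2_GENOTYPES if cross.cross_type == "f2" else BACKCROSS_GENOTYPES
    names = (
        list(cross.phenotypes.columns)
        + list(cross.covariates.columns)
        + list(cross.map["name"])
    )
    n_other = len(cross.phenotypes.columns) + len(cross.covariates.columns)
    chrom = [""] * n_other + [str(c) for c in cross.map["chromosome"]]
    pos = [""] * n_other + [_trim_float(p) for p in cross.map["position"]]
    rows = [names, chrom, pos]
    probs = cross.genotype_probabilities
    for i in range(cross.n_individuals):
        row = [_trim_float(v) for v in cross.phenotypes.iloc[i]]
        row += [str(v) for v in cross.covariates.iloc[i]]
        for l in range(cross.n_loci):
            p = probs[l, i]
            j = int(np.argmax(p))
            row.append(letters[j] if abs(p[j] - 1.0) <= 1e-6 else "-")
        rows.append(row)
    text = "\n".join(",".join(map(str, row)) for row in rows) + "\n"
    _write_text(cross_file, text)


def write_probability_table(cross: CrossData, path) -> None:
    letters = F2_GENOTYPES if cross.cross_type == "f2" else BACKCROSS_GENOTYPES
    records = []
    for l, name in enumerate(cross.map["name"]):
        for i in range(cross.n_individuals):
            rec = {"locus": name, "individual": i + 1}
            rec.update(
                {f"p_{g}": cross.genotype_probabilities[l, i, j] for j, g in enumerate(letters)}
            )
            records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def write_scan_tsv(result, path) -> None:
    """Scan result as TSV with a versioned schema comment line."""
    tab = result.table()
    buf = io.StringIO()
    buf.write(f"# {TSV_SCHEMA_VERSION} scan test={result.test_name} n_perms={result.n_perms}\n")
    tab.to_csv(buf, sep="\t", index=False)
    _write_text(path, buf.getvalue())


def write_rate_table_tsv(results: pd.DataFrame, path) -> None:
    """Long-format study results pivoted to the conventional wide layout."""
    wide = simstudy.rate_table_wide(results)
    buf = io.StringIO()
    buf.write(f"# {TSV_SCHEMA_VERSION} rate-table\n")
    wide.to_csv(buf, sep="\t")
    _write_text(path, buf.getvalue())


def _trim_float(v) -> str:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return str(v)
    if np.isnan(f):
        return "-"
    return repr(f)  # shortest exact round-trip representation


def _write_text(path_or_buf, text: str) -> None:
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# synthetic fixture crosses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth QTL planted in a fixture cross."""

    chromosome: str
    locus_index: int  # within its chromosome
    alpha: float = 0.0
    theta: float = 0.0


def make_fixture_cross(
    n_individuals: int = 300,
    n_loci_per_chr: int = 11,
    n_chr: int = 2,
    planted_effects: Sequence[PlantedEffect] = (),
    seed: Optional[int] = None,
    locus_spacing_cm: float = 5.0,
    stay_prob: float = 0.8,
    covariate_gamma: np.ndarray = GAMMA_BVH,
    cross_type: str = "f2",
) -> Tuple[CrossData, dict]:
    """Generate a synthetic cross with optional planted mean/variance QTL.

    Genotypes follow a simple exchangeable-correlation chain along each
    chromosome (each locus copies its neighbor with probability
    ``stay_prob``, else redraws).  The phenotype follows the study's
    generative model extended with covariate mean effects: a five-level
    "family"-like factor drives both mean shifts and (via
    ``covariate_gamma``) background variance heterogeneity, plus a binary
    "sex" mean effect.  Returns the cross and a ground-truth record.
    """
    if n_individuals % 5 != 0:
        raise ValueError("n_individuals must be divisible by 5 for the block covariate")
    if cross_type != "f2":
        raise ValueError("fixture generation currently supports F2 crosses only")
    rng = np.random.default_rng(seed)
    n = n_individuals

    family = simstudy.covariate_blocks(n)
    sex = rng.integers(0, 2, size=n)
    family_mean_effects = np.linspace(-0.3, 0.3, 5)
    sex_effect = 0.4

    chrom_names = [f"chr{c + 1}" for c in range(n_chr)]
    genotypes: List[np.ndarray] = []
    map_rows = []
    for chrom in chrom_names:
        q = np.empty((n_loci_per_chr, n))
        q[0] = simstudy.simulate_genotypes(n, rng)
        for l in range(1, n_loci_per_chr):
            fresh = simstudy.simulate_genotypes(n, rng)
            keep = rng.random(n) < stay_prob
            q[l] = np.where(keep, q[l - 1], fresh)
        for l in range(n_loci_per_chr):
            genotypes.append(q[l])
            map_rows.append(
                {
                    "chromosome": chrom,
                    "position": l * locus_spacing_cm,
                    "name": f"{chrom}_m{l + 1}",
                }
            )
    geno = np.array(genotypes)  # (L, n) values in {-1, 0, 1}

    effect_lookup: Dict[Tuple[str, int], PlantedEffect] = {}
    for eff in planted_effects:
        if eff.chromosome not in chrom_names:
            raise ValueError(f"unknown chromosome {eff.chromosome!r}")
        if not 0 <= eff.locus_index < n_loci_per_chr:
            raise ValueError(f"locus index {eff.locus_index} out of range")
        effect_lookup[(eff.chromosome, eff.locus_index)] = eff

    mean = family_mean_effects[family - 1] + sex_effect * sex
    log_sd = np.asarray(covariate_gamma, dtype=float)[family - 1]
    for l, row in enumerate(map_rows):
        key = (row["chromosome"], int(round(row["position"] / locus_spacing_cm)))
        if key in effect_lookup:
            eff = effect_lookup[key]
            mean = mean + eff.alpha * geno[l]
            log_sd = log_sd + eff.theta * geno[l]
    y = rng.normal(mean, np.exp(log_sd))

    L = geno.shape[0]
    probs = np.zeros((L, n, 3))
    # hard genotypes as certain probability triples: columns AA, AB, BB <- q=1,0,-1
    probs[:, :, 0] = geno == 1
    probs[:, :, 1] = geno == 0
    probs[:, :, 2] = geno == -1

    cross = CrossData(
        phenotypes=pd.DataFrame({"pheno": y}),
        covariates=pd.DataFrame(
            {"family": pd.Categorical(family), "sex": pd.Categorical(sex)}
        ),
        genotype_probabilities=probs,
        map=pd.DataFrame(map_rows),
        cross_type=cross_type,
    )
    truth = {
        "planted_effects": list(planted_effects),
        "family_mean_effects": family_mean_effects,
        "sex_effect": sex_effect,
        "covariate_gamma": np.asarray(covariate_gamma, dtype=float),
        "genotypes": geno,
        "seed": seed,
    }
    return cross, truth
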