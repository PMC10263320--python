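"""Clock robustness (CV / nCV) and clock-network preservation (Spearman
correlation matrix + Mantel permutation test).

The normalized coefficient of variation (nCV) of a gene is its coefficient
of variation across samples divided by the mean CV of *all* genes retained
in the dataset. In population data with unknown collection times, rhythmic
genes spread their oscillation across samples, so core-clock nCV acts as a
surrogate for relative oscillation amplitude: an intact clock gives high
clock-gene nCV, a disrupted clock collapses it toward (or below) 1.

Network preservation is assessed by computing the Spearman correlation
matrix over a core-clock gene set and comparing it with a reference matrix
(shipped with the package, regenerable, or user-supplied) via a Mantel
permutation test: the statistic is the Pearson correlation of the two upper
off-diagonal triangles, the null jointly permutes the row/column labels of
one matrix, and the z-statistic locates the observed correlation within the
permutation null. Higher z means the clock-gene covariation structure is
closer to the reference (a more intact clock network).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess_io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: default 11-gene set for nCV summaries
NCV_GENE_SET = (
    "ARNTL", "CLOCK", "NPAS2", "NR1D1", "NR1D2",
    "PER1", "PER2", "PER3", "CRY1", "CRY2", "DBP",
)

#: default 17-gene set for the clock correlation matrix
CORRELATION_GENE_SET = NCV_GENE_SET + (
    "BHLHE40", "BHLHE41", "TEF", "HLF", "NFIL3", "RORC",
)


@dataclass
class NCVResult:
    per_gene_cv: pd.Series
    dataset_mean_cv: float
    per_gene_ncv: pd.Series
    mean_ncv: float
    n_genes_used: int
    missing_genes: tuple = ()


@dataclass
class NCVComparison:
    mean_difference: float
    p_value: float
    n_genes: int
    method: str


@dataclass
class CorrelationComparison:
    rho_matrix: pd.DataFrame
    reference: pd.DataFrame
    mantel_r: float
    z_stat: float
    p_value: float
    n_permutations: int
    seed: object


def compute_cv(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene coefficient of variation: population SD / mean.

    Genes with zero mean are excluded with a warning; an all-zero matrix is
    an error.
    """
    vals = matrix.values.to_numpy(dtype=float)
    means = vals.mean(axis=1)
    if np.all(means == 0):
        raise ValueError("all-zero expression matrix: CV undefined")
    keep = means > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} gene(s) with zero mean from CV")
    sd = vals[keep].std(axis=1, ddof=0)
    return pd.Series(sd / means[keep], index=matrix.genes[keep], name="cv")


def compute_ncv(matrix: ExpressionMatrix, gene_set=NCV_GENE_SET) -> NCVResult:
    """nCV of a clock gene set against the mean CV of all retained genes.

    The denominator is the mean CV over *every* gene in the matrix (after
    whatever filtering the caller applied), not just the set.
    """
    cv = compute_cv(matrix)
    if len(matrix.samples) < 30:
        warnings.warn(
            f"nCV computed on {len(matrix.samples)} samples; population-level "
            "inference is recommended at >= 30"
        )
    gene_set = tuple(gene_set)
    present = [g for g in gene_set if g in cv.index]
    missing = tuple(g for g in gene_set if g not in cv.index)
    if not present:
        raise ValueError("gene set has no overlap with the matrix genes")
    if missing:
        logger.warning("nCV gene set members absent from matrix: %s", ", ".join(missing))
    mean_cv = float(cv.mean())
    if mean_cv == 0:
        raise ValueError("every gene is constant: the dataset mean CV is 0 and nCV is undefined")
    ncv = cv.loc[present] / mean_cv
    return NCVResult(
        per_gene_cv=cv.loc[present],
        dataset_mean_cv=mean_cv,
        per_gene_ncv=ncv.rename("ncv"),
        mean_ncv=float(ncv.mean()),
        n_genes_used=len(present),
        missing_genes=missing,
    )


def compare_ncv_groups(result_a: NCVResult, result_b: NCVResult,
                       method: str = "paired_t") -> NCVComparison:
    """Compare per-gene nCV between two conditions over the shared gene set.

    Paired across genes (default: paired two-sided t-test; "wilcoxon" for
    the signed-rank alternative). Identical inputs return p = 1 by contract.
    """
    shared = result_a.per_gene_ncv.index.intersection(result_b.per_gene_ncv.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes to compare nCV between groups")
    a = result_a.per_gene_ncv.loc[shared].to_numpy()
    b = result_b.per_gene_ncv.loc[shared].to_numpy()
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff, 0.0):
        return NCVComparison(0.0, 1.0, len(shared), method)
    if method == "paired_t":
        stat = stats.ttest_rel(a, b)
        p = float(stat.pvalue)
    elif method == "wilcoxon":
        p = float(stats.wilcoxon(a, b).pvalue)
    else:
        raise ValueError(f"unknown comparison method {method!r}")
    return NCVComparison(mean_diff, p, len(shared), method)


def clock_correlation_matrix(matrix: ExpressionMatrix,
                             correlation_set=CORRELATION_GENE_SET) -> pd.DataFrame:
    """Spearman correlation matrix (average-rank ties) over the clock set.

    Missing genes are dropped with a log message; zero-variance genes get
    correlation 0 with every other gene (unit diagonal kept) so that a
    fully flattened clock yields a well-defined, near-empty matrix rather
    than NaNs.
    """
    if len(matrix.samples) < 5:
        raise ValueError("need >= 5 samples for a clock correlation matrix")
    present = [g for g in correlation_set if g in matrix.genes]
    if len(present) < 2:
        raise ValueError("fewer than 2 correlation-set genes present in the matrix")
    missing = [g for g in correlation_set if g not in matrix.genes]
    if missing:
        logger.warning("correlation set members absent from matrix: %s", ", ".join(missing))
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    constant = sub.std(axis=1) == 0
    # Spearman = Pearson on average ranks (robust to scipy's scalar returns
    # for 2-variable or constant-column inputs)
    ranks = np.apply_along_axis(stats.rankdata, 1, sub)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.nan_to_num(np.atleast_2d(np.asarray(rho, dtype=float)), nan=0.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance gene(s) assigned 0 correlations"
        )
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=present, columns=present)


def _triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if den == 0.0:
        return 0.0
    return float(xc @ yc) / den


def mantel_compare(rho_matrix: pd.DataFrame, reference: pd.DataFrame,
                   n_permutations: int = 10_000, seed: int = 0,
                   exact: bool = False) -> CorrelationComparison:
    """Mantel test between an observed and a reference correlation matrix.

    The statistic is the Pearson correlation of the upper off-diagonal
    triangles over the shared gene labels. The null jointly permutes the
    row/column labels of the reference matrix; the one-sided (greater)
    permutation p-value is (#{r_null >= r_obs} + 1) / (n + 1), and
    z = (r_obs - mean(r_null)) / SD(r_null) (population SD).

    With ``exact=True`` all label permutations are enumerated (feasible only
    for small gene sets) and ``n_permutations`` is ignored.
    """
    shared = [g for g in rho_matrix.index if g in reference.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared genes for a Mantel comparison")
    a = rho_matrix.loc[shared, shared].to_numpy(dtype=float)
    b = reference.loc[shared, shared].to_numpy(dtype=float)
    n = len(shared)
    a_tri = _triangle(a)
    r_obs = _pearson(a_tri, _triangle(b))

    if exact:
        perms = itertools.permutations(range(n))
        r_null = np.array([_pearson(a_tri, _triangle(b[np.ix_(p, p)])) for p in perms])
        n_perm = len(r_null)
    else:
        if n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        rng = np.random.default_rng(seed)
        r_null = np.empty(n_permutations)
        for i in range(n_permutations):
            p = rng.permutation(n)
            r_null[i] = _pearson(a_tri, _triangle(b[np.ix_(p, p)]))
        n_perm = n_permutations
    sd = float(r_null.std(ddof=0))
    z = (r_obs - float(r_null.mean())) / sd if sd > 0 else math.inf
    p = (int(np.sum(r_null >= r_obs)) + 1) / (n_perm + 1)
    return CorrelationComparison(
        rho_matrix=rho_matrix.loc[shared, shared],
        reference=reference.loc[shared, shared],
        mantel_r=r_obs,
        z_stat=float(z),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed if not exact else None,
    )


def load_reference_correlation(path=None) -> pd.DataFrame:
    """Load a reference clock correlation matrix (square, labeled TSV).

    Without a path, loads the packaged simulation-derived default (intact
    cohort, low noise; see ``synthetic_data.make_reference_correlation``).
    """
    if path is None:
        ref = resources.files("clockscope.data").joinpath("reference_correlation.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1] or not (df.index == df.columns).all():
        raise ValueError("reference correlation matrix must be square with matching labels")
    return df
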