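"""Statistical battery for relating variant counts to branch features.

Spearman rank correlation is computed as the product moment of mid-ranks
(ties averaged); the two-sided p-value uses the large-sample t
approximation. Linear fits are ordinary least squares with an intercept;
the outlier test Bonferroni-adjusts two-sided p-values of externally
studentized residuals against t with n-3 degrees of freedom (simple
regression), reporting at most ``n_max`` observations — the behavior of
the standard regression-outlier test in the R ecosystem. Gene-set
overlaps use the upper-tail hypergeometric probability with
Benjamini–Hochberg adjustment across a batch. The species PCA sums
BLOSUM62 substitution scores over selected alignment sites into a
pairwise similarity matrix and spectrally decomposes it (double-centered
by default, classical-MDS style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from Bio.Align import substitution_matrices
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import OLSInfluence

from .seqio import Level, MultipleAlignment


class UndefinedStatisticError(ValueError):
    """Statistic undefined for the input (e.g. constant vector)."""


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation on mid-ranks with t-approximate p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("rank correlation undefined for constant input")
    rx = sps.rankdata(x)  # mid-ranks for ties
    ry = sps.rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    rho = float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=p, n=n)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    residuals: np.ndarray
    studentized_residuals: np.ndarray  # externally studentized
    n: int


def fit_linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS y ~ x with intercept, adjusted R^2, and studentized residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("x is constant; design matrix singular")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    if res.mse_resid > 1e-12 * max(1.0, float(np.var(y))):
        studentized = np.asarray(OLSInfluence(res).resid_studentized_external)
    else:  # (numerically) perfect fit: no meaningful studentization
        studentized = np.zeros(n)
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        residuals=np.asarray(res.resid),
        studentized_residuals=studentized,
        n=n,
    )


@dataclass
class OutlierReport:
    indices: list[int]           # largest |studentized residual| first
    adjusted_p: list[float]      # Bonferroni-adjusted, aligned with indices
    n_max: int


def bonferroni_outlier_test(
    fit: RegressionFit, n_max: int = 3, alpha: float = 0.05
) -> OutlierReport:
    """Bonferroni outlier test on externally studentized residuals.

    Each observation's two-sided p against t(n-3) is multiplied by n and
    capped at 1; up to ``n_max`` observations with adjusted p < alpha are
    reported, largest |residual| first.
    """
    n = fit.n
    if n <= 3:
        raise ValueError("outlier test needs more than 3 observations")
    r = fit.studentized_residuals
    raw = 2.0 * sps.t.sf(np.abs(r), df=n - 3)
    adj = np.minimum(raw * n, 1.0)
    order = np.argsort(-np.abs(r), kind="stable")
    indices = [int(i) for i in order if adj[i] < alpha][:n_max]
    return OutlierReport(
        indices=indices, adjusted_p=[float(adj[i]) for i in indices], n_max=n_max
    )


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int
    set_a_size: int
    set_b_size: int
    universe: int
    p_value: float
    adjusted_p: Optional[float] = None


def hypergeometric_overlap(
    set_a_size: int, set_b_size: int, overlap: int, universe: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= overlap) for two gene sets."""
    if not (0 <= set_a_size <= universe and 0 <= set_b_size <= universe):
        raise ValueError("set sizes must lie within the universe")
    if not 0 <= overlap <= min(set_a_size, set_b_size):
        raise ValueError("overlap exceeds a set size")
    p = float(sps.hypergeom.sf(overlap - 1, universe, set_a_size, set_b_size))
    return EnrichmentResult(overlap, set_a_size, set_b_size, universe, min(p, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PcaResult:
    species_ids: list[str]
    score_matrix: np.ndarray     # symmetric summed-substitution-score matrix
    eigenvalues: np.ndarray      # descending
    coordinates: np.ndarray      # n_species x n_components (PC1, PC2, ...)


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM62_MIN = float(np.min(np.asarray(_BLOSUM62)))


def _pair_score(a: str, b: str, gap_score: float, x_score: float) -> float:
    if a == "-" or b == "-":
        return gap_score
    if a == "X" or b == "X":
        return x_score
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return x_score


def blosum62_pca(
    aln: MultipleAlignment,
    sites: Sequence[int],
    center: bool = True,
    gap_score: Optional[float] = None,
    x_score: float = 0.0,
) -> PcaResult:
    """Species ordination from summed BLOSUM62 scores over selected sites.

    Pairwise species similarity is the sum of substitution scores over
    the 1-based ``sites``; a gap against anything scores the matrix
    minimum (configurable), ``X`` scores 0. The similarity matrix is
    double-centered (classical MDS; disable with ``center=False``) and
    spectrally decomposed; coordinates are eigenvector * sqrt(eigenvalue)
    over non-negative eigenvalues.
    """
    if aln.level is not Level.AMINO_ACID:
        raise ValueError("PCA operates on amino-acid alignments")
    n = aln.n_species
    if n < 3:
        raise ValueError("need at least 3 species")
    for s in sites:
        if not 1 <= s <= aln.length:
            raise IndexError(f"site {s} outside 1..{aln.length}")
    gap = _BLOSUM62_MIN if gap_score is None else gap_score

    cols = [[row[s - 1] for row in aln.rows] for s in sites]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            total = sum(_pair_score(col[i], col[j], gap, x_score) for col in cols)
            S[i, j] = S[j, i] = total

    M = S
    if center:
        J = np.eye(n) - np.ones((n, n)) / n
        M = J @ S @ J
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = eigvals > 1e-10
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    if coords.shape[1] < 2:  # degenerate: everything at the origin
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
    return PcaResult(
        species_ids=list(aln.species_ids),
        score_matrix=S,
        eigenvalues=eigvals,
        coordinates=coords,
    )
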