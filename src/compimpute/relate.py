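"""VanRaden genomic relationships and the relatedness-accuracy regression.

The genomic relationship matrix is

    G = M M' / sum_i 2 p_i (1 - p_i)

where row entries of the incidence matrix M are 0 - 2p_i, 1 - 2p_i and
2 - 2p_i for genotypes AA, AB and BB, and p_i is the frequency of allele B
at marker i.  Each target animal's maximum relationship to the reference set
summarises how well its haplotypes are represented there; imputation
accuracy is then regressed on that maximum with a quadratic (curvilinear)
ordinary-least-squares fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import MISSING, DataValidationError, GenotypeMatrix
from .panels import Scenario

log = logging.getLogger(__name__)


@dataclass
class GRM:
    """Genomic relationship matrix with the frequencies that built it."""

    matrix: np.ndarray              # (n, n) symmetric
    sample_ids: list[str]
    p_b: np.ndarray                 # allele-B frequency per marker
    freq_source: str
    denominator: float
    n_mean_imputed: int = 0

    def submatrix(self, row_ids, col_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        ri = [lookup[s] for s in row_ids]
        ci = [lookup[s] for s in col_ids]
        return self.matrix[np.ix_(ri, ci)]


def compute_grm(matrix: GenotypeMatrix, freq_source: str = "all_samples",
                frequencies: np.ndarray | None = None,
                reference_ids=None) -> GRM:
    """Build the VanRaden G from genotype codes.

    ``freq_source`` selects the p_i: ``all_samples`` (default), and
    ``reference_only`` / ``supplied`` for sensitivity checks.  Missing
    genotypes are mean-imputed at 2 p_i before centring (counted, logged).
    """
    g = matrix.genotypes.astype(np.float64)
    called = matrix.genotypes != MISSING
    if freq_source == "supplied":
        if frequencies is None:
            raise DataValidationError("freq_source='supplied' needs frequencies")
        p = np.asarray(frequencies, dtype=float)
    elif freq_source == "reference_only":
        if reference_ids is None:
            raise DataValidationError("freq_source='reference_only' needs ids")
        ridx = matrix.sample_index(list(reference_ids))
        p = _freq(matrix.genotypes[ridx], called[ridx])
    elif freq_source == "all_samples":
        p = _freq(matrix.genotypes, called)
    else:
        raise DataValidationError(f"unknown freq_source {freq_source!r}")
    if len(p) != matrix.n_markers:
        raise DataValidationError("frequency vector length mismatch")
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise DataValidationError(
            "all markers monomorphic: VanRaden denominator is zero")
    n_imputed = int((~called).sum())
    if n_imputed:
        log.info("GRM: mean-imputed %d missing genotype(s) at 2p", n_imputed)
    Z = np.where(called, g, 2.0 * p[None, :]) - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    return GRM(G, list(matrix.sample_ids), p, freq_source, denom, n_imputed)


def _freq(g: np.ndarray, called: np.ndarray) -> np.ndarray:
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(n, 1)), 0.0)


def max_relationship(grm: GRM, scenario: Scenario) -> pd.DataFrame:
    """Each target's maximum G entry against the reference animals.

    Returns a frame (target_id, max_relationship); summary statistics via
    :func:`relationship_summary`.
    """
    if not scenario.reference_ids:
        raise DataValidationError("empty reference population")
    sub = grm.submatrix(scenario.target_ids, scenario.reference_ids)
    return pd.DataFrame({"target_id": scenario.target_ids,
                         "max_relationship": sub.max(axis=1)})


def relationship_summary(maxrel: pd.DataFrame) -> dict:
    v = maxrel["max_relationship"]
    return {"min": float(v.min()), "mean": float(v.mean()),
            "max": float(v.max()), "n": int(len(v))}


@dataclass
class RelatednessRegression:
    """Quadratic OLS of per-animal concordance on maximum relationship."""

    coefficients: np.ndarray        # intercept, linear, ..., degree terms
    pvalues: np.ndarray
    fitted: np.ndarray
    centred: bool
    x_mean: float
    model: object                   # statsmodels results, for summaries

    @property
    def linear_coefficient(self) -> float:
        return float(self.coefficients[1])

    @property
    def linear_pvalue(self) -> float:
        return float(self.pvalues[1])


def regress_cr_on_relationship(cr: np.ndarray, maxrel: np.ndarray,
                               degree: int = 2,
                               centre: bool = True) -> RelatednessRegression:
    """Fit CR ~ 1 + x + x² (curvilinear) by ordinary least squares.

    With ``centre=True`` (default) x is mean-centred before forming powers,
    so the linear coefficient is the slope at the mean relatedness — the
    raw x and x² regressors are otherwise near-collinear over the narrow
    observed range.  Coefficient p-values are standard t-tests.
    """
    y = np.asarray(cr, dtype=float)
    x = np.asarray(maxrel, dtype=float)
    if y.shape != x.shape:
        raise DataValidationError("cr and relationship vectors differ in length")
    if len(y) < degree + 2:
        raise DataValidationError(f"need at least {degree + 2} animals")
    if np.ptp(x) == 0:
        raise DataValidationError("maximum relationship is constant")
    x_mean = float(x.mean()) if centre else 0.0
    xc = x - x_mean
    X = np.column_stack([xc ** d for d in range(degree + 1)])
    res = sm.OLS(y, X).fit()
    return RelatednessRegression(np.asarray(res.params), np.asarray(res.pvalues),
                                 np.asarray(res.fittedvalues), centre, x_mean,
                                 res)
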