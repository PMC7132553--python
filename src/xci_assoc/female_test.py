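"""Female ordered-genotype logistic fit and the three component statistics.

The female model ``logit Pr(Y=1) = b0 + b1 G_f1 + b2 G_f2 + b3 G_f1 G_f2`` is
saturated on the four ordered-genotype cells, so without covariates the
maximum-likelihood fit has a closed form in the cell log-odds and the observed
information is analytic (``1/r + 1/s`` per cell).  With covariates the same
model is fitted iteratively.

From a fit we form the three one-sided *step contrasts* implied by the
generalized genetic model's ordered penetrances,

    c1 = b1            (a/a -> A/a: gaining a paternal mutant copy)
    c2 = b1 + b3       (a/A -> A/A: the same step on a mutant maternal background)
    c3 = b1 + b2 + b3  (a/a -> A/A: the homozygote contrast),

each non-negative when penetrances increase in the mutant allele, and whiten
them with the symmetric inverse square root of their estimated covariance.
The whitened components Z1, Z2, Z3 are asymptotically independent standard
normals under the null, which makes Fisher's combination of their one-sided
p-values exactly chi^2 with 6 df, and — because the step-contrast basis maps
onto its own negation under the allele relabeling A <-> a — the right- and
left-sided combinations exchange exactly when the allele labels are swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .genetic_model import FemaleCoefficients
from .genotype_data import GenotypeCounts, IndividualRecord

#: Step contrasts as rows acting on (b1, b2, b3).
STEP_CONTRASTS = np.array([[1.0, 0.0, 0.0],
                           [1.0, 0.0, 1.0],
                           [1.0, 1.0, 1.0]])

#: The same contrasts acting on the four cell log-odds (a/a, a/A, A/a, A/A).
_STEP_CONTRASTS_CELLS = np.array([[-1.0, 0.0, 1.0, 0.0],
                                  [0.0, -1.0, 0.0, 1.0],
                                  [-1.0, 0.0, 0.0, 1.0]])

#: Map from cell log-odds to (b1, b2, b3).
_BETA_FROM_CELLS = np.array([[-1.0, 0.0, 1.0, 0.0],
                             [-1.0, 1.0, 0.0, 0.0],
                             [1.0, -1.0, -1.0, 1.0]])

_PVAL_FLOOR = np.finfo(float).tiny


class DegenerateFitError(ValueError):
    """The female table cannot support a fit (empty cell after correction policy)."""


class FitConvergenceError(RuntimeError):
    """The iterative logistic fit failed (separation or rank deficiency)."""


@dataclass
class FemaleFit:
    """Fitted female model: coefficients with covariance, fit path, diagnostics."""

    coefficients: FemaleCoefficients
    path: Literal["saturated", "glm"]
    converged: bool
    zero_cell_corrected: bool = False


@dataclass
class FemaleComponentStats:
    """Whitened component statistics with one-sided p-values per component."""

    z: np.ndarray            # (3,) whitened Z1, Z2, Z3
    p_right: np.ndarray      # 1 - Phi(Z_i)
    p_left: np.ndarray       # Phi(Z_i)


@dataclass
class FisherCombination:
    """Fisher's combination of three one-sided p-values.

    ``statistic`` is -2 sum log p ~ chi^2_6 under the null; ``z_score`` is the
    normal transform Phi^{-1}(1 - p) of the combination p-value.
    """

    statistic: float
    p_value: float
    z_score: float


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_female_saturated(
    counts: GenotypeCounts,
    zero_cell: Literal["haldane", "error"] = "haldane",
) -> FemaleFit:
    """Closed-form saturated fit from the female 2x4 table.

    Coefficients are contrasts of per-cell log-odds ``log(r_g / s_g)``; the
    covariance of (b1, b2, b3) comes from the per-cell variances ``1/r + 1/s``.
    When any cell is empty, the Haldane-Anscombe correction adds 0.5 to every
    cell of the female table (policy ``"haldane"``, the default) so the closed
    form stays defined; pass ``zero_cell="error"`` to reject such tables.
    """
    r = counts.female_case.astype(float)
    s = counts.female_control.astype(float)
    if counts.r_f == 0 or counts.s_f == 0:
        raise DegenerateFitError("female stratum needs at least one case and one control")
    corrected = False
    if np.any(r == 0) or np.any(s == 0):
        if zero_cell == "error":
            raise DegenerateFitError("empty female cell and zero_cell='error'")
        r = r + 0.5
        s = s + 0.5
        corrected = True
    log_odds = np.log(r / s)
    v = 1.0 / r + 1.0 / s
    beta = _BETA_FROM_CELLS @ log_odds
    cov = _BETA_FROM_CELLS @ np.diag(v) @ _BETA_FROM_CELLS.T
    coef = FemaleCoefficients(b0=float(log_odds[0]), b1=float(beta[0]),
                              b2=float(beta[1]), b3=float(beta[2]), cov=cov)
    return FemaleFit(coefficients=coef, path="saturated", converged=True,
                     zero_cell_corrected=corrected)


def fit_female_glm(records: Sequence[IndividualRecord]) -> FemaleFit:
    """Iteratively-reweighted-least-squares fit of the female model.

    Accepts female records, optionally with covariates; the design is
    ``(1, G_f1, G_f2, G_f1 G_f2, covariates)``.  The coefficient covariance is
    the inverse observed Fisher information.  Raises
    :class:`FitConvergenceError` on separation or rank deficiency, naming the
    offending column.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    females = [rec for rec in records if rec.sex == "F"]
    if not females:
        raise DegenerateFitError("no female records")
    y = np.array([rec.phenotype for rec in females], dtype=float)
    if y.min() == y.max():
        raise DegenerateFitError("female stratum needs at least one case and one control")
    g1 = np.array([rec.genotype.paternal for rec in females], dtype=float)
    g2 = np.array([rec.genotype.maternal for rec in females], dtype=float)
    X = np.column_stack([np.ones_like(g1), g1, g2, g1 * g2])
    names = ["const", "G_f1", "G_f2", "G_f1:G_f2"]
    n_cov = 0 if females[0].covariates is None else len(females[0].covariates)
    if n_cov:
        covs = np.array([rec.covariates for rec in females], dtype=float)
        X = np.column_stack([X, covs])
        names += [f"c{k + 1}" for k in range(n_cov)]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _first_dependent_column(X, names)
        raise FitConvergenceError(f"design matrix is rank deficient (column {bad!r})")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitConvergenceError("logistic fit did not converge (possible separation)")
    params = res.params
    cov = np.asarray(res.cov_params())[1:4, 1:4]
    coef = FemaleCoefficients(b0=float(params[0]), b1=float(params[1]),
                              b2=float(params[2]), b3=float(params[3]), cov=cov)
    return FemaleFit(coefficients=coef, path="glm", converged=True)


def _first_dependent_column(X: np.ndarray, names: list[str]) -> str:
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            return names[j]
    return names[-1]


# ---------------------------------------------------------------------------
# Component statistics and Fisher combinations
# ---------------------------------------------------------------------------

def female_components(fit: FemaleFit) -> FemaleComponentStats:
    """Whitened step-contrast statistics Z1, Z2, Z3 from a converged fit."""
    if not fit.converged:
        raise FitConvergenceError("cannot form components from a non-converged fit")
    if fit.coefficients.cov is None:
        raise ValueError("fit carries no coefficient covariance")
    c = STEP_CONTRASTS @ fit.coefficients.effects
    S = STEP_CONTRASTS @ fit.coefficients.cov @ STEP_CONTRASTS.T
    w, V = np.linalg.eigh(S)
    if np.any(w <= 0):
        raise DegenerateFitError("contrast covariance is singular (zero-variance component)")
    z = (V * (1.0 / np.sqrt(w))) @ (V.T @ c)
    return FemaleComponentStats(z=z, p_right=stats.norm.sf(z), p_left=stats.norm.cdf(z))


def _fisher(p: np.ndarray) -> FisherCombination:
    clipped = np.clip(p, _PVAL_FLOOR, 1.0)
    if np.any(p < _PVAL_FLOOR):
        warnings.warn("component p-value underflow clamped to the smallest positive "
                      "double", RuntimeWarning, stacklevel=3)
    statistic = float(-2.0 * np.sum(np.log(clipped)))
    p_value = float(stats.chi2.sf(statistic, df=6))
    z_score = float(stats.norm.isf(np.clip(p_value, 1e-300, 1 - 1e-16)))
    return FisherCombination(statistic=statistic, p_value=p_value, z_score=z_score)


def fisher_right(components: FemaleComponentStats) -> FisherCombination:
    """Fisher combination of the right-sided component p-values (mutant allele A)."""
    return _fisher(components.p_right)


def fisher_left(components: FemaleComponentStats) -> FisherCombination:
    """Fisher combination of the left-sided component p-values (mutant allele a)."""
    return _fisher(components.p_left)


# ---------------------------------------------------------------------------
# Vectorized batch path (Monte-Carlo engine)
# ---------------------------------------------------------------------------

def female_components_batch(
    female_case: np.ndarray, female_control: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Whitened component statistics for stacked count tables.

    ``female_case``/``female_control`` are (reps, 4) arrays.  Applies the
    all-cell Haldane-Anscombe correction to replicates with any empty cell.
    Returns ``(Z (reps, 3), corrected (reps,) bool)``.
    """
    r = np.asarray(female_case, dtype=float)
    s = np.asarray(female_control, dtype=float)
    corrected = ((r == 0) | (s == 0)).any(axis=1)
    if corrected.any():
        r = r.copy(); s = s.copy()
        r[corrected] += 0.5
        s[corrected] += 0.5
    log_odds = np.log(r / s)
    v = 1.0 / r + 1.0 / s
    c = log_odds @ _STEP_CONTRASTS_CELLS.T
    S = np.einsum("ik,rk,jk->rij", _STEP_CONTRASTS_CELLS, v, _STEP_CONTRASTS_CELLS)
    w, V = np.linalg.eigh(S)
    inv_sqrt = np.einsum("rik,rk,rjk->rij", V, 1.0 / np.sqrt(w), V)
    z = np.einsum("rij,rj->ri", inv_sqrt, c)
    return z, corrected


def fisher_batch(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right- and left-sided Fisher chi^2_6 statistics for stacked Z arrays."""
    p_right = np.clip(stats.norm.sf(z), _PVAL_FLOOR, 1.0)
    p_left = np.clip(stats.norm.cdf(z), _PVAL_FLOOR, 1.0)
    return (-2.0 * np.log(p_right).sum(axis=1),
            -2.0 * np.log(p_left).sum(axis=1))
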