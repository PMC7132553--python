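"""Male component statistic Z_m.

Males are hemizygous, so the male logistic model reduces to a comparison of
mutant-allele frequencies between cases and controls.  Without covariates the
Wald statistic simplifies to the pooled-variance two-sample proportion
statistic, standard normal under the null; with covariates the logistic Wald
statistic is used.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .genotype_data import GenotypeCounts, IndividualRecord


class MaleFitError(RuntimeError):
    """The male logistic fit failed (separation or rank deficiency)."""


def male_z_counts(counts: GenotypeCounts) -> float:
    """Closed-form male statistic from the 2x2 male count table.

    ``Z_m = (p_case - p_control) / sqrt(p (1 - p) (1/r_m + 1/s_m))`` with the
    pooled mutant-allele frequency ``p``.  A monomorphic male stratum carries
    no information; it yields ``Z_m = 0`` with a warning.
    """
    r_m, s_m = counts.r_m, counts.s_m
    if r_m == 0 or s_m == 0:
        raise ValueError("male stratum needs at least one case and one control")
    p_case = counts.male_case[1] / r_m
    p_control = counts.male_control[1] / s_m
    pooled = (counts.male_case[1] + counts.male_control[1]) / (r_m + s_m)
    if pooled in (0.0, 1.0):
        warnings.warn("monomorphic male stratum: Z_m set to 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / r_m + 1 / s_m))
    return float((p_case - p_control) / se)


def fit_male_glm(records: Sequence[IndividualRecord]) -> float:
    """Wald statistic of the allele coefficient in the male logistic model.

    Design is ``(1, G_m, covariates)``.  Asymptotically equivalent to
    :func:`male_z_counts` without covariates.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    males = [rec for rec in records if rec.sex == "M"]
    if not males:
        raise ValueError("no male records")
    y = np.array([rec.phenotype for rec in males], dtype=float)
    if y.min() == y.max():
        raise ValueError("male stratum needs at least one case and one control")
    g = np.array([rec.genotype.allele for rec in males], dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    if males[0].covariates is not None:
        X = np.column_stack([X, np.array([rec.covariates for rec in males], dtype=float)])
    if g.min() == g.max():
        warnings.warn("monomorphic male stratum: Z_m set to 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MaleFitError("male design matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise MaleFitError(f"male logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise MaleFitError("male logistic fit did not converge (possible separation)")
    return float(res.params[1] / res.bse[1])


def male_z_batch(
    male_case: np.ndarray, male_control: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`male_z_counts` for stacked (reps, 2) male count arrays.

    Monomorphic replicates yield 0.
    """
    mc = np.asarray(male_case, dtype=float)
    ms = np.asarray(male_control, dtype=float)
    r_m = mc.sum(axis=1)
    s_m = ms.sum(axis=1)
    if np.any(r_m == 0) or np.any(s_m == 0):
        raise ValueError("male stratum needs at least one case and one control")
    p_case = mc[:, 1] / r_m
    p_control = ms[:, 1] / s_m
    pooled = (mc[:, 1] + ms[:, 1]) / (r_m + s_m)
    var = pooled * (1 - pooled) * (1 / r_m + 1 / s_m)
    ok = var > 0
    z = np.zeros(mc.shape[0])
    z[ok] = (p_case[ok] - p_control[ok]) / np.sqrt(var[ok])
    return z
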