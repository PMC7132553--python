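"""Competitor X-chromosome association tests.

Reference implementations of the tests the Monte-Carlo comparison is run
against, built from the cited originals' standard definitions:

* allele-based tests ``Z_A`` and ``Z_mfA`` (assume Hardy-Weinberg equilibrium
  in females) and genotype-based trend tests ``Z_C`` and ``Z_mfG`` (robust to
  departures from it), the latter pair with female dose 0/1/2 and male dose
  0/1;
* Clayton's score tests ``T_A`` (1 df) and ``T_AD`` (2 df), which code
  homozygous females and hemizygous males identically (female 0/1/2, male
  0/2) to reflect random X-inactivation;
* the sex-stratified allele test ``S_A`` (chi^2 with 2 df);
* the XWAS logistic-regression tests ``FM_01``, ``FM_02`` (male dose 0/1 or
  0/2, sex as covariate) and the sex-stratified Fisher combination ``FM_F``;
* ``Xcat``, a robust categorical test under the generalized genetic model
  (unordered female genotypes, one-sided step contrasts combined with the
  male statistic by Fisher's method, right/left maximized);
* ``Z_max``, the maximum of the trend statistics under the three dosage
  compensation codings of the female heterozygote (0, 1 or 2 against male
  0/2), with its p-value from the joint trivariate normal null.

These comparators are validated qualitatively (null size, known inflation
patterns, power ordering); they are not byte-compatible reimplementations of
the original software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .genotype_data import GenotypeCounts

_PVAL_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class ComparatorResult:
    """Statistic and p-value of one comparator test."""

    name: str
    statistic: float
    p_value: float
    df: Optional[int] = None


def _two_sided_normal(name: str, z: float) -> ComparatorResult:
    return ComparatorResult(name=name, statistic=float(z),
                            p_value=float(2 * stats.norm.sf(abs(z))))


def _monomorphic(counts: GenotypeCounts) -> bool:
    total_a = (counts.female_case[1:3].sum() + counts.female_control[1:3].sum()
               + 2 * (counts.female_case[3] + counts.female_control[3])
               + counts.male_case[1] + counts.male_control[1])
    total_alleles = 2 * counts.n_f + counts.n_m
    return total_a == 0 or total_a == total_alleles


def _proportion_z(x1: float, n1: float, x0: float, n0: float) -> float:
    """Pooled-variance two-sample proportion statistic; 0 when degenerate."""
    if n1 == 0 or n0 == 0:
        return 0.0
    pooled = (x1 + x0) / (n1 + n0)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n0)
    if var <= 0:
        return 0.0
    return float((x1 / n1 - x0 / n0) / np.sqrt(var))


def _trend_z(case: np.ndarray, control: np.ndarray, scores: np.ndarray) -> float:
    """Two-sample trend statistic with pooled score variance; 0 when degenerate."""
    n_r, n_s = case.sum(), control.sum()
    if n_r == 0 or n_s == 0:
        return 0.0
    total = case + control
    n = total.sum()
    mean = (total @ scores) / n
    var = (total @ scores**2) / n - mean**2
    denom = var * (1 / n_r + 1 / n_s)
    if denom <= 0:
        return 0.0
    return float(((case @ scores) / n_r - (control @ scores) / n_s) / np.sqrt(denom))


def _female_unordered(counts: GenotypeCounts) -> tuple[np.ndarray, np.ndarray]:
    """Collapse ordered female cells to unordered (a/a, het, A/A) counts."""
    def collapse(row: np.ndarray) -> np.ndarray:
        return np.array([row[0], row[1] + row[2], row[3]], dtype=float)

    return collapse(counts.female_case), collapse(counts.female_control)


def _allele_counts(counts: GenotypeCounts, sex: str) -> tuple[float, float, float, float]:
    """(A alleles, total alleles) for cases and controls of one sex."""
    if sex == "F":
        ca, ct = _female_unordered(counts)
        return ca[1] + 2 * ca[2], 2 * ca.sum(), ct[1] + 2 * ct[2], 2 * ct.sum()
    return (float(counts.male_case[1]), float(counts.r_m),
            float(counts.male_control[1]), float(counts.s_m))


def _stratified_combine(z_f: float, z_m: float, n_f: int, n_m: int) -> float:
    return float((n_f * z_f + n_m * z_m) / np.hypot(n_f, n_m))


def _warn_if_monomorphic(counts: GenotypeCounts, name: str) -> None:
    if _monomorphic(counts):
        warnings.warn(f"{name}: monomorphic input carries no information",
                      RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Allele- and genotype-based tests (Zheng-style) and the stratified S_A
# ---------------------------------------------------------------------------

def z_a(counts: GenotypeCounts) -> ComparatorResult:
    """Pooled allele-count test (females contribute two alleles, males one)."""
    _warn_if_monomorphic(counts, "Z_A")
    fa1, fn1, fa0, fn0 = _allele_counts(counts, "F")
    ma1, mn1, ma0, mn0 = _allele_counts(counts, "M")
    z = _proportion_z(fa1 + ma1, fn1 + mn1, fa0 + ma0, fn0 + mn0)
    return _two_sided_normal("Z_A", z)


def z_c(counts: GenotypeCounts) -> ComparatorResult:
    """Pooled genotype trend test, female dose 0/1/2 and male dose 0/1."""
    _warn_if_monomorphic(counts, "Z_C")
    ca, ct = _female_unordered(counts)
    case = np.concatenate([ca, counts.male_case.astype(float)])
    control = np.concatenate([ct, counts.male_control.astype(float)])
    scores = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
    return _two_sided_normal("Z_C", _trend_z(case, control, scores))


def z_mfa(counts: GenotypeCounts) -> ComparatorResult:
    """Sex-stratified allele test, strata weighted by sample size."""
    _warn_if_monomorphic(counts, "Z_mfA")
    z_f = _proportion_z(*_allele_counts(counts, "F"))
    z_m = _proportion_z(*_allele_counts(counts, "M"))
    return _two_sided_normal("Z_mfA", _stratified_combine(z_f, z_m, counts.n_f, counts.n_m))


def z_mfg(counts: GenotypeCounts) -> ComparatorResult:
    """Sex-stratified genotype trend test (female dose 0/1/2, male 0/1)."""
    _warn_if_monomorphic(counts, "Z_mfG")
    ca, ct = _female_unordered(counts)
    z_f = _trend_z(ca, ct, np.array([0.0, 1.0, 2.0]))
    z_m = _trend_z(counts.male_case.astype(float), counts.male_control.astype(float),
                   np.array([0.0, 1.0]))
    return _two_sided_normal("Z_mfG", _stratified_combine(z_f, z_m, counts.n_f, counts.n_m))


def stratified_sa(counts: GenotypeCounts) -> ComparatorResult:
    """Sex-stratified allele test S_A: sum of squared per-sex statistics, chi^2_2."""
    _warn_if_monomorphic(counts, "S_A")
    z_f = _proportion_z(*_allele_counts(counts, "F"))
    z_m = _proportion_z(*_allele_counts(counts, "M"))
    s = z_f**2 + z_m**2
    return ComparatorResult("S_A", float(s), float(stats.chi2.sf(s, df=2)), df=2)


# ---------------------------------------------------------------------------
# Clayton's score tests
# ---------------------------------------------------------------------------

def _score_test(case: np.ndarray, control: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Multi-df score test of association between affection and score columns.

    ``case``/``control`` are cell counts, ``X`` the (cells, k) score matrix.
    Returns the chi^2 statistic and df.
    """
    n_r, n_s = case.sum(), control.sum()
    n = n_r + n_s
    total = case + control
    xbar = (total @ X) / n
    Xc = X - xbar
    U = case @ Xc
    V = (n_r * n_s / n**2) * (Xc.T * total) @ Xc  # hypergeometric-style null covariance
    V = np.atleast_2d(V)
    rank = np.linalg.matrix_rank(V, tol=1e-12)
    stat = float(U @ np.linalg.pinv(V) @ U)
    return stat, rank


_CLAYTON_CELLS_X = np.array([0.0, 1.0, 2.0, 0.0, 2.0])  # aa, het, AA, a, A
_CLAYTON_HET = np.array([0.0, 1.0, 0.0, 0.0, 0.0])


def _pooled_cells(counts: GenotypeCounts) -> tuple[np.ndarray, np.ndarray]:
    ca, ct = _female_unordered(counts)
    return (np.concatenate([ca, counts.male_case.astype(float)]),
            np.concatenate([ct, counts.male_control.astype(float)]))


def clayton_ta(counts: GenotypeCounts) -> ComparatorResult:
    """Clayton's 1-df score test with female dose 0/1/2 and male dose 0/2."""
    _warn_if_monomorphic(counts, "T_A")
    case, control = _pooled_cells(counts)
    z = _trend_z(case, control, _CLAYTON_CELLS_X)
    return _two_sided_normal("T_A", z)


def clayton_tad(counts: GenotypeCounts) -> ComparatorResult:
    """Clayton's 2-df score test adding the female dominance contrast."""
    _warn_if_monomorphic(counts, "T_AD")
    case, control = _pooled_cells(counts)
    X = np.column_stack([_CLAYTON_CELLS_X, _CLAYTON_HET])
    stat, df = _score_test(case, control, X)
    return ComparatorResult("T_AD", stat, float(stats.chi2.sf(stat, df=df)), df=df)


# ---------------------------------------------------------------------------
# XWAS-style logistic regressions
# ---------------------------------------------------------------------------

def _fm_wald(counts: GenotypeCounts, male_dose: float, name: str) -> ComparatorResult:
    """Wald test of the dose coefficient in y ~ dose + sex, fit on cell weights."""
    import statsmodels.api as sm

    # rows: female aa/het/AA then male a/A, for cases (y=1) and controls (y=0)
    ca, ct = _female_unordered(counts)
    doses = [0.0, 1.0, 2.0, 0.0, male_dose]
    sexes = [0.0, 0.0, 0.0, 1.0, 1.0]
    ys, Xs, ws = [], [], []
    for y, cells in ((1.0, np.concatenate([ca, counts.male_case])),
                     (0.0, np.concatenate([ct, counts.male_control]))):
        for dose, sex, w in zip(doses, sexes, cells):
            if w > 0:
                ys.append(y)
                Xs.append([1.0, dose, sex])
                ws.append(float(w))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(np.array(ys), np.array(Xs), family=sm.families.Binomial(),
                     freq_weights=np.array(ws)).fit()
    z = float(res.params[1] / res.bse[1])
    return _two_sided_normal(name, z)


def fm_01(counts: GenotypeCounts) -> ComparatorResult:
    """XWAS FM_01: logistic regression with male genotype coded 0/1."""
    _warn_if_monomorphic(counts, "FM_01")
    return _fm_wald(counts, male_dose=1.0, name="FM_01")


def fm_02(counts: GenotypeCounts) -> ComparatorResult:
    """XWAS FM_02: logistic regression with male genotype coded 0/2."""
    _warn_if_monomorphic(counts, "FM_02")
    return _fm_wald(counts, male_dose=2.0, name="FM_02")


def fm_f(counts: GenotypeCounts) -> ComparatorResult:
    """XWAS FM_F: Fisher combination of sex-stratified two-sided p-values, chi^2_4."""
    _warn_if_monomorphic(counts, "FM_F")
    ca, ct = _female_unordered(counts)
    z_f = _trend_z(ca, ct, np.array([0.0, 1.0, 2.0]))
    z_m = _trend_z(counts.male_case.astype(float), counts.male_control.astype(float),
                   np.array([0.0, 1.0]))
    p_f = max(2 * stats.norm.sf(abs(z_f)), _PVAL_FLOOR)
    p_m = max(2 * stats.norm.sf(abs(z_m)), _PVAL_FLOOR)
    stat = -2.0 * (np.log(p_f) + np.log(p_m))
    return ComparatorResult("FM_F", float(stat), float(stats.chi2.sf(stat, df=4)), df=4)


# ---------------------------------------------------------------------------
# Xcat and Z_max
# ---------------------------------------------------------------------------

def xcat(counts: GenotypeCounts) -> ComparatorResult:
    """Robust categorical test under the generalized genetic model.

    Female statistics are the standardized unordered step contrasts (het vs
    a/a and A/A vs het in cell log-odds, Haldane-Anscombe corrected when a
    cell is empty); with the male statistic they are combined by Fisher's
    method (chi^2 with 6 df) using right- and left-sided p-values, and the
    larger combination is reported with the doubled-tail bound.
    """
    _warn_if_monomorphic(counts, "Xcat")
    ca, ct = _female_unordered(counts)
    if np.any(ca == 0) or np.any(ct == 0):
        ca = ca + 0.5
        ct = ct + 0.5
    log_odds = np.log(ca / ct)
    v = 1.0 / ca + 1.0 / ct
    z_f1 = (log_odds[1] - log_odds[0]) / np.sqrt(v[1] + v[0])
    z_f2 = (log_odds[2] - log_odds[1]) / np.sqrt(v[2] + v[1])
    z_m = _proportion_z(counts.male_case[1], counts.r_m,
                        counts.male_control[1], counts.s_m)
    z = np.array([z_f1, z_f2, z_m])
    f_r = -2.0 * np.sum(np.log(np.clip(stats.norm.sf(z), _PVAL_FLOOR, 1.0)))
    f_l = -2.0 * np.sum(np.log(np.clip(stats.norm.cdf(z), _PVAL_FLOOR, 1.0)))
    stat = float(max(f_r, f_l))
    p = min(1.0, 2.0 * float(stats.chi2.sf(stat, df=6)))
    return ComparatorResult("Xcat", stat, p, df=6)


def zmax(counts: GenotypeCounts) -> ComparatorResult:
    """Maximum trend statistic over the three dosage compensation codings.

    The female heterozygote is coded 0, 1 or 2 (mutant copy silenced, random
    inactivation, mutant copy active) against female homozygote/male codes
    0 and 2; the p-value is the exceedance probability of max |Z| under the
    joint normal null with correlations estimated from the pooled genotype
    distribution.  The three codings are ``s_0 + gamma * het``, so the joint
    law is a rank-2 Gaussian and the box probability reduces to a
    one-dimensional integral over intersected slabs.
    """
    _warn_if_monomorphic(counts, "Z_max")
    case, control = _pooled_cells(counts)
    total = case + control
    n = total.sum()
    gammas = (0.0, 1.0, 2.0)
    score_sets = [np.array([0.0, het, 2.0, 0.0, 2.0]) for het in gammas]
    zs = np.array([_trend_z(case, control, sc) for sc in score_sets])
    m = float(np.abs(zs).max())
    # pooled moments of the base coding and the female het indicator
    probs = total / n
    s0 = score_sets[0]
    het = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    mu0, muh = probs @ s0, probs @ het
    var0 = probs @ (s0 - mu0) ** 2
    varh = probs @ (het - muh) ** 2
    cov0h = probs @ ((s0 - mu0) * (het - muh))
    if var0 <= 0:
        return ComparatorResult("Z_max", 0.0, 1.0)
    # Z_gamma = (U0 + gamma Uh) / sd_gamma with (U0, Uh) = Cholesky (X, Y)
    resid = max(varh - cov0h**2 / var0, 0.0)
    alphas = np.sqrt(var0) + np.array(gammas) * cov0h / np.sqrt(var0)
    betas = np.array(gammas) * np.sqrt(resid)
    sds = np.sqrt(var0 + 2 * np.array(gammas) * cov0h + np.array(gammas) ** 2 * varh)
    x = np.linspace(-8.0, 8.0, 1601)
    lo = np.full_like(x, -np.inf)
    hi = np.full_like(x, np.inf)
    feasible = np.ones_like(x, dtype=bool)
    for a, b, sd in zip(alphas, betas, sds):
        bound = m * sd
        if abs(b) < 1e-14:
            feasible &= np.abs(a * x) <= bound
        else:
            l1 = (-bound - a * x) / b
            l2 = (bound - a * x) / b
            lo = np.maximum(lo, np.minimum(l1, l2))
            hi = np.minimum(hi, np.maximum(l1, l2))
    length = np.where(feasible, np.clip(stats.norm.cdf(hi) - stats.norm.cdf(lo), 0, 1), 0.0)
    inside = float(np.trapezoid(stats.norm.pdf(x) * length, x))
    p = min(1.0, max(0.0, 1.0 - inside))
    return ComparatorResult("Z_max", m, p)


def zxcii_comparator(counts: GenotypeCounts) -> ComparatorResult:
    """The package's own test in comparator form (for method tables)."""
    from .combine import zxcii_test

    res = zxcii_test(counts)
    return ComparatorResult("Z_XCII", res.statistic, res.p_value)


#: Registry of all tests by CLI name.
METHODS: dict[str, Callable[[GenotypeCounts], ComparatorResult]] = {
    "zxcii": zxcii_comparator,
    "zmax": zmax,
    "xcat": xcat,
    "sa": stratified_sa,
    "fm02": fm_02,
    "zc": z_c,
    "zmfg": z_mfg,
    "ta": clayton_ta,
    "tad": clayton_tad,
    "fm01": fm_01,
    "fmf": fm_f,
    "zmfa": z_mfa,
    "za": z_a,
}
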