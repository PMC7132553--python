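"""Penetrance / regression-coefficient conversions, XCI degree and imprinting measure.

The female ordered-genotype logistic model is

    logit Pr(Y=1 | G_f1, G_f2) = beta_f0 + beta_f1 G_f1 + beta_f2 G_f2
                                 + beta_f3 G_f1 G_f2,

where G_f1 (G_f2) counts the mutant allele A on the paternal (maternal) X.
The model is saturated on the four ordered genotypes, so the coefficients are
logit contrasts of the penetrances against the a/a baseline.  Two scalar
summaries interpret a coefficient set:

* the X-inactivation degree ``gamma = (b1 + b2) / (b1 + b2 + b3)``, on [0, 2]
  under the generalized genetic model — 2 for a mutant allele active in all
  cells (dominant-like), 1 for random inactivation (additive), 0 for a fully
  silenced mutant (recessive-like);
* the imprinting measure ``b2 - b1`` — zero without parent-of-origin effects,
  positive when the maternally inherited copy carries the larger effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit


class UndefinedGammaError(ZeroDivisionError):
    """The XCI degree is undefined: the homozygote effect b1 + b2 + b3 is zero."""


@dataclass(frozen=True)
class PenetranceSet:
    """The six penetrances: female a/a, a/A, A/a, A/A and male a, A."""

    f0: float
    f01: float
    f10: float
    f2: float
    m0: float
    m1: float

    def __post_init__(self) -> None:
        for name, val in self.as_dict().items():
            if not 0.0 < val < 1.0:
                raise ValueError(f"penetrance {name}={val} must lie strictly in (0, 1)")

    def as_dict(self) -> dict[str, float]:
        return {"f0": self.f0, "f01": self.f01, "f10": self.f10,
                "f2": self.f2, "m0": self.m0, "m1": self.m1}

    @property
    def female(self) -> np.ndarray:
        """Female penetrances in cell order (a/a, a/A, A/a, A/A)."""
        return np.array([self.f0, self.f01, self.f10, self.f2])

    @property
    def male(self) -> np.ndarray:
        return np.array([self.m0, self.m1])

    def is_generalized_model(self) -> bool:
        """Ordered penetrances: monotone from a/a through both heterozygotes to A/A."""
        inc = self.f0 <= min(self.f01, self.f10) and max(self.f01, self.f10) <= self.f2
        dec = self.f0 >= max(self.f01, self.f10) and min(self.f01, self.f10) >= self.f2
        return inc or dec


@dataclass(frozen=True)
class FemaleCoefficients:
    """Coefficients of the female ordered-genotype logistic model.

    ``cov`` is the (optional) 3x3 covariance of (b1, b2, b3).
    """

    b0: float
    b1: float
    b2: float
    b3: float
    cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for val in (self.b0, self.b1, self.b2, self.b3):
            if not np.isfinite(val):
                raise ValueError("coefficients must be finite")
        if self.cov is not None:
            cov = np.asarray(self.cov, dtype=float)
            if cov.shape != (3, 3):
                raise ValueError("cov must be 3x3")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("cov must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) < -1e-10):
                raise ValueError("cov must be positive semi-definite")
            object.__setattr__(self, "cov", cov)

    @property
    def effects(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3])


@dataclass(frozen=True)
class MaleCoefficients:
    """Coefficients of the male logistic model: intercept, allele effect, its SE."""

    b0: float
    bm: float
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.b0) and np.isfinite(self.bm)):
            raise ValueError("coefficients must be finite")


def penetrance_to_coefficients(
    p: PenetranceSet,
) -> tuple[FemaleCoefficients, MaleCoefficients]:
    """Convert penetrances to logistic coefficients (logit contrasts vs baseline).

    ``b1`` is the paternal-allele effect (A/a vs a/a), ``b2`` the maternal one
    (a/A vs a/a) and ``b3`` the interaction completing the A/A cell.
    """
    b0 = float(logit(p.f0))
    b1 = float(logit(p.f10) - logit(p.f0))
    b2 = float(logit(p.f01) - logit(p.f0))
    b3 = float(logit(p.f2) - logit(p.f0)) - b1 - b2
    bm0 = float(logit(p.m0))
    bm = float(logit(p.m1) - logit(p.m0))
    return FemaleCoefficients(b0, b1, b2, b3), MaleCoefficients(bm0, bm)


def coefficients_to_penetrances(
    female: FemaleCoefficients, male: MaleCoefficients
) -> PenetranceSet:
    """Exact inverse of :func:`penetrance_to_coefficients`."""
    return PenetranceSet(
        f0=float(expit(female.b0)),
        f01=float(expit(female.b0 + female.b2)),
        f10=float(expit(female.b0 + female.b1)),
        f2=float(expit(female.b0 + female.b1 + female.b2 + female.b3)),
        m0=float(expit(male.b0)),
        m1=float(expit(male.b0 + male.bm)),
    )


def xci_degree(c: FemaleCoefficients) -> float:
    """Degree of X-inactivation, gamma = (b1 + b2) / (b1 + b2 + b3).

    Raises :class:`UndefinedGammaError` when the homozygote effect
    ``b1 + b2 + b3`` vanishes (no overall genotype effect to calibrate against).
    """
    den = c.b1 + c.b2 + c.b3
    if den == 0.0:
        raise UndefinedGammaError("b1 + b2 + b3 = 0: XCI degree undefined")
    return (c.b1 + c.b2) / den


def imprinting_measure(c: FemaleCoefficients) -> float:
    """Parent-of-origin effect measure ``b2 - b1``.

    Zero means no parent-of-origin effect; positive means the maternal copy
    carries the larger effect (paternal-imprinting direction).
    """
    return c.b2 - c.b1
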