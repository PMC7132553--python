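"""Assembly of the sex-combined statistics Z^R, Z^L and the robust test Z_XCII.

The female Fisher combination is transformed to a normal score and combined
with the male statistic by sample-size weighting,

    Z^R = (n_f z_f^R + n_m Z_m) / sqrt(n_f^2 + n_m^2)
    Z^L = (n_f z_f^L - n_m Z_m) / sqrt(n_f^2 + n_m^2),

each standard normal under the overall null.  Z^R is sensitive when the mutant
allele is A (all components pushed right), Z^L when it is a (components pushed
left, males with a negative allele effect — hence the minus sign).  When the
mutant allele is unknown the test statistic is ``Z_XCII = max(Z^L, Z^R)``; as
-Z^L and Z^R are non-decreasing functions of the independent components
(Z1, Z2, Z3, Z_m), the positive-dependence bound gives the conservative
approximate p-value ``min(1, 2 (1 - Phi(Z_XCII)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .female_test import (
    FemaleComponentStats,
    FemaleFit,
    FisherCombination,
    female_components,
    fisher_left,
    fisher_right,
    fit_female_glm,
    fit_female_saturated,
)
from .genotype_data import GenotypeCounts, IndividualRecord, aggregate
from .male_test import fit_male_glm, male_z_counts

_NORM_CLIP = (1e-300, 1.0 - 1e-16)

Alternative = Literal["two-sided", "right", "left"]


@dataclass
class TestResult:
    """Full breakdown of one Z_XCII test."""

    statistic: float
    p_value: float
    z_right: float
    z_left: float
    alternative: Alternative
    n_f: int
    n_m: int
    z_components: Optional[np.ndarray] = None   # female Z1, Z2, Z3
    z_m: Optional[float] = None
    fisher_right: Optional[FisherCombination] = None
    fisher_left: Optional[FisherCombination] = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def fisher_dict(f: Optional[FisherCombination]) -> Optional[dict]:
            if f is None:
                return None
            return {"statistic": f.statistic, "p_value": f.p_value, "z_score": f.z_score}

        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "z_right": self.z_right,
            "z_left": self.z_left,
            "alternative": self.alternative,
            "n_f": self.n_f,
            "n_m": self.n_m,
            "z_components": None if self.z_components is None else list(map(float, self.z_components)),
            "z_m": self.z_m,
            "fisher_right": fisher_dict(self.fisher_right),
            "fisher_left": fisher_dict(self.fisher_left),
            "diagnostics": self.diagnostics,
        }


def combine_right(fisher_right_z: float, z_m: float, n_f: int, n_m: int) -> float:
    """Sample-size-weighted combination Z^R of the female score and Z_m.

    The ``sqrt(n_f^2 + n_m^2)`` normalization is the unique scaling under
    which proportional weighting of two independent standard normals is again
    standard normal.  An empty stratum collapses the weight onto the other
    component exactly.
    """
    if n_f < 0 or n_m < 0 or n_f + n_m == 0:
        raise ValueError("need a positive total sample size")
    return float((n_f * fisher_right_z + n_m * z_m) / np.hypot(n_f, n_m))


def combine_left(fisher_left_z: float, z_m: float, n_f: int, n_m: int) -> float:
    """Sample-size-weighted combination Z^L, with Z_m entering negatively.

    The mutant-allele-a alternative pushes the male allele effect negative, so
    -Z_m is the male evidence in that direction.
    """
    if n_f < 0 or n_m < 0 or n_f + n_m == 0:
        raise ValueError("need a positive total sample size")
    return float((n_f * fisher_left_z - n_m * z_m) / np.hypot(n_f, n_m))


def zxcii(z_left: float, z_right: float) -> tuple[float, float]:
    """The robust statistic ``max(Z^L, Z^R)`` and its bounded p-value ``2 xi``."""
    statistic = max(z_left, z_right)
    p = min(1.0, 2.0 * float(stats.norm.sf(statistic)))
    return statistic, p


def zxcii_test(
    data: Union[GenotypeCounts, Sequence[IndividualRecord]],
    alternative: Alternative = "two-sided",
) -> TestResult:
    """End-to-end Z_XCII test from a count table or per-individual records.

    A :class:`GenotypeCounts` input takes the closed-form saturated path;
    a record list takes the regression path (and supports covariates).
    With ``alternative="right"`` (``"left"``) the one-sided p-value of Z^R
    (Z^L) is reported instead, for a mutant allele known to be A (a).
    """
    diagnostics: dict = {}
    if isinstance(data, GenotypeCounts):
        counts = data
        records = None
    else:
        records = list(data)
        counts = aggregate(records)

    n_f, n_m = counts.n_f, counts.n_m
    has_f = counts.r_f > 0 and counts.s_f > 0
    has_m = counts.r_m > 0 and counts.s_m > 0
    if not (has_f or has_m):
        raise ValueError("need at least one sex stratum with both cases and controls")

    comp: Optional[FemaleComponentStats] = None
    f_right: Optional[FisherCombination] = None
    f_left: Optional[FisherCombination] = None
    z_m: Optional[float] = None

    if has_f:
        try:
            if records is None:
                fit: FemaleFit = fit_female_saturated(counts)
            else:
                fit = fit_female_glm(records)
        except Exception as exc:
            raise type(exc)(f"female stage: {exc}") from exc
        comp = female_components(fit)
        f_right = fisher_right(comp)
        f_left = fisher_left(comp)
        diagnostics["female_path"] = fit.path
        diagnostics["zero_cell_corrected"] = fit.zero_cell_corrected
    if has_m:
        try:
            if records is None:
                z_m = male_z_counts(counts)
            else:
                z_m = fit_male_glm(records)
        except Exception as exc:
            raise type(exc)(f"male stage: {exc}") from exc
        diagnostics["male_path"] = "counts" if records is None else "glm"

    zf_r = f_right.z_score if f_right is not None else 0.0
    zf_l = f_left.z_score if f_left is not None else 0.0
    w_f = n_f if has_f else 0
    w_m = n_m if has_m else 0
    z_right = combine_right(zf_r, z_m or 0.0, w_f, w_m)
    z_left = combine_left(zf_l, z_m or 0.0, w_f, w_m)

    statistic, p_two = zxcii(z_left, z_right)
    if alternative == "two-sided":
        stat_out, p_out = statistic, p_two
    elif alternative == "right":
        stat_out, p_out = z_right, float(stats.norm.sf(z_right))
    elif alternative == "left":
        stat_out, p_out = z_left, float(stats.norm.sf(z_left))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return TestResult(
        statistic=stat_out,
        p_value=p_out,
        z_right=z_right,
        z_left=z_left,
        alternative=alternative,
        n_f=n_f,
        n_m=n_m,
        z_components=None if comp is None else comp.z,
        z_m=z_m,
        fisher_right=f_right,
        fisher_left=f_left,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Vectorized batch path
# ---------------------------------------------------------------------------

def zxcii_batch(
    female_case: np.ndarray,
    female_control: np.ndarray,
    male_case: np.ndarray,
    male_control: np.ndarray,
) -> np.ndarray:
    """Two-sided Z_XCII p-values for stacked count tables (Monte-Carlo engine)."""
    from .female_test import female_components_batch, fisher_batch
    from .male_test import male_z_batch

    z, _ = female_components_batch(female_case, female_control)
    fr, fl = fisher_batch(z)
    z_m = male_z_batch(male_case, male_control)
    n_f = np.asarray(female_case).sum(axis=1) + np.asarray(female_control).sum(axis=1)
    n_m = np.asarray(male_case).sum(axis=1) + np.asarray(male_control).sum(axis=1)
    p_fr = np.clip(stats.chi2.sf(fr, df=6), *_NORM_CLIP)
    p_fl = np.clip(stats.chi2.sf(fl, df=6), *_NORM_CLIP)
    zf_r = stats.norm.isf(p_fr)
    zf_l = stats.norm.isf(p_fl)
    den = np.hypot(n_f, n_m)
    z_right = (n_f * zf_r + n_m * z_m) / den
    z_left = (n_f * zf_l - n_m * z_m) / den
    return np.minimum(1.0, 2.0 * stats.norm.sf(np.maximum(z_left, z_right)))
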