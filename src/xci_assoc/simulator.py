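"""Retrospective case-control genotype simulation on the X chromosome.

Genotype frequencies in the offspring generation follow either random mating
(paternal allele at the fathers' mutant frequency, maternal at the mothers')
or a Hardy-Weinberg-disequilibrium model indexed by an inbreeding coefficient
rho.  Disease status is driven by the six penetrances; case and control totals
per sex are fixed by design, so female counts are drawn from quadrinomial
distributions over the four ordered genotypes conditional on affection status,
and male counts from binomials — the classical retrospective sampling scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genetic_model import PenetranceSet
from .genotype_data import GenotypeCounts


@dataclass(frozen=True)
class PopulationModel:
    """Parental allele frequencies, optionally with inbreeding.

    ``rho`` parameterizes a heterozygote deficit (rho > 0) or excess (rho < 0)
    in female offspring and is only meaningful when the parental frequencies
    are equal.
    """

    p_f_par: float
    p_m_par: float
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        for name, p in (("p_f_par", self.p_f_par), ("p_m_par", self.p_m_par)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} must lie strictly in (0, 1)")
        if self.rho is not None:
            if self.p_f_par != self.p_m_par:
                raise ValueError("inbreeding coefficient requires equal parental frequencies")
            p = self.p_f_par
            if self.rho < -p / (1 - p) or self.rho < -(1 - p) / p:
                raise ValueError("rho yields negative genotype frequencies")


@dataclass(frozen=True)
class GenotypeFreqs:
    """Offspring genotype frequencies: female ordered cells and male cells."""

    female: np.ndarray  # (g_f0, g_f01, g_f10, g_f2) over a/a, a/A, A/a, A/A
    male: np.ndarray    # (g_m0, g_m1) over a, A

    def __post_init__(self) -> None:
        f = np.asarray(self.female, dtype=float)
        m = np.asarray(self.male, dtype=float)
        if f.shape != (4,) or m.shape != (2,):
            raise ValueError("female freqs must be length 4, male length 2")
        if np.any(f < 0) or np.any(m < 0):
            raise ValueError("genotype frequencies must be non-negative")
        if abs(f.sum() - 1) > 1e-12 or abs(m.sum() - 1) > 1e-12:
            raise ValueError("genotype frequencies must sum to 1")
        object.__setattr__(self, "female", f)
        object.__setattr__(self, "male", m)


@dataclass(frozen=True)
class CellProbs:
    """Retrospective sampling distributions per sex, with sex-specific prevalences."""

    female_case: np.ndarray
    female_control: np.ndarray
    male_case: np.ndarray
    male_control: np.ndarray
    prevalence_f: float
    prevalence_m: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulation cell."""

    population: PopulationModel
    penetrances: PenetranceSet
    r_f: int
    s_f: int
    r_m: int
    s_m: int
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("r_f", self.r_f), ("s_f", self.s_f),
                        ("r_m", self.r_m), ("s_m", self.s_m)):
            if n < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def N(self) -> int:
        return self.r_f + self.s_f + self.r_m + self.s_m

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "p_f_par": self.population.p_f_par,
            "p_m_par": self.population.p_m_par,
            "rho": self.population.rho,
            "penetrances": self.penetrances.as_dict(),
            "r_f": self.r_f, "s_f": self.s_f, "r_m": self.r_m, "s_m": self.s_m,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        pen = d["penetrances"]
        return cls(
            population=PopulationModel(
                p_f_par=float(d["p_f_par"]), p_m_par=float(d["p_m_par"]),
                rho=None if d.get("rho") is None else float(d["rho"]),
            ),
            penetrances=PenetranceSet(**{k: float(v) for k, v in pen.items()}),
            r_f=int(d["r_f"]), s_f=int(d["s_f"]), r_m=int(d["r_m"]), s_m=int(d["s_m"]),
            seed=int(d.get("seed", 0)),
        )


def offspring_freqs_random_mating(pm: PopulationModel) -> GenotypeFreqs:
    """Offspring genotype frequencies under random mating.

    A daughter's paternal allele is drawn at the fathers' frequency and her
    maternal allele at the mothers'; sons inherit maternally.
    """
    if pm.rho is not None:
        raise ValueError("random-mating frequencies do not use rho; see offspring_freqs_hwd")
    pf, pmale = pm.p_f_par, pm.p_m_par
    female = np.array([
        (1 - pmale) * (1 - pf),
        (1 - pmale) * pf,
        pmale * (1 - pf),
        pmale * pf,
    ])
    male = np.array([1 - pf, pf])
    return GenotypeFreqs(female=female, male=male)


def offspring_freqs_hwd(p: float, rho: float) -> GenotypeFreqs:
    """Offspring genotype frequencies under Hardy-Weinberg disequilibrium.

    ``g_f0 = (1-p)^2 + rho p (1-p)``, ``g_f01 = g_f10 = (1-rho) p (1-p)``,
    ``g_f2 = p^2 + rho p (1-p)``; male frequencies are (1-p, p).
    """
    female = np.array([
        (1 - p) ** 2 + rho * p * (1 - p),
        (1 - rho) * p * (1 - p),
        (1 - rho) * p * (1 - p),
        p ** 2 + rho * p * (1 - p),
    ])
    if np.any(female < 0):
        raise ValueError(f"p={p}, rho={rho} yields negative genotype frequencies")
    return GenotypeFreqs(female=female, male=np.array([1 - p, p]))


def scenario_freqs(cfg: ScenarioConfig) -> GenotypeFreqs:
    """Offspring frequencies implied by a scenario's population model."""
    if cfg.population.rho is None:
        return offspring_freqs_random_mating(cfg.population)
    return offspring_freqs_hwd(cfg.population.p_f_par, cfg.population.rho)


def retrospective_cell_probs(freqs: GenotypeFreqs, pen: PenetranceSet) -> CellProbs:
    """Case/control genotype sampling distributions given frequencies and penetrances.

    Case cell probabilities are ``g * phi / phi_sex`` and control probabilities
    ``g * (1 - phi) / (1 - phi_sex)``, with ``phi_sex`` the sex-specific
    prevalence.
    """
    phi_f = float(freqs.female @ pen.female)
    phi_m = float(freqs.male @ pen.male)
    for name, phi in (("female", phi_f), ("male", phi_m)):
        if not 0.0 < phi < 1.0:
            raise ValueError(f"{name} prevalence {phi} leaves no cases or no controls")
    return CellProbs(
        female_case=freqs.female * pen.female / phi_f,
        female_control=freqs.female * (1 - pen.female) / (1 - phi_f),
        male_case=freqs.male * pen.male / phi_m,
        male_control=freqs.male * (1 - pen.male) / (1 - phi_m),
        prevalence_f=phi_f,
        prevalence_m=phi_m,
    )


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # counter-based substream: replicate k is reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


def sample_counts(cfg: ScenarioConfig, replicate: int = 0) -> GenotypeCounts:
    """Draw one replicate of the sex-stratified count table for a scenario.

    Deterministic given ``(cfg.seed, replicate)``; each replicate uses its own
    counter-indexed substream.
    """
    rng = _replicate_rng(cfg.seed, replicate)
    probs = retrospective_cell_probs(scenario_freqs(cfg), cfg.penetrances)
    return GenotypeCounts(
        female_case=rng.multinomial(cfg.r_f, probs.female_case),
        female_control=rng.multinomial(cfg.s_f, probs.female_control),
        male_case=rng.multinomial(cfg.r_m, probs.male_case),
        male_control=rng.multinomial(cfg.s_m, probs.male_control),
    )


def sample_counts_batch(
    cfg: ScenarioConfig, reps: int, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``reps`` replicates as stacked count arrays for the vectorized engine.

    Returns ``(female_case (reps,4), female_control (reps,4), male_case (reps,2),
    male_control (reps,2))``.  Uses a single spawned stream (seeded from
    ``cfg.seed`` when ``rng`` is not given), so the batch as a whole is
    deterministic given the scenario.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    probs = retrospective_cell_probs(scenario_freqs(cfg), cfg.penetrances)
    fc = rng.multinomial(cfg.r_f, probs.female_case, size=reps)
    fs = rng.multinomial(cfg.s_f, probs.female_control, size=reps)
    mc = rng.multinomial(cfg.r_m, probs.male_case, size=reps)
    ms = rng.multinomial(cfg.s_m, probs.male_control, size=reps)
    return fc, fs, mc, ms


def expand_to_records(counts: GenotypeCounts):
    """Deterministically expand a count table into per-individual records.

    Used to feed the covariate-capable regression paths and record-based
    comparators from aggregated data.
    """
    from .genotype_data import IndividualRecord, MaleGenotype, OrderedFemaleGenotype

    records = []
    for pheno, row in ((1, counts.female_case), (0, counts.female_control)):
        for cell, n in enumerate(row):
            geno = OrderedFemaleGenotype(paternal=cell // 2, maternal=cell % 2)
            records.extend(
                IndividualRecord(sex="F", phenotype=pheno, genotype=geno)
                for _ in range(int(n))
            )
    for pheno, row in ((1, counts.male_case), (0, counts.male_control)):
        for allele, n in enumerate(row):
            records.extend(
                IndividualRecord(sex="M", phenotype=pheno, genotype=MaleGenotype(allele))
                for _ in range(int(n))
            )
    return records
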