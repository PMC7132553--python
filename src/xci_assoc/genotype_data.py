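"""Data model and I/O for ordered X-chromosome genotypes.

On the X, a female heterozygote carries the mutant allele ``A`` on either her
paternal or her maternal copy; the two configurations (written ``A/a`` and
``a/A``, paternal allele left of the slash) can differ in penetrance when the
locus is imprinted.  Resolving which configuration a daughter carries requires
her parents' genotypes, hence the trio machinery here.  Males are hemizygous
and inherit their single X maternally, so no parental data are needed for them.

The central container, :class:`GenotypeCounts`, is the sex-stratified table of
ordered-genotype counts for cases and controls — the sufficient statistic for
every covariate-free test in this package.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Female ordered-genotype cell labels, in table order.  Cell index is
#: ``2 * paternal + maternal`` where each is the count of allele A on that copy.
FEMALE_CELLS = ("a/a", "a/A", "A/a", "A/A")
#: Male (hemizygous) cell labels.
MALE_CELLS = ("a", "A")


class MendelianError(ValueError):
    """A trio's genotypes are impossible under Mendelian X-linked inheritance."""


class PhaseAmbiguityError(ValueError):
    """A heterozygous daughter's phase cannot be resolved from the available parents."""


@dataclass(frozen=True)
class OrderedFemaleGenotype:
    """Ordered female X genotype: allele-A counts on the paternal and maternal copy."""

    paternal: int  # count of allele A on the paternal X (0 or 1)
    maternal: int  # count of allele A on the maternal X (0 or 1)

    def __post_init__(self) -> None:
        if self.paternal not in (0, 1) or self.maternal not in (0, 1):
            raise ValueError("allele counts on each X copy must be 0 or 1")

    @property
    def cell(self) -> int:
        """Index into :data:`FEMALE_CELLS`."""
        return 2 * self.paternal + self.maternal

    @property
    def label(self) -> str:
        return FEMALE_CELLS[self.cell]


@dataclass(frozen=True)
class MaleGenotype:
    """Hemizygous male X genotype: count of allele A on the single (maternal) X."""

    allele: int

    def __post_init__(self) -> None:
        if self.allele not in (0, 1):
            raise ValueError("male allele count must be 0 or 1")

    @property
    def label(self) -> str:
        return MALE_CELLS[self.allele]


@dataclass(frozen=True)
class IndividualRecord:
    """One phenotyped individual with a (phase-resolved) X genotype.

    ``phenotype`` is 1 for affected, 0 for unaffected.  ``covariates`` is an
    optional numeric vector entering the logistic model alongside the genotype.
    """

    sex: str  # "F" or "M"
    phenotype: int
    genotype: OrderedFemaleGenotype | MaleGenotype
    covariates: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.phenotype not in (0, 1):
            raise ValueError("phenotype must be 0 or 1")
        if self.sex == "F" and not isinstance(self.genotype, OrderedFemaleGenotype):
            raise ValueError("female records carry an OrderedFemaleGenotype")
        if self.sex == "M" and not isinstance(self.genotype, MaleGenotype):
            raise ValueError("male records carry a MaleGenotype")


@dataclass(frozen=True)
class TrioRecord:
    """A daughter with (possibly partial) parental genotype information.

    ``daughter`` and ``mother`` are unordered allele-A counts (0, 1 or 2);
    ``father`` is the paternal hemizygous allele count (0 or 1) or ``None`` if
    the father is ungenotyped.
    """

    daughter: int
    father: Optional[int]
    mother: Optional[int]
    phenotype: int

    def __post_init__(self) -> None:
        if self.daughter not in (0, 1, 2):
            raise ValueError("daughter genotype must be an allele count in {0,1,2}")
        if self.father not in (0, 1, None):
            raise ValueError("father genotype must be 0, 1 or None")
        if self.mother not in (0, 1, 2, None):
            raise ValueError("mother genotype must be an allele count in {0,1,2} or None")
        if self.phenotype not in (0, 1):
            raise ValueError("phenotype must be 0 or 1")


@dataclass
class GenotypeCounts:
    """Sex-stratified ordered-genotype counts for cases and controls.

    Female rows are over the four ordered cells ``a/a, a/A, A/a, A/A``; male
    rows over ``a, A``.  All entries are non-negative integers.
    """

    female_case: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    female_control: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    male_case: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    male_control: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))

    def __post_init__(self) -> None:
        self.female_case = _as_count_vector(self.female_case, 4, "female_case")
        self.female_control = _as_count_vector(self.female_control, 4, "female_control")
        self.male_case = _as_count_vector(self.male_case, 2, "male_case")
        self.male_control = _as_count_vector(self.male_control, 2, "male_control")

    # ---- totals -----------------------------------------------------------
    @property
    def r_f(self) -> int:
        return int(self.female_case.sum())

    @property
    def s_f(self) -> int:
        return int(self.female_control.sum())

    @property
    def n_f(self) -> int:
        return self.r_f + self.s_f

    @property
    def r_m(self) -> int:
        return int(self.male_case.sum())

    @property
    def s_m(self) -> int:
        return int(self.male_control.sum())

    @property
    def n_m(self) -> int:
        return self.r_m + self.s_m

    @property
    def n_r(self) -> int:
        return self.r_f + self.r_m

    @property
    def n_s(self) -> int:
        return self.s_f + self.s_m

    @property
    def N(self) -> int:
        return self.n_f + self.n_m

    def relabeled(self) -> "GenotypeCounts":
        """Counts after swapping the allele labels A <-> a.

        Reverses the female cell order (``a/a`` <-> ``A/A``, ``a/A`` <-> ``A/a``)
        and the male columns.
        """
        return GenotypeCounts(
            female_case=self.female_case[::-1].copy(),
            female_control=self.female_control[::-1].copy(),
            male_case=self.male_case[::-1].copy(),
            male_control=self.male_control[::-1].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeCounts):
            return NotImplemented
        return (
            np.array_equal(self.female_case, other.female_case)
            and np.array_equal(self.female_control, other.female_control)
            and np.array_equal(self.male_case, other.male_case)
            and np.array_equal(self.male_control, other.male_control)
        )


def _as_count_vector(x, length: int, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.shape != (length,):
        raise ValueError(f"{name} must have shape ({length},), got {arr.shape}")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr.astype(float) != np.round(arr.astype(float))):
        raise ValueError(f"{name} must contain integers")
    if np.any(np.asarray(arr, dtype=np.int64) < 0):
        raise ValueError(f"{name} must be non-negative")
    return np.asarray(arr, dtype=np.int64)


# ---------------------------------------------------------------------------
# Phase resolution from trios
# ---------------------------------------------------------------------------

def resolve_phase(trio: TrioRecord) -> OrderedFemaleGenotype:
    """Resolve a daughter's ordered genotype from parental genotypes.

    The paternal allele equals the father's single X allele; the maternal
    allele is whichever daughter allele the father does not explain.
    Homozygous daughters are phased without parental data.  Raises
    :class:`MendelianError` on inconsistent trios and
    :class:`PhaseAmbiguityError` when a heterozygous daughter cannot be phased
    (father missing and mother heterozygous or missing).
    """
    d, f, m = trio.daughter, trio.father, trio.mother
    if d in (0, 2):
        pat = mat = d // 2
        if f is not None and f != pat:
            raise MendelianError(
                f"daughter {FEMALE_CELLS[3 * pat]} is incompatible with father "
                f"{MALE_CELLS[f]}: paternal allele must equal the father's"
            )
        if m is not None and ((mat == 1 and m == 0) or (mat == 0 and m == 2)):
            raise MendelianError(
                f"daughter allele-count {d} is incompatible with mother allele-count {m}"
            )
        return OrderedFemaleGenotype(paternal=pat, maternal=mat)

    # heterozygous daughter
    if f is not None:
        pat = f
        mat = 1 - pat
        if m is not None and ((mat == 1 and m == 0) or (mat == 0 and m == 2)):
            raise MendelianError(
                f"heterozygous daughter with father {MALE_CELLS[f]} requires maternal "
                f"allele {mat}, impossible for mother allele-count {m}"
            )
        return OrderedFemaleGenotype(paternal=pat, maternal=mat)
    if m is not None and m in (0, 2):
        mat = m // 2
        return OrderedFemaleGenotype(paternal=1 - mat, maternal=mat)
    raise PhaseAmbiguityError(
        "heterozygous daughter with missing father and non-informative mother"
    )


def resolve_trios(
    trios: Iterable[TrioRecord],
) -> tuple[list[IndividualRecord], int]:
    """Phase a collection of trios into female records, dropping the unresolvable.

    Mendelian-inconsistent trios raise; ambiguous heterozygotes are dropped and
    counted.  Returns ``(records, n_dropped)``.
    """
    records: list[IndividualRecord] = []
    dropped = 0
    for trio in trios:
        try:
            geno = resolve_phase(trio)
        except PhaseAmbiguityError:
            dropped += 1
            continue
        records.append(IndividualRecord(sex="F", phenotype=trio.phenotype, genotype=geno))
    return records, dropped


def aggregate(records: Sequence[IndividualRecord]) -> GenotypeCounts:
    """Tally individual records into a :class:`GenotypeCounts` table."""
    if len(records) == 0:
        raise ValueError("cannot aggregate an empty record list")
    counts = GenotypeCounts()
    tally: Counter[tuple[str, int, int]] = Counter()
    for rec in records:
        cell = rec.genotype.cell if rec.sex == "F" else rec.genotype.allele
        tally[(rec.sex, rec.phenotype, cell)] += 1
    for (sex, pheno, cell), n in tally.items():
        if sex == "F":
            target = counts.female_case if pheno == 1 else counts.female_control
        else:
            target = counts.male_case if pheno == 1 else counts.male_control
        target[cell] += n
    return counts


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = list(FEMALE_CELLS) + list(MALE_CELLS)


def write_counts_tsv(counts: GenotypeCounts, path) -> None:
    """Write a count table as TSV: rows ``case``/``control``, six genotype columns."""
    df = pd.DataFrame(
        {
            col: [case_row[i], ctrl_row[i]]
            for (case_row, ctrl_row, cols) in (
                (counts.female_case, counts.female_control, FEMALE_CELLS),
                (counts.male_case, counts.male_control, MALE_CELLS),
            )
            for i, col in enumerate(cols)
        },
        index=["case", "control"],
    )
    df.index.name = "status"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path) -> GenotypeCounts:
    """Read a count table written by :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV is missing columns {missing}")
    for row in ("case", "control"):
        if row not in df.index:
            raise ValueError(f"counts TSV is missing row {row!r}")
    def row(status: str, cols) -> np.ndarray:
        vals = df.loc[status, list(cols)].to_numpy(dtype=float)
        return vals
    return GenotypeCounts(
        female_case=row("case", FEMALE_CELLS),
        female_control=row("control", FEMALE_CELLS),
        male_case=row("case", MALE_CELLS),
        male_control=row("control", MALE_CELLS),
    )


def write_records_tsv(records: Sequence[IndividualRecord], path) -> None:
    """Write per-individual records as TSV.

    Columns: ``id, sex, phenotype, pat_allele, mat_allele, allele`` plus
    ``c1..ck`` covariate columns; female rows fill the two phased-allele
    columns, male rows fill ``allele``.
    """
    n_cov = 0
    for rec in records:
        if rec.covariates is not None:
            n_cov = max(n_cov, len(rec.covariates))
    rows = []
    for i, rec in enumerate(records):
        row: dict = {"id": i, "sex": rec.sex, "phenotype": rec.phenotype,
                     "pat_allele": pd.NA, "mat_allele": pd.NA, "allele": pd.NA}
        if rec.sex == "F":
            row["pat_allele"] = rec.genotype.paternal
            row["mat_allele"] = rec.genotype.maternal
        else:
            row["allele"] = rec.genotype.allele
        for k in range(n_cov):
            row[f"c{k + 1}"] = rec.covariates[k] if rec.covariates is not None else pd.NA
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list[IndividualRecord]:
    """Read per-individual records written by :func:`write_records_tsv`."""
    df = pd.read_csv(path, sep="\t")
    cov_cols = [c for c in df.columns if c.startswith("c") and c[1:].isdigit()]
    records: list[IndividualRecord] = []
    for _, row in df.iterrows():
        covs = None
        if cov_cols and not any(pd.isna(row[c]) for c in cov_cols):
            covs = tuple(float(row[c]) for c in cov_cols)
        if row["sex"] == "F":
            geno: OrderedFemaleGenotype | MaleGenotype = OrderedFemaleGenotype(
                paternal=int(row["pat_allele"]), maternal=int(row["mat_allele"])
            )
        else:
            geno = MaleGenotype(allele=int(row["allele"]))
        records.append(
            IndividualRecord(sex=str(row["sex"]), phenotype=int(row["phenotype"]),
                             genotype=geno, covariates=covs)
        )
    return records


def read_trios_tsv(path) -> list[TrioRecord]:
    """Read daughter-parent trios from a PED-like TSV.

    Expected columns: ``family, id, father, mother, sex, phenotype, genotype``
    with one row per individual and allele-A counts in ``genotype`` (0/1/2 for
    females, 0/1 for males).  A family's daughter is the female row whose
    ``father``/``mother`` fields name other rows; missing parents are encoded
    as ``0`` in the pointer columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "id": str,
                                            "father": str, "mother": str})
    trios: list[TrioRecord] = []
    for _, fam in df.groupby("family", sort=False):
        by_id = {str(r["id"]): r for _, r in fam.iterrows()}
        daughters = fam[(fam["sex"] == "F") & ((fam["father"] != "0") | (fam["mother"] != "0"))]
        for _, d in daughters.iterrows():
            father = by_id.get(str(d["father"])) if str(d["father"]) != "0" else None
            mother = by_id.get(str(d["mother"])) if str(d["mother"]) != "0" else None
            trios.append(
                TrioRecord(
                    daughter=int(d["genotype"]),
                    father=None if father is None else int(father["genotype"]),
                    mother=None if mother is None else int(mother["genotype"]),
                    phenotype=int(d["phenotype"]),
                )
            )
    return trios
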