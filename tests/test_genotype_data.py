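"""Phase resolution, tallying and TSV round-trips."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xci_assoc import (
    GenotypeCounts,
    IndividualRecord,
    MaleGenotype,
    MendelianError,
    OrderedFemaleGenotype,
    PhaseAmbiguityError,
    TrioRecord,
    aggregate,
    read_counts_tsv,
    read_records_tsv,
    read_trios_tsv,
    resolve_phase,
    resolve_trios,
    write_counts_tsv,
    write_records_tsv,
)


class TestResolvePhase:
    @pytest.mark.parametrize(
        "daughter, father, mother, expected",
        [
            (2, None, None, (1, 1)),   # homozygote phase is forced
            (0, None, None, (0, 0)),
            (2, 1, 2, (1, 1)),
            (1, 0, 1, (0, 1)),         # father a -> maternal mutant: a/A
            (1, 0, 2, (0, 1)),
            (1, 1, None, (1, 0)),      # father A -> paternal mutant: A/a
            (1, None, 0, (1, 0)),      # homozygous mother phases without father
            (1, None, 2, (0, 1)),
        ],
    )
    def test_resolved_configurations(self, daughter, father, mother, expected):
        geno = resolve_phase(TrioRecord(daughter, father, mother, phenotype=1))
        assert (geno.paternal, geno.maternal) == expected

    @pytest.mark.parametrize(
        "daughter, father, mother",
        [
            (0, 1, None),  # father carries A but daughter has none
            (2, 0, None),
            (2, 1, 0),     # mother cannot contribute the maternal A
            (0, None, 2),
            (1, 0, 0),     # het daughter needs a maternal A the mother lacks
            (1, 1, 2),     # het daughter with father A needs maternal a
        ],
    )
    def test_mendelian_inconsistency_rejected(self, daughter, father, mother):
        with pytest.raises(MendelianError):
            resolve_phase(TrioRecord(daughter, father, mother, phenotype=0))

    @pytest.mark.parametrize("mother", [1, None])
    def test_unresolvable_heterozygote(self, mother):
        with pytest.raises(PhaseAmbiguityError):
            resolve_phase(TrioRecord(1, None, mother, phenotype=1))

    def test_round_trip_over_all_consistent_trios(self):
        """Simulating a daughter from parents and re-phasing recovers her genotype.

        Exhaustive over all father x mother x maternal-transmission combinations.
        """
        for father, mother in itertools.product((0, 1), (0, 1, 2)):
            maternal_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[mother]
            for mat in maternal_alleles:
                truth = OrderedFemaleGenotype(paternal=father, maternal=mat)
                trio = TrioRecord(daughter=father + mat, father=father,
                                  mother=mother, phenotype=1)
                assert resolve_phase(trio) == truth

    def test_resolve_trios_drops_and_counts_ambiguous(self):
        trios = [
            TrioRecord(1, 0, None, 1),
            TrioRecord(1, None, 1, 1),  # ambiguous: dropped
            TrioRecord(2, None, None, 0),
        ]
        records, dropped = resolve_trios(trios)
        assert dropped == 1
        assert [r.genotype.label for r in records] == ["a/A", "A/A"]


class TestAggregate:
    def test_single_records_tally(self):
        records = [
            IndividualRecord("F", 1, OrderedFemaleGenotype(0, 1)),
            IndividualRecord("M", 0, MaleGenotype(1)),
        ]
        counts = aggregate(records)
        assert counts.female_case[1] == 1
        assert counts.male_control[1] == 1
        assert counts.N == 2
        assert counts.female_control.sum() == 0 and counts.male_case.sum() == 0

    def test_matches_brute_force_tally(self, rng):
        cells = rng.integers(0, 4, size=60)
        phenos = rng.integers(0, 2, size=60)
        sexes = rng.integers(0, 2, size=60)
        records = []
        expected = np.zeros((2, 2, 4), dtype=int)  # sex x phenotype x cell
        for cell, y, s in zip(cells, phenos, sexes):
            if s == 0:
                geno = OrderedFemaleGenotype(int(cell) // 2, int(cell) % 2)
                records.append(IndividualRecord("F", int(y), geno))
                expected[0, y, cell] += 1
            else:
                geno = MaleGenotype(int(cell) % 2)
                records.append(IndividualRecord("M", int(y), geno))
                expected[1, y, int(cell) % 2] += 1
        counts = aggregate(records)
        assert np.array_equal(counts.female_case, expected[0, 1])
        assert np.array_equal(counts.female_control, expected[0, 0])
        assert np.array_equal(counts.male_case, expected[1, 1, :2])
        assert np.array_equal(counts.male_control, expected[1, 0, :2])
        assert counts.N == 60 and counts.n_f + counts.n_m == counts.n_r + counts.n_s

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestCountsIO:
    @given(
        fc=st.lists(st.integers(0, 500), min_size=4, max_size=4),
        fs=st.lists(st.integers(0, 500), min_size=4, max_size=4),
        mc=st.lists(st.integers(0, 500), min_size=2, max_size=2),
        ms=st.lists(st.integers(0, 500), min_size=2, max_size=2),
    )
    def test_round_trip_identity(self, tmp_path_factory, fc, fs, mc, ms):
        counts = GenotypeCounts(fc, fs, mc, ms)
        path = tmp_path_factory.mktemp("io") / "counts.tsv"
        write_counts_tsv(counts, path)
        assert read_counts_tsv(path) == counts

    def test_negative_cell_rejected(self, tmp_path):
        counts = GenotypeCounts([1, 2, 3, 4], [4, 3, 2, 1], [5, 6], [7, 8])
        path = tmp_path / "counts.tsv"
        write_counts_tsv(counts, path)
        text = path.read_text().replace("\t4\t", "\t-4\t", 1)
        path.write_text(text)
        with pytest.raises(ValueError):
            read_counts_tsv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("status\ta/a\ta/A\n(case)\t1\t2\n")
        with pytest.raises(ValueError):
            read_counts_tsv(path)

    def test_totals_invariant(self, tmp_path, example_counts):
        path = tmp_path / "counts.tsv"
        write_counts_tsv(example_counts, path)
        counts = read_counts_tsv(path)
        assert counts.N == counts.n_f + counts.n_m == counts.n_r + counts.n_s


class TestRecordsIO:
    def test_round_trip_with_covariates(self, tmp_path):
        records = [
            IndividualRecord("F", 1, OrderedFemaleGenotype(1, 0), covariates=(0.5, 1.0)),
            IndividualRecord("M", 0, MaleGenotype(0), covariates=(1.5, -2.0)),
        ]
        path = tmp_path / "records.tsv"
        write_records_tsv(records, path)
        back = read_records_tsv(path)
        assert back == records


class TestTriosIO:
    def test_ped_like_parsing(self, tmp_path):
        path = tmp_path / "trios.tsv"
        path.write_text(
            "family\tid\tfather\tmother\tsex\tphenotype\tgenotype\n"
            "fam1\t1\t0\t0\tM\t0\t0\n"
            "fam1\t2\t0\t0\tF\t0\t1\n"
            "fam1\t3\t1\t2\tF\t1\t1\n"
            "fam2\t1\t0\t0\tM\t0\t1\n"
            "fam2\t3\t1\t0\tF\t0\t2\n"
        )
        trios = read_trios_tsv(path)
        assert trios == [
            TrioRecord(daughter=1, father=0, mother=1, phenotype=1),
            TrioRecord(daughter=2, father=1, mother=None, phenotype=0),
        ]


class TestGenotypeCounts:
    def test_relabeled_reverses_cells(self, example_counts):
        swapped = example_counts.relabeled()
        assert np.array_equal(swapped.female_case, example_counts.female_case[::-1])
        assert np.array_equal(swapped.male_control, example_counts.male_control[::-1])
        assert swapped.relabeled() == example_counts

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCounts(female_case=[1.5, 0, 0, 0])

    def test_ordered_genotype_cell_mapping(self):
        labels = [OrderedFemaleGenotype(p, m).label
                  for p in (0, 1) for m in (0, 1)]
        assert labels == ["a/a", "a/A", "A/a", "A/A"]
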