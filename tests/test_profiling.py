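import pytest

from capmir.io import SequenceRecord
from capmir.profiling import (
    CategorySummary,
    LibraryQC,
    category_percentages,
    first_nucleotide_bias,
    length_distribution,
    percent,
    positional_nucleotide_bias,
    qc_percentages,
)

# the two libraries' published QC accounting (fetal; six-month)
FC_QC = LibraryQC(
    total_reads=15731062, high_quality=15685279, adapter3_null=2683,
    insert_null=2119, adapter5_contaminants=19517, smaller_than_18nt=33482,
    polyA=21, clean_reads=15627457,
)
SMC_QC = LibraryQC(
    total_reads=15676284, high_quality=15630959, adapter3_null=3257,
    insert_null=636, adapter5_contaminants=17252, smaller_than_18nt=16062,
    polyA=31, clean_reads=15593721,
)


class TestQCPercentages:
    @pytest.mark.parametrize(
        "qc, category, expected",
        [
            (FC_QC, "high_quality", 100.00),
            (FC_QC, "clean_reads", 99.63),
            (FC_QC, "smaller_than_18nt", 0.21),
            (FC_QC, "adapter3_null", 0.02),
            (FC_QC, "insert_null", 0.01),
            (FC_QC, "adapter5_contaminants", 0.12),
            (FC_QC, "polyA", 0.00),
            (SMC_QC, "clean_reads", 99.76),
            (SMC_QC, "smaller_than_18nt", 0.10),
            (SMC_QC, "adapter5_contaminants", 0.11),
            (SMC_QC, "insert_null", 0.00),
        ],
    )
    def test_reproduces_published_percentages(self, qc, category, expected):
        frame = qc_percentages(qc).set_index("category")
        assert frame.loc[category, "percent"] == expected

    def test_all_clean_is_100(self):
        qc = LibraryQC(10, 10, 0, 0, 0, 0, 0, 10)
        frame = qc_percentages(qc).set_index("category")
        assert frame.loc["clean_reads", "percent"] == 100.00

    def test_accounting_invariant_enforced(self):
        with pytest.raises(ValueError, match="high_quality"):
            LibraryQC(10, 10, 1, 0, 0, 0, 0, 10)

    def test_zero_high_quality_rejected(self):
        with pytest.raises(ValueError):
            qc_percentages(LibraryQC(0, 0, 0, 0, 0, 0, 0, 0))


class TestCategoryPercentages:
    FC = CategorySummary(
        unique={
            "miRNA": 4229, "exon_antisense": 892, "exon_sense": 28465,
            "intron_antisense": 2087, "intron_sense": 12410, "rRNA": 42174,
            "scRNA": 15, "snRNA": 2057, "snoRNA": 1649, "tRNA": 8800,
            "unann": 214422,
        },
        reads={
            "miRNA": 12740265, "exon_antisense": 965, "exon_sense": 29875,
            "intron_antisense": 5792, "intron_sense": 54645, "rRNA": 435237,
            "scRNA": 17, "snRNA": 6055, "snoRNA": 7294, "tRNA": 54890,
            "unann": 2292422,
        },
        total_unique=317200,
        total_reads=15627457,
    )

    def test_reproduces_published_percentages(self):
        frame = category_percentages(self.FC).set_index("category")
        assert frame.loc["miRNA", "read_percent"] == 81.52
        assert frame.loc["miRNA", "unique_percent"] == 1.33
        assert frame.loc["unann", "read_percent"] == 14.67
        assert frame.loc["rRNA", "unique_percent"] == 13.30

    def test_six_month_mirna_read_percent(self):
        cs = CategorySummary(
            unique={"miRNA": 2679, "rest": 247261},
            reads={"miRNA": 12934004, "rest": 2659717},
            total_unique=249940,
            total_reads=15593721,
        )
        frame = category_percentages(cs).set_index("category")
        assert frame.loc["miRNA", "read_percent"] == 82.94

    def test_single_category_is_100(self):
        cs = CategorySummary({"miRNA": 5}, {"miRNA": 9}, 5, 9)
        frame = category_percentages(cs).set_index("category")
        assert frame.loc["miRNA", "read_percent"] == 100.00

    def test_percentages_sum_to_100_within_rounding(self):
        frame = category_percentages(self.FC)
        assert abs(frame.read_percent.sum() - 100) <= 0.01 * len(frame)
        assert abs(frame.unique_percent.sum() - 100) <= 0.01 * len(frame)

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            CategorySummary({"a": 1}, {"a": 1}, 2, 1)


class TestRounding:
    def test_half_up_at_boundary(self):
        # 0.125% rounds up, not to even
        assert percent(125, 100000) == 0.13
        assert percent(1, 8) == 12.50


class TestLengthDistribution:
    def test_fractions(self):
        reads = [
            (SequenceRecord("a", "A" * 22), 3),
            (SequenceRecord("b", "A" * 21), 1),
        ]
        assert length_distribution(reads) == {22: 0.75, 21: 0.25}

    def test_empty_input(self):
        assert length_distribution([]) == {}

    def test_out_of_range_binned_as_other(self):
        reads = [(SequenceRecord("a", "A" * 40), 1), (SequenceRecord("b", "A" * 20), 1)]
        dist = length_distribution(reads)
        assert dist == {20: 0.5, "other": 0.5}
        assert sum(dist.values()) == pytest.approx(1.0)


class TestNucleotideBias:
    def test_all_u_start(self):
        seqs = [SequenceRecord(f"s{i}", "T" + "A" * 21) for i in range(4)]
        frame = first_nucleotide_bias(seqs)
        assert frame.loc[22, "U"] == 1.0

    def test_half_and_half_at_one_length(self):
        seqs = [SequenceRecord("a", "TA" * 11), SequenceRecord("b", "AA" * 11)]
        frame = first_nucleotide_bias(seqs)
        assert frame.loc[22, "U"] == 0.5
        assert frame.loc[22, "A"] == 0.5

    def test_rows_sum_to_one(self, rng):
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT"), rng.integers(18, 26))))
            for i in range(50)
        ]
        frame = first_nucleotide_bias(seqs)
        assert frame.sum(axis=1).tolist() == pytest.approx([1.0] * len(frame))

    def test_positional_homopolymer(self):
        seqs = [SequenceRecord(f"s{i}", "T" * 24) for i in range(3)]
        frame = positional_nucleotide_bias(seqs)
        assert (frame["U"] == 1.0).all()
        assert (frame["GC"] == 0.0).all()

    def test_position1_gc_hand_count(self):
        seqs = [SequenceRecord("g", "GAAAAAAAAAAAAAAAAAAAAA")] + [
            SequenceRecord(f"a{i}", "AAAAAAAAAAAAAAAAAAAAAA") for i in range(9)
        ]
        frame = positional_nucleotide_bias(seqs)
        assert frame.loc[1, "GC"] == pytest.approx(0.10)

    def test_short_sequences_skip_trailing_positions(self):
        seqs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "AC")]
        frame = positional_nucleotide_bias(seqs)
        # positions 3-4 only see the longer sequence
        assert frame.loc[3, "G"] == 1.0
        assert len(frame) == 4
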