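"""Codon consequence annotation and observed-variant tabulation."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from smorfval import variant_effects as ve
from smorfval._seq import Genome, revcomp
from smorfval.errors import CoordinateError, DataError

ORF_START = 30  # see toy_genome fixture
TOY_ORF_SEQ = "ATGGAATTTCTGTATCCAGGCAAAGACTAA"


def toy_orf(strand="+", exons=None):
    exons = exons or ((ORF_START, ORF_START + 30),)
    return ve.OrfModel("toy", "chrT", strand, exons)


class TestSplicedSequence:
    def test_plus_strand_single_exon_is_genome_slice(self, toy_genome):
        orf = toy_orf()
        assert ve.spliced_sequence(orf, toy_genome) == TOY_ORF_SEQ

    def test_minus_strand_is_reverse_complement(self):
        genome = Genome({"chrT": "NNN".replace("N", "A") + "ATGAAA" + "CCCC"})
        orf = ve.OrfModel("m", "chrT", "-", ((3, 9),))
        assert ve.spliced_sequence(orf, genome) == revcomp("ATGAAA") == "TTTCAT"

    def test_two_exons_concatenate_in_transcription_order(self, toy_genome):
        orf = ve.OrfModel("x", "chrT", "+", ((30, 45), (60, 75)))
        expect = toy_genome.sequence("chrT", 30, 45) + toy_genome.sequence("chrT", 60, 75)
        assert ve.spliced_sequence(orf, toy_genome) == expect

    def test_out_of_bounds_exon_raises(self, toy_genome):
        orf = ve.OrfModel("x", "chrT", "+", ((100, 200),))
        with pytest.raises(CoordinateError):
            ve.spliced_sequence(orf, toy_genome)


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "codon_idx,offset,ref,alt,expected",
        [
            (1, 2, "A", "G", "synonymous"),  # GAA -> GAG (Glu)
            (3, 2, "G", "A", "synonymous"),  # CTG -> CTA (Leu)
            (5, 1, "C", "G", "missense"),  # CCA -> CGA (P -> R)
        ],
    )
    def test_genetic_code_cases(self, toy_genome, codon_idx, offset, ref, alt, expected):
        orf = toy_orf()
        pos = ORF_START + 3 * codon_idx + offset
        got = ve.classify_consequence(orf, toy_genome, pos, ref, alt)
        assert got == expected

    def test_stop_gain(self, toy_genome):
        # codon 4 TAT -> TAA
        orf = toy_orf()
        pos = ORF_START + 3 * 4 + 2
        assert ve.classify_consequence(orf, toy_genome, pos, "T", "A") == "stop_gain"

    def test_missense(self, toy_genome):
        # codon 2 TTT -> TGT (F -> C)
        orf = toy_orf()
        pos = ORF_START + 3 * 2 + 1
        assert ve.classify_consequence(orf, toy_genome, pos, "T", "G") == "missense"

    def test_start_loss_in_initiator(self, toy_genome):
        orf = toy_orf()
        assert (
            ve.classify_consequence(orf, toy_genome, ORF_START + 2, "G", "A")
            == "start_loss"
        )

    def test_stop_loss_in_terminal_codon(self, toy_genome):
        # TAA -> CAA (Gln)
        orf = toy_orf()
        pos = ORF_START + 27
        assert ve.classify_consequence(orf, toy_genome, pos, "T", "C") == "stop_loss"

    def test_terminal_stop_to_stop_is_synonymous(self, toy_genome):
        # TAA -> TAG
        orf = toy_orf()
        pos = ORF_START + 29
        assert ve.classify_consequence(orf, toy_genome, pos, "A", "G") == "synonymous"

    def test_reference_mismatch_raises(self, toy_genome):
        orf = toy_orf()
        with pytest.raises(DataError):
            ve.classify_consequence(orf, toy_genome, ORF_START, "C", "G")

    def test_outside_entity_raises(self, toy_genome):
        orf = toy_orf()
        ref = toy_genome.sequence("chrT", 5, 6)
        with pytest.raises(CoordinateError):
            ve.classify_consequence(orf, toy_genome, 5, ref, "A" if ref != "A" else "C")

    def test_splice_positions_classified(self):
        rng = np.random.default_rng(0)
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        genome = Genome({"chrT": filler})
        orf = ve.OrfModel("s", "chrT", "+", ((10, 25), (55, 70)))
        for pos in (25, 26, 53, 54):
            ref = genome.sequence("chrT", pos, pos + 1)
            alt = "A" if ref != "A" else "C"
            assert ve.classify_consequence(orf, genome, pos, ref, alt) == "splice"


class TestEnumeratePossibleSnvs:
    def test_three_records_per_exonic_base(self, toy_genome, uniform_rate_table):
        orf = toy_orf()
        df = ve.enumerate_possible_snvs(orf, toy_genome, uniform_rate_table)
        assert len(df) == 3 * 30
        assert (df.groupby("pos").size() == 3).all()

    def test_thirty_codon_orf_gives_270_snvs(self, uniform_rate_table):
        rng = np.random.default_rng(3)
        body = "".join(
            rng.choice(["GAA", "TTC", "CTG", "AAA", "CCA", "GGT"]) for _ in range(28)
        )
        seq = "A" * 10 + "ATG" + body + "TAA" + "A" * 10
        genome = Genome({"chrT": seq})
        orf = ve.OrfModel("o30", "chrT", "+", ((10, 100),))
        df = ve.enumerate_possible_snvs(orf, genome, uniform_rate_table)
        assert len(df) == 270

    def test_class_partition_per_codon(self, toy_genome, uniform_rate_table):
        orf = toy_orf()
        df = ve.enumerate_possible_snvs(orf, toy_genome, uniform_rate_table)
        per_codon = df.groupby("codon_index")["consequence"].count()
        assert (per_codon == 9).all()

    def test_polyleucine_synonymous_fraction_matches_brute_force(self, uniform_rate_table):
        """For CTG codons, exhaustive re-translation (via an independent
        translator) gives 4/9 synonymous single-base changes."""
        n_leu = 20
        seq = "C" * 10 + "ATG" + "CTG" * n_leu + "TAA" + "G" * 10
        genome = Genome({"chrT": seq})
        orf = ve.OrfModel("leu", "chrT", "+", ((10, 13 + 3 * n_leu + 3),))
        df = ve.enumerate_possible_snvs(orf, genome, uniform_rate_table)
        middle = df[(df.codon_index >= 1) & (df.codon_index <= n_leu)]
        frac_syn = (middle["consequence"] == "synonymous").mean()
        # independent oracle: enumerate all 9 changes of CTG with Bio.Seq
        syn = 0
        for i in range(3):
            for b in "ACGT":
                if b == "CTG"[i]:
                    continue
                alt = "CTG"[:i] + b + "CTG"[i + 1 :]
                syn += str(Seq(alt).translate()) == str(Seq("CTG").translate())
        assert frac_syn == pytest.approx(syn / 9)
        assert syn == 4

    def test_strand_symmetric_class_counts(self, uniform_rate_table):
        """An entity and its reverse-complement mirror yield identical
        consequence class counts."""
        rng = np.random.default_rng(9)
        body = "".join(
            rng.choice(["GAA", "TGC", "CTG", "AAA", "CAT", "GGT", "TGG"]) for _ in range(30)
        )
        cds = "ATG" + body + "TGA"
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        fwd = Genome({"chrT": pad + cds + pad})
        rev = Genome({"chrT": pad + revcomp(cds) + pad})
        span = (20, 20 + len(cds))
        orf_f = ve.OrfModel("f", "chrT", "+", (span,))
        orf_r = ve.OrfModel("r", "chrT", "-", (span,))
        df_f = ve.enumerate_possible_snvs(orf_f, fwd, uniform_rate_table)
        df_r = ve.enumerate_possible_snvs(orf_r, rev, uniform_rate_table)
        counts_f = df_f["consequence"].value_counts().to_dict()
        counts_r = df_r["consequence"].value_counts().to_dict()
        assert counts_f == counts_r


class TestTabulateObserved:
    def _variants(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "AF"])

    def test_ns_ratio(self, toy_genome):
        orf = toy_orf()
        rows = [
            # three synonymous: GAA->GAG, CTG->CTA, TAA->TAG
            ("chrT", ORF_START + 5, "A", "G", 1e-4),
            ("chrT", ORF_START + 11, "G", "A", 1e-4),
            ("chrT", ORF_START + 29, "A", "G", 1e-4),
            # missense: TTT->TGT
            ("chrT", ORF_START + 7, "T", "G", 1e-4),
            ("chrT", ORF_START + 13, "A", "G", 1e-4),  # TAT->TGT missense
        ]
        obs = ve.tabulate_observed(orf, toy_genome, self._variants(rows))
        assert obs.n_syn == 3 and obs.n_mis == 2
        assert obs.ns_ratio == pytest.approx(2 / 3)

    def test_maf_threshold_strict(self, toy_genome):
        orf = toy_orf()
        rows = [("chrT", ORF_START + 5, "A", "G", 0.002)]
        obs = ve.tabulate_observed(orf, toy_genome, self._variants(rows))
        assert obs.n_syn == 0

    def test_high_af_is_folded(self, toy_genome):
        # AF 0.9995 folds to MAF 0.0005 < 0.001
        orf = toy_orf()
        rows = [("chrT", ORF_START + 5, "A", "G", 0.9995)]
        obs = ve.tabulate_observed(orf, toy_genome, self._variants(rows))
        assert obs.n_syn == 1

    def test_zero_synonymous_flags_ratios_missing(self, toy_genome):
        orf = toy_orf()
        rows = [("chrT", ORF_START + 7, "T", "G", 1e-4)]
        obs = ve.tabulate_observed(orf, toy_genome, self._variants(rows))
        assert obs.ns_ratio is None and obs.lofs_ratio is None
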