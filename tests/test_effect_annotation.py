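"""Effect classification, EMS flagging, the SNP screen, Table-style fixture."""

import numpy as np
import pandas as pd
import pytest

from bsamap.effect_annotation import (
    GeneModel,
    GeneModelError,
    ReferenceMismatchError,
    classify_effect,
    count_candidate_genes,
    flag_ems_transition,
    load_candidate_snp_fixture,
    load_gene_models,
    screen_annotated,
    screen_pipeline,
)
from bsamap.indexcalc import ScreenConfig
from bsamap.variant_io import PooledVariant

from conftest import COMPLEMENT, depths_for_delta, make_table, write_gff3

# independent oracle: the standard genetic code, written out by hand
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def variant(chrom, pos, ref, alt):
    return PooledVariant(chrom, pos, ref, alt, 0, 30, 20, 10)


def single_cds_gene(codon, chrom="chrT"):
    """Genome + plus-strand gene whose CDS is exactly one codon at 3..5."""
    genome = {chrom: "TT" + codon + "TT"}
    model = GeneModel(
        gene_id="g1", chrom=chrom, strand="+",
        exons=((1, 7),), cds_segments=((3, 5),),
    )
    return genome, model


class TestFlagEmsTransition:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("G", "A", True), ("C", "T", True), ("T", "G", False), ("A", "G", False)],
    )
    def test_canonical_pairs(self, ref, alt, expected):
        assert flag_ems_transition(variant("chr1", 10, ref, alt)) is expected


class TestCodingEffects:
    def test_worked_missense_example(self):
        # G→A at the first base of an alanine GCG codon gives ACG (threonine);
        # codon 159 of a long CDS so the amino-acid label reads A159T
        cds = "GCG" * 160
        genome = {"chr4": "AA" + cds + "AA"}
        model = GeneModel(
            gene_id="wb1", chrom="chr4", strand="+",
            exons=((3, 482),), cds_segments=((3, 482),),
        )
        # codon 159 occupies CDS offsets 474..476 -> genomic 477..479
        v = variant("chr4", 477, "G", "A")
        (ann,) = classify_effect(v, [model], genome)
        assert ann.effect == "missense"
        assert ann.codon_change == "GCG>ACG"
        assert ann.aa_change == "A159T"
        assert ann.ems_canonical is True

    def test_nonsense_from_arginine_codon(self):
        # C→T turns CGA (Arg) into TGA (stop): the printed "R to *" class
        genome, model = single_cds_gene("CGA")
        (ann,) = classify_effect(variant("chrT", 3, "C", "T"), [model], genome)
        assert ann.effect == "nonsense"
        assert ann.aa_change == "R1*"
        assert ann.ems_canonical is True

    def test_synonymous_third_position(self):
        genome, model = single_cds_gene("GCG")
        (ann,) = classify_effect(variant("chrT", 5, "G", "A"), [model], genome)
        assert ann.effect == "synonymous"
        assert ann.codon_change == "GCG>GCA"

    def test_translation_matches_code_table_oracle(self):
        # every codon x position x alternate base against the hand-written code
        for codon in STANDARD_CODE:
            genome, model = single_cds_gene(codon)
            for within in range(3):
                ref = codon[within]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    (ann,) = classify_effect(
                        variant("chrT", 3 + within, ref, alt), [model], genome
                    )
                    mutated = codon[:within] + alt + codon[within + 1 :]
                    aa_ref, aa_alt = STANDARD_CODE[codon], STANDARD_CODE[mutated]
                    if aa_ref == aa_alt:
                        expected = "synonymous"
                    elif aa_alt == "*":
                        expected = "nonsense"
                    else:
                        expected = "missense"
                    assert ann.effect == expected, (codon, within, alt)
                    assert ann.codon_change == f"{codon}>{mutated}"

    def test_ref_mismatch_errors(self):
        genome, model = single_cds_gene("GCG")
        with pytest.raises(ReferenceMismatchError, match="chrT:3"):
            classify_effect(variant("chrT", 3, "A", "T"), [model], genome)

    def test_cds_frame_inconsistency_rejected(self):
        with pytest.raises(GeneModelError, match="divisible by 3"):
            GeneModel(
                gene_id="bad", chrom="chr1", strand="+",
                exons=((1, 10),), cds_segments=((1, 5),),
            )


def two_exon_gene(strand="+"):
    """Gene with a 5' UTR exon stretch, an intron and a CDS across exons.

    exons 101-200 and 301-400; CDS 150-200 + 301-351 (102 bp = 34 codons);
    on '+' the 5' UTR is 101-149 and the 3' UTR 352-400.
    """
    return GeneModel(
        gene_id="g2", chrom="chrG", strand=strand,
        exons=((101, 200), (301, 400)),
        cds_segments=((150, 200), (301, 351)),
    )


@pytest.fixture
def gene_genome(rng):
    seq = "".join(rng.choice(list("ACGT"), size=500))
    return {"chrG": seq}


class TestNonCodingEffects:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (250, "intron"),       # deep intron, 50 bp from boundaries
            (205, "splice_region"),  # 5 bp into the intron
            (296, "splice_region"),  # 5 bp before the next exon
            (120, "five_prime_utr"),
            (380, "three_prime_utr"),
            (50, "intergenic"),
        ],
    )
    def test_classes(self, gene_genome, pos, expected):
        ref = gene_genome["chrG"][pos - 1]
        alt = "A" if ref != "A" else "C"
        (ann,) = classify_effect(
            variant("chrG", pos, ref, alt), [two_exon_gene()], gene_genome
        )
        assert ann.effect == expected

    def test_exonic_noncoding_near_boundary_is_splice_region(self, gene_genome):
        # 3' UTR base 2 bp from the exon2 start boundary (intron-adjacent)
        model = two_exon_gene()
        pos = 353  # 3' UTR (352-400), 52 bp from boundary 301: NOT splice
        ref = gene_genome["chrG"][pos - 1]
        alt = "A" if ref != "A" else "C"
        (ann,) = classify_effect(variant("chrG", pos, ref, alt), [model], gene_genome)
        assert ann.effect == "three_prime_utr"
        # and a UTR base right at an intron-adjacent boundary is splice_region
        model2 = GeneModel(
            gene_id="g4", chrom="chrG", strand="+",
            exons=((101, 200), (301, 400)),
            cds_segments=((320, 400),),  # 81 bp CDS; exon1 + 301-319 are 5' UTR
        )
        pos2 = 302  # 1 bp from boundary 301, non-CDS
        ref2 = gene_genome["chrG"][pos2 - 1]
        alt2 = "A" if ref2 != "A" else "C"
        (ann2,) = classify_effect(variant("chrG", pos2, ref2, alt2), [model2], gene_genome)
        assert ann2.effect == "splice_region"

    def test_strand_mirror_gives_identical_classes(self, gene_genome):
        # mirror the genome and gene; every position must classify the same
        L = len(gene_genome["chrG"])
        mirrored_seq = gene_genome["chrG"].translate(COMPLEMENT)[::-1]
        mirror_genome = {"chrG": mirrored_seq}

        def mirror_interval(iv):
            s, e = iv
            return (L - e + 1, L - s + 1)

        fwd = two_exon_gene("+")
        rev = GeneModel(
            gene_id="g2", chrom="chrG", strand="-",
            exons=tuple(sorted(mirror_interval(iv) for iv in fwd.exons)),
            cds_segments=tuple(sorted(mirror_interval(iv) for iv in fwd.cds_segments)),
        )
        for pos in (120, 160, 199, 205, 250, 296, 320, 351, 380, 50):
            ref = gene_genome["chrG"][pos - 1]
            alt = "A" if ref != "A" else "C"
            (ann_f,) = classify_effect(
                variant("chrG", pos, ref, alt), [fwd], gene_genome
            )
            m_pos = L - pos + 1
            m_ref = ref.translate(COMPLEMENT)
            m_alt = alt.translate(COMPLEMENT)
            (ann_r,) = classify_effect(
                variant("chrG", m_pos, m_ref, m_alt), [rev], mirror_genome
            )
            assert ann_f.effect == ann_r.effect, pos
            if ann_f.aa_change:
                assert ann_f.aa_change == ann_r.aa_change
                assert ann_f.codon_change == ann_r.codon_change

    def test_every_gene_position_gets_exactly_one_class(self, gene_genome):
        model = two_exon_gene()
        for pos in range(model.start, model.end + 1):
            ref = gene_genome["chrG"][pos - 1]
            alt = "A" if ref != "A" else "C"
            anns = classify_effect(variant("chrG", pos, ref, alt), [model], gene_genome)
            assert len(anns) == 1
            assert anns[0].effect != "intergenic"


class TestGff3Loading:
    def test_round_trip_through_gff3(self, tmp_path, gene_genome):
        model = two_exon_gene()
        path = tmp_path / "genes.gff3"
        write_gff3(path, [model])
        (loaded,) = load_gene_models(path)
        assert loaded.gene_id == "g2"
        assert loaded.exons == model.exons
        assert loaded.cds_segments == model.cds_segments
        assert loaded.strand == "+"
        # classification agrees with the hand-built model
        for pos in (120, 205, 250, 380):
            ref = gene_genome["chrG"][pos - 1]
            alt = "A" if ref != "A" else "C"
            (a1,) = classify_effect(variant("chrG", pos, ref, alt), [model], gene_genome)
            (a2,) = classify_effect(variant("chrG", pos, ref, alt), [loaded], gene_genome)
            assert a1.effect == a2.effect


class TestScreenPipeline:
    def test_six_snp_synthetic_case(self, rng):
        # constructed: one Δ too high, one intergenic, one synonymous,
        # three qualifying -> 3 survive, attrition {step i: 1, step ii: 2}
        cds = "GCG" * 40
        genome = {"chrS": ("T" * 100) + cds + ("T" * 280)}
        model = GeneModel(
            gene_id="gs", chrom="chrS", strand="+",
            exons=((101, 220),), cds_segments=((101, 220),),
        )
        rows = [
            ("chrS", 101, "G", "A", *depths_for_delta(0.9)),   # removed step i
            ("chrS", 300, "T", "C", *depths_for_delta(0.7)),   # intergenic
            ("chrS", 106, "G", "A", *depths_for_delta(0.7)),   # synonymous (3rd pos)
            ("chrS", 104, "G", "A", *depths_for_delta(0.7)),   # missense
            ("chrS", 110, "G", "T", *depths_for_delta(0.65)),  # missense
            ("chrS", 113, "G", "A", *depths_for_delta(0.75)),  # missense
        ]
        table = make_table(rows)
        result = screen_pipeline(table, [model], genome, ScreenConfig())
        assert result.attrition == {
            "input": 6,
            "removed_delta_screen": 1,
            "removed_effect_screen": 2,
            "retained": 3,
        }
        assert sorted(result.annotated["pos"]) == [104, 110, 113]
        assert set(result.annotated["effect"]) == {"missense"}
        assert list(result.worklist["flank_start"]) == [1, 1, 1]
        assert (result.worklist["flank_end"] == result.worklist["pos"] + 250).all()

    def test_empty_table(self):
        result = screen_pipeline(make_table([]), [], {"chr1": "ACGT"})
        assert len(result.annotated) == 0
        assert result.attrition["retained"] == 0
        assert result.attrition["removed_delta_screen"] == 0


class TestCandidateFixture:
    def test_screen_retains_all_nineteen(self):
        df = load_candidate_snp_fixture()
        assert len(df) == 19
        survivors, attrition = screen_annotated(df, ScreenConfig())
        assert attrition["retained"] == 19
        assert len(survivors) == 19

    def test_twelve_candidate_genes(self):
        df = load_candidate_snp_fixture()
        survivors, _ = screen_annotated(df, ScreenConfig())
        assert count_candidate_genes(survivors) == 12

    def test_delta_range_and_noncanonical_row(self):
        df = load_candidate_snp_fixture()
        assert df["delta"].max() == pytest.approx(0.758)
        assert df["delta"].min() == pytest.approx(0.61)
        # the top-Δ SNP is a T→G change, not a canonical EMS transition
        top = df.loc[df["delta"].idxmax()]
        v = variant(top["chrom"], int(top["pos"]), top["ref"], top["alt"])
        assert flag_ems_transition(v) is False
        # the glycosyl-hydrolase missense SNP is canonical G→A
        orf6 = df[df["gene_id"] == "ORF6"].iloc[0]
        assert (orf6["ref"], orf6["alt"]) == ("G", "A")

    def test_count_candidate_genes_edge_cases(self):
        assert count_candidate_genes(pd.DataFrame(columns=["gene_id", "effect"])) == 0
        two_in_one = pd.DataFrame(
            {"gene_id": ["gX", "gX"], "effect": ["missense", "intron"]}
        )
        assert count_candidate_genes(two_in_one) == 1
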