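"""SNP effect classification against gene models and the three-step screen.

Effect vocabulary: ``intergenic``, ``intron``, ``splice_region``,
``five_prime_utr``, ``three_prime_utr``, ``synonymous``, ``missense``,
``nonsense``.  Coding effects are computed by substituting the alternate
base into the strand-corrected codon and translating with the standard
genetic code.

Splice regions follow the common annotation convention: intronic positions
within 8 bp of an exon boundary (taking precedence over plain ``intron``)
and non-coding exonic positions within 3 bp of an intron-adjacent boundary
(taking precedence over the UTR labels).  CDS positions always classify by
their codon consequence.

The screen applies the published two computational steps — (i) keep SNPs
with Δ(SNP index) inside the retention band, (ii) drop intergenic and
synonymous SNPs — and exports the survivors as a validation worklist with
flanking coordinates for Sanger primer design (the wet-lab third step).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .indexcalc import ScreenConfig, screen_delta
from .variant_io import PooledVariant, VariantTable

__all__ = [
    "EFFECT_CLASSES",
    "CODING_EFFECTS",
    "GeneModel",
    "EffectAnnotation",
    "GeneModelError",
    "ReferenceMismatchError",
    "load_gene_models",
    "classify_effect",
    "flag_ems_transition",
    "screen_annotated",
    "screen_pipeline",
    "count_candidate_genes",
    "load_candidate_snp_fixture",
]

EFFECT_CLASSES = (
    "intergenic",
    "intron",
    "splice_region",
    "five_prime_utr",
    "three_prime_utr",
    "synonymous",
    "missense",
    "nonsense",
)
CODING_EFFECTS = frozenset({"synonymous", "missense", "nonsense"})
DROPPED_EFFECTS = frozenset({"intergenic", "synonymous"})

SPLICE_INTRON_BP = 8
SPLICE_EXON_BP = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class GeneModelError(ValueError):
    """A gene model is internally inconsistent (ordering, frame)."""


class ReferenceMismatchError(ValueError):
    """Variant reference base disagrees with the genome sequence."""


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS/UTR structure of one transcript, 1-based inclusive intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int], ...]
    five_prime_utr: tuple[tuple[int, int], ...] = ()
    three_prime_utr: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))
        object.__setattr__(self, "cds_segments", tuple(sorted(self.cds_segments)))
        cds_len = sum(e - s + 1 for s, e in self.cds_segments)
        if self.cds_segments and cds_len % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {cds_len} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class EffectAnnotation:
    """Classified consequence of one SNP against one gene model."""

    variant: PooledVariant
    gene_id: str | None
    effect: str
    aa_change: str | None = None  # e.g. "A159T"; stop written as '*'
    codon_change: str | None = None  # e.g. "GCG>ACG", coding strand
    ems_canonical: bool = False


def flag_ems_transition(variant: PooledVariant) -> bool:
    """True iff the substitution is the canonical EMS change G→A (or C→T)."""
    pair = (variant.ref_base, variant.alt_base)
    return pair in {("G", "A"), ("C", "T")}


def _get_seq(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx.Fasta or a {chrom: str} dict."""
    seq = genome[chrom][start - 1 : end]
    return str(getattr(seq, "seq", seq)).upper()


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _utr_intervals(model: GeneModel) -> tuple[tuple, tuple]:
    """(five', three') UTR intervals, inferred from exon − CDS if absent."""
    if model.five_prime_utr or model.three_prime_utr or not model.cds_segments:
        return model.five_prime_utr, model.three_prime_utr
    cds_lo = model.cds_segments[0][0]
    cds_hi = model.cds_segments[-1][1]
    before, after = [], []
    for s, e in model.exons:
        if s < cds_lo:
            before.append((s, min(e, cds_lo - 1)))
        if e > cds_hi:
            after.append((max(s, cds_hi + 1), e))
    if model.strand == "+":
        return tuple(before), tuple(after)
    return tuple(after), tuple(before)


def _splice_distances(model: GeneModel, pos: int) -> tuple[int | None, int | None]:
    """(distance into intron, distance into exon) from the nearest
    intron-adjacent exon boundary; None where not applicable.

    Intronic distance 1 means the base next to an exon; exonic distance 0
    means the terminal exon base.  Gene-terminal exon edges (not adjacent
    to an intron) never count.
    """
    intron_d = exon_d = None
    boundaries: list[int] = []
    for (_, e1), (s2, _) in zip(model.exons, model.exons[1:]):
        boundaries.extend((e1, s2))
        if e1 < pos < s2:  # inside this intron
            intron_d = min(pos - e1, s2 - pos)
    if _in_intervals(pos, model.exons) and boundaries:
        exon_d = min(abs(pos - b) for b in boundaries)
    return intron_d, exon_d


def _coding_consequence(
    variant: PooledVariant, model: GeneModel, genome
) -> tuple[str, str, str]:
    """(effect, aa_change, codon_change) for a CDS position."""
    segs = model.cds_segments
    offset = 0  # genomic-order offset of variant within concatenated CDS
    for s, e in segs:
        if s <= variant.pos <= e:
            offset += variant.pos - s
            break
        offset += e - s + 1
    total = sum(e - s + 1 for s, e in segs)
    cds_pos = offset if model.strand == "+" else total - 1 - offset
    codon_number = cds_pos // 3 + 1
    within = cds_pos % 3

    # pull the codon's three genomic positions (genomic order)
    cds_positions: list[int] = []
    if model.strand == "+":
        want = range(codon_number * 3 - 3, codon_number * 3)
    else:
        want = range(total - codon_number * 3, total - codon_number * 3 + 3)
    running = 0
    for s, e in segs:
        seg_len = e - s + 1
        for w in want:
            if running <= w < running + seg_len:
                cds_positions.append(s + (w - running))
        running += seg_len
    bases = [_get_seq(genome, model.chrom, p, p) for p in cds_positions]
    codon_genomic = "".join(bases)
    if model.strand == "+":
        codon_ref = codon_genomic
        alt_coding = variant.alt_base
        idx = within
    else:
        codon_ref = codon_genomic.translate(_COMPLEMENT)[::-1]
        alt_coding = variant.alt_base.translate(_COMPLEMENT)
        idx = within
    codon_alt = codon_ref[:idx] + alt_coding + codon_ref[idx + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        # includes stop-loss, which the output vocabulary folds into missense
        effect = "missense"
    aa_change = f"{aa_ref}{codon_number}{aa_alt}"
    codon_change = f"{codon_ref}>{codon_alt}"
    return effect, aa_change, codon_change


def classify_effect(
    variant: PooledVariant,
    gene_models: list[GeneModel],
    genome,
) -> list[EffectAnnotation]:
    """Classify one SNP against every overlapping gene model.

    Returns one annotation per overlapping model, or a single
    ``intergenic`` annotation when nothing overlaps.  The variant's
    reference base is checked against the genome sequence.
    """
    genome_base = _get_seq(genome, variant.chrom, variant.pos, variant.pos)
    if genome_base != variant.ref_base:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: variant ref {variant.ref_base} "
            f"!= genome {genome_base}"
        )
    ems = flag_ems_transition(variant)
    hits = [
        m
        for m in gene_models
        if m.chrom == variant.chrom and m.contains(variant.pos)
    ]
    if not hits:
        return [
            EffectAnnotation(variant=variant, gene_id=None, effect="intergenic",
                             ems_canonical=ems)
        ]
    out = []
    for model in hits:
        pos = variant.pos
        in_exon = _in_intervals(pos, model.exons)
        intron_d, exon_d = _splice_distances(model, pos)
        if not in_exon:
            effect = (
                "splice_region"
                if intron_d is not None and intron_d <= SPLICE_INTRON_BP
                else "intron"
            )
            out.append(
                EffectAnnotation(variant=variant, gene_id=model.gene_id,
                                 effect=effect, ems_canonical=ems)
            )
            continue
        if _in_intervals(pos, model.cds_segments):
            effect, aa_change, codon_change = _coding_consequence(
                variant, model, genome
            )
            out.append(
                EffectAnnotation(
                    variant=variant,
                    gene_id=model.gene_id,
                    effect=effect,
                    aa_change=aa_change,
                    codon_change=codon_change,
                    ems_canonical=ems,
                )
            )
            continue
        if exon_d is not None and exon_d <= SPLICE_EXON_BP:
            out.append(
                EffectAnnotation(variant=variant, gene_id=model.gene_id,
                                 effect="splice_region", ems_canonical=ems)
            )
            continue
        five, three = _utr_intervals(model)
        if _in_intervals(pos, five):
            effect = "five_prime_utr"
        elif _in_intervals(pos, three):
            effect = "three_prime_utr"
        else:
            # exon with no CDS annotation at all: non-coding transcript
            effect = "intron" if model.cds_segments else "intergenic"
        out.append(
            EffectAnnotation(variant=variant, gene_id=model.gene_id,
                             effect=effect, ems_canonical=ems)
        )
    return out


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Load transcript models from GFF3 (gene/mRNA/exon/CDS/UTR features).

    One :class:`GeneModel` per mRNA; ``gene_id`` is the parent gene's ID so
    isoforms of one gene count once in candidate-gene tallies.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = tuple(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = tuple((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        five = tuple(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="five_prime_UTR")
        )
        three = tuple(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="three_prime_UTR")
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                five_prime_utr=five,
                three_prime_utr=three,
            )
        )
    return models


@dataclass
class ScreenResult:
    """Output of the screening pipeline."""

    annotated: pd.DataFrame  # one row per surviving (SNP, gene) annotation
    attrition: dict[str, int]
    worklist: pd.DataFrame  # survivors with flanking coordinates


ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "delta",
    "gene_id",
    "effect",
    "aa_change",
    "codon_change",
    "ems_canonical",
]


def screen_annotated(
    annotated: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply screen steps (i) and (ii) to an already-annotated long table.

    ``annotated`` has one row per (SNP, gene) with at least chrom, pos,
    alt, delta and effect columns.  Step (i) keeps SNPs with Δ inside the
    retention band; step (ii) keeps a SNP if ANY of its annotations is
    neither intergenic nor synonymous, and then reports only those
    qualifying annotation rows.  Returns (surviving rows, attrition log
    counting distinct SNPs removed per step).
    """
    key = ["chrom", "pos", "alt"]
    n_input = annotated.drop_duplicates(key).shape[0]
    step1 = annotated[
        (annotated["delta"] >= config.delta_low)
        & (annotated["delta"] <= config.delta_high)
    ]
    n_step1 = step1.drop_duplicates(key).shape[0]
    qualifying = step1[~step1["effect"].isin(DROPPED_EFFECTS)]
    n_step2 = qualifying.drop_duplicates(key).shape[0]
    attrition = {
        "input": n_input,
        "removed_delta_screen": n_input - n_step1,
        "removed_effect_screen": n_step1 - n_step2,
        "retained": n_step2,
    }
    return qualifying.reset_index(drop=True), attrition


def screen_pipeline(
    table: VariantTable,
    gene_models: list[GeneModel],
    genome,
    config: ScreenConfig = ScreenConfig(),
    flank_bp: int = 250,
) -> ScreenResult:
    """The three-step SNP screen on a variant table.

    (i) Δ retention band; (ii) effect-based removal of intergenic and
    synonymous SNPs; (iii) is wet-lab Sanger confirmation, represented here
    only as the exported worklist of surviving SNPs with ±``flank_bp``
    coordinates for primer design.
    """
    step1 = screen_delta(table, config)
    rows = []
    for v in step1.variants():
        for ann in classify_effect(v, gene_models, genome):
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref_base,
                    "alt": v.alt_base,
                    "delta": v.delta,
                    "gene_id": ann.gene_id,
                    "effect": ann.effect,
                    "aa_change": ann.aa_change,
                    "codon_change": ann.codon_change,
                    "ems_canonical": ann.ems_canonical,
                }
            )
    annotated = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    n_input = len(table)
    n_step1 = len(step1)
    if len(annotated):
        surviving, _ = screen_annotated(annotated, config)
    else:
        surviving = annotated
    n_retained = surviving.drop_duplicates(["chrom", "pos", "alt"]).shape[0]
    attrition = {
        "input": n_input,
        "removed_delta_screen": n_input - n_step1,
        "removed_effect_screen": n_step1 - n_retained,
        "retained": n_retained,
    }
    snps = surviving.drop_duplicates(["chrom", "pos", "alt"])
    worklist = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "ref": snps["ref"],
            "alt": snps["alt"],
            "flank_start": np.maximum(1, snps["pos"] - flank_bp),
            "flank_end": snps["pos"] + flank_bp,
        }
    ).reset_index(drop=True)
    return ScreenResult(annotated=surviving, attrition=attrition, worklist=worklist)


def count_candidate_genes(annotated: pd.DataFrame) -> int:
    """Distinct gene ids among non-intergenic annotation rows."""
    if len(annotated) == 0:
        return 0
    genes = annotated.loc[
        annotated["effect"] != "intergenic", "gene_id"
    ].dropna()
    return int(genes.nunique())


_FIXTURE_LABEL_MAP = [
    ("Missense", "missense"),
    ("Nonsense", "nonsense"),
    ("Splice region", "splice_region"),
    ("Intron", "intron"),
    ("3", "three_prime_utr"),
    ("5", "five_prime_utr"),
]


def load_candidate_snp_fixture() -> pd.DataFrame:
    """The published 19-SNP candidate table (chromosome 4 of rice).

    Positions, bases, Δ values and printed mutation-type labels as
    reported for the white-belly endosperm mutant; the underlying gene
    structures are not reconstructed, so ``effect`` is mapped from the
    printed label.
    """
    path = files("bsamap").joinpath("data/wb1_candidate_snps.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")

    def to_effect(label: str) -> str:
        for prefix, effect in _FIXTURE_LABEL_MAP:
            if label.startswith(prefix):
                return effect
        raise ValueError(f"unrecognised mutation-type label {label!r}")

    df["effect"] = df["mutation_type"].map(to_effect)
    return df
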