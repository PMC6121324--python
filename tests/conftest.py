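"""Shared fixtures and builders for the test suite.

Everything is generated programmatically; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bsamap.variant_io import COUNT_COLUMNS, VariantTable

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def make_table(rows, min_depth: int = 10) -> VariantTable:
    """VariantTable from (chrom, pos, ref, alt, a_ref, a_alt, b_ref, b_alt) rows."""
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return VariantTable(df, min_depth=min_depth)


def depths_for_delta(delta: float, depth: int = 30) -> tuple[int, int, int, int]:
    """Pool depths giving snp_index_a = 1 and snp_index_b = 1 − delta."""
    b_alt = round((1.0 - delta) * depth)
    return 0, depth, depth - b_alt, b_alt


def random_genome(chrom_lengths: dict[str, int], rng: np.random.Generator,
                  table: VariantTable | None = None) -> dict[str, str]:
    """Random genome dict; if a table is given, its ref bases are patched in."""
    genome = {
        chrom: "".join(rng.choice(list("ACGT"), size=length))
        for chrom, length in chrom_lengths.items()
    }
    if table is not None:
        for row in table.df.itertuples(index=False):
            seq = genome[row.chrom]
            genome[row.chrom] = seq[: row.pos - 1] + row.ref + seq[row.pos :]
    return genome


def write_fasta(path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path, models) -> None:
    """Write GeneModels as GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g = m.gene_id
            fh.write(
                f"{m.chrom}\tt\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={g}\n"
            )
            fh.write(
                f"{m.chrom}\tt\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={g}.1;Parent={g}\n"
            )
            for i, (s, e) in enumerate(m.exons):
                fh.write(
                    f"{m.chrom}\tt\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={g}.1.exon{i};Parent={g}.1\n"
                )
            for i, (s, e) in enumerate(m.cds_segments):
                fh.write(
                    f"{m.chrom}\tt\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={g}.1.cds{i};Parent={g}.1\n"
                )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
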