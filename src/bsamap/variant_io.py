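"""Reading and writing the pooled variant tables the pipeline operates on.

The internal container is :class:`VariantTable` — a pandas DataFrame of
biallelic SNPs sorted by (chrom, pos), one row per SNP, with per-pool
ref/alt read depths for the mutant-phenotype pool (A) and the
wild-phenotype pool (B), plus the derived SNP indices and Δ(SNP index).

Two input dialects are supported: a standard VCF with two pool samples
carrying allelic-depth (AD) FORMAT fields, and a plain tab-separated
counts table with header ``chrom pos ref alt a_ref a_alt b_ref b_alt``.
Both produce identical tables from equivalent content.

Missing/undefined values are written as empty strings, never ``.``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from . import indexcalc

__all__ = [
    "PooledVariant",
    "VariantTable",
    "VariantFormatError",
    "read_vcf",
    "read_counts_table",
    "write_table",
    "write_vcf",
]

VALID_BASES = frozenset("ACGT")

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "a_ref", "a_alt", "b_ref", "b_alt"]
INDEX_COLUMNS = ["snp_index_a", "snp_index_b", "delta"]
TABLE_COLUMNS = COUNT_COLUMNS + INDEX_COLUMNS


class VariantFormatError(ValueError):
    """A record or row violates the expected variant-table format."""


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNP with per-pool allelic depths and derived indices."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    depth_a_ref: int
    depth_a_alt: int
    depth_b_ref: int
    depth_b_alt: int
    snp_index_a: float = math.nan
    snp_index_b: float = math.nan
    delta: float = math.nan


class VariantTable:
    """Sorted collection of pooled variants with provenance metadata.

    Parameters
    ----------
    df:
        DataFrame with at least the eight count columns.  Derived index
        columns are (re)computed at construction from ``min_depth``.
    min_depth:
        Minimum per-pool total depth for a SNP index to be defined.
    provenance:
        Free-form metadata (source file, filters applied, seeds).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        min_depth: int = 10,
        provenance: dict | None = None,
        validate: bool = True,
    ) -> None:
        df = df.loc[:, COUNT_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for col in ("a_ref", "a_alt", "b_ref", "b_alt"):
            df[col] = df[col].astype(np.int64)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        df = indexcalc.compute_index_columns(df, min_depth)
        if validate:
            self._validate(df)
        self.df = df
        self.min_depth = int(min_depth)
        self.provenance = dict(provenance or {})

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for col in ("a_ref", "a_alt", "b_ref", "b_alt"):
            if (df[col] < 0).any():
                row = df.index[df[col] < 0][0]
                raise VariantFormatError(f"negative depth in column {col}, row {row}")
        bad_base = ~(df["ref"].isin(VALID_BASES) & df["alt"].isin(VALID_BASES))
        if bad_base.any():
            row = df.index[bad_base][0]
            raise VariantFormatError(
                f"non-ACGT base at {df.at[row, 'chrom']}:{df.at[row, 'pos']}"
            )
        same = df["ref"] == df["alt"]
        if same.any():
            row = df.index[same][0]
            raise VariantFormatError(
                f"ref == alt at {df.at[row, 'chrom']}:{df.at[row, 'pos']}"
            )
        if df.duplicated(subset=["chrom", "pos", "alt"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos", "alt"])].iloc[0]
            raise VariantFormatError(f"duplicate variant {dup['chrom']}:{dup['pos']}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        """New table with the rows selected by a boolean mask (order kept)."""
        sub = VariantTable(
            self.df.loc[np.asarray(mask, dtype=bool)],
            min_depth=self.min_depth,
            provenance=dict(self.provenance),
            validate=False,
        )
        return sub

    def variants(self) -> Iterator[PooledVariant]:
        for row in self.df.itertuples(index=False):
            yield PooledVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref,
                alt_base=row.alt,
                depth_a_ref=int(row.a_ref),
                depth_a_alt=int(row.a_alt),
                depth_b_ref=int(row.b_ref),
                depth_b_alt=int(row.b_alt),
                snp_index_a=float(row.snp_index_a),
                snp_index_b=float(row.snp_index_b),
                delta=float(row.delta),
            )

    def equals(self, other: "VariantTable") -> bool:
        """Equality of counts and (nan-aware) derived columns."""
        if len(self) != len(other):
            return False
        a, b = self.df, other.df
        if not a[COUNT_COLUMNS].reset_index(drop=True).equals(
            b[COUNT_COLUMNS].reset_index(drop=True)
        ):
            return False
        for col in INDEX_COLUMNS:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if not np.allclose(x, y, equal_nan=True):
                return False
        return True


def read_counts_table(path, min_depth: int = 10) -> VariantTable:
    """Read the TSV counts dialect (header: chrom pos ref alt a_ref a_alt b_ref b_alt).

    Extra columns (e.g. previously written index columns) are ignored and
    recomputed.  A malformed row raises :class:`VariantFormatError` naming
    its 1-based line number.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COUNT_COLUMNS if c not in raw.columns]
    if missing:
        raise VariantFormatError(f"{path}: missing columns {missing}")
    out = raw.loc[:, COUNT_COLUMNS].copy()
    for col in ("pos", "a_ref", "a_alt", "b_ref", "b_alt"):
        numeric = pd.to_numeric(out[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            line = int(out.index[bad][0]) + 2  # header is line 1
            raise VariantFormatError(
                f"{path}: malformed value {out[col][bad].iloc[0]!r} "
                f"in column {col}, line {line}"
            )
        out[col] = numeric.astype(np.int64)
    try:
        return VariantTable(out, min_depth=min_depth, provenance={"source": str(path)})
    except VariantFormatError as exc:
        raise VariantFormatError(f"{path}: {exc}") from exc


def write_table(table: VariantTable, path) -> None:
    """Write a table as TSV; undefined indices become empty cells.

    Round-trips losslessly through :func:`read_counts_table` (at the same
    ``min_depth``).
    """
    out = table.df.copy()
    for col in INDEX_COLUMNS:
        out[col] = out[col].map(lambda v: "" if math.isnan(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_vcf(
    path,
    pool_a_sample: str,
    pool_b_sample: str,
    min_depth: int = 10,
) -> VariantTable:
    """Read pooled allelic depths from a two-sample VCF.

    Only biallelic SNP records are used; indels, multi-allelic and
    non-ACGT records are skipped (count recorded in provenance under
    ``skipped_records``).  A used record lacking the AD FORMAT field
    raises :class:`VariantFormatError` identifying the record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (pool_a_sample, pool_b_sample):
        if name not in samples:
            raise KeyError(
                f"sample {name!r} not in VCF {path} (samples: {samples})"
            )
    ia, ib = samples.index(pool_a_sample), samples.index(pool_b_sample)
    rows: list[tuple] = []
    skipped = 0
    for v in vcf:
        if (
            v.is_indel
            or not v.is_snp
            or len(v.ALT) != 1
            or v.REF not in VALID_BASES
            or v.ALT[0] not in VALID_BASES
        ):
            skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise VariantFormatError(
                f"record {v.CHROM}:{v.POS} has no AD allelic-depth field"
            )
        ad = np.asarray(ad)
        a_ref, a_alt = int(ad[ia, 0]), int(ad[ia, 1])
        b_ref, b_alt = int(ad[ib, 0]), int(ad[ib, 1])
        if min(a_ref, a_alt, b_ref, b_alt) < 0:
            raise VariantFormatError(
                f"record {v.CHROM}:{v.POS} has missing AD values"
            )
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], a_ref, a_alt, b_ref, b_alt))
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return VariantTable(
        df,
        min_depth=min_depth,
        provenance={
            "source": str(path),
            "pool_a_sample": pool_a_sample,
            "pool_b_sample": pool_b_sample,
            "skipped_records": skipped,
        },
    )


def write_vcf(
    table: VariantTable,
    path,
    pool_a_sample: str = "POOL_A",
    pool_b_sample: str = "POOL_B",
) -> None:
    """Write a minimal two-sample VCF 4.2 with GT:AD fields.

    Genotypes are emitted as ``./.`` (pools are not diploid individuals);
    only the allelic depths carry information.
    """
    chroms = list(dict.fromkeys(table.df["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=bsamap\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{pool_a_sample}\t{pool_b_sample}\n"
        )
        for row in table.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:AD\t./.:{row.a_ref},{row.a_alt}\t./.:{row.b_ref},{row.b_alt}\n"
            )
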