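"""Pool statistics for two-pool bulked-segregant mapping.

The core quantities of the method:

* **SNP index** — the fraction of reads in a pool carrying the non-reference
  allele at a SNP.  Because both pools are aligned to a public reference
  genome (not a parental assembly), fixed parental-line differences sit near
  index 1 in *both* pools and cancel in the difference.
* **Δ(SNP index)** — index of the mutant-phenotype pool (A) minus that of
  the wild-phenotype pool (B).  For a recessive causal SNP the expectations
  are 1 (pool A), 1/3 (pool B) and hence Δ = 2/3; unlinked loci expect
  1/2, 1/2 and Δ = 0.
* **pooled Fst** — Nei's G_ST computed from the two pool allele
  frequencies, an equivalent view of the same pool divergence.
* **segregation test** — chi-square goodness of fit of an F2 phenotype
  count pair against a Mendelian ratio (default 3:1 for a single
  recessive gene).

Undefined values (e.g. an index at insufficient depth) are represented as
``nan`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenConfig",
    "SegregationResult",
    "snp_index",
    "delta_index",
    "pooled_fst",
    "screen_delta",
    "segregation_test",
    "compute_index_columns",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Retention band for the Δ(SNP index) screen, inclusive at both ends."""

    delta_low: float = 0.6
    delta_high: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_low < self.delta_high <= 1.0):
            raise ValueError(
                f"require 0 <= delta_low < delta_high <= 1, got "
                f"[{self.delta_low}, {self.delta_high}]"
            )


@dataclass(frozen=True)
class SegregationResult:
    """Chi-square goodness of fit of a phenotype count pair to a ratio."""

    observed_dominant: int
    observed_recessive: int
    ratio: tuple[float, float]
    chi_square: float
    p_value: float
    alpha: float
    degrees_of_freedom: int = 1
    consistent: bool = field(default=False)


def snp_index(depth_ref: int, depth_alt: int) -> float:
    """Fraction of reads carrying the non-reference allele.

    Returns ``nan`` when total depth is zero (the undefined-value signal).
    """
    if depth_ref < 0 or depth_alt < 0:
        raise ValueError("read depths must be non-negative")
    total = depth_ref + depth_alt
    if total == 0:
        return math.nan
    return depth_alt / total


def delta_index(index_a: float, index_b: float) -> float:
    """Δ(SNP index) = index_a − index_b; nan if either side is undefined."""
    if math.isnan(index_a) or math.isnan(index_b):
        return math.nan
    return index_a - index_b


def pooled_fst(p_a: float, p_b: float) -> float:
    """Nei's G_ST between two pools from their allele frequencies.

    G_ST = (H_T − H_S) / H_T with H_T the expected heterozygosity at the
    pooled mean frequency and H_S the mean within-pool heterozygosity.
    Defined as 0 when H_T = 0 (both pools fixed for the same allele).
    """
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency {p} outside [0, 1]")
    p_bar = (p_a + p_b) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return 0.0
    h_s = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
    return min(1.0, max(0.0, (h_t - h_s) / h_t))


def screen_delta(table, config: ScreenConfig = ScreenConfig()):
    """Step (i) of the SNP screen: keep variants with Δ inside the band.

    Bounds are inclusive; variants with undefined Δ are dropped.  Input
    order is preserved.  Works on any object exposing a ``df`` DataFrame
    with a ``delta`` column and a ``subset(mask)`` constructor
    (:class:`bsamap.variant_io.VariantTable`).
    """
    delta = table.df["delta"]
    mask = (delta >= config.delta_low) & (delta <= config.delta_high)
    return table.subset(mask.fillna(False).to_numpy())


def segregation_test(
    n_dominant: int,
    n_recessive: int,
    ratio: tuple[float, float] = (3.0, 1.0),
    alpha: float = 0.05,
) -> SegregationResult:
    """Chi-square goodness-of-fit of phenotype counts to a Mendelian ratio.

    ``consistent`` is True when the statistic is below the df=1 critical
    value at ``alpha`` (3.841 at the default 0.05), i.e. the counts do not
    reject the stated segregation model.
    """
    if n_dominant < 0 or n_recessive < 0:
        raise ValueError("phenotype counts must be non-negative")
    total = n_dominant + n_recessive
    if total == 0:
        raise ValueError("cannot test segregation of zero individuals")
    r_dom, r_rec = ratio
    if r_dom <= 0 or r_rec <= 0:
        raise ValueError("expected ratio terms must be positive")
    expected = np.array([r_dom, r_rec]) / (r_dom + r_rec) * total
    chisq, p_value = stats.chisquare([n_dominant, n_recessive], f_exp=expected)
    critical = stats.chi2.ppf(1.0 - alpha, df=1)
    return SegregationResult(
        observed_dominant=int(n_dominant),
        observed_recessive=int(n_recessive),
        ratio=(float(r_dom), float(r_rec)),
        chi_square=float(chisq),
        p_value=float(p_value),
        alpha=float(alpha),
        degrees_of_freedom=1,
        consistent=bool(chisq < critical),
    )


def compute_index_columns(df: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    """Vectorised per-pool indices and Δ for a counts DataFrame.

    An index is defined only where the pool's total depth reaches
    ``min_depth``; Δ is defined iff both indices are.  Returns a copy with
    ``snp_index_a``, ``snp_index_b`` and ``delta`` columns (nan =
    undefined).
    """
    out = df.copy()
    for pool in ("a", "b"):
        ref = out[f"{pool}_ref"].to_numpy(dtype=float)
        alt = out[f"{pool}_alt"].to_numpy(dtype=float)
        total = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(total >= max(min_depth, 1), alt / total, np.nan)
        out[f"snp_index_{pool}"] = idx
    out["delta"] = out["snp_index_a"] - out["snp_index_b"]
    return out
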