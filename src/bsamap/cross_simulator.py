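"""Forward-genetic simulator of the two-pool bulked-segregant cross design.

The emulated experiment: an EMS mutant carrying a single recessive causal
mutation is crossed back to its (pre-mutagenesis) progenitor line, the F1
is selfed, and F2 plants are phenotyped.  DNA of ``pool_size`` recessive-
phenotype plants (Pool A) and ``pool_size`` dominant-phenotype plants
(Pool B) is pooled in equal ratio and short-read sequenced at ~30×.  Both
parents additionally share fixed differences versus the public reference
genome ("background" SNPs), which is what lets the method skip assembling
a parental reference: those variants sit near SNP index 1 in both pools
and cancel in Δ.

Model choices:

* Meiosis under the Haldane model — per-chromosome crossover counts are
  Poisson with mean equal to the map length in Morgans (uniform crossover
  positions, no interference); chromosomes assort independently.
* Phenotype is fully penetrant: mutant iff mutant-allele dosage 2 at the
  causal SNP, optionally misread at ``phenotyping_error_rate`` per plant.
* Pooled read counts per SNP and pool: depth ~ Poisson(mean_depth),
  mutant-allele reads ~ Binomial(depth, f′) with
  f′ = f·(1−e) + (1−f)·e, f the pool mutant-allele frequency and e the
  per-read sequencing error rate.

Everything is driven by one integer seed; equal seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .variant_io import COUNT_COLUMNS, VariantTable

__all__ = [
    "SimConfig",
    "CrossTruth",
    "PoolShortfallError",
    "simulate_cross",
    "phenotype_ratio",
    "advance_generation",
    "pool_from_pedigrees",
    "sample_pool_reads",
    "truth_table",
]

BASES = ("A", "C", "G", "T")
# ordered (ref, alt) pairs; the canonical EMS changes are G>A and C>T
EMS_PAIRS = (("G", "A"), ("C", "T"))
NON_EMS_PAIRS = tuple(
    (r, a) for r in BASES for a in BASES if r != a and (r, a) not in EMS_PAIRS
)


class PoolShortfallError(RuntimeError):
    """A phenotype class holds fewer plants than the requested pool size."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cross and pooled sequencing design.

    Defaults mirror the emulated study: 12 chromosomes of 30 Mb (≈360 Mb
    genome), two pools of 50 plants, ~30× coverage, and a mapping
    population grown from 100 F2 individuals.
    """

    n_chromosomes: int = 12
    chrom_length_bp: int = 30_000_000
    n_ems_snps: int = 500
    n_background_snps: int = 2_000
    causal_index: Optional[int] = None  # index into EMS SNPs (genome order)
    recomb_rate_cm_per_mb: float = 4.0
    n_f2_individuals: int = 100
    pool_size: int = 50
    mean_depth: float = 30.0
    seq_error_rate: float = 0.002
    phenotyping_error_rate: float = 0.0
    ems_transition_fraction: float = 0.7
    min_depth: int = 10
    on_pool_shortfall: str = "augment"  # or "fail"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("genome dimensions must be positive")
        if self.n_ems_snps < 1:
            raise ValueError("need at least one EMS SNP")
        if self.n_background_snps < 0:
            raise ValueError("n_background_snps must be >= 0")
        if self.recomb_rate_cm_per_mb <= 0 or self.mean_depth <= 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.seq_error_rate < 0.5:
            raise ValueError("seq_error_rate must be in [0, 0.5)")
        if not 0 <= self.phenotyping_error_rate < 0.5:
            raise ValueError("phenotyping_error_rate must be in [0, 0.5)")
        if not 0 <= self.ems_transition_fraction <= 1:
            raise ValueError("ems_transition_fraction must be in [0, 1]")
        if self.pool_size < 1 or self.n_f2_individuals < 2:
            raise ValueError("population and pool sizes must be positive")
        if self.causal_index is not None and not (
            0 <= self.causal_index < self.n_ems_snps
        ):
            raise ValueError("causal_index outside EMS SNP range")
        if self.on_pool_shortfall not in ("augment", "fail"):
            raise ValueError("on_pool_shortfall must be 'augment' or 'fail'")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {name: self.chrom_length_bp for name in self.chrom_names()}

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length_bp / 1e6 * self.recomb_rate_cm_per_mb / 100.0


@dataclass
class CrossTruth:
    """Ground truth behind one simulated variant table.

    ``genotypes`` holds mutant-allele dosage (0/1/2) per individual and
    SNP, in genome-sorted SNP order matching the emitted table; ``hap1``
    and ``hap2`` keep the phased haplotypes so later generations can be
    bred from any individual.
    """

    config: SimConfig
    snp_chrom: np.ndarray  # str array, sorted with snp_pos
    snp_pos: np.ndarray
    snp_ref: np.ndarray
    snp_alt: np.ndarray
    is_ems: np.ndarray  # bool; background SNPs are fixed in both parents
    causal_idx: int  # index into the sorted SNP arrays
    hap1: np.ndarray  # (n_individuals, n_snps) int8
    hap2: np.ndarray
    phenotypes: np.ndarray  # bool, True = mutant (recessive) phenotype
    observed_phenotypes: np.ndarray  # after phenotyping error
    pool_a: np.ndarray  # indices of recessive-pool individuals
    pool_b: np.ndarray
    generation: str = "F2"
    pedigree_parent: Optional[np.ndarray] = None  # F3: parent index per plant

    @property
    def genotypes(self) -> np.ndarray:
        return self.hap1 + self.hap2

    @property
    def n_individuals(self) -> int:
        return self.hap1.shape[0]

    @property
    def causal_chrom(self) -> str:
        return str(self.snp_chrom[self.causal_idx])

    @property
    def causal_pos(self) -> int:
        return int(self.snp_pos[self.causal_idx])

    def unlinked_ems_mask(self) -> np.ndarray:
        """EMS SNPs on chromosomes other than the causal one."""
        return self.is_ems & (self.snp_chrom != self.snp_chrom[self.causal_idx])


def _draw_snps(config: SimConfig, rng: np.random.Generator):
    """Unique sorted SNP coordinates, bases and EMS flags; causal index."""
    n_total = config.n_ems_snps + config.n_background_snps
    seen: set[tuple[int, int]] = set()
    chroms = np.empty(n_total, dtype=np.int64)
    pos = np.empty(n_total, dtype=np.int64)
    filled = 0
    while filled < n_total:
        c = int(rng.integers(config.n_chromosomes))
        p = int(rng.integers(1, config.chrom_length_bp + 1))
        if (c, p) in seen:
            continue
        seen.add((c, p))
        chroms[filled], pos[filled] = c, p
        filled += 1
    is_ems = np.zeros(n_total, dtype=bool)
    is_ems[: config.n_ems_snps] = True

    ref = np.empty(n_total, dtype="U1")
    alt = np.empty(n_total, dtype="U1")
    for i in range(n_total):
        if is_ems[i] and rng.random() < config.ems_transition_fraction:
            ref[i], alt[i] = EMS_PAIRS[int(rng.integers(2))]
        else:
            ref[i], alt[i] = NON_EMS_PAIRS[int(rng.integers(len(NON_EMS_PAIRS)))]

    order = np.lexsort((pos, chroms))
    chroms, pos, ref, alt, is_ems = (
        chroms[order], pos[order], ref[order], alt[order], is_ems[order]
    )
    ems_global = np.flatnonzero(is_ems)
    which = (
        int(rng.integers(config.n_ems_snps))
        if config.causal_index is None
        else config.causal_index
    )
    causal_idx = int(ems_global[which])
    # the emulated causal change is a canonical EMS transition
    ref[causal_idx], alt[causal_idx] = "G", "A"
    names = np.array(config.chrom_names())
    return names[chroms], pos, ref, alt, is_ems, causal_idx


def _meiosis(
    parent_hap_a: np.ndarray,
    parent_hap_b: np.ndarray,
    parent_of_gamete: np.ndarray,
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamete haplotypes under the Haldane model.

    ``parent_hap_a/b`` are (n_parents, n_snps) phased parental haplotypes;
    each gamete recombines the two haplotypes of its parent independently
    per chromosome.
    """
    n_g = len(parent_of_gamete)
    n_snps = len(snp_pos)
    out = np.empty((n_g, n_snps), dtype=np.int8)
    morgans = config.morgans_per_chrom
    for chrom in np.unique(snp_chrom):
        cols = np.flatnonzero(snp_chrom == chrom)
        p = snp_pos[cols].astype(np.float64)
        phase = rng.integers(0, 2, size=(n_g, 1), dtype=np.int16)
        k = rng.poisson(morgans, size=n_g)
        crossings = np.zeros((n_g, len(cols)), dtype=np.int16)
        k_max = int(k.max(initial=0))
        if k_max:
            x = rng.uniform(0, config.chrom_length_bp, size=(n_g, k_max))
            x[np.arange(k_max)[None, :] >= k[:, None]] = np.inf
            for i in range(k_max):
                crossings += x[:, i : i + 1] <= p[None, :]
        origin = (phase + crossings) & 1
        ha = parent_hap_a[parent_of_gamete[:, None], cols[None, :]]
        hb = parent_hap_b[parent_of_gamete[:, None], cols[None, :]]
        out[:, cols] = np.where(origin == 0, ha, hb)
    return out


def _f2_batch(
    n: int,
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    is_ems: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Phased haplotype pair for n F2 individuals.

    The F1 is heterozygous at every EMS SNP (mutant haplotype carries the
    alternate allele) and homozygous alternate at every background SNP.
    """
    n_snps = len(snp_pos)
    mutant_hap = np.ones((1, n_snps), dtype=np.int8)  # EMS alt + background alt
    wt_hap = np.ones((1, n_snps), dtype=np.int8)
    wt_hap[0, is_ems] = 0  # progenitor line lacks the induced mutations
    parent = np.zeros(n, dtype=np.int64)
    g1 = _meiosis(mutant_hap, wt_hap, parent, snp_chrom, snp_pos, config, rng)
    g2 = _meiosis(mutant_hap, wt_hap, parent, snp_chrom, snp_pos, config, rng)
    return g1, g2


def _observe_phenotypes(
    phenotypes: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.phenotyping_error_rate == 0:
        return phenotypes.copy()
    flips = rng.random(len(phenotypes)) < config.phenotyping_error_rate
    return phenotypes ^ flips


def sample_pool_reads(truth: CrossTruth, rng: np.random.Generator) -> VariantTable:
    """Pooled sequencing of the two pools recorded in ``truth``.

    Pool allele frequency is the mean mutant-allele dosage over pooled
    plants (equal DNA per plant); read counts follow the Poisson/Binomial
    model with sequencing error folded into the allele-read probability.
    """
    config = truth.config
    geno = truth.genotypes
    rows = {}
    for pool_name, members in (("a", truth.pool_a), ("b", truth.pool_b)):
        f = geno[members].mean(axis=0) / 2.0
        f_prime = f * (1 - config.seq_error_rate) + (1 - f) * config.seq_error_rate
        depth = rng.poisson(config.mean_depth, size=len(f))
        alt = rng.binomial(depth, f_prime)
        rows[f"{pool_name}_ref"] = depth - alt
        rows[f"{pool_name}_alt"] = alt
    df = pd.DataFrame(
        {
            "chrom": truth.snp_chrom,
            "pos": truth.snp_pos,
            "ref": truth.snp_ref,
            "alt": truth.snp_alt,
            **rows,
        },
        columns=COUNT_COLUMNS,
    )
    return VariantTable(
        df,
        min_depth=config.min_depth,
        provenance={
            "source": "bsamap.cross_simulator",
            "seed": config.seed,
            "generation": truth.generation,
        },
    )


def simulate_cross(config: SimConfig) -> tuple[VariantTable, CrossTruth]:
    """Simulate the full design: cross, selfing, pooling, pooled reads.

    If a phenotype class is smaller than ``pool_size`` (with the default
    100 F2 only ~25 plants show the recessive phenotype), behaviour follows
    ``on_pool_shortfall``: ``"augment"`` grows the unselected population in
    batches of ``n_f2_individuals`` until both classes suffice — the
    stand-in for the real design's extra plants grown from selfed
    pedigrees — while ``"fail"`` raises :class:`PoolShortfallError`.
    """
    rng = np.random.default_rng(config.seed)
    snp_chrom, snp_pos, ref, alt, is_ems, causal_idx = _draw_snps(config, rng)

    h1, h2 = _f2_batch(
        config.n_f2_individuals, snp_chrom, snp_pos, is_ems, config, rng
    )
    phen = (h1[:, causal_idx] + h2[:, causal_idx]) == 2
    obs = _observe_phenotypes(phen, config, rng)
    batches = 1
    while (
        min(int(obs.sum()), int((~obs).sum())) < config.pool_size
    ):
        if config.on_pool_shortfall == "fail":
            raise PoolShortfallError(
                f"phenotype classes {int(obs.sum())} mutant / "
                f"{int((~obs).sum())} wild cannot fill pools of "
                f"{config.pool_size}"
            )
        if batches >= 100:
            raise RuntimeError("population augmentation did not converge")
        b1, b2 = _f2_batch(
            config.n_f2_individuals, snp_chrom, snp_pos, is_ems, config, rng
        )
        bp = (b1[:, causal_idx] + b2[:, causal_idx]) == 2
        h1, h2 = np.vstack([h1, b1]), np.vstack([h2, b2])
        phen = np.concatenate([phen, bp])
        obs = np.concatenate([obs, _observe_phenotypes(bp, config, rng)])
        batches += 1

    pool_a = rng.choice(np.flatnonzero(obs), size=config.pool_size, replace=False)
    pool_b = rng.choice(np.flatnonzero(~obs), size=config.pool_size, replace=False)
    truth = CrossTruth(
        config=config,
        snp_chrom=snp_chrom,
        snp_pos=snp_pos,
        snp_ref=ref,
        snp_alt=alt,
        is_ems=is_ems,
        causal_idx=causal_idx,
        hap1=h1,
        hap2=h2,
        phenotypes=phen,
        observed_phenotypes=obs,
        pool_a=np.sort(pool_a),
        pool_b=np.sort(pool_b),
        generation="F2",
    )
    table = sample_pool_reads(truth, rng)
    return table, truth


def phenotype_ratio(truth: CrossTruth) -> float:
    """Dominant : recessive ratio (as a float) from true phenotypes."""
    n_rec = int(truth.phenotypes.sum())
    n_dom = int((~truth.phenotypes).sum())
    if n_rec == 0:
        raise ValueError("no recessive-phenotype individuals; ratio undefined")
    return n_dom / n_rec


def advance_generation(
    truth: CrossTruth,
    config: SimConfig | None = None,
    progeny_per_parent: int = 10,
    rng: np.random.Generator | None = None,
) -> CrossTruth:
    """Self every individual to produce the next-generation pedigrees.

    Returns a new truth whose individuals are the selfed progeny
    (``progeny_per_parent`` plants per pedigree); ``pedigree_parent``
    records each plant's parent.  Pools are left empty — select them with
    :func:`pool_from_pedigrees`.
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    n_parents = truth.n_individuals
    parent_of = np.repeat(np.arange(n_parents), progeny_per_parent)
    g1 = _meiosis(
        truth.hap1, truth.hap2, parent_of, truth.snp_chrom, truth.snp_pos,
        config, rng,
    )
    g2 = _meiosis(
        truth.hap1, truth.hap2, parent_of, truth.snp_chrom, truth.snp_pos,
        config, rng,
    )
    phen = (g1[:, truth.causal_idx] + g2[:, truth.causal_idx]) == 2
    obs = _observe_phenotypes(phen, config, rng)
    return CrossTruth(
        config=config,
        snp_chrom=truth.snp_chrom,
        snp_pos=truth.snp_pos,
        snp_ref=truth.snp_ref,
        snp_alt=truth.snp_alt,
        is_ems=truth.is_ems,
        causal_idx=truth.causal_idx,
        hap1=g1,
        hap2=g2,
        phenotypes=phen,
        observed_phenotypes=obs,
        pool_a=np.empty(0, dtype=np.int64),
        pool_b=np.empty(0, dtype=np.int64),
        generation="F3",
        pedigree_parent=parent_of,
    )


def pool_from_pedigrees(
    truth: CrossTruth,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CrossTruth:
    """Select pools using pedigree-verified phenotypes (one plant each).

    A pedigree is recessive-verified when every plant in it shows the
    mutant phenotype (homozygotes breed true, heterozygote pedigrees
    segregate); Pool A takes one observed-mutant plant from each of
    ``pool_size`` such pedigrees.  Pool B takes one observed-wild plant
    from ``pool_size`` distinct non-verified pedigrees.  Because the whole
    pedigree backs each classification, per-plant phenotyping errors are
    far less likely to contaminate the pools than with direct F2 pooling.
    """
    config = config or truth.config
    if truth.pedigree_parent is None:
        raise ValueError("truth has no pedigree structure; run advance_generation")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2_000_003)
    parent_of = truth.pedigree_parent
    obs = truth.observed_phenotypes
    pedigrees = np.unique(parent_of)
    rec_candidates, wild_candidates = [], []
    for ped in pedigrees:
        members = np.flatnonzero(parent_of == ped)
        if obs[members].all():
            rec_candidates.append(int(rng.choice(members)))
        else:
            wild_members = members[~obs[members]]
            wild_candidates.append(int(rng.choice(wild_members)))
    if len(rec_candidates) < config.pool_size:
        raise PoolShortfallError(
            f"only {len(rec_candidates)} recessive-verified pedigrees for a "
            f"pool of {config.pool_size}"
        )
    if len(wild_candidates) < config.pool_size:
        raise PoolShortfallError(
            f"only {len(wild_candidates)} segregating/wild pedigrees for a "
            f"pool of {config.pool_size}"
        )
    pool_a = rng.choice(rec_candidates, size=config.pool_size, replace=False)
    pool_b = rng.choice(wild_candidates, size=config.pool_size, replace=False)
    return replace(truth, pool_a=np.sort(pool_a), pool_b=np.sort(pool_b))


def truth_table(truth: CrossTruth) -> pd.DataFrame:
    """Per-SNP truth sidecar: coordinates, class, causal flag, pool frequencies."""
    geno = truth.genotypes
    df = pd.DataFrame(
        {
            "chrom": truth.snp_chrom,
            "pos": truth.snp_pos,
            "ref": truth.snp_ref,
            "alt": truth.snp_alt,
            "is_ems": truth.is_ems,
            "is_causal": False,
            "freq_pool_a": np.nan,
            "freq_pool_b": np.nan,
        }
    )
    df.loc[truth.causal_idx, "is_causal"] = True
    if len(truth.pool_a):
        df["freq_pool_a"] = geno[truth.pool_a].mean(axis=0) / 2.0
    if len(truth.pool_b):
        df["freq_pool_b"] = geno[truth.pool_b].mean(axis=0) / 2.0
    return df
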