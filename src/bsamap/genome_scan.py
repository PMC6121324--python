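"""Sliding-window smoothing of Δ(SNP index) and candidate-region calling.

Windows (default 50 kb, walking 10 kb) are anchored at position 1 on each
chromosome and use half-open membership [start, end).  A window's statistic
is the unweighted mean Δ over the SNPs inside it with defined Δ; windows
holding fewer than ``min_snps_per_window`` such SNPs are reported with an
undefined (nan) mean rather than zero, so empty stretches never suppress a
candidate region.

Candidate regions are maximal runs of consecutive windows at or above
``region_threshold`` (optionally bridging up to ``max_gap_windows``
below-threshold windows), ranked by their peak window mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "CandidateRegion",
    "read_chrom_lengths",
    "sliding_windows",
    "call_candidate_regions",
    "manhattan_table",
]

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "mean_delta"]


@dataclass(frozen=True)
class ScanConfig:
    window_size: int = 50_000
    step_size: int = 10_000
    min_snps_per_window: int = 1
    region_threshold: float = 0.5
    max_gap_windows: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step_size <= 0:
            raise ValueError("window_size and step_size must be positive")
        if self.step_size > self.window_size:
            raise ValueError("step_size must not exceed window_size")
        if self.min_snps_per_window < 1:
            raise ValueError("min_snps_per_window must be >= 1")
        if self.max_gap_windows < 0:
            raise ValueError("max_gap_windows must be >= 0")


@dataclass(frozen=True)
class CandidateRegion:
    """A contiguous span of elevated windowed Δ, with its peak window."""

    chrom: str
    start: int
    end: int  # exclusive bound, last window start + window_size
    peak_start: int
    peak_end: int
    peak_mean_delta: float
    n_windows: int
    n_snps: int | None = None  # distinct SNPs in span, when a table is given


def read_chrom_lengths(path) -> dict[str, int]:
    """Chromosome lengths from a two-column TSV (name, length; .fai works)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad length {parts[1]!r}"
                ) from exc
    if not lengths:
        raise ValueError(f"{path}: no chromosome lengths found")
    return lengths


def _window_starts(length: int, step: int) -> np.ndarray:
    n = (length - 1) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64)


def sliding_windows(
    table, chrom_lengths: dict[str, int], config: ScanConfig = ScanConfig()
) -> pd.DataFrame:
    """Tile each chromosome with sliding windows and average Δ per window.

    Returns a DataFrame with columns chrom, start (1-based), end
    (exclusive, start + window_size), n_snps (SNPs with defined Δ) and
    mean_delta (nan when n_snps < min_snps_per_window).  Window starts on a
    chromosome form the arithmetic sequence 1, 1+step, ... up to the
    chromosome length.
    """
    df = table.df
    for row in df.itertuples(index=False):
        if row.chrom not in chrom_lengths:
            raise ValueError(f"variant {row.chrom}:{row.pos} on undeclared chromosome")
        if row.pos > chrom_lengths[row.chrom]:
            raise ValueError(
                f"variant {row.chrom}:{row.pos} beyond declared length "
                f"{chrom_lengths[row.chrom]}"
            )
    w, s = config.window_size, config.step_size
    n_cover = -(-w // s)  # ceil
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = _window_starts(length, s)
        n_win = len(starts)
        sums = np.zeros(n_win)
        counts = np.zeros(n_win, dtype=np.int64)
        sub = df[df["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        defined = ~np.isnan(delta)
        pos, delta = pos[defined], delta[defined]
        if len(pos):
            k_hi = (pos - 1) // s  # last window index containing the SNP
            for off in range(n_cover):
                k = k_hi - off
                valid = (k >= 0) & (1 + k * s + w > pos)
                np.add.at(sums, k[valid], delta[valid])
                np.add.at(counts, k[valid], 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts >= config.min_snps_per_window, sums / np.maximum(counts, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + w,
                    "n_snps": counts,
                    "mean_delta": means,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_candidate_regions(
    windows: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
    table=None,
) -> list[CandidateRegion]:
    """Merge threshold-passing windows into candidate regions.

    A region is a maximal run of consecutive *defined* windows (per
    chromosome, in genomic order; windows with no SNPs are skipped so that
    empty stretches never suppress a region) whose mean Δ is >=
    ``region_threshold``; up to ``max_gap_windows`` consecutive defined
    below-threshold windows may be bridged inside a run.  Regions are
    returned sorted by peak window mean, descending.  When ``table`` is
    given, each region also counts the distinct SNPs (with defined Δ)
    inside its span.
    """
    regions: list[CandidateRegion] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        mean = grp["mean_delta"].to_numpy()
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        defined = np.flatnonzero(~np.isnan(mean))
        if len(defined) == 0:
            continue
        # rank within the defined subsequence: undefined windows neither
        # qualify nor count toward the gap allowance
        rank_of = np.full(len(mean), -1, dtype=np.int64)
        rank_of[defined] = np.arange(len(defined))
        qual = np.zeros(len(mean), dtype=bool)
        qual[defined] = mean[defined] >= config.region_threshold
        idx = np.flatnonzero(qual)
        if len(idx) == 0:
            continue
        # group qualifying window indices, bridging small gaps (measured in
        # defined windows between successive qualifying ones)
        breaks = np.flatnonzero(np.diff(rank_of[idx]) - 1 > config.max_gap_windows)
        groups = np.split(idx, breaks + 1)
        for g in groups:
            first, last = g[0], g[-1]
            peak = g[int(np.nanargmax(mean[g]))]
            n_snps = None
            if table is not None:
                sub = table.df
                in_span = (
                    (sub["chrom"] == chrom)
                    & (sub["pos"] >= start[first])
                    & (sub["pos"] < end[last])
                    & sub["delta"].notna()
                )
                n_snps = int(in_span.sum())
            regions.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start=int(start[first]),
                    end=int(end[last]),
                    peak_start=int(start[peak]),
                    peak_end=int(end[peak]),
                    peak_mean_delta=float(mean[peak]),
                    n_windows=int(last - first + 1),
                    n_snps=n_snps,
                )
            )
    regions.sort(key=lambda r: r.peak_mean_delta, reverse=True)
    return regions


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Candidate regions as a DataFrame (for TSV output)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "peak_start": r.peak_start,
                "peak_end": r.peak_end,
                "peak_mean_delta": r.peak_mean_delta,
                "n_windows": r.n_windows,
                "n_snps": "" if r.n_snps is None else r.n_snps,
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "peak_start",
            "peak_end",
            "peak_mean_delta",
            "n_windows",
            "n_snps",
        ],
    )


def manhattan_table(
    windows: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Plot-ready table: one row per defined window with a genome-wide x.

    x is the window midpoint plus the cumulative length of the preceding
    chromosomes (in the order of ``chrom_lengths``); on a single
    chromosome x is simply the window midpoint.
    """
    offsets: dict[str, int] = {}
    running = 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = running
        running += length
    out = windows[windows["mean_delta"].notna()].copy()
    if len(out) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_delta", "x"])
    out["x"] = out["chrom"].map(offsets) + (out["start"] + out["end"]) / 2.0
    out = out.sort_values("x").reset_index(drop=True)
    return out[["chrom", "start", "end", "mean_delta", "x"]]
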