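"""Per-bin strand-imbalance testing and R-loop call assembly.

The caller tests, for every candidate bin, whether plus- and minus-strand
fragment counts are compatible with a 50/50 split (two-sided exact binomial),
adjusts across the candidate universe with Benjamini-Hochberg, applies the
density / log2-ratio / q thresholds, and merges surviving bins of the same
imbalance direction into R-loop calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .coverage import StrandedFragmentSet, bin_density
from .intervals import (
    GenomeAssembly,
    IntervalSet,
    filter_candidates,
    make_windows,
    subtract_blacklist,
)

DensityMode = Literal["mean", "sum", "max"]

BIN_STAT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "plus_density",
    "minus_density",
    "plus_count",
    "minus_count",
    "log2_ratio",
    "p_value",
    "q_value",
]

CALL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "displaced_strand",
    "density",
    "n_bins",
    "min_q",
]


@dataclass
class CallerConfig:
    """Thresholds and geometry of the R-loop caller.

    Defaults follow the standard rule set: 500/250 bp sliding bins,
    candidate bins need >= 250 bp peak overlap, calls need mean strand
    density strictly above 20 reads-per-base, |log2 strand ratio| >= 1
    (pseudocount 1 on both densities) and BH q <= 0.05.
    """

    bin_width: int = 500
    bin_step: int = 250
    min_peak_overlap: int = 250
    min_density: float = 20.0
    min_abs_log2_ratio: float = 1.0
    max_q: float = 0.05
    pseudocount: float = 1.0
    merge_gap: int = 0
    density_mode: DensityMode = "mean"

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if not 1 <= self.bin_step <= self.bin_width:
            raise ValueError("bin_step must satisfy 1 <= step <= width")
        if self.min_peak_overlap < 1:
            raise ValueError("min_peak_overlap must be >= 1")
        if self.min_density < 0:
            raise ValueError("min_density must be >= 0")
        if self.min_abs_log2_ratio < 0:
            raise ValueError("min_abs_log2_ratio must be >= 0")
        if not 0 < self.max_q <= 1:
            raise ValueError("max_q must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.density_mode not in ("mean", "sum", "max"):
            raise ValueError(f"unknown density_mode {self.density_mode!r}")


@dataclass
class CallResult:
    """Output of :func:`call_pipeline`."""

    calls: pd.DataFrame
    bin_stats: pd.DataFrame
    config: CallerConfig
    n_windows: int = 0
    n_candidates: int = 0


def binom_two_sided(plus_counts: np.ndarray, minus_counts: np.ndarray) -> np.ndarray:
    """Vectorized two-sided exact binomial p-values at p0 = 0.5.

    For a symmetric binomial the minimum-likelihood two-sided p-value
    collapses to min(1, 2 * P(X <= min(k, n-k))); n = 0 gives p = 1.
    """
    k = np.asarray(plus_counts, dtype=np.int64)
    m = np.asarray(minus_counts, dtype=np.int64)
    if (k < 0).any() or (m < 0).any():
        raise ValueError("fragment counts must be non-negative")
    n = k + m
    lower = np.minimum(k, m)
    p = np.minimum(1.0, 2.0 * binom.cdf(lower, np.maximum(n, 1), 0.5))
    return np.where(n == 0, 1.0, p)


def strand_imbalance_test(plus_count: int, minus_count: int) -> float:
    """Two-sided exact binomial p for plus_count of (plus+minus) trials at 0.5."""
    if plus_count < 0 or minus_count < 0:
        raise ValueError("fragment counts must be non-negative")
    return float(binom_two_sided(np.array([plus_count]), np.array([minus_count]))[0])


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=np.float64)
    q[order] = q_sorted
    return q


def compute_bin_stats(density: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Augment a bin-density frame with log2 ratio, binomial p and BH q.

    The BH universe is exactly the rows of ``density``; callers must pass the
    candidate-bin table, nothing wider.

    log2_ratio is computed as log2(plus + pc) - log2(minus + pc) so that
    swapping strands negates it bit-exactly.
    """
    stats = density.copy()
    stats["log2_ratio"] = np.log2(stats["plus_density"].to_numpy() + pseudocount) - np.log2(
        stats["minus_density"].to_numpy() + pseudocount
    )
    stats["p_value"] = binom_two_sided(
        stats["plus_count"].to_numpy(), stats["minus_count"].to_numpy()
    )
    stats["q_value"] = bh_adjust(stats["p_value"].to_numpy())
    return stats


def _combined_density(stats: pd.DataFrame, mode: DensityMode) -> np.ndarray:
    p = stats["plus_density"].to_numpy()
    m = stats["minus_density"].to_numpy()
    if mode == "mean":
        return (p + m) / 2.0
    if mode == "sum":
        return p + m
    return np.maximum(p, m)


def call_rloop_bins(stats: pd.DataFrame, cfg: CallerConfig) -> pd.DataFrame:
    """Select significant bins.

    Thresholds follow the printed rules exactly: density strictly ``>``,
    |log2 ratio| ``>=``, q ``<=``.
    """
    if len(stats) == 0:
        return stats
    keep = (
        (_combined_density(stats, cfg.density_mode) > cfg.min_density)
        & (np.abs(stats["log2_ratio"].to_numpy()) >= cfg.min_abs_log2_ratio)
        & (stats["q_value"].to_numpy() <= cfg.max_q)
    )
    return stats[keep].reset_index(drop=True)


def merge_rloop_bins(significant: pd.DataFrame, cfg: CallerConfig) -> pd.DataFrame:
    """Merge overlapping/book-ended significant bins into R-loop calls.

    Bins dominant on opposite strands never merge: the displaced strand is a
    physical property of the structure. Per-call density is the mean of
    |plus_density - minus_density| over constituent bins; min_q is the
    smallest constituent q.
    """
    if len(significant) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    rows = []
    sig = significant.sort_values(["chrom", "start", "end"], kind="mergesort")
    direction = np.where(sig["log2_ratio"].to_numpy() >= 0, "+", "-")
    for (chrom, strand), grp in sig.assign(_dir=direction).groupby(
        ["chrom", "_dir"], sort=False
    ):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        diff = np.abs(grp["plus_density"].to_numpy() - grp["minus_density"].to_numpy())
        qv = grp["q_value"].to_numpy()
        cmax = np.maximum.accumulate(e)
        new = np.ones(len(s), dtype=bool)
        if len(s) > 1:
            new[1:] = s[1:] > cmax[:-1] + cfg.merge_gap
        gid = np.cumsum(new) - 1
        for g in range(gid[-1] + 1):
            sel = gid == g
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(s[sel].min()),
                    "end": int(e[sel].max()),
                    "displaced_strand": strand,
                    "density": float(diff[sel].mean()),
                    "n_bins": int(sel.sum()),
                    "min_q": float(qv[sel].min()),
                }
            )
    calls = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end"], kind="mergesort", ignore_index=True
    )
    calls.insert(3, "name", [f"RLoop_{i + 1}" for i in range(len(calls))])
    return calls[CALL_COLUMNS]


def call_pipeline(
    frags: StrandedFragmentSet,
    peaks: IntervalSet,
    blacklist: IntervalSet | None,
    assembly: GenomeAssembly,
    cfg: CallerConfig | None = None,
) -> CallResult:
    """Full caller: windows -> blacklist -> peak filter -> stats -> calls."""
    cfg = cfg or CallerConfig()
    windows = make_windows(assembly, cfg.bin_width, cfg.bin_step)
    n_windows = len(windows)
    if blacklist is not None and len(blacklist):
        windows = subtract_blacklist(windows, blacklist)
    candidates = filter_candidates(windows, peaks, cfg.min_peak_overlap)
    if len(candidates) == 0:
        return CallResult(
            calls=pd.DataFrame(columns=CALL_COLUMNS),
            bin_stats=pd.DataFrame(columns=BIN_STAT_COLUMNS),
            config=cfg,
            n_windows=n_windows,
            n_candidates=0,
        )
    density = bin_density(frags, candidates)
    stats = compute_bin_stats(density, cfg.pseudocount)
    significant = call_rloop_bins(stats, cfg)
    calls = merge_rloop_bins(significant, cfg)
    return CallResult(
        calls=calls,
        bin_stats=stats,
        config=cfg,
        n_windows=n_windows,
        n_candidates=len(candidates),
    )


@dataclass
class CensusResult:
    """Genome-wide imbalanced-bin census (volcano-plot table)."""

    n_imbalanced: int
    table: pd.DataFrame


def imbalanced_bin_census(
    frags: StrandedFragmentSet,
    assembly: GenomeAssembly,
    bin_width: int = 2000,
    pseudocount: float = 1.0,
    min_abs_log2_ratio: float = 1.0,
    max_q: float = 0.05,
) -> CensusResult:
    """Count non-overlapping genome-wide bins with imbalanced strand signal.

    Bins passing |log2 ratio| >= min_abs_log2_ratio and q <= max_q are
    counted; the full per-bin table is returned for volcano plotting.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    bins = make_windows(assembly, bin_width, bin_width)
    density = bin_density(frags, bins)
    stats = compute_bin_stats(density, pseudocount)
    imbalanced = (np.abs(stats["log2_ratio"]) >= min_abs_log2_ratio) & (
        stats["q_value"] <= max_q
    )
    stats["imbalanced"] = imbalanced
    return CensusResult(n_imbalanced=int(imbalanced.sum()), table=stats)


def write_calls(calls: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write calls as BED6+3 (name, score = round(density*10), strand, then
    density, n_bins, min_q)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"#{line}\n")
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                f"{int(round(row.density * 10))}\t{row.displaced_strand}\t"
                f"{row.density:.6f}\t{row.n_bins}\t{row.min_q:.6g}\n"
            )


def read_calls(path, assembly: GenomeAssembly | None = None) -> pd.DataFrame:
    """Read a calls BED written by :func:`write_calls`."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns in calls BED")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "name": fields[3],
                    "displaced_strand": fields[5],
                    "density": float(fields[6]),
                    "n_bins": int(fields[7]),
                    "min_q": float(fields[8]),
                }
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if assembly is not None and len(calls):
        unknown = ~calls["chrom"].isin(assembly.names)
        if unknown.any():
            raise ValueError(f"unknown chromosome {calls['chrom'][unknown].iloc[0]!r}")
    return calls
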