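"""Genomic-category assignment, metagene profiles, overlap fractions and
binned Pearson correlations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import (
    GenomeAssembly,
    IntervalSet,
    make_windows,
    merge_intervals,
    overlap_lengths,
    read_bed,
)

CATEGORIES = ("promoter", "tes", "gene_body", "intergenic")

GENE_COLUMNS = ["chrom", "start", "end", "strand", "name"]


class GeneModel:
    """Gene intervals with strand-aware TSS/TES.

    TSS is the 5' end (start for '+' genes, end for '-' genes); TES is the
    opposite end.
    """

    def __init__(self, frame: pd.DataFrame, assembly: GenomeAssembly | None = None):
        missing = [c for c in ("chrom", "start", "end", "strand") if c not in frame.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        frame = frame.copy()
        if "name" not in frame.columns:
            frame["name"] = [f"gene_{i + 1}" for i in range(len(frame))]
        if len(frame) and not frame["strand"].isin(["+", "-"]).all():
            raise ValueError("every gene needs a '+' or '-' strand")
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        if (frame["start"] >= frame["end"]).any():
            raise ValueError("gene with start >= end")
        plus = frame["strand"] == "+"
        frame["tss"] = np.where(plus, frame["start"], frame["end"])
        frame["tes"] = np.where(plus, frame["end"], frame["start"])
        self.df = frame.reset_index(drop=True)
        self.assembly = assembly

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path: str | Path, assembly: GenomeAssembly | None = None) -> "GeneModel":
        iset = read_bed(path, assembly)
        df = iset.df[["chrom", "start", "end", "strand", "name"]]
        return cls(df, assembly=assembly)

    @classmethod
    def from_table(cls, path: str | Path, assembly: GenomeAssembly | None = None) -> "GeneModel":
        """Read a 5-column TSV: chrom, start, end, strand, name."""
        df = pd.read_csv(path, sep="\t", header=None, names=GENE_COLUMNS, comment="#")
        return cls(df, assembly=assembly)

    def flipped_strands(self) -> "GeneModel":
        df = self.df[GENE_COLUMNS].copy()
        df["strand"] = np.where(df["strand"] == "+", "-", "+")
        return GeneModel(df, assembly=self.assembly)


@dataclass
class CategoryScheme:
    """Window conventions for promoter/TES/gene-body assignment.

    Precedence is total and fixed: promoter > TES > gene body > intergenic.
    The window sizes are this implementation's convention and configurable.
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 1000
    tes_window: int = 1000

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.tes_window) < 0:
            raise ValueError("window sizes must be >= 0")


def _category_sets(
    genes: GeneModel, scheme: CategoryScheme, assembly: GenomeAssembly
) -> dict[str, IntervalSet]:
    df = genes.df
    plus = df["strand"] == "+"
    lengths = df["chrom"].map(dict(assembly)).to_numpy()
    prom_start = np.where(
        plus,
        df["tss"] - scheme.promoter_upstream,
        df["tss"] - scheme.promoter_downstream,
    )
    prom_end = np.where(
        plus,
        df["tss"] + scheme.promoter_downstream,
        df["tss"] + scheme.promoter_upstream,
    )
    tes_start = df["tes"] - scheme.tes_window
    tes_end = df["tes"] + scheme.tes_window
    out: dict[str, IntervalSet] = {}
    for label, starts, ends in (
        ("promoter", prom_start, prom_end),
        ("tes", tes_start, tes_end),
        ("gene_body", df["start"].to_numpy(), df["end"].to_numpy()),
    ):
        s = np.clip(np.asarray(starts, dtype=np.int64), 0, lengths)
        e = np.clip(np.asarray(ends, dtype=np.int64), 0, lengths)
        keep = e > s
        iset = IntervalSet.from_arrays(
            df["chrom"].to_numpy()[keep], s[keep], e[keep], assembly=assembly
        )
        out[label] = merge_intervals(iset)
    return out


def assign_categories(
    regions: pd.DataFrame | IntervalSet,
    genes: GeneModel,
    scheme: CategoryScheme | None = None,
    assembly: GenomeAssembly | None = None,
) -> pd.Series:
    """Category of each region's midpoint under promoter > TES > body precedence.

    Accepts any frame with chrom/start/end; returns a row-aligned Series.
    """
    scheme = scheme or CategoryScheme()
    df = regions.df if isinstance(regions, IntervalSet) else regions
    assembly = assembly or genes.assembly
    if assembly is None:
        raise ValueError("an assembly is required for category assignment")
    if len(genes) == 0:
        raise ValueError("gene model is empty")
    cats = _category_sets(genes, scheme, assembly)
    result = np.full(len(df), "intergenic", dtype=object)
    mid = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    points = IntervalSet.from_arrays(df["chrom"].to_numpy(), mid, mid + 1, assembly=assembly)
    # points are canonically sorted; map back to the input row order
    order = np.lexsort((mid, df["chrom"].map(assembly.order_map).to_numpy()))
    for label in ("gene_body", "tes", "promoter"):  # ascending precedence, later wins
        hit_sorted = overlap_lengths(points, cats[label]) > 0
        hits = np.zeros(len(df), dtype=bool)
        hits[order] = hit_sorted
        result[hits] = label
    return pd.Series(result, index=df.index, name="category")


def assign_category(
    region, genes: GeneModel, scheme: CategoryScheme | None = None, assembly=None
) -> str:
    """Scalar convenience wrapper around :func:`assign_categories`."""
    df = pd.DataFrame({"chrom": [region.chrom], "start": [region.start], "end": [region.end]})
    return assign_categories(df, genes, scheme, assembly).iloc[0]


def _resample_body(values: np.ndarray, body_bins: int) -> np.ndarray:
    """Length-normalize per-bp values into body_bins mean slices."""
    edges = np.floor(np.linspace(0, len(values), body_bins + 1)).astype(np.int64)
    cum = np.concatenate(([0.0], np.nancumsum(values)))
    cnt = np.concatenate(([0], np.cumsum(~np.isnan(values))))
    sums = cum[edges[1:]] - cum[edges[:-1]]
    counts = cnt[edges[1:]] - cnt[edges[:-1]]
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def metagene_profile(
    signal: Mapping[str, np.ndarray] | tuple[Mapping[str, np.ndarray], Mapping[str, np.ndarray]],
    genes: GeneModel,
    assembly: GenomeAssembly,
    flank: int = 3000,
    body_bins: int = 100,
    flank_bin_size: int = 50,
    mode: str = "plain",
) -> np.ndarray:
    """Mean TSS->TES oriented profile: fixed flanks, length-normalized body.

    mode='plain' averages a single per-bp track. mode='relative' takes a
    (plus_track, minus_track) pair and averages the nontemplate-minus-template
    difference per gene: for a '+' gene the template strand is '-', so the
    relative signal is plus - minus; for a '-' gene it is minus - plus.

    Out-of-chromosome flank positions are NaN and excluded from the mean.
    Genes shorter than body_bins bp are skipped.
    """
    if flank % flank_bin_size != 0:
        raise ValueError("flank must be a multiple of flank_bin_size")
    if mode not in ("plain", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    n_flank_bins = flank // flank_bin_size
    width = 2 * n_flank_bins + body_bins
    total = np.zeros(width)
    count = np.zeros(width)
    for row in genes.df.itertuples(index=False):
        glen = row.end - row.start
        if glen < body_bins:
            continue
        length = assembly[row.chrom]
        lo = row.start - flank
        hi = row.end + flank
        window = np.full(hi - lo, np.nan)
        s_clip, e_clip = max(lo, 0), min(hi, length)
        if mode == "plain":
            values = np.asarray(signal[row.chrom][s_clip:e_clip], dtype=np.float64)
        else:
            plus_track, minus_track = signal
            diff = np.asarray(plus_track[row.chrom][s_clip:e_clip], dtype=np.float64) - np.asarray(
                minus_track[row.chrom][s_clip:e_clip], dtype=np.float64
            )
            values = diff if row.strand == "+" else -diff
        window[s_clip - lo : e_clip - lo] = values
        if row.strand == "-":
            window = window[::-1]
        up = window[:flank].reshape(n_flank_bins, flank_bin_size)
        body = _resample_body(window[flank : flank + glen], body_bins)
        down = window[flank + glen :].reshape(n_flank_bins, flank_bin_size)
        with np.errstate(invalid="ignore"):
            profile = np.concatenate([np.nanmean(up, axis=1), body, np.nanmean(down, axis=1)])
        ok = ~np.isnan(profile)
        total[ok] += profile[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


def overlap_fraction(set_a: IntervalSet, set_b: IntervalSet) -> float:
    """Fraction of A's intervals with >= 1 bp overlap with B (asymmetric)."""
    if len(set_a) == 0:
        raise ValueError("overlap fraction undefined for an empty query set")
    return float((overlap_lengths(set_a, set_b) > 0).mean())


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def binned_pearson(
    signal_a: Mapping[str, np.ndarray],
    signal_b: Mapping[str, np.ndarray],
    assembly: GenomeAssembly,
    bin_size: int = 5000,
    restrict_to: IntervalSet | None = None,
    blacklist: IntervalSet | None = None,
) -> CorrelationResult:
    """Pearson r between two per-bp tracks averaged over fixed-size bins.

    Blacklist-overlapping bins are dropped; if restrict_to is given, only
    bins overlapping it are kept. p comes from the t transform on n-2 df.
    """
    bins = make_windows(assembly, bin_size, bin_size)
    keep = np.ones(len(bins), dtype=bool)
    if blacklist is not None and len(blacklist):
        keep &= overlap_lengths(bins, blacklist) == 0
    if restrict_to is not None:
        keep &= overlap_lengths(bins, restrict_to) > 0
    means_a = []
    means_b = []
    offset = 0
    for chrom, grp in bins.by_chrom():
        sel = keep[offset : offset + len(grp)]
        offset += len(grp)
        if not sel.any():
            continue
        bs = grp["start"].to_numpy()[sel]
        be = grp["end"].to_numpy()[sel]
        for sig, acc in ((signal_a, means_a), (signal_b, means_b)):
            cum = np.concatenate(([0.0], np.cumsum(np.asarray(sig[chrom], dtype=np.float64))))
            acc.append((cum[be] - cum[bs]) / (be - bs))
    n = int(sum(len(a) for a in means_a))
    if n < 3:
        raise ValueError(f"need >= 3 bins for correlation, got {n}")
    a = np.concatenate(means_a)
    b = np.concatenate(means_b)
    r, p = sps.pearsonr(a, b)
    return CorrelationResult(r=float(r), p=float(p), n=n)


@dataclass
class CallSummary:
    length_histogram: pd.DataFrame
    count_by_category: pd.Series | None
    density_by_category: pd.Series | None


def call_summaries(
    calls: pd.DataFrame,
    genes: GeneModel | None = None,
    scheme: CategoryScheme | None = None,
    assembly: GenomeAssembly | None = None,
    length_bin: int = 250,
) -> CallSummary:
    """Length histogram (fixed 250-bp bins) and per-category count/density."""
    if len(calls) == 0:
        raise ValueError("no calls to summarize")
    lengths = (calls["end"] - calls["start"]).to_numpy()
    n_bins = int(lengths.max() // length_bin) + 1
    edges = np.arange(0, (n_bins + 1) * length_bin, length_bin)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = pd.DataFrame(
        {"length_lo": edges[:-1], "length_hi": edges[1:], "count": counts}
    )
    count_by = density_by = None
    if genes is not None:
        cats = assign_categories(calls, genes, scheme, assembly)
        count_by = cats.value_counts().reindex(CATEGORIES, fill_value=0)
        density_by = calls.groupby(cats)["density"].mean().reindex(CATEGORIES)
    return CallSummary(
        length_histogram=hist, count_by_category=count_by, density_by_category=density_by
    )
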