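"""Strand-separated fragment sets and per-bin coverage statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeAssembly, IntervalSet

ReadMode = Literal["single_end", "paired_fragments"]


@dataclass
class StrandedFragmentSet:
    """Fragments split by strand; the caller's raw input.

    ``plus``/``minus`` hold the fragments whose ssDNA signal maps to the
    respective strand. Within each set every record carries that strand label.
    """

    plus: IntervalSet
    minus: IntervalSet
    assembly: GenomeAssembly
    label: str = ""

    @property
    def library_size(self) -> int:
        return len(self.plus) + len(self.minus)

    def swap_strands(self) -> "StrandedFragmentSet":
        """Relabel every fragment's strand (plus <-> minus)."""
        plus_df = self.minus.df.assign(strand="+")
        minus_df = self.plus.df.assign(strand="-")
        return StrandedFragmentSet(
            plus=IntervalSet(plus_df, assembly=self.assembly, validate=False),
            minus=IntervalSet(minus_df, assembly=self.assembly, validate=False),
            assembly=self.assembly,
            label=self.label,
        )


def reads_to_fragments(
    reads: IntervalSet,
    assembly: GenomeAssembly,
    mode: ReadMode = "single_end",
    extend_to: int = 150,
) -> StrandedFragmentSet:
    """Turn aligned read intervals into stranded fragments.

    single_end: a plus-strand read becomes [start, start+extend_to), a
    minus-strand read [end-extend_to, end); both clipped to the chromosome.
    paired_fragments: records pass through unchanged (they already span the
    fragment) and are only strand-split.

    Every read must carry a definite strand; '.' raises ValueError.
    """
    if mode not in ("single_end", "paired_fragments"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single_end" and extend_to < 1:
        raise ValueError("extend_to must be >= 1")
    df = reads.df
    if len(df) and (df["strand"] == ".").any():
        raise ValueError(f"unstranded read encountered in {mode} mode")
    lengths = df["chrom"].map(dict(assembly)) if len(df) else pd.Series(dtype=np.int64)
    if mode == "single_end" and len(df):
        df = df.copy()
        plus_mask = df["strand"] == "+"
        df.loc[plus_mask, "end"] = np.minimum(
            df.loc[plus_mask, "start"] + extend_to, lengths[plus_mask]
        )
        df.loc[~plus_mask, "start"] = np.maximum(df.loc[~plus_mask, "end"] - extend_to, 0)
    plus = IntervalSet(df[df["strand"] == "+"] if len(df) else None, assembly=assembly)
    minus = IntervalSet(df[df["strand"] == "-"] if len(df) else None, assembly=assembly)
    return StrandedFragmentSet(plus=plus, minus=minus, assembly=assembly)


def coverage_track(iset: IntervalSet, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
    """Per-bp fragment coverage as one float array per chromosome."""
    track: dict[str, np.ndarray] = {}
    for chrom, length in assembly.items():
        starts, ends = iset.chrom_arrays(chrom)
        diff = np.bincount(starts, minlength=length + 1).astype(np.int64)
        diff -= np.bincount(ends, minlength=length + 1)
        track[chrom] = np.cumsum(diff)[:length].astype(np.float64)
    return track


def strand_tracks(
    frags: StrandedFragmentSet,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """(plus, minus) per-bp coverage tracks."""
    return (
        coverage_track(frags.plus, frags.assembly),
        coverage_track(frags.minus, frags.assembly),
    )


def _bin_strand_stats(
    starts: np.ndarray,
    ends: np.ndarray,
    length: int,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(density, count) per bin for one strand on one chromosome.

    density = overlapped fragment bp / bin length; count = fragments with
    >= 1 bp overlap.
    """
    if len(starts) == 0:
        n = len(bin_starts)
        return np.zeros(n), np.zeros(n, dtype=np.int64)
    diff = np.bincount(starts, minlength=length + 1).astype(np.int64)
    diff -= np.bincount(ends, minlength=length + 1)
    cov = np.cumsum(diff)[:length]
    cum = np.concatenate(([0], np.cumsum(cov)))
    overlap_bp = cum[bin_ends] - cum[bin_starts]
    density = overlap_bp / (bin_ends - bin_starts)
    s_sorted = np.sort(starts)
    e_sorted = np.sort(ends)
    count = np.searchsorted(s_sorted, bin_ends, side="left") - np.searchsorted(
        e_sorted, bin_starts, side="right"
    )
    return density, count.astype(np.int64)


def bin_density(frags: StrandedFragmentSet, bins: IntervalSet) -> pd.DataFrame:
    """Per-bin, per-strand mean coverage (reads-per-base) and fragment counts.

    Returns a frame with chrom/start/end plus plus_density, minus_density,
    plus_count, minus_count, row-aligned with the canonical bin order.
    """
    assembly = frags.assembly
    pieces = []
    for chrom, grp in bins.by_chrom():
        length = assembly[chrom]
        bs = grp["start"].to_numpy()
        be = grp["end"].to_numpy()
        p_dens, p_cnt = _bin_strand_stats(*frags.plus.chrom_arrays(chrom), length, bs, be)
        m_dens, m_cnt = _bin_strand_stats(*frags.minus.chrom_arrays(chrom), length, bs, be)
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": bs,
                    "end": be,
                    "plus_density": p_dens,
                    "minus_density": m_dens,
                    "plus_count": p_cnt,
                    "minus_count": m_cnt,
                }
            )
        )
    if not pieces:
        return pd.DataFrame(
            columns=[
                "chrom",
                "start",
                "end",
                "plus_density",
                "minus_density",
                "plus_count",
                "minus_count",
            ]
        )
    return pd.concat(pieces, ignore_index=True)


def pool_replicates(replicates: Sequence[StrandedFragmentSet]) -> StrandedFragmentSet:
    """Multiset union of replicate fragment sets (library sizes add)."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    assembly = replicates[0].assembly
    for rep in replicates[1:]:
        if rep.assembly != assembly:
            raise ValueError("replicates are on different assemblies")
    if len(replicates) == 1:
        return replicates[0]
    plus = IntervalSet(
        pd.concat([r.plus.df for r in replicates], ignore_index=True),
        assembly=assembly,
        validate=False,
    )
    minus = IntervalSet(
        pd.concat([r.minus.df for r in replicates], ignore_index=True),
        assembly=assembly,
        validate=False,
    )
    label = "+".join(r.label for r in replicates if r.label)
    return StrandedFragmentSet(plus=plus, minus=minus, assembly=assembly, label=label)
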