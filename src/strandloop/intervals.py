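"""Genomic interval primitives: assemblies, BED/BedGraph I/O, windowing, interval algebra.

All coordinates are 0-based half-open (BED convention). 1-based numbers only
ever appear in error messages that refer to file lines.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: canonical column order of the backing frame
CORE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedFormatError(ValueError):
    """Malformed or out-of-assembly BED/BedGraph record."""


class Interval(NamedTuple):
    """A single genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeAssembly(Mapping):
    """Ordered map of chromosome name -> length in bp.

    Chromosome order is the insertion order and defines the canonical sort
    order of every :class:`IntervalSet` tied to this assembly.
    """

    def __init__(self, lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        self._lengths: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            length = int(length)
            if not name or any(c.isspace() for c in name):
                raise ValueError(f"invalid chromosome name {name!r}")
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[name] = length
        if not self._lengths:
            raise ValueError("assembly has no chromosomes")
        self._order = {name: i for i, name in enumerate(self._lengths)}

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeAssembly):
            return NotImplemented
        return list(self._lengths.items()) == list(other._lengths.items())

    def __repr__(self) -> str:
        return f"GenomeAssembly({self._lengths!r})"

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    @property
    def order_map(self) -> dict[str, int]:
        return dict(self._order)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeAssembly":
        """Read a two-column chrom-sizes TSV (name <TAB> length)."""
        items: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise BedFormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                try:
                    items.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise BedFormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
        return cls(items)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly.from_file(path)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=object),
            "score": pd.Series(dtype=float),
            "strand": pd.Series(dtype=object),
        }
    )


class IntervalSet:
    """Sorted collection of intervals backed by a pandas DataFrame.

    The backing frame always carries the columns in :data:`CORE_COLUMNS` (extra
    columns are preserved) and is sorted by (assembly chromosome order, start,
    end, strand, name). Treat ``.df`` as read-only.
    """

    def __init__(
        self,
        frame: pd.DataFrame | None = None,
        assembly: GenomeAssembly | None = None,
        validate: bool = True,
    ):
        if frame is None or len(frame) == 0:
            frame = _empty_frame()
        else:
            frame = frame.copy()
        for col, default in (("name", "."), ("score", np.nan), ("strand", ".")):
            if col not in frame.columns:
                frame[col] = default
        missing = [c for c in ("chrom", "start", "end") if c not in frame.columns]
        if missing:
            raise ValueError(f"interval frame missing columns {missing}")
        frame["chrom"] = frame["chrom"].astype(str)
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        frame["strand"] = frame["strand"].astype(str)
        extra = [c for c in frame.columns if c not in CORE_COLUMNS]
        frame = frame[CORE_COLUMNS + extra]
        self.assembly = assembly
        if validate and len(frame):
            bad = ~frame["strand"].isin(STRANDS)
            if bad.any():
                raise BedFormatError(f"invalid strand value {frame['strand'][bad].iloc[0]!r}")
            if (frame["start"] < 0).any():
                raise BedFormatError("negative start coordinate")
            if (frame["start"] >= frame["end"]).any():
                row = frame[frame["start"] >= frame["end"]].iloc[0]
                raise BedFormatError(
                    f"start >= end at {row['chrom']}:{row['start']}-{row['end']}"
                )
            if assembly is not None:
                lengths = frame["chrom"].map(dict(assembly))
                if lengths.isna().any():
                    unknown = frame["chrom"][lengths.isna()].iloc[0]
                    raise BedFormatError(f"unknown chromosome {unknown!r}")
                if (frame["end"] > lengths).any():
                    row = frame[frame["end"] > lengths].iloc[0]
                    raise BedFormatError(
                        f"interval {row['chrom']}:{row['start']}-{row['end']} exceeds chromosome end"
                    )
        if len(frame):
            key = (
                frame["chrom"].map(assembly.order_map)
                if assembly is not None
                else frame["chrom"]
            )
            frame = (
                frame.assign(_key=key)
                .sort_values(["_key", "start", "end", "strand", "name"], kind="mergesort")
                .drop(columns="_key")
            )
        self._frame = frame.reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[Interval]:
        for row in self._frame.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end), row.strand, row.name, row.score)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self._frame[["chrom", "start", "end", "strand"]]
        b = other._frame[["chrom", "start", "end", "strand"]]
        return a.equals(b)

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple] | Iterable[Interval],
        assembly: GenomeAssembly | None = None,
    ) -> "IntervalSet":
        rows = [Interval(*rec) for rec in records]
        frame = pd.DataFrame(rows, columns=list(Interval._fields))
        return cls(frame, assembly=assembly)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str] | np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        strands: Sequence[str] | np.ndarray | str = ".",
        assembly: GenomeAssembly | None = None,
    ) -> "IntervalSet":
        frame = pd.DataFrame(
            {
                "chrom": np.asarray(chroms, dtype=object),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
            }
        )
        frame["strand"] = strands
        return cls(frame, assembly=assembly)

    def by_chrom(self) -> Iterator[tuple[str, pd.DataFrame]]:
        """Yield (chrom, sub-frame) in canonical chromosome order."""
        if len(self._frame) == 0:
            return
        yield from self._frame.groupby("chrom", sort=False)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) int64 arrays of intervals on one chromosome."""
        sub = self._frame[self._frame["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def total_bp(self) -> int:
        """Summed interval lengths (duplicates counted)."""
        return int((self._frame["end"] - self._frame["start"]).sum())

    def to_bed(self, path: str | Path, extra_cols: Sequence[str] = ()) -> None:
        write_bed(self, path, extra_cols=extra_cols)


def _check_same_assembly(a: IntervalSet, b: IntervalSet) -> GenomeAssembly | None:
    if a.assembly is not None and b.assembly is not None and a.assembly != b.assembly:
        raise ValueError("interval sets are on different assemblies")
    return a.assembly or b.assembly


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    permissive: bool = False,
) -> IntervalSet:
    """Read a BED3/BED6 file.

    Malformed lines always raise :class:`BedFormatError` naming the 1-based
    line number. Records on unknown chromosomes or exceeding the chromosome
    end raise too, unless ``permissive`` is set, in which case they are
    dropped and counted on the returned set's ``n_rejected`` attribute.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    scores: list[float] = []
    strands: list[str] = []
    n_rejected = 0
    lengths = dict(assembly) if assembly is not None else None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise BedFormatError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise BedFormatError(f"{path}:{lineno}: start >= end")
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in STRANDS:
                raise BedFormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if lengths is not None:
                if chrom not in lengths:
                    if permissive:
                        n_rejected += 1
                        continue
                    raise BedFormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > lengths[chrom]:
                    if permissive:
                        n_rejected += 1
                        continue
                    raise BedFormatError(
                        f"{path}:{lineno}: interval exceeds chromosome end ({end} > {lengths[chrom]})"
                    )
            name = fields[3] if len(fields) >= 4 else "."
            score_field = fields[4] if len(fields) >= 5 else "."
            try:
                score = float(score_field) if score_field != "." else float("nan")
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: bad score {score_field!r}") from exc
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            names.append(name)
            scores.append(score)
            strands.append(strand)
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "name": names,
            "score": scores,
            "strand": strands,
        }
    )
    iset = IntervalSet(frame, assembly=assembly, validate=False)
    iset.n_rejected = n_rejected
    if n_rejected:
        logger.warning("%s: rejected %d out-of-assembly records", path, n_rejected)
    return iset


def _format_score(x: float) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "0"
    if float(x) == int(x):
        return str(int(x))
    return format(float(x), "g")


def write_bed(iset: IntervalSet, path: str | Path, extra_cols: Sequence[str] = ()) -> None:
    """Write BED6 (+ optional extra columns); output is canonically sorted."""
    with open(path, "w") as fh:
        for row in iset.df.itertuples(index=False):
            fields = [
                row.chrom,
                str(int(row.start)),
                str(int(row.end)),
                str(row.name),
                _format_score(row.score),
                row.strand,
            ]
            for col in extra_cols:
                val = getattr(row, col)
                fields.append(format(val, ".6g") if isinstance(val, float) else str(val))
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
    """Read a BedGraph into per-bp float arrays, one per chromosome.

    Overlapping records are summed (matches genomecov accumulation).
    """
    track = {name: np.zeros(length, dtype=np.float64) for name, length in assembly.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            if chrom not in track:
                raise BedFormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: bad record") from exc
            if not 0 <= start < end <= assembly[chrom]:
                raise BedFormatError(f"{path}:{lineno}: coordinates out of bounds")
            track[chrom][start:end] += value
    return track


def write_bedgraph(
    track: Mapping[str, np.ndarray], path: str | Path, assembly: GenomeAssembly
) -> None:
    """Write per-bp arrays as BedGraph (zero runs omitted, values %.6f)."""
    with open(path, "w") as fh:
        for chrom in assembly:
            if chrom not in track:
                continue
            arr = np.asarray(track[chrom], dtype=np.float64)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], breaks, [arr.size]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6f}\n")


def make_windows(assembly: GenomeAssembly, width: int, step: int) -> IntervalSet:
    """Tile every chromosome with [k*step, k*step + width) windows.

    Terminal windows are truncated at the chromosome end and flagged in the
    boolean ``partial`` column; they are retained, not dropped.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if not 1 <= step <= width:
        raise ValueError(f"step must satisfy 1 <= step <= width, got {step}")
    frames = []
    for chrom, length in assembly.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "partial": ends - starts < width,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return IntervalSet(frame, assembly=assembly, validate=False)


def merge_intervals(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is <= max_gap (book-ended merge at gap 0).

    Strand is ignored; output carries chrom/start/end only. Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    chroms: list[str] = []
    starts_out: list[np.ndarray] = []
    ends_out: list[np.ndarray] = []
    for chrom, grp in iset.by_chrom():
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        cmax = np.maximum.accumulate(e)
        new = np.ones(len(s), dtype=bool)
        if len(s) > 1:
            new[1:] = s[1:] > cmax[:-1] + max_gap
        firsts = np.flatnonzero(new)
        merged_starts = s[firsts]
        merged_ends = np.maximum.reduceat(e, firsts)
        chroms.extend([chrom] * len(firsts))
        starts_out.append(merged_starts)
        ends_out.append(merged_ends)
    if not chroms:
        return IntervalSet(assembly=iset.assembly)
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts_out),
            "end": np.concatenate(ends_out),
        }
    )
    return IntervalSet(frame, assembly=iset.assembly, validate=False)


def overlap_lengths(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query total overlap (bp) with the *union* of subject intervals.

    Returned array is positionally aligned with ``query.df`` rows.
    """
    _check_same_assembly(query, subject)
    out = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return out
    merged = merge_intervals(subject)
    sub_by_chrom = {chrom: grp for chrom, grp in merged.by_chrom()}
    for chrom, grp in query.by_chrom():
        sub = sub_by_chrom.get(chrom)
        if sub is None:
            continue
        ms = sub["start"].to_numpy()
        me = sub["end"].to_numpy()
        cum = np.concatenate(([0], np.cumsum(me - ms)))
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        lo = np.searchsorted(me, qs, side="right")
        hi = np.searchsorted(ms, qe, side="left")
        has = hi > lo
        ov = np.zeros(len(qs), dtype=np.int64)
        if has.any():
            lo_c = np.minimum(lo, len(ms) - 1)
            hi_c = np.maximum(hi, 1) - 1
            left_trim = np.maximum(qs - ms[lo_c], 0)
            right_trim = np.maximum(me[hi_c] - qe, 0)
            ov[has] = (cum[hi] - cum[lo] - left_trim - right_trim)[has]
        out[grp.index.to_numpy()] = ov
    return out


def subtract_blacklist(bins: IntervalSet, blacklist: IntervalSet) -> IntervalSet:
    """Drop every bin with >= 1 bp overlap with any blacklist interval.

    Bins are removed whole, never trimmed.
    """
    if len(bins) == 0 or len(blacklist) == 0:
        return bins
    keep = overlap_lengths(bins, blacklist) == 0
    frame = bins.df[keep]
    return IntervalSet(frame, assembly=bins.assembly, validate=False)


def filter_candidates(bins: IntervalSet, peaks: IntervalSet, min_overlap: int = 250) -> IntervalSet:
    """Keep bins whose total overlap with the union of peaks is >= min_overlap bp."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(bins) == 0:
        return bins
    keep = overlap_lengths(bins, peaks) >= min_overlap
    frame = bins.df[keep]
    return IntervalSet(frame, assembly=bins.assembly, validate=False)
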