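"""Synthetic stranded-fragment data with planted R-loops and transcription
bubbles, plus machine-readable truth sets.

The signal model: background ssDNA coverage is symmetric Poisson noise on
both strands. A transcription bubble elevates both strands equally to
``mean_depth``. An R-loop puts ``mean_depth`` on the displaced strand and
``mean_depth / asymmetry_ratio`` on the hybrid-protected strand. RNase H at
efficiency e moves both strand intensities a fraction e of the way toward
their mean (covering both template exposure and strand re-annealing);
DRB / triptolide simply delete features whose retention flag is off.

Randomness: one global seed; every (chromosome x strand) background unit and
every (feature x strand) unit draws from its own spawned substream, keyed by
position in a fixed unit list. Conditions that leave a unit's intensity
unchanged therefore reproduce its fragments bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import StrandedFragmentSet
from .intervals import GenomeAssembly, IntervalSet, merge_intervals, write_bed

FEATURE_KINDS = ("rloop", "bubble")

TRUTH_COLUMNS = [
    "name",
    "chrom",
    "start",
    "end",
    "kind",
    "displaced_strand",
    "plus_depth",
    "minus_depth",
]


@dataclass
class PlantedFeature:
    """One planted locus: an R-loop (asymmetric) or a bubble (symmetric)."""

    chrom: str
    start: int
    end: int
    kind: str = "rloop"
    displaced_strand: str = "+"
    asymmetry_ratio: float = 4.0
    mean_depth: float = 40.0
    retained_drb: bool = True
    retained_trp: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "bubble":
            self.asymmetry_ratio = 1.0
        if self.asymmetry_ratio < 1.0:
            raise ValueError("asymmetry_ratio must be >= 1")
        if self.displaced_strand not in ("+", "-"):
            raise ValueError("displaced_strand must be '+' or '-'")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.start >= self.end:
            raise ValueError("feature start >= end")


@dataclass
class SimConfig:
    """Full description of a synthetic experiment."""

    assembly: GenomeAssembly
    features: Sequence[PlantedFeature] = field(default_factory=list)
    genes: pd.DataFrame | None = None
    background_depth: float = 1.0
    fragment_length: int = 150
    rnase_h_efficiency: Mapping[float, float] = field(default_factory=dict)
    blacklist: Sequence[tuple[str, int, int]] = field(default_factory=list)
    nb_dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if self.background_depth < 0:
            raise ValueError("background_depth must be >= 0")
        for dose, eff in self.rnase_h_efficiency.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficiency for dose {dose} outside [0, 1]")
        for i, feat in enumerate(self.features):
            if feat.chrom not in self.assembly:
                raise ValueError(f"feature on unknown chromosome {feat.chrom!r}")
            if feat.end > self.assembly[feat.chrom]:
                raise ValueError("feature exceeds chromosome end")
            if feat.end - feat.start < self.fragment_length:
                raise ValueError("feature shorter than fragment_length")
            if not feat.name:
                feat.name = f"feat_{i + 1}"
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @classmethod
    def from_dict(cls, spec: Mapping) -> "SimConfig":
        assembly = GenomeAssembly(spec["assembly"])
        features = [PlantedFeature(**f) for f in spec.get("features", [])]
        genes = None
        if spec.get("genes"):
            genes = pd.DataFrame(
                spec["genes"], columns=["chrom", "start", "end", "strand", "name"]
            )
        return cls(
            assembly=assembly,
            features=features,
            genes=genes,
            background_depth=float(spec.get("background_depth", 1.0)),
            fragment_length=int(spec.get("fragment_length", 150)),
            rnase_h_efficiency={
                float(k): float(v) for k, v in spec.get("rnase_h_efficiency", {}).items()
            },
            blacklist=[tuple(b) for b in spec.get("blacklist", [])],
            nb_dispersion=spec.get("nb_dispersion"),
            seed=int(spec.get("seed", 0)),
        )


@dataclass
class SimTruth:
    """Expected per-strand intensities of every planted feature."""

    condition: str
    features: pd.DataFrame  # TRUTH_COLUMNS


def parse_condition(condition: str) -> tuple[str, float | None]:
    """'control' | 'drb' | 'trp' | 'rnase_h:<dose>' -> (kind, dose)."""
    if condition in ("control", "drb", "trp"):
        return condition, None
    if condition.startswith("rnase_h:"):
        return "rnase_h", float(condition.split(":", 1)[1])
    raise ValueError(f"unknown condition {condition!r}")


def expected_intensities(cfg: SimConfig, condition: str) -> list[tuple[float, float]]:
    """Expected (plus, minus) mean coverage of each feature under a condition.

    Background is not included; it adds on top on both strands.
    """
    kind, dose = parse_condition(condition)
    if kind == "rnase_h":
        if dose not in cfg.rnase_h_efficiency:
            raise ValueError(f"no efficiency configured for dose {dose}")
        eff = cfg.rnase_h_efficiency[dose]
    out = []
    for feat in cfg.features:
        displaced = feat.mean_depth
        paired = feat.mean_depth / feat.asymmetry_ratio
        if kind == "rnase_h":
            mid = (displaced + paired) / 2.0
            displaced = displaced - eff * (displaced - mid)
            paired = paired + eff * (mid - paired)
        elif kind == "drb" and not feat.retained_drb:
            displaced = paired = 0.0
        elif kind == "trp" and not feat.retained_trp:
            displaced = paired = 0.0
        if feat.displaced_strand == "+":
            out.append((displaced, paired))
        else:
            out.append((paired, displaced))
    return out


def _unit_streams(cfg: SimConfig) -> list[np.random.Generator]:
    n_units = 2 * len(cfg.assembly) + 2 * len(cfg.features)
    children = np.random.SeedSequence(cfg.seed).spawn(n_units)
    return [np.random.default_rng(c) for c in children]


def _draw_count(rng: np.random.Generator, lam: float, dispersion: float | None) -> int:
    if lam <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(lam))
    # gamma-poisson mixture with shape = dispersion (variance lam + lam^2/r)
    return int(rng.poisson(rng.gamma(dispersion, lam / dispersion)))


def simulate_condition(cfg: SimConfig, condition: str = "control") -> tuple[StrandedFragmentSet, SimTruth]:
    """Draw a stranded fragment set for one condition, with its truth table."""
    parse_condition(condition)  # validate early
    f = cfg.fragment_length
    rngs = _unit_streams(cfg)
    per_strand: dict[str, list[tuple[str, np.ndarray]]] = {"+": [], "-": []}
    unit = 0
    for chrom, length in cfg.assembly.items():
        for strand in ("+", "-"):
            rng = rngs[unit]
            unit += 1
            span = length - f
            if span < 0:
                continue
            lam = cfg.background_depth * length / f
            n = _draw_count(rng, lam, cfg.nb_dispersion)
            if n:
                starts = np.sort(rng.integers(0, span + 1, size=n))
                per_strand[strand].append((chrom, starts))
    intensities = expected_intensities(cfg, condition)
    for feat, (plus_int, minus_int) in zip(cfg.features, intensities):
        for strand, intensity in (("+", plus_int), ("-", minus_int)):
            rng = rngs[unit]
            unit += 1
            lam = intensity * (feat.end - feat.start) / f
            n = _draw_count(rng, lam, cfg.nb_dispersion)
            if n:
                starts = np.sort(rng.integers(feat.start, feat.end - f + 1, size=n))
                per_strand[strand].append((feat.chrom, starts))
    sets = {}
    for strand in ("+", "-"):
        if per_strand[strand]:
            chroms = np.concatenate(
                [np.full(len(s), c, dtype=object) for c, s in per_strand[strand]]
            )
            starts = np.concatenate([s for _, s in per_strand[strand]])
        else:
            chroms = np.array([], dtype=object)
            starts = np.array([], dtype=np.int64)
        sets[strand] = IntervalSet.from_arrays(
            chroms, starts, starts + f, strands=strand, assembly=cfg.assembly
        )
    truth = pd.DataFrame(
        [
            {
                "name": feat.name,
                "chrom": feat.chrom,
                "start": feat.start,
                "end": feat.end,
                "kind": feat.kind,
                "displaced_strand": feat.displaced_strand,
                "plus_depth": plus_int,
                "minus_depth": minus_int,
            }
            for feat, (plus_int, minus_int) in zip(cfg.features, intensities)
        ],
        columns=TRUTH_COLUMNS,
    )
    frags = StrandedFragmentSet(
        plus=sets["+"], minus=sets["-"], assembly=cfg.assembly, label=condition
    )
    return frags, SimTruth(condition=condition, features=truth)


def _safe_name(condition: str) -> str:
    return condition.replace(":", "_").replace(".", "p")


def emit_fixture_bundle(
    cfg: SimConfig,
    outdir: str | Path,
    conditions: Sequence[str] = ("control",),
    peak_pad: int = 500,
) -> dict[str, Path]:
    """Write a complete, byte-reproducible fixture directory.

    Contents: chrom.sizes, genes.bed, blacklist.bed, peaks.bed (union of
    planted loci and gene spans padded by ``peak_pad``), one fragment BED and
    one truth TSV per condition, and a manifest TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    cfg.assembly.to_file(paths["chrom_sizes"])

    paths["genes"] = outdir / "genes.bed"
    if cfg.genes is not None and len(cfg.genes):
        genes = IntervalSet(
            cfg.genes[["chrom", "start", "end", "strand", "name"]],
            assembly=cfg.assembly,
        )
        write_bed(genes, paths["genes"])
    else:
        paths["genes"].write_text("")

    paths["blacklist"] = outdir / "blacklist.bed"
    if cfg.blacklist:
        bl = IntervalSet.from_records(
            [(c, s, e) for c, s, e in cfg.blacklist], assembly=cfg.assembly
        )
        write_bed(bl, paths["blacklist"])
    else:
        paths["blacklist"].write_text("")

    peak_rows = [(f.chrom, f.start, f.end) for f in cfg.features]
    if cfg.genes is not None and len(cfg.genes):
        peak_rows += list(
            cfg.genes[["chrom", "start", "end"]].itertuples(index=False, name=None)
        )
    paths["peaks"] = outdir / "peaks.bed"
    if peak_rows:
        padded = [
            (c, max(0, s - peak_pad), min(cfg.assembly[c], e + peak_pad))
            for c, s, e in peak_rows
        ]
        peaks = merge_intervals(IntervalSet.from_records(padded, assembly=cfg.assembly))
        write_bed(peaks, paths["peaks"])
    else:
        paths["peaks"].write_text("")

    manifest_rows = []
    for condition in conditions:
        frags, truth = simulate_condition(cfg, condition)
        tag = _safe_name(condition)
        frag_path = outdir / f"frags_{tag}.bed"
        with open(frag_path, "w") as fh:
            for iset in (frags.plus, frags.minus):
                for row in iset.df.itertuples(index=False):
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t{row.strand}\n")
        truth_path = outdir / f"truth_{tag}.tsv"
        truth.features.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")
        _, dose = parse_condition(condition)
        manifest_rows.append(
            {
                "label": condition,
                "frags_path": frag_path.name,
                "truth_path": truth_path.name,
                "dose_or_time": "" if dose is None else format(dose, "g"),
            }
        )
        paths[f"frags:{condition}"] = frag_path
        paths[f"truth:{condition}"] = truth_path

    paths["manifest"] = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)
    return paths


@dataclass
class ScoreResult:
    sensitivity: float
    precision: float
    strand_accuracy: float
    precision_defined: bool
    n_calls: int
    n_truth_rloops: int


def score_calls(calls: pd.DataFrame, truth: SimTruth, assembly: GenomeAssembly) -> ScoreResult:
    """Compare calls against planted R-loops (bubbles count only as decoys).

    sensitivity: planted R-loops recovered by >= 1 bp call overlap.
    precision: calls overlapping any planted R-loop (undefined -> 0, flagged).
    strand_accuracy: recovered calls whose displaced strand matches the
    best-overlapping planted R-loop.
    """
    feats = truth.features
    if len(feats) == 0:
        raise ValueError("truth set is empty")
    rloops = feats[feats["kind"] == "rloop"]
    if len(rloops) == 0:
        raise ValueError("truth set contains no planted R-loops")
    from .intervals import overlap_lengths  # local import to avoid cycle noise

    rloop_iset = IntervalSet(
        rloops[["chrom", "start", "end"]], assembly=assembly, validate=False
    )
    n_truth = len(rloops)
    if len(calls) == 0:
        return ScoreResult(0.0, 0.0, 0.0, False, 0, n_truth)
    call_iset = IntervalSet(
        calls[["chrom", "start", "end"]], assembly=assembly, validate=False
    )
    recovered = overlap_lengths(rloop_iset, call_iset) > 0
    sensitivity = float(recovered.mean())
    # per-call best-overlap truth match (small n: quadratic scan per chrom)
    matched = 0
    strand_ok = 0
    for call in calls.itertuples(index=False):
        sub = rloops[rloops["chrom"] == call.chrom]
        ov = np.minimum(sub["end"].to_numpy(), call.end) - np.maximum(
            sub["start"].to_numpy(), call.start
        )
        if len(ov) == 0 or ov.max() <= 0:
            continue
        matched += 1
        best = sub.iloc[int(np.argmax(ov))]
        if best["displaced_strand"] == call.displaced_strand:
            strand_ok += 1
    precision = matched / len(calls)
    strand_accuracy = strand_ok / matched if matched else 0.0
    return ScoreResult(
        sensitivity=sensitivity,
        precision=precision,
        strand_accuracy=strand_accuracy,
        precision_defined=True,
        n_calls=len(calls),
        n_truth_rloops=n_truth,
    )
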