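"""Cross-condition comparison of R-loop calls: dose-response summaries and
the three-type classification under elongation-inhibitor treatments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, CategoryScheme, GeneModel, assign_categories
from .caller import CallerConfig
from .coverage import StrandedFragmentSet, bin_density
from .intervals import IntervalSet, overlap_lengths

TYPE_LABELS = ("I", "II", "III", "unclassified")


@dataclass
class ConditionResult:
    """Calls plus fragments for one experimental arm."""

    label: str
    calls: pd.DataFrame
    frags: StrandedFragmentSet
    config: CallerConfig | None = None

    @property
    def scale(self) -> float:
        """Reads-per-million factor."""
        size = self.frags.library_size
        if size == 0:
            raise ValueError(f"condition {self.label!r} has an empty library")
        return 1e6 / size


def _calls_iset(cond: ConditionResult) -> IntervalSet:
    return IntervalSet(
        cond.calls[["chrom", "start", "end"]], assembly=cond.frags.assembly, validate=False
    )


def _check_configs(*conditions: ConditionResult) -> None:
    configs = [c.config for c in conditions if c.config is not None]
    for cfg in configs[1:]:
        if cfg != configs[0]:
            raise ValueError("conditions were called with different caller configs")


def _scaled_region_density(cond: ConditionResult, regions: IntervalSet) -> np.ndarray:
    """Reads-per-million-scaled |plus - minus| mean density over fixed regions."""
    bd = bin_density(cond.frags, regions)
    return (
        np.abs(bd["plus_density"].to_numpy() - bd["minus_density"].to_numpy()) * cond.scale
    )


def classify_types(
    control: ConditionResult,
    drb: ConditionResult,
    trp: ConditionResult,
    mode: str = "overlap",
    density_ratio: float = 0.5,
) -> pd.DataFrame:
    """Label every control R-loop by its response to the two inhibitors.

    type I: retained under DRB, lost under triptolide. type II: lost under
    both. type III: retained under both. The remaining combination (lost
    under DRB, retained under triptolide) is surfaced as 'unclassified'.

    mode='overlap' binarizes retention as >= 1 bp overlap with any call in
    the treated condition. mode='density' instead requires the treated
    RPM-scaled strand-difference density over the control region to stay at
    >= density_ratio of the control's.
    """
    if mode not in ("overlap", "density"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_configs(control, drb, trp)
    if len(control.calls) == 0:
        out = control.calls.copy()
        out["type"] = pd.Series(dtype=object)
        return out
    # reorder calls into canonical assembly order so rows align with the
    # IntervalSet built from them
    order_map = control.frags.assembly.order_map
    out = (
        control.calls.assign(_k=control.calls["chrom"].map(order_map))
        .sort_values(["_k", "start", "end"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    regions = IntervalSet(
        out[["chrom", "start", "end"]], assembly=control.frags.assembly, validate=False
    )
    if mode == "overlap":
        retained_drb = overlap_lengths(regions, _calls_iset(drb)) > 0
        retained_trp = overlap_lengths(regions, _calls_iset(trp)) > 0
    else:
        base = _scaled_region_density(control, regions)
        retained_drb = _scaled_region_density(drb, regions) >= density_ratio * base
        retained_trp = _scaled_region_density(trp, regions) >= density_ratio * base
    rtype = np.full(len(out), "unclassified", dtype=object)
    rtype[retained_drb & ~retained_trp] = "I"
    rtype[~retained_drb & ~retained_trp] = "II"
    rtype[retained_drb & retained_trp] = "III"
    out["type"] = rtype
    return out


def dose_response(
    conditions: Sequence[ConditionResult],
    genes: GeneModel,
    scheme: CategoryScheme | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per condition x genomic category: call count and scaled mean density.

    Density is the RPM-scaled mean |plus - minus| coverage measured on the
    FIRST condition's call regions (a fixed reference panel, so conditions
    are compared on identical loci); call counts come from each condition's
    own calls. The flags frame reports, per category, whether density and
    count are non-increasing across the given condition order.
    """
    if len(conditions) < 1:
        raise ValueError("need at least one condition")
    _check_configs(*conditions)
    reference = conditions[0]
    if len(reference.calls) == 0:
        raise ValueError("reference condition has no calls")
    regions = _calls_iset(reference)
    region_cats = assign_categories(
        regions, genes, scheme, assembly=reference.frags.assembly
    ).to_numpy()
    rows = []
    for cond in conditions:
        dens = _scaled_region_density(cond, regions)
        if len(cond.calls):
            own_cats = assign_categories(
                cond.calls, genes, scheme, assembly=cond.frags.assembly
            ).to_numpy()
        else:
            own_cats = np.array([], dtype=object)
        for cat in CATEGORIES:
            sel = region_cats == cat
            rows.append(
                {
                    "condition": cond.label,
                    "category": cat,
                    "n_calls": int((own_cats == cat).sum()),
                    "mean_density_scaled": float(dens[sel].mean()) if sel.any() else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    flags = []
    for cat in CATEGORIES:
        sub = table[table["category"] == cat]
        dens_seq = sub["mean_density_scaled"].to_numpy()
        count_seq = sub["n_calls"].to_numpy()
        flags.append(
            {
                "category": cat,
                "density_nonincreasing": bool(np.all(np.diff(dens_seq) <= 0))
                if not np.isnan(dens_seq).any()
                else False,
                "count_nonincreasing": bool(np.all(np.diff(count_seq) <= 0)),
            }
        )
    return table, pd.DataFrame(flags)


def timecourse_summary(
    conditions: Sequence[ConditionResult],
    genes: GeneModel,
    scheme: CategoryScheme | None = None,
) -> pd.DataFrame:
    """Per condition, the percentage of its calls in each genomic category.

    Percentages sum to 100 per condition (0 across the board for a condition
    without calls).
    """
    if len(conditions) < 1:
        raise ValueError("need at least one condition")
    rows = []
    for cond in conditions:
        if len(cond.calls):
            cats = assign_categories(
                cond.calls, genes, scheme, assembly=cond.frags.assembly
            )
            counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)
            pct = counts / counts.sum() * 100.0
        else:
            pct = pd.Series(0.0, index=list(CATEGORIES))
        for cat in CATEGORIES:
            rows.append(
                {"condition": cond.label, "category": cat, "percent": float(pct[cat])}
            )
    return pd.DataFrame(rows)
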