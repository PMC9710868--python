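from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import strandloop as sl


@pytest.fixture
def asm_small() -> sl.GenomeAssembly:
    return sl.GenomeAssembly({"chrT": 1200, "chrU": 400})


@pytest.fixture
def asm_100k() -> sl.GenomeAssembly:
    return sl.GenomeAssembly({"chrA": 60_000, "chrB": 40_000})


def make_gene_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])


@pytest.fixture
def planted_sim() -> tuple[sl.SimConfig, sl.IntervalSet]:
    """Small simulation: one R-loop + one bubble, with matching peaks."""
    asm = sl.GenomeAssembly({"chr1": 200_000})
    feats = [
        sl.PlantedFeature("chr1", 50_000, 51_000, "rloop", "+", 4.0, 40.0, name="r1"),
        sl.PlantedFeature("chr1", 120_000, 121_000, "bubble", "+", 1.0, 40.0, name="b1"),
    ]
    cfg = sl.SimConfig(
        assembly=asm,
        features=feats,
        background_depth=1.0,
        seed=11,
        rnase_h_efficiency={0: 0.0, 50: 0.3, 100: 0.5, 150: 0.7, 999: 1.0},
    )
    peaks = sl.IntervalSet.from_records(
        [("chr1", 49_500, 51_500), ("chr1", 119_500, 121_500)], assembly=asm
    )
    return cfg, peaks
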