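"""Independent brute-force reimplementations used as oracles.

Everything here deliberately avoids the package's vectorized code paths:
coverage by per-bp accumulation, binomial tails by direct pmf summation,
BH by the textbook double pass, merging by a plain scan.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def brute_binom_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0=0.5 by summing pmf over both tails."""
    if n == 0:
        return 1.0
    m = min(k, n - k)
    total = 0.0
    for i in range(0, m + 1):
        total += binom.pmf(i, n, 0.5)
    for i in range(n - m, n + 1):
        if i > m:  # avoid double counting the centre when k == n - k
            total += binom.pmf(i, n, 0.5)
    return min(1.0, total)


def brute_bh(pvals):
    """Textbook BH step-up via explicit min-over-larger-ranks."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = float("inf")
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        q[i] = min(running, 1.0)
    return q


def brute_coverage(fragments, length):
    """Per-bp coverage by looping over fragments."""
    cov = np.zeros(length, dtype=np.int64)
    for start, end in fragments:
        cov[start:end] += 1
    return cov


def brute_call_pipeline(
    plus_frags,
    minus_frags,
    peaks,
    blacklist,
    chrom_lengths,
    *,
    bin_width=500,
    bin_step=250,
    min_peak_overlap=250,
    min_density=20.0,
    min_abs_log2_ratio=1.0,
    max_q=0.05,
    pseudocount=1.0,
    merge_gap=0,
):
    """Single-pass reimplementation of the whole caller on a toy genome.

    Fragment/peak/blacklist inputs are {chrom: [(start, end), ...]} dicts.
    Returns (calls, bin_stats) where calls is a list of dicts and bin_stats a
    list of per-candidate-bin dicts in genome order.
    """
    bins = []
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            s, e = pos, min(pos + bin_width, length)
            bins.append((chrom, s, e))
            pos += bin_step
    # blacklist: drop any bin with >= 1 bp overlap
    kept = []
    for chrom, s, e in bins:
        hit = any(
            min(e, be) - max(s, bs) > 0 for bs, be in blacklist.get(chrom, [])
        )
        if not hit:
            kept.append((chrom, s, e))
    # peak filter against the union of peaks
    candidates = []
    for chrom, s, e in kept:
        cov = np.zeros(e - s, dtype=bool)
        for ps, pe in peaks.get(chrom, []):
            lo, hi = max(s, ps), min(e, pe)
            if hi > lo:
                cov[lo - s : hi - s] = True
        if int(cov.sum()) >= min_peak_overlap:
            candidates.append((chrom, s, e))
    # per-bin stats
    cov_cache = {}
    for chrom, length in chrom_lengths.items():
        cov_cache[chrom] = (
            brute_coverage(plus_frags.get(chrom, []), length),
            brute_coverage(minus_frags.get(chrom, []), length),
        )
    stats = []
    for chrom, s, e in candidates:
        pcov, mcov = cov_cache[chrom]
        pd_ = float(pcov[s:e].sum()) / (e - s)
        md_ = float(mcov[s:e].sum()) / (e - s)
        pc = sum(1 for fs, fe in plus_frags.get(chrom, []) if fs < e and fe > s)
        mc = sum(1 for fs, fe in minus_frags.get(chrom, []) if fs < e and fe > s)
        log2r = np.log2(pd_ + pseudocount) - np.log2(md_ + pseudocount)
        p = brute_binom_two_sided(pc, pc + mc)
        stats.append(
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "plus_density": pd_,
                "minus_density": md_,
                "plus_count": pc,
                "minus_count": mc,
                "log2_ratio": float(log2r),
                "p_value": p,
            }
        )
    qvals = brute_bh([b["p_value"] for b in stats])
    for b, q in zip(stats, qvals):
        b["q_value"] = q
    # thresholds: density strictly >, |log2| >=, q <=
    significant = [
        b
        for b in stats
        if (b["plus_density"] + b["minus_density"]) / 2.0 > min_density
        and abs(b["log2_ratio"]) >= min_abs_log2_ratio
        and b["q_value"] <= max_q
    ]
    # merge same-direction overlapping/book-ended bins by a plain scan
    calls = []
    for direction in ("+", "-"):
        members = [
            b
            for b in significant
            if (b["log2_ratio"] >= 0) == (direction == "+")
        ]
        members.sort(key=lambda b: (b["chrom"], b["start"], b["end"]))
        current = None
        group = []

        def flush():
            if group:
                calls.append(
                    {
                        "chrom": group[0]["chrom"],
                        "start": min(b["start"] for b in group),
                        "end": max(b["end"] for b in group),
                        "displaced_strand": direction,
                        "density": float(
                            np.mean(
                                [abs(b["plus_density"] - b["minus_density"]) for b in group]
                            )
                        ),
                        "n_bins": len(group),
                        "min_q": min(b["q_value"] for b in group),
                    }
                )

        for b in members:
            if (
                current is not None
                and b["chrom"] == current["chrom"]
                and b["start"] <= current["end"] + merge_gap
            ):
                group.append(b)
                current = {
                    "chrom": current["chrom"],
                    "end": max(current["end"], b["end"]),
                }
            else:
                flush()
                group = [b]
                current = {"chrom": b["chrom"], "end": b["end"]}
        flush()
    calls.sort(key=lambda c: (c["chrom"], c["start"], c["end"]))
    return calls, stats
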