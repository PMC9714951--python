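"""Independent brute-force oracles: plain-Python per-probe loops.

These deliberately avoid every vectorized code path of the package so that
set-equality against them is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math


def ts_hyper_probes(df, tumors, normals, normal_max=0.2, delta=0.4):
    """Per-probe evaluation of the two TS-Hyper clauses."""
    called = set()
    for probe in df.index:
        row = df.loc[probe]
        n_vals = [row[s] for s in normals]
        t_vals = [row[s] for s in tumors]
        clause1 = all(v <= normal_max for v in n_vals)
        clause2 = (sum(t_vals) / len(t_vals)) - (sum(n_vals) / len(n_vals)) >= delta
        if clause1 and clause2:
            called.add(probe)
    return called


def panel_candidates(df, regions, positives, negatives, high_beta=0.5,
                     low_beta=0.2, min_high_count=None):
    """Island probes passing the high/low panel clauses."""
    if min_high_count is None:
        min_high_count = len(positives)
    keep = set()
    for probe in df.index:
        if regions[probe] != "island":
            continue
        row = df.loc[probe]
        n_high = sum(1 for s in positives if row[s] > high_beta)
        all_low = all(row[s] < low_beta for s in negatives)
        if n_high >= min_high_count and all_low:
            keep.add(probe)
    return keep


def normal_unmethylated(df, regions, normals, max_beta=0.2):
    keep = set()
    for probe in df.index:
        if regions[probe] != "island":
            continue
        if all(df.loc[probe, s] < max_beta for s in normals):
            keep.add(probe)
    return keep


def burden_count(df, sample, reference, high_beta=0.5):
    return sum(1 for probe in reference if df.loc[probe, sample] > high_beta)


def masked_cell_count(p_df, alpha):
    count = 0
    for probe in p_df.index:
        for sample in p_df.columns:
            if p_df.loc[probe, sample] >= alpha:
                count += 1
    return count


def complete_probes(df, core_samples):
    keep = set()
    for probe in df.index:
        if all(not math.isnan(df.loc[probe, s]) for s in core_samples):
            keep.add(probe)
    return keep


def top_sd_probes(df, k):
    """Exhaustive sort by sample SD (ddof=1), ties by probe ID."""
    stats = []
    for probe in df.index:
        vals = [df.loc[probe, s] for s in df.columns]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        stats.append((-math.sqrt(var), probe))
    stats.sort()
    return [probe for _, probe in stats[:k]]
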