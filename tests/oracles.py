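"""Independent brute-force oracles, deliberately naive.

Pure-python dictionary counting and hand sums-of-squares formulas, sharing
no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import product


def brute_entropies(seq, states):
    """Counts, transition probabilities, visit law, Ht and Hs by enumeration."""
    n = {(a, b): 0 for a in states for b in states}
    for a, b in zip(seq, seq[1:]):
        n[(a, b)] += 1
    P = {}
    for a in states:
        row_total = sum(n[(a, b)] for b in states)
        for b in states:
            P[(a, b)] = n[(a, b)] / row_total if row_total else 0.0
    pi = {s: seq.count(s) / len(seq) for s in states} if seq else None
    ht = hs = None
    if pi is not None:
        ht = 0.0
        for a in states:
            row_h = -sum(
                P[(a, b)] * math.log2(P[(a, b)]) for b in states if P[(a, b)] > 0
            )
            ht += pi[a] * row_h
        hs = -sum(pi[s] * math.log2(pi[s]) for s in states if pi[s] > 0)
    return n, P, pi, ht, hs


def balanced_two_way_ss(values):
    """Hand SS decomposition for a balanced two-factor layout.

    ``values`` maps (level_a, level_b) -> list of replicates (equal lengths).
    Returns dict of SS and df per effect plus F statistics.
    """
    a_levels = sorted({k[0] for k in values})
    b_levels = sorted({k[1] for k in values})
    n = len(next(iter(values.values())))
    assert all(len(v) == n for v in values.values()), "oracle needs balance"
    all_vals = [y for v in values.values() for y in v]
    gm = sum(all_vals) / len(all_vals)
    mean_a = {
        a: sum(y for b in b_levels for y in values[(a, b)]) / (n * len(b_levels))
        for a in a_levels
    }
    mean_b = {
        b: sum(y for a in a_levels for y in values[(a, b)]) / (n * len(a_levels))
        for b in b_levels
    }
    mean_ab = {k: sum(v) / n for k, v in values.items()}
    ss_a = n * len(b_levels) * sum((mean_a[a] - gm) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - gm) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (mean_ab[(a, b)] - mean_a[a] - mean_b[b] + gm) ** 2
        for a, b in product(a_levels, b_levels)
    )
    ss_e = sum(
        (y - mean_ab[k]) ** 2 for k, v in values.items() for y in v
    )
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(all_vals) - len(a_levels) * len(b_levels)
    ms_e = ss_e / df_e if df_e else float("nan")
    out = {
        "ss": {"a": ss_a, "b": ss_b, "ab": ss_ab, "resid": ss_e},
        "df": {"a": df_a, "b": df_b, "ab": df_ab, "resid": df_e},
    }
    out["F"] = {
        k: (out["ss"][k] / out["df"][k]) / ms_e if ms_e > 0 else float("nan")
        for k in ("a", "b", "ab")
    }
    out["eta_p2"] = {
        k: out["ss"][k] / (out["ss"][k] + ss_e) if (out["ss"][k] + ss_e) > 0 else 0.0
        for k in ("a", "b", "ab")
    }
    return out
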