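"""Independent brute-force oracles, coded from the definitions only.

These deliberately avoid the package's vectorised implementations: plain
Python loops, exhaustive DP, explicit risk-set tabulation and grid search.
"""

from __future__ import annotations

import math


def glocal_score_oracle(read: str, ref: str, match: int = 2, mismatch: int = 3,
                        gap_open: int = 1, gap_extend: int = 1,
                        gap_bar: int = 10) -> float:
    """Exhaustive affine-gap DP: global in read, free ends in reference.

    A gap of length L costs gap_open + gap_extend * L; gaps need at least
    gap_bar read bases on each side; N never matches.  Returns the best score
    over all end positions (alignments cannot end in a reference gap).
    """
    n, m = len(read), len(ref)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0.0
    for i in range(1, n + 1):
        allow_ins = (i - 1 >= gap_bar) and (n - i >= gap_bar)
        allow_del = (i >= gap_bar) and (n - i >= gap_bar)
        for j in range(m + 1):
            if j >= 1:
                a, b = read[i - 1], ref[j - 1]
                s = match if (a == b and a != "N" and b != "N") else -mismatch
                prev = max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1])
                if prev > NEG:
                    M[i][j] = prev + s
            if allow_ins:
                open_from = max(M[i - 1][j], I[i - 1][j], D[i - 1][j]) - gap_open
                best = max(open_from, I[i - 1][j])
                if best > NEG:
                    I[i][j] = best - gap_extend
            if allow_del and j >= 1:
                open_from = max(M[i][j - 1], I[i][j - 1]) - gap_open
                best = max(open_from, D[i][j - 1])
                if best > NEG:
                    D[i][j] = best - gap_extend
    return max(max(M[n]), max(I[n]))


def ssgsea_walk_oracle(values: dict[str, float], signature: set[str],
                       alpha: float = 0.25) -> float:
    """Single-sample GSEA running-sum score for one sample, step by step."""
    order = sorted(values, key=lambda g: (-values[g], g))
    n = len(order)
    in_set = [g in signature for g in order]
    n_in = sum(in_set)
    assert 0 < n_in < n
    sum_w = sum((n - pos) ** alpha for pos, flag in enumerate(in_set) if flag)
    cum_in = cum_out = score = 0.0
    for pos, flag in enumerate(in_set):
        if flag:
            cum_in += (n - pos) ** alpha / sum_w
        else:
            cum_out += 1.0 / (n - n_in)
        score += cum_in - cum_out
    return score


def logrank_oracle(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by explicit risk-set tabulation."""
    data = [(t, e, 0) for t, e in zip(times_a, events_a)]
    data += [(t, e, 1) for t, e in zip(times_b, events_b)]
    event_times = sorted({t for t, e, _ in data if e == 1})
    observed_a = expected_a = variance = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in data if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d_a = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 0)
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0
    return (observed_a - expected_a) ** 2 / variance


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Cox partial log-likelihood for a single covariate, no tied event times."""
    ll = 0.0
    for i, (t, e) in enumerate(zip(times, events)):
        if not e:
            continue
        risk = [math.exp(beta * x[j]) for j, tj in enumerate(times) if tj >= t]
        ll += beta * x[i] - math.log(sum(risk))
    return ll


def cox_grid_maximizer(times, events, x, lo: float = -5.0, hi: float = 5.0,
                       rounds: int = 6, points: int = 201) -> float:
    """Iteratively refined grid search maximising the partial likelihood."""
    best = 0.0
    for _ in range(rounds):
        grid = [lo + (hi - lo) * k / (points - 1) for k in range(points)]
        vals = [cox_partial_loglik(b, times, events, x) for b in grid]
        best = grid[vals.index(max(vals))]
        span = (hi - lo) / (points - 1)
        lo, hi = best - 2 * span, best + 2 * span
    return best
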