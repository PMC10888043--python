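"""Independent brute-force oracles used by the test suite.

These deliberately re-derive statistics from first principles (pair
enumeration, per-event-time 2x2 tables) and share no code with the package.
"""

import numpy as np
from scipy.stats import chi2


def brute_force_concordance(times, events, risks):
    """Harrell's C by exhaustive ordered-pair enumeration.

    A pair (i, j) is comparable when subject i has an event and either
    T_i < T_j, or T_i == T_j with j censored. Tied-time pairs where both had
    events are not comparable. Higher risk should predict earlier failure;
    tied risks score 0.5. Returns None when no pair is comparable.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risks = np.asarray(risks, float)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            comparable = (times[i] < times[j]) or (
                times[i] == times[j] and events[j] == 0)
            if not comparable:
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return None if den == 0 else num / den


def hand_log_rank(times_a, events_a, times_b, events_b):
    """Two-group log-rank statistic from per-event-time 2x2 tables."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    all_times = np.unique(np.concatenate([
        times_a[events_a == 1], times_b[events_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n1 = np.sum(times_a >= t)
        n2 = np.sum(times_b >= t)
        d1 = np.sum((times_a == t) & (events_a == 1))
        d2 = np.sum((times_b == t) & (events_b == 1))
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, df=1))
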