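"""Independent brute-force oracles used to validate the optimised code paths.

These deliberately re-derive results with the simplest possible algorithms
(full dynamic programmes, linear scans, explicit loops) and share no code
with the implementations they check.
"""

from __future__ import annotations

import math


def brute_viterbi(ev_means, mu, sig, log_m, log_i, log_s):
    """Exhaustive O(E*K^2) Viterbi over the match/insert/skip profile HMM.

    Returns (assignment of each event to a k-mer, best log score).  The
    skip move is priced per skipped k-mer, including leading and trailing
    skips, exactly as in the aligner's model.
    """
    n_events, n_kmers = len(ev_means), len(mu)
    NEG = -math.inf
    v = [[NEG] * n_kmers for _ in range(n_events)]
    back = [[None] * n_kmers for _ in range(n_events)]

    def emis(i, j):
        z = (ev_means[i] - mu[j]) / sig[j]
        return -0.5 * z * z - math.log(sig[j])

    for j in range(n_kmers):
        v[0][j] = emis(0, j) + j * log_s
    for i in range(1, n_events):
        for j in range(n_kmers):
            best, arg = NEG, None
            # match with any number of preceding skips
            for jp in range(j):
                cand = v[i - 1][jp] + log_m + (j - 1 - jp) * log_s
                if cand > best:
                    best, arg = cand, ("m", jp)
            cand = v[i - 1][j] + log_i
            if cand > best:
                best, arg = cand, ("i", j)
            v[i][j] = emis(i, j) + best
            back[i][j] = arg
    best, bestj = NEG, None
    for j in range(n_kmers):
        cand = v[n_events - 1][j] + (n_kmers - 1 - j) * log_s
        if cand > best:
            best, bestj = cand, j
    assign = [0] * n_events
    j = bestj
    for i in range(n_events - 1, 0, -1):
        assign[i] = j
        j = back[i][j][1]
    assign[0] = j
    return assign, best


def brute_confusion(probs, truths, threshold):
    """Explicit-loop confusion counts."""
    tp = fp = tn = fn = 0
    for p, t in zip(probs, truths):
        call = p > threshold
        if call and t:
            tp += 1
        elif call and not t:
            fp += 1
        elif not call and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_nearest_origin_distance(call_start, call_end, origins):
    """Signed midpoint distance to the nearest origin interval, linear scan."""
    mid = (call_start + call_end) / 2.0
    best = None
    for start, end in origins:
        if call_end > start and call_start < end:
            return 0.0
        if mid < start:
            signed = start - mid
        else:
            signed = -(mid - (end - 1))
        if best is None or abs(signed) < abs(best):
            best = signed
    return float(best)


def brute_merge_runs(positions, selected, gap_tolerance, min_length):
    """Explicit run construction over selected positions with gap closure."""
    runs = []
    current = None
    for pos, sel in zip(positions, selected):
        if not sel:
            continue
        if current is None:
            current = [pos, pos]
        elif pos - current[1] <= gap_tolerance:
            current[1] = pos
        else:
            runs.append(tuple(current))
            current = [pos, pos]
    if current is not None:
        runs.append(tuple(current))
    return [(a, b + 1) for a, b in runs if (b + 1) - a >= min_length]
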