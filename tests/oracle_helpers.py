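"""Independent brute-force oracles used by the test suite.

Everything here is coded from the rule definitions, deliberately not
sharing any code path with the package implementations it checks.
"""

from __future__ import annotations

import math


def eight_type_oracle(pn_call: str, cn_call: str, delta_cp: float, thresh: float = 0.1):
    """Trajectory type by literal case analysis of the decision table."""
    if pn_call == "hyper":
        if cn_call == "hyper":
            if delta_cp > thresh:
                return 1
            return 2
        if cn_call == "none":
            return 3
        if cn_call == "hypo":
            return 4
    if pn_call == "hypo":
        if cn_call == "hypo":
            if delta_cp < -thresh:
                return 5
            return 6
        if cn_call == "none":
            return 7
        if cn_call == "hyper":
            return 8
    return None


def fisher_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """One-sided Fisher p = P(overlap >= k) by exact rational enumeration."""
    denom = math.comb(N, n)
    tail = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return tail / denom


def bh_oracle(pvals):
    """Step-up BH applied literally to the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
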