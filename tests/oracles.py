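"""Independent brute-force reference implementations used only by tests.

These are deliberately literal transcriptions of the defining formulas —
plain Python loops, ``math`` arithmetic, no shared code with the package —
so that agreement between the two routes is meaningful.
"""

import math


def brute_hill(p, q):
    """Hill number by direct summation of p_i^q."""
    p = [x for x in p if x > 0]
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x ** q for x in p) ** (1.0 / (1.0 - q))


def brute_decompose(columns, q):
    """Equal-weight alpha/gamma/beta for N communities, by direct summation."""
    N = len(columns)
    S = len(columns[0])
    pooled = [sum(col[i] for col in columns) / N for i in range(S)]
    gamma = brute_hill(pooled, q)
    weighted = [col[i] / N for col in columns for i in range(S) if col[i] > 0]
    if q == 1:
        alpha = math.exp(-sum(w * math.log(w) for w in weighted)) / N
    else:
        alpha = sum(w ** q for w in weighted) ** (1.0 / (1.0 - q)) / N
    return alpha, gamma, gamma / alpha


def brute_local(beta, N, q):
    if q == 1:
        return math.log(beta) / math.log(N)
    return (beta ** (1.0 - q) - 1.0) / (N ** (1.0 - q) - 1.0)


def brute_regional(beta, N, q):
    if q == 1:
        return math.log(beta) / math.log(N)
    return (beta ** (q - 1.0) - 1.0) / (N ** (q - 1.0) - 1.0)
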