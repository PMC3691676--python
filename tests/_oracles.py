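"""Independent small-scale oracles used by the test suite."""

import itertools


def brute_force_enumeration(i, k, n, N, span):
    """Exact Pr(X(k) - X(i) <= span) by enumerating all N**n draws."""
    count = 0
    for draw in itertools.product(range(1, N + 1), repeat=n):
        s = sorted(draw)
        if s[k - 1] - s[i - 1] <= span:
            count += 1
    return count / N**n
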