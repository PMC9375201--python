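"""Brute-force oracles shared across test modules."""

import itertools


def all_partitions(n):
    """Every set partition of n items as a restricted-growth label vector."""
    def grow(prefix):
        if len(prefix) == n:
            yield list(prefix)
            return
        top = max(prefix, default=-1)
        for c in range(top + 2):
            yield from grow(prefix + [c])
    yield from grow([])


def brute_force_ari(a, b):
    """Pair-counting ARI: agreement over the C(n,2) item pairs."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n00 += (not sa) and (not sb)
        n10 += sa and (not sb)
        n01 += (not sa) and sb
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom
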