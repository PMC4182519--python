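"""Independent brute-force oracles used to cross-check the vectorized engine.

Everything here works household by household in exact rational arithmetic,
deliberately sharing no code with the package internals.
"""

from fractions import Fraction


def af_bruteforce(g0, weights, s, k, inclusive=True):
    """Per-household enumeration of H, A, M0, censored headcounts, contributions.

    All arithmetic in Fractions; floats are converted exactly.
    """
    weights = [Fraction(w) for w in weights]
    k = Fraction(k)
    n = len(g0)
    m = len(weights)
    sw = [Fraction(float(x)) for x in s]
    c = [
        sum((weights[j] for j in range(m) if g0[i][j]), Fraction(0))
        for i in range(n)
    ]
    poor = [(ci >= k) if inclusive else (ci > k) for ci in c]
    stot = sum(sw, Fraction(0))
    h = sum((sw[i] for i in range(n) if poor[i]), Fraction(0)) / stot
    m0 = sum((sw[i] * c[i] for i in range(n) if poor[i]), Fraction(0)) / stot
    a = m0 / h if h > 0 else Fraction(0)
    ch = [
        sum((sw[i] for i in range(n) if poor[i] and g0[i][j]), Fraction(0)) / stot
        for j in range(m)
    ]
    contrib = [weights[j] * ch[j] / m0 for j in range(m)] if m0 > 0 else None
    return {
        "H": float(h),
        "A": float(a),
        "M0": float(m0),
        "CH": [float(x) for x in ch],
        "contrib": None if contrib is None else [float(x) for x in contrib],
    }


def headcount_at_k(g0, weights, s, k, inclusive=True):
    """Brute-force weighted headcount at one poverty cut-off."""
    return af_bruteforce(g0, weights, s, k, inclusive)["H"]


def quantile_scan(values, weights, q):
    """Sort-and-scan weighted quantile: smallest v with cum weight >= q."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc / total >= q:
            return v
    return pairs[-1][0]
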